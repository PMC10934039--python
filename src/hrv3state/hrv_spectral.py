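"""Maximum-entropy (Burg autoregressive) spectral HRV estimation.

Short-window frequency-domain HRV: an AR model is fitted to each mean-removed
30-s tachogram window by the Burg lattice recursion (the maximum entropy
method), the one-sided AR power spectral density is evaluated on a dense
frequency grid, and the low-frequency (0.04-0.15 Hz) and high-frequency
(0.15-0.4 Hz) band powers are integrated. Windows are stepped every 2 s so
the LF, HF, LF/HF and heart-rate trends track autonomic state changes on the
time scale of a short behavioural paradigm, where Fourier periodograms would
need several minutes of stationary data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ModelError, ValidationError
from .signal_io import Tachogram

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
DEFAULT_ORDER = 16
DEFAULT_WINDOW_S = 30.0
DEFAULT_STEP_S = 2.0
N_FREQS = 1024


@dataclass
class ARModel:
    """Autoregressive model x_t = sum_k coefficients[k] x_{t-k} + e_t.

    ``noise_var`` is the innovation variance (ms^2 for R-R input);
    ``reflection`` holds the Burg reflection coefficients, all in (-1, 1)
    for a stable model.
    """

    order: int
    coefficients: np.ndarray
    noise_var: float
    reflection: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.reflection = np.asarray(self.reflection, dtype=float)
        if self.noise_var < 0:
            raise ValidationError("innovation variance cannot be negative")

    @property
    def stable(self) -> bool:
        # Burg with all reflection coefficients in (-1, 1) is stable by
        # construction; the root check (with a tolerance for the numerical
        # error of root-finding near the unit circle) covers hand-built models
        if self.reflection.size:
            return bool(np.all(np.abs(self.reflection) < 1.0))
        if self.coefficients.size == 0:
            return True
        roots = np.roots(np.concatenate(([1.0], -self.coefficients)))
        return bool(np.all(np.abs(roots) < 1.0 + 1e-6))


@dataclass
class SpectralFrame:
    """One-sided PSD (ms^2/Hz) of a single analysis window ending at ``t_end`` s."""

    t_end: float
    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(self.psd < 0):
            raise ValidationError("PSD must be non-negative")


@dataclass
class HRVTrend:
    """LF/HF band powers (ms^2), their ratio and heart rate (bpm), sampled every step.

    ``lfhf`` is NaN for frames where HF power is zero.
    """

    t: np.ndarray
    lf: np.ndarray
    hf: np.ndarray
    lfhf: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "lf", "hf", "lfhf", "hr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def __len__(self) -> int:
        return self.t.size

    def slice(self, mask: np.ndarray) -> "HRVTrend":
        return HRVTrend(self.t[mask], self.lf[mask], self.hf[mask],
                        self.lfhf[mask], self.hr[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "lf_ms2": self.lf, "hf_ms2": self.hf,
             "lf_hf": self.lfhf, "hr_bpm": self.hr}
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        # missing LF/HF written as empty cells
        self.to_frame().to_csv(path, index=False, na_rep="")


def burg_ar(segment: np.ndarray, order: int) -> ARModel:
    """Fit an AR model by the Burg lattice recursion (maximum entropy method).

    The segment mean is subtracted internally. Reflection coefficients are
    chosen to minimise the sum of forward and backward prediction error
    power at each lattice stage, which keeps them in (-1, 1) and the model
    stable. A constant segment yields a zero-variance model rather than an
    error.
    """
    x = np.asarray(segment, dtype=float)
    if order < 1:
        raise ValidationError(f"AR order must be >= 1, got {order}")
    if x.size <= order:
        raise InsufficientDataError(
            f"segment length {x.size} must exceed AR order {order}"
        )
    x = x - np.mean(x)
    energy = float(np.dot(x, x)) / x.size
    if energy <= 1e-30:
        return ARModel(order=order, coefficients=np.zeros(order), noise_var=0.0,
                       reflection=np.zeros(order))

    f = x.copy()  # forward prediction errors
    b = x.copy()  # backward prediction errors
    a = np.zeros(0)
    refl = np.zeros(order)
    e = energy
    for m in range(1, order + 1):
        ff = f[1:]
        bb = b[:-1]
        den = float(np.dot(ff, ff) + np.dot(bb, bb))
        k = 0.0 if den <= 1e-300 else -2.0 * float(np.dot(ff, bb)) / den
        refl[m - 1] = k
        # Levinson-Durbin order update of the error-filter coefficients
        a = np.concatenate((a + k * a[::-1], [k]))
        e *= 1.0 - k * k
        f, b = ff + k * bb, bb + k * ff
    # error filter A(z) = 1 + sum a_k z^-k  ->  prediction coefficients -a
    return ARModel(order=order, coefficients=-a, noise_var=max(e, 0.0),
                   reflection=refl)


def refined_freq_grid(model: ARModel, rate: float, n_base: int = N_FREQS) -> np.ndarray:
    """Uniform [0, rate/2] grid densified around the model's spectral peaks.

    An AR model of a nearly deterministic oscillation places poles very close
    to the unit circle, producing Lorentzian peaks whose half-width
    (1 - |pole|)/(pi dt) Hz can be far below any uniform grid spacing; their
    finite power is then misintegrated by a trapezoid rule. Log-spaced offsets
    around each pole frequency, from a hundredth of the half-width out to the
    full Nyquist range, make the trapezoidal band integrals accurate for
    arbitrarily sharp peaks.
    """
    nyq = rate / 2.0
    freqs = np.linspace(0.0, nyq, n_base)
    if model.coefficients.size == 0 or model.noise_var == 0.0:
        return freqs
    roots = np.roots(np.concatenate(([1.0], -model.coefficients)))
    dt = 1.0 / rate
    extra = []
    for r in roots:
        mag = abs(r)
        if mag < 0.5:  # broad feature, base grid suffices
            continue
        f0 = abs(np.angle(r)) / (2.0 * np.pi * dt)
        if not (0.0 <= f0 <= nyq):
            continue
        half_width = max((1.0 - mag) / (np.pi * dt), 1e-18)
        hi = max(nyq, 10.0 * half_width)
        offsets = half_width * np.logspace(-2.0, np.log10(hi / half_width), 80)
        # the exact peak centre is excluded: at a pole numerically on the unit
        # circle the denominator there underflows to zero
        extra.append(np.concatenate((f0 - offsets, f0 + offsets)))
    if not extra:
        return freqs
    allf = np.concatenate([freqs, *extra])
    return np.unique(allf[(allf >= 0.0) & (allf <= nyq)])


def ar_psd(model: ARModel, rate: float, freqs: np.ndarray | None = None) -> SpectralFrame:
    """One-sided AR power spectral density on a frequency grid.

    psd(f) = 2 * noise_var * dt / |1 - sum_k c_k exp(-i 2 pi f k dt)|^2 with
    dt = 1/rate; the factor 2 folds negative frequencies so the integral over
    [0, rate/2] equals the process variance. When ``freqs`` is omitted, a
    peak-refined grid (see :func:`refined_freq_grid`) is used so band
    integrals stay accurate for very sharp spectra.
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    if model.reflection.size and np.any(np.abs(model.reflection) >= 1.0):
        raise ModelError(
            f"unstable AR model: reflection coefficients {model.reflection}"
        )
    if not model.stable:
        raise ModelError(
            f"unstable AR model (characteristic root outside unit circle); "
            f"reflection coefficients {model.reflection}"
        )
    if freqs is None:
        freqs = refined_freq_grid(model, rate)
    freqs = np.asarray(freqs, dtype=float)
    dt = 1.0 / rate
    if model.noise_var == 0.0:
        return SpectralFrame(t_end=np.nan, freqs=freqs, psd=np.zeros_like(freqs))
    k = np.arange(1, model.coefficients.size + 1)
    denom = np.abs(
        1.0 - np.exp(-2j * np.pi * np.outer(freqs, k) * dt) @ model.coefficients
    ) ** 2
    with np.errstate(divide="ignore"):
        psd = 2.0 * model.noise_var * dt / denom
    # a grid point coinciding with a pole on the unit circle (to machine
    # precision) yields an infinity; cap it at the largest finite value
    bad = ~np.isfinite(psd)
    if np.any(bad):
        finite = psd[~bad]
        psd[bad] = float(np.max(finite)) if finite.size else 0.0
    return SpectralFrame(t_end=np.nan, freqs=freqs, psd=psd)


def band_power(frame: SpectralFrame, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over ``band`` [f_lo, f_hi], in ms^2.

    PSD values at the band edges are obtained by linear interpolation so the
    integral is exact for the trapezoid through the stored grid.
    """
    lo, hi = band
    if hi <= lo:
        raise ValidationError(f"inverted band [{lo}, {hi}]")
    fmax = float(frame.freqs[-1])
    if lo < float(frame.freqs[0]) - 1e-12 or hi > fmax + 1e-9:
        raise ValidationError(
            f"band [{lo}, {hi}] Hz outside spectral grid [0, {fmax:g}] Hz"
        )
    hi = min(hi, fmax)
    inside = (frame.freqs > lo) & (frame.freqs < hi)
    f = np.concatenate(([lo], frame.freqs[inside], [hi]))
    p = np.concatenate((
        [np.interp(lo, frame.freqs, frame.psd)],
        frame.psd[inside],
        [np.interp(hi, frame.freqs, frame.psd)],
    ))
    return float(np.trapezoid(p, f))


def sliding_trend(
    tach: Tachogram,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    order: int = DEFAULT_ORDER,
    n_freqs: int = N_FREQS,
) -> HRVTrend:
    """LF/HF/LF:HF/HR trend from windows of ``window_s`` s stepped every ``step_s`` s.

    Each frame at time t summarises the preceding window (t - window_s, t]:
    the window is mean-removed, an AR model of the given order is fitted by
    Burg, the LF and HF band powers are integrated from its spectrum, and the
    heart rate is 60000 / mean(window R-R ms). The first frame is emitted
    ``window_s`` after the tachogram start. LF/HF is NaN where HF is zero.
    """
    if tach.span < window_s:
        raise InsufficientDataError(
            f"tachogram span {tach.span:.1f} s shorter than window {window_s:g} s"
        )
    times = tach.times
    t_ends = np.arange(tach.t_start + window_s, tach.t_start + tach.span + 1e-9, step_s)
    lf = np.empty(t_ends.size)
    hf = np.empty(t_ends.size)
    lfhf = np.empty(t_ends.size)
    hr = np.empty(t_ends.size)
    for i, t_end in enumerate(t_ends):
        i_lo = int(np.searchsorted(times, t_end - window_s, side="right"))
        i_hi = int(np.searchsorted(times, t_end + 1e-9, side="right"))
        window = tach.values[i_lo:i_hi]
        model = burg_ar(window, order)
        frame = ar_psd(model, tach.rate, refined_freq_grid(model, tach.rate, n_freqs))
        lf[i] = band_power(frame, LF_BAND)
        hf[i] = band_power(frame, HF_BAND)
        lfhf[i] = lf[i] / hf[i] if hf[i] > 0 else np.nan
        hr[i] = 60000.0 / float(np.mean(window))
    return HRVTrend(t=t_ends, lf=lf, hf=hf, lfhf=lfhf, hr=hr)
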