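"""Two-group Fisher linear discriminant for the 12 HRV/HR features.

The screening statistic is a linear discriminant score

    D = a HF[Rest] + b HF[Task/Rest] + c HF[After/Rest]
      + d LF[Rest] + e LF[Task/Rest] + f LF[After/Rest]
      + g LF/HF[Rest] + h LF/HF[Task/Rest] + i LF/HF[After/Rest]
      + j HR[Rest] + k HR[Task/Rest] + l HR[After/Rest]
      - discriminant point,

positive when the former diagnosis of the group pair is supported and
negative for the latter. Coefficients are the Fisher solution
(pooled within-group covariance)^-1 (mean difference) with an equal-prior
midpoint threshold; group separation is quantified by the Mahalanobis
distance between the group means, tested with the two-sample Hotelling T^2
F approximation. With 12 features and clinical group sizes of a few dozen
the pooled covariance can be ill-conditioned, so a small ridge term is
supported.
"""

from __future__ import annotations

import json
import os
import string
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ModelError, ValidationError
from .paradigm import FEATURE_NAMES, round_half_up

N_FEATURES = 12
COEF_LETTERS = tuple(string.ascii_lowercase[:N_FEATURES])  # a..l

# default ridge as a fraction of the mean pooled-covariance diagonal
DEFAULT_RIDGE_FRACTION = 1e-6


@dataclass
class DiscriminantModel:
    """Fitted two-group linear discriminant (former, latter) with midpoint threshold."""

    group_pair: tuple[str, str]
    coefficients: np.ndarray
    discriminant_point: float
    means: dict[str, np.ndarray]
    pooled_cov: np.ndarray
    ridge: float = 0.0
    degenerate: bool = False
    n_per_group: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.pooled_cov = np.asarray(self.pooled_cov, dtype=float)

    @property
    def n_features(self) -> int:
        return self.coefficients.size

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        letters = (
            COEF_LETTERS
            if self.n_features == N_FEATURES
            else tuple(f"c{i}" for i in range(self.n_features))
        )
        payload = {
            "group_pair": list(self.group_pair),
            "coefficients": dict(zip(letters, self.coefficients.tolist())),
            "feature_names": (
                list(FEATURE_NAMES) if self.n_features == N_FEATURES else None
            ),
            "discriminant_point": self.discriminant_point,
            "ridge": self.ridge,
            "degenerate": self.degenerate,
            "n_per_group": self.n_per_group,
            "means": {g: m.tolist() for g, m in self.means.items()},
            "pooled_cov": self.pooled_cov.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "DiscriminantModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            group_pair=tuple(payload["group_pair"]),
            coefficients=np.array(list(payload["coefficients"].values())),
            discriminant_point=payload["discriminant_point"],
            means={g: np.array(m) for g, m in payload["means"].items()},
            pooled_cov=np.array(payload["pooled_cov"]),
            ridge=payload.get("ridge", 0.0),
            degenerate=payload.get("degenerate", False),
            n_per_group=payload.get("n_per_group", {}),
        )


@dataclass
class ConfusionTable:
    """Counts under the former-group-positive convention (D > 0 supports former)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def n_former(self) -> int:
        return self.tp + self.fn

    @property
    def n_latter(self) -> int:
        return self.fp + self.tn


@dataclass
class SeparationStats:
    """Mahalanobis distance between group means with Hotelling T^2 significance."""

    md: float
    t2: float
    p: float


def fit_lda(
    X_former: np.ndarray,
    X_latter: np.ndarray,
    group_pair: tuple[str, str] = ("former", "latter"),
    ridge: float = 0.0,
) -> DiscriminantModel:
    """Fisher linear discriminant with equal priors and midpoint threshold.

    coefficients = (pooled_cov + ridge*I)^-1 (mu_former - mu_latter);
    discriminant_point = coefficients . (mu_former + mu_latter)/2, so the
    score is positive at the former mean and negative at the latter mean.
    ``ridge`` regularises an ill-conditioned pooled covariance; with
    ridge = 0 a singular covariance raises :class:`ModelError`.
    """
    Xf = np.atleast_2d(np.asarray(X_former, dtype=float))
    Xl = np.atleast_2d(np.asarray(X_latter, dtype=float))
    if Xf.shape[1] != Xl.shape[1]:
        raise ValidationError("feature dimension mismatch between groups")
    n1, n2 = Xf.shape[0], Xl.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 subjects")
    if ridge < 0:
        raise ValidationError("ridge must be >= 0")
    p = Xf.shape[1]
    mu_f, mu_l = Xf.mean(axis=0), Xl.mean(axis=0)
    S1 = np.cov(Xf, rowvar=False, ddof=1)
    S2 = np.cov(Xl, rowvar=False, ddof=1)
    pooled = ((n1 - 1) * np.atleast_2d(S1) + (n2 - 1) * np.atleast_2d(S2)) / (n1 + n2 - 2)

    diff = mu_f - mu_l
    degenerate = bool(np.allclose(diff, 0.0))
    reg = pooled + ridge * np.eye(p)
    if degenerate:
        coef = np.zeros(p)
    else:
        try:
            cond = np.linalg.cond(reg)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            if ridge == 0:
                raise ModelError(
                    "pooled covariance is singular or near-singular; pass a "
                    "ridge > 0 (e.g. 1e-6 x mean diagonal) or use pseudo-inverse mode"
                )
            coef = np.linalg.pinv(reg) @ diff
        else:
            coef = np.linalg.solve(reg, diff)
    point = float(coef @ (mu_f + mu_l) / 2.0)
    return DiscriminantModel(
        group_pair=tuple(group_pair),
        coefficients=coef,
        discriminant_point=point,
        means={group_pair[0]: mu_f, group_pair[1]: mu_l},
        pooled_cov=pooled,
        ridge=ridge,
        degenerate=degenerate,
        n_per_group={group_pair[0]: n1, group_pair[1]: n2},
    )


def default_ridge(pooled_cov: np.ndarray, fraction: float = DEFAULT_RIDGE_FRACTION) -> float:
    """Conventional small ridge: ``fraction`` of the mean covariance diagonal."""
    return float(fraction * np.mean(np.diag(np.atleast_2d(pooled_cov))))


def d_score(model: DiscriminantModel, features: np.ndarray) -> float | np.ndarray:
    """Discriminant score(s): coefficients . features - discriminant_point.

    Accepts a single feature vector or an (n, p) matrix.
    """
    x = np.asarray(getattr(features, "values", features), dtype=float)
    if x.shape[-1] != model.n_features:
        raise ValidationError(
            f"feature length {x.shape[-1]} does not match model ({model.n_features})"
        )
    scores = x @ model.coefficients - model.discriminant_point
    return float(scores) if scores.ndim == 0 else scores


def classify_cohort(
    model: DiscriminantModel,
    features: np.ndarray,
    labels: list[str],
) -> ConfusionTable:
    """Count positive/negative D-scores per true group (ties D = 0 count negative)."""
    labels = list(labels)
    if not labels:
        raise ValidationError("empty cohort")
    former, latter = model.group_pair
    foreign = sorted({lab for lab in labels if lab not in model.group_pair})
    if foreign:
        raise ValidationError(f"labels {foreign} not in model group pair {model.group_pair}")
    scores = np.atleast_1d(d_score(model, np.atleast_2d(features)))
    lab = np.asarray(labels)
    pos = scores > 0
    return ConfusionTable(
        tp=int(np.sum((lab == former) & pos)),
        fn=int(np.sum((lab == former) & ~pos)),
        fp=int(np.sum((lab == latter) & pos)),
        tn=int(np.sum((lab == latter) & ~pos)),
    )


def sens_spec(ct: ConfusionTable) -> tuple[float, float]:
    """Sensitivity and specificity in percent, half-up rounded to 1 decimal."""
    if ct.n_former == 0 or ct.n_latter == 0:
        raise ValidationError("undefined metric: a group margin is empty")
    sens = round_half_up(100.0 * ct.tp / ct.n_former)
    spec = round_half_up(100.0 * ct.tn / ct.n_latter)
    return sens, spec


def mahalanobis(model: DiscriminantModel) -> float:
    """Mahalanobis distance between the two group means under the pooled covariance."""
    if model.degenerate:
        return 0.0
    former, latter = model.group_pair
    diff = model.means[former] - model.means[latter]
    reg = model.pooled_cov + model.ridge * np.eye(model.n_features)
    try:
        sol = np.linalg.solve(reg, diff)
    except np.linalg.LinAlgError as exc:
        raise ModelError("singular pooled covariance; use ridge > 0") from exc
    md2 = float(diff @ sol)
    if md2 < 0:
        raise ModelError("non-positive-definite pooled covariance")
    return float(np.sqrt(md2))


def hotelling_p(md: float, n1: int, n2: int, p_dim: int) -> SeparationStats:
    """Two-sample Hotelling T^2 significance of a Mahalanobis distance.

    T^2 = (n1 n2 / (n1 + n2)) md^2;
    F = T^2 (n1 + n2 - p - 1) / (p (n1 + n2 - 2)) ~ F(p, n1 + n2 - p - 1).
    """
    if md < 0:
        raise ValidationError("Mahalanobis distance cannot be negative")
    if n1 + n2 <= p_dim + 1:
        raise ValidationError(
            f"insufficient degrees of freedom: n1 + n2 = {n1 + n2} <= p + 1 = {p_dim + 1}"
        )
    t2 = (n1 * n2 / (n1 + n2)) * md**2
    df2 = n1 + n2 - p_dim - 1
    f_stat = t2 * df2 / (p_dim * (n1 + n2 - 2))
    p_val = float(stats.f.sf(f_stat, p_dim, df2))
    return SeparationStats(md=md, t2=float(t2), p=max(p_val, np.finfo(float).tiny))


def separation(model: DiscriminantModel) -> SeparationStats:
    """Mahalanobis distance and its Hotelling T^2 p-value for a fitted model."""
    md = mahalanobis(model)
    former, latter = model.group_pair
    return hotelling_p(
        md, model.n_per_group[former], model.n_per_group[latter], model.n_features
    )


def confusion_report(
    ct: ConfusionTable, group_pair: tuple[str, str], stats_: SeparationStats | None = None
) -> str:
    """Render a counts/sensitivity/specificity text block for one group pair."""
    former, latter = group_pair
    sens, spec = sens_spec(ct)
    lines = [
        f"{former} vs. {latter}",
        f"{'':12s}{'D > 0':>8s}{'D < 0':>8s}{'Total':>8s}",
        f"{former:12s}{ct.tp:>8d}{ct.fn:>8d}{ct.n_former:>8d}",
        f"{latter:12s}{ct.fp:>8d}{ct.tn:>8d}{ct.n_latter:>8d}",
        f"{'Total':12s}{ct.tp + ct.fp:>8d}{ct.fn + ct.tn:>8d}",
        f"sensitivity {sens:.1f}%   specificity {spec:.1f}%",
    ]
    if stats_ is not None:
        lines.append(f"Md = {stats_.md:.2f}   p = {stats_.p:.3g}")
    return "\n".join(lines)
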