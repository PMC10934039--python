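"""Random-number-generation task scoring.

During the 100-s task the subject vocalises the digits 0-9 in as random an
order as she can, one per second. Task performance is summarised by the RNG
index, Evans' digram-redundancy statistic: with n_ij the count of the ordered
adjacent pair (i, j) and n_i. its row sum,

    RNG = sum_{ij} n_ij ln n_ij / sum_i n_i. ln n_i.

It is 0 when every adjacent ordered pair is distinct (maximal sequential
variety) and 1 for a constant sequence (maximal repetition); human
"random" production typically scores in the 0.3-0.45 range. A naive
same-digit-repeat frequency is also provided, but under uniform randomness
its expectation is ~0.1, far below the range human studies report, so the
digram-redundancy form is the default.
"""

from __future__ import annotations

import math
import os
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ValidationError

NOMINAL_LENGTH = 100


@dataclass
class DigitSequence:
    """Ordered digits 0-9 produced during the task (nominal length 100)."""

    digits: np.ndarray

    def __post_init__(self) -> None:
        self.digits = np.asarray(self.digits, dtype=int)
        if self.digits.size < 2:
            raise InsufficientDataError("digit sequence needs at least 2 digits")
        if np.any((self.digits < 0) | (self.digits > 9)):
            raise ValidationError("digits must be integers 0-9")

    def __len__(self) -> int:
        return self.digits.size

    @classmethod
    def from_text(cls, text: str) -> "DigitSequence":
        """Parse a one-line string of digit characters (whitespace/commas ignored)."""
        chars = [c for c in text.strip() if c not in " ,\t\n"]
        bad = [c for c in chars if not c.isdigit()]
        if bad:
            raise ValidationError(f"non-digit symbols in sequence: {sorted(set(bad))}")
        return cls(digits=np.array([int(c) for c in chars]))

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "DigitSequence":
        with open(path) as fh:
            return cls.from_text(fh.read())

    def to_text(self) -> str:
        return "".join(str(d) for d in self.digits)


def rng_index(seq: DigitSequence, method: str = "digram") -> float:
    """Task-performance score in [0, 1]; higher means more repetitive output.

    ``digram`` (default): Evans' digram-redundancy index defined above.
    ``repeat_pair``: fraction of adjacent pairs that are the same digit.
    """
    d = seq.digits
    if method == "repeat_pair":
        return float(np.mean(d[1:] == d[:-1]))
    if method != "digram":
        raise ValidationError(f"unknown RNG index method {method!r}")
    pairs = Counter(zip(d[:-1].tolist(), d[1:].tolist()))
    first = Counter(d[:-1].tolist())
    num = sum(n * math.log(n) for n in pairs.values() if n > 0)
    den = sum(n * math.log(n) for n in first.values() if n > 0)
    if den == 0.0:  # every digit used at most once as a pair head
        return 0.0
    return num / den


def validate_sequence(seq: DigitSequence | str, expected_len: int = NOMINAL_LENGTH) -> dict:
    """Report-only check of sequence length and symbol domain; never mutates.

    Accepts either a parsed :class:`DigitSequence` or raw text (in which case
    foreign symbols are reported rather than raising).
    """
    if isinstance(seq, DigitSequence):
        n = len(seq)
        bad_symbols: list[str] = []
    else:
        chars = [c for c in str(seq).strip() if c not in " ,\t\n"]
        n = len(chars)
        bad_symbols = sorted({c for c in chars if not c.isdigit()})
    report = {
        "length": n,
        "expected_length": expected_len,
        "length_ok": n == expected_len,
        "symbols_ok": not bad_symbols,
        "bad_symbols": bad_symbols,
    }
    report["clean"] = report["length_ok"] and report["symbols_ok"]
    return report
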