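"""Observer- and modality-agreement statistics.

Bland-Altman bias and limits of agreement, two-way intra-class correlation
(single-rater forms, with the conventional "ICC > 0.75 is good agreement"
rule), Spearman rank correlation, and the Welch two-sided t-test used for
comparing segmentation times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .errors import InvalidArgumentError, UndefinedICCError
from .pulsation import WelchResult, two_sided_ttest  # shared implementation

__all__ = [
    "PairedMeasurements", "BlandAltmanResult", "ICCResult",
    "bland_altman", "icc_two_way", "spearman_corr", "two_sided_ttest",
]

#: limits-of-agreement multiplier (conventional 95% normal range)
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedMeasurements:
    """Two equal-length measurement vectors on the same subjects."""

    a: np.ndarray
    b: np.ndarray
    label_a: str = "a"
    label_b: str = "b"
    units: str = ""

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or a.shape != b.shape:
            raise InvalidArgumentError("paired vectors must be 1D and equal length")
        if a.size < 2:
            raise InvalidArgumentError("need at least 2 pairs")
        if np.any(np.isnan(a)) or np.any(np.isnan(b)):
            raise InvalidArgumentError("pairs must be complete (no NaN)")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float                 # mean(a - b)
    loa_half_width: float       # 1.96 * SD(a - b), sample SD
    differences: np.ndarray
    means: np.ndarray

    @property
    def loa_lower(self) -> float:
        return self.bias - self.loa_half_width

    @property
    def loa_upper(self) -> float:
        return self.bias + self.loa_half_width


@dataclass(frozen=True)
class ICCResult:
    icc: float
    form: str
    good_agreement: bool        # strict: icc > 0.75


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of paired measurements."""
    d = pairs.a - pairs.b
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=float(d.mean()),
        loa_half_width=LOA_MULTIPLIER * sd,
        differences=d,
        means=(pairs.a + pairs.b) / 2.0,
    )


def icc_two_way(ratings: np.ndarray, form: str = "ICC2_1") -> ICCResult:
    """Single-rater intra-class correlation from a subjects x raters matrix.

    ``ICC2_1``: two-way random effects, absolute agreement —
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    ``ICC3_1``: two-way mixed, consistency — (MSR - MSE) / (MSR + (k-1) MSE).
    Agreement is called good when ICC exceeds 0.75 (strict inequality).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidArgumentError("ratings must be a (>=2 subjects) x (>=2 raters) matrix")
    if np.any(np.isnan(x)):
        raise InvalidArgumentError("ratings must have no missing cells")
    if form not in ("ICC2_1", "ICC3_1"):
        raise InvalidArgumentError(f"unknown ICC form {form!r}")
    n, k = x.shape
    gm = x.mean()
    sst = ((x - gm) ** 2).sum()
    if sst == 0:
        raise UndefinedICCError("zero total variance: ICC undefined")
    ssr = k * ((x.mean(axis=1) - gm) ** 2).sum()
    ssc = n * ((x.mean(axis=0) - gm) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "ICC2_1":
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse)
    icc = float(icc)
    return ICCResult(icc=icc, form=form, good_agreement=icc > 0.75)


def spearman_corr(pairs: PairedMeasurements) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    if pairs.n < 3:
        raise InvalidArgumentError("Spearman correlation needs n >= 3")
    if np.all(pairs.a == pairs.a[0]) or np.all(pairs.b == pairs.b[0]):
        raise InvalidArgumentError("correlation undefined for a constant vector")
    r, _ = _st.spearmanr(pairs.a, pairs.b)
    return float(r)
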