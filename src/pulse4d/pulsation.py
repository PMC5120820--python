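"""Volume-curve normalization and pulsation-plausibility statistics.

An aneurysm's per-phase volume curve is compared with an arterial pulse-wave
template of the middle cerebral artery by the symmetric Hausdorff distance
between the two sampled curves, each min-max normalized to [0, 1].  A set of
random curves drawn from the noise characteristics of the CT images
(Gaussian, mean 0.5, SD 0.2) provides the null distribution: if the volume
curves sit significantly closer to the pulse wave than the random curves do
(Welch t-test), their shape is unlikely to be a product of image noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy import stats as _st

from .errors import DegenerateCurveError, InvalidArgumentError

NormState = Literal["raw", "minmax01", "mean1"]


@dataclass(frozen=True)
class PulseWave:
    """Arterial pulse-wave template sampled once per cardiac phase.

    Values are min-max normalized to [0, 1]; ``source`` records whether the
    template came from a file (e.g. the transcranial-ultrasound table) or the
    built-in analytic stand-in.
    """

    values: np.ndarray
    source: str = "builtin"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise InvalidArgumentError("pulse wave needs >= 2 samples")
        if not (np.isclose(v.min(), 0.0) and np.isclose(v.max(), 1.0)):
            raise InvalidArgumentError("pulse wave must be min-max normalized")
        object.__setattr__(self, "values", v)

    @property
    def n_phases(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class VolumeCurve:
    """Per-phase aneurysm volumes (mm^3) plus normalization state."""

    values: np.ndarray
    label: str = ""
    normalization: NormState = "raw"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise InvalidArgumentError("volume curve needs >= 2 phases")
        if self.normalization == "raw" and np.any(v <= 0):
            raise InvalidArgumentError("raw volumes must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_phases(self) -> int:
        return self.values.size

    @property
    def phase_fractions(self) -> np.ndarray:
        return np.arange(self.n_phases) / self.n_phases


@dataclass(frozen=True)
class RandomNull:
    """Random curves with the CT-noise moments and their pulse-wave distances."""

    curves: np.ndarray          # (n_curves, n_phases)
    distances: np.ndarray       # (n_curves,)
    mean: float = 0.5
    sd: float = 0.2
    seed: int | None = None

    @property
    def n_curves(self) -> int:
        return self.curves.shape[0]


class WelchResult(NamedTuple):
    t: float
    p: float
    mean_a: float
    mean_b: float


def _values(curve) -> np.ndarray:
    if isinstance(curve, (VolumeCurve, PulseWave)):
        return curve.values
    return np.asarray(curve, dtype=float)


def normalize_minmax(curve: VolumeCurve) -> VolumeCurve:
    """Rescale to min 0, max 1.  Constant curves are degenerate (flat)."""
    v = curve.values
    rng = v.max() - v.min()
    if rng == 0:
        raise DegenerateCurveError(f"constant curve {curve.label!r} cannot be min-max normalized")
    return replace(curve, values=(v - v.min()) / rng, normalization="minmax01")


def normalize_mean_one(curve: VolumeCurve) -> VolumeCurve:
    """Rescale to mean 1 (used for cross-aneurysm comparability plots)."""
    m = curve.values.mean()
    if m <= 0:
        raise InvalidArgumentError("mean must be positive for mean-1 normalization")
    return replace(curve, values=curve.values / m, normalization="mean1")


def pulsation_amplitude(curve: VolumeCurve | Sequence[float]) -> float:
    """Pulsation amplitude Vmax / Vmin; scale-invariant, >= 1 by construction."""
    v = _values(curve)
    if np.any(v <= 0):
        raise InvalidArgumentError("amplitude requires positive volumes")
    return float(v.max() / v.min())


def curve_points(values: np.ndarray, value_only: bool = False) -> np.ndarray:
    """Embed a sampled curve as a 2D point set {(t_i, v_i)}, t_i = i/(n-1).

    With ``value_only`` the time coordinate is dropped (1D point set).
    """
    v = np.asarray(values, dtype=float)
    if value_only:
        return v[:, None]
    t = np.arange(v.size) / (v.size - 1)
    return np.column_stack([t, v])


def hausdorff_distance(a, b, value_only: bool = False) -> float:
    """Symmetric Hausdorff distance between two equally sampled curves.

    Curves are embedded as point sets {(i/(n-1), v_i)} and the classic
    max(h(A,B), h(B,A)) with h(A,B) = max_a min_b ||a-b||_2 is evaluated
    exactly over the full distance matrix.
    """
    va, vb = _values(a), _values(b)
    if va.size != vb.size:
        raise InvalidArgumentError(f"curve lengths differ: {va.size} vs {vb.size}")
    pa = curve_points(va, value_only)
    pb = curve_points(vb, value_only)
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def generate_random_null(
    n_curves: int,
    n_phases: int,
    seed: int | np.random.Generator | None,
    pulse: PulseWave,
    mean: float = 0.5,
    sd: float = 0.2,
    clip: bool = True,
    renorm: bool = False,
    value_only: bool = False,
) -> RandomNull:
    """Draw i.i.d. Gaussian(mean, sd) curves and measure their pulse distances.

    By default the draws are clipped to [0, 1] and NOT re-normalized; both
    behaviours can be toggled to bracket the sensitivity of the null.
    """
    if n_curves < 1:
        raise InvalidArgumentError("n_curves must be >= 1")
    if n_phases != pulse.n_phases:
        raise InvalidArgumentError("null phase count must match the pulse wave")
    rng = np.random.default_rng(seed)
    curves = rng.normal(mean, sd, size=(n_curves, n_phases))
    if clip:
        curves = np.clip(curves, 0.0, 1.0)
    if renorm:
        lo = curves.min(axis=1, keepdims=True)
        hi = curves.max(axis=1, keepdims=True)
        curves = (curves - lo) / np.where(hi > lo, hi - lo, 1.0)
    dists = np.array([hausdorff_distance(c, pulse, value_only) for c in curves])
    return RandomNull(
        curves=curves, distances=dists, mean=mean, sd=sd,
        seed=seed if isinstance(seed, int) else None,
    )


def two_sided_ttest(sample_a, sample_b) -> WelchResult:
    """Welch (unequal-variance) two-sided t-test; degenerate variances fall
    back to exact equality of means (p = 1 if all values coincide)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("both samples need n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        same = np.isclose(a.mean(), b.mean())
        return WelchResult(0.0 if same else np.inf, 1.0 if same else 0.0,
                           float(a.mean()), float(b.mean()))
    t, p = _st.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(t), float(p), float(a.mean()), float(b.mean()))


def pulsation_test(curve_distances, null: RandomNull) -> WelchResult:
    """Welch t-test of curve-to-pulse distances against the random null."""
    return two_sided_ttest(curve_distances, null.distances)


def classify_curve(
    curve: VolumeCurve,
    pulse: PulseWave,
    null: RandomNull,
    flat_threshold: float = 1.02,
    percentile: float = 5.0,
    value_only: bool = False,
) -> str:
    """Heuristic grouping into pulsatile / random / flat profiles.

    The thresholds are pragmatic conveniences: a curve is *flat* when its
    amplitude is below ``flat_threshold``, *pulsatile* when its min-max
    normalized distance to the pulse wave is below the ``percentile``-th
    percentile of the null distances, and *random* otherwise.
    """
    if curve.normalization != "minmax01" and pulsation_amplitude(curve) < flat_threshold:
        return "flat"
    try:
        norm = curve if curve.normalization == "minmax01" else normalize_minmax(curve)
    except DegenerateCurveError:
        return "flat"
    d = hausdorff_distance(norm, pulse, value_only)
    if d < float(np.percentile(null.distances, percentile)):
        return "pulsatile"
    return "random"


@dataclass
class PulsationReport:
    """Cohort-level pulsation-plausibility summary."""

    labels: list[str]
    distances: np.ndarray
    amplitudes: np.ndarray
    classes: list[str]
    null: RandomNull
    t: float
    p: float
    mean_curves: float
    mean_null: float

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "distances": self.distances.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "classes": list(self.classes),
            "null_distances": self.null.distances.tolist(),
            "t": self.t,
            "p": self.p,
            "mean_curve_distance": self.mean_curves,
            "mean_null_distance": self.mean_null,
        }


def cohort_pulsation_report(
    curves: Sequence[VolumeCurve],
    pulse: PulseWave,
    null: RandomNull,
    value_only: bool = False,
    flat_threshold: float = 1.02,
    percentile: float = 5.0,
) -> PulsationReport:
    """Min-max normalize each curve, measure its pulse-wave Hausdorff distance,
    and test the cohort against the random null with a Welch t-test."""
    dists, amps, classes, labels = [], [], [], []
    for i, c in enumerate(curves):
        labels.append(c.label or f"curve_{i}")
        amps.append(pulsation_amplitude(c) if c.normalization != "minmax01" else np.nan)
        try:
            norm = c if c.normalization == "minmax01" else normalize_minmax(c)
        except DegenerateCurveError:
            warnings.warn(f"curve {labels[-1]} is constant; excluded from the t-test")
            dists.append(np.nan)
            classes.append("flat")
            continue
        dists.append(hausdorff_distance(norm, pulse, value_only))
        classes.append(classify_curve(c, pulse, null, flat_threshold, percentile, value_only))
    dists = np.asarray(dists)
    ok = ~np.isnan(dists)
    if ok.sum() >= 2:
        res = pulsation_test(dists[ok], null)
    elif ok.sum() == 1:
        # single aneurysm: one-sample t-test of the null distances against it
        d = float(dists[ok][0])
        t, p = _st.ttest_1samp(null.distances, d)
        res = WelchResult(-float(t), float(p), d, float(null.distances.mean()))
    else:
        res = WelchResult(np.nan, np.nan, np.nan, float(null.distances.mean()))
    return PulsationReport(
        labels=labels, distances=dists, amplitudes=np.asarray(amps),
        classes=classes, null=null, t=res.t, p=res.p,
        mean_curves=res.mean_a, mean_null=res.mean_b,
    )
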