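"""Basidiospore morphometrics: the (min) MV ± sd (max) summary scheme, the
length/width ratio Q, Bonferroni-corrected pairwise comparisons and 95%
coverage ellipses for length-width scatter plots.

Q is computed per spore (length divided by width) and then averaged, so the
reported q_mean carries its own standard deviation - the convention used when
spore tables print "Q = 1.82 ± 0.12".  For independent normal length and
width this per-spore mean exceeds the simple ratio of mean length to mean
width by a factor of approximately (1 + sd_width²/mean_width²) (second-order
delta method), which the consistency checker exploits to flag summary rows
whose printed Q cannot have been produced from the printed moments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SporeMeasurementSet:
    """Per-spore (length, width) measurements in micrometres for one species."""

    species: str
    lengths: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if len(self.lengths) != len(self.widths):
            raise ValueError("lengths and widths differ in number")
        if len(self.lengths) < 1:
            raise ValueError("need at least one spore measurement")
        if (self.lengths <= 0).any() or (self.widths <= 0).any():
            raise ValueError("spore dimensions must be positive")

    @property
    def n(self) -> int:
        return len(self.lengths)

    @property
    def q(self) -> np.ndarray:
        """Per-spore length/width ratios."""
        return self.lengths / self.widths


@dataclass
class SporeSummary:
    """The study's summary scheme: (min) MV ± sd (max) per dimension plus Q."""

    species: str
    n: int
    min_length: float
    mean_length: float
    sd_length: float
    max_length: float
    min_width: float
    mean_width: float
    sd_width: float
    max_width: float
    q_mean: float
    q_sd: float

    def scheme(self) -> str:
        """Render in the conventional textual form."""
        return (
            f"({self.min_length:.1f}) {self.mean_length:.1f} ± {self.sd_length:.2f} "
            f"({self.max_length:.1f}) x ({self.min_width:.1f}) {self.mean_width:.1f} "
            f"± {self.sd_width:.2f} ({self.max_width:.1f}) µm; "
            f"Q = {self.q_mean:.2f} ± {self.q_sd:.2f} (n = {self.n})"
        )


@dataclass
class EllipseSpec:
    """A bivariate coverage ellipse in the length-width plane."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float  # radians, first principal axis vs. length axis
    coverage: float
    _cov_inv: np.ndarray | None = None

    def contains(self, lengths: np.ndarray, widths: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.column_stack([lengths, widths]) - np.asarray(self.center)
        r2 = stats.chi2.ppf(self.coverage, df=2)
        if self._cov_inv is not None:
            m = np.einsum("ij,jk,ik->i", pts, self._cov_inv, pts)
            return m <= r2
        # reconstruct from axes/orientation
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, s], [-s, c]])
        local = pts @ rot.T
        a, b = self.semi_axes
        return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def summarize_spores(s: SporeMeasurementSet) -> SporeSummary:
    """Compute the (min) MV ± sd (max) x (min) MV ± sd (max), Q summary.

    Sample standard deviations use the n-1 denominator (0 when n = 1); Q is
    averaged over per-spore ratios.
    """
    q = s.q
    return SporeSummary(
        species=s.species,
        n=s.n,
        min_length=float(s.lengths.min()),
        mean_length=float(s.lengths.mean()),
        sd_length=_sd(s.lengths),
        max_length=float(s.lengths.max()),
        min_width=float(s.widths.min()),
        mean_width=float(s.widths.mean()),
        sd_width=_sd(s.widths),
        max_width=float(s.widths.max()),
        q_mean=float(q.mean()),
        q_sd=_sd(q),
    )


_METRICS = ("length", "width", "Q")


def _metric_values(s: SporeMeasurementSet, metric: str) -> np.ndarray:
    if metric == "length":
        return s.lengths
    if metric == "width":
        return s.widths
    if metric == "Q":
        return s.q
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


def compare_species(
    sets: list[SporeMeasurementSet], metric: str, alpha: float = 0.05
) -> list[dict]:
    """All pairwise Welch t-tests on one spore metric, Bonferroni corrected.

    The correction family is the set of unordered pairs within this metric:
    each raw p-value is multiplied by the number of pairs and capped at 1.
    Returns one record per pair with raw and corrected p-values and a
    significance flag at ``alpha``.
    """
    if len(sets) < 2:
        raise ValueError("need at least two measurement sets to compare")
    for s in sets:
        if s.n < 2:
            raise ValueError(f"set {s.species!r} has n < 2")
    pairs = list(itertools.combinations(range(len(sets)), 2))
    records = []
    for i, j in pairs:
        a = _metric_values(sets[i], metric)
        b = _metric_values(sets[j], metric)
        t, p_raw = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(p_raw):  # zero variance in both samples, identical means
            t, p_raw = 0.0, 1.0
        p_corr = min(1.0, p_raw * len(pairs))
        records.append(
            {
                "species_a": sets[i].species,
                "species_b": sets[j].species,
                "metric": metric,
                "t": float(t),
                "p_raw": float(p_raw),
                "p_bonferroni": float(p_corr),
                "significant": bool(p_corr < alpha),
            }
        )
    return records


def coverage_ellipse(s: SporeMeasurementSet, coverage: float = 0.95) -> EllipseSpec:
    """Population coverage ellipse from the sample mean and covariance.

    The squared Mahalanobis radius equals the chi-square(2 df) quantile at the
    coverage level (5.991 at 95%), so for bivariate-normal data the ellipse
    asymptotically contains the stated fraction of the measurements.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    if s.n < 3:
        raise ValueError("need at least 3 spores for a covariance ellipse")
    pts = np.column_stack([s.lengths, s.widths])
    cov = np.cov(pts, rowvar=False)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= 1e-12 * max(1.0, float(np.trace(cov)) ** 2):
        raise ValueError(
            "sample covariance is singular (collinear or identical points); "
            "an ellipse is not defined"
        )
    r2 = stats.chi2.ppf(coverage, df=2)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    semi_axes = tuple(float(np.sqrt(r2 * v)) for v in eigval)
    orientation = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return EllipseSpec(
        center=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
        semi_axes=semi_axes,
        orientation=orientation,
        coverage=coverage,
        _cov_inv=np.linalg.inv(cov),
    )


def expected_q(mean_length: float, mean_width: float, sd_width: float) -> float:
    """Delta-method expectation of the per-spore mean Q for independent normals."""
    return mean_length / mean_width * (1.0 + sd_width**2 / mean_width**2)


def check_summary_consistency(summary: SporeSummary, tolerance: float = 0.02) -> dict:
    """Internal-consistency report for a printed spore summary.

    Flags the row when the printed q_mean deviates from the delta-method
    expectation (independent normals) by more than ``tolerance``, or when a
    min exceeds its mean or a mean its max.
    """
    issues: list[str] = []
    exp_q = expected_q(summary.mean_length, summary.mean_width, summary.sd_width)
    if abs(summary.q_mean - exp_q) > tolerance:
        issues.append(
            f"q_mean {summary.q_mean:.3f} deviates from delta-method expectation "
            f"{exp_q:.3f} by more than {tolerance}"
        )
    for dim in ("length", "width"):
        lo = getattr(summary, f"min_{dim}")
        mv = getattr(summary, f"mean_{dim}")
        hi = getattr(summary, f"max_{dim}")
        if lo > mv:
            issues.append(f"min_{dim} {lo} exceeds mean {mv}")
        if mv > hi:
            issues.append(f"mean_{dim} {mv} exceeds max {hi}")
    return {
        "species": summary.species,
        "expected_q": float(exp_q),
        "q_mean": summary.q_mean,
        "consistent": not issues,
        "issues": issues,
    }
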