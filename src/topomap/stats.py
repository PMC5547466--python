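"""Population summaries, significance tests and interpolation fits.

Per-nucleus class or enrichment profiles are aggregated over a population
of nuclei (mean, SD, SEM per class).  Group differences are tested with
the Wilcoxon rank-sum test (exact enumeration for small tie-free samples,
otherwise the normal approximation with continuity correction) or the
two-tailed Student's t test; families of pairwise comparisons are
Bonferroni-corrected.  Class-index trends are summarized by a
second-order polynomial fit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .topography import ClassProfile, EnrichmentProfile

log = logging.getLogger(__name__)


def star_label(p: float) -> str:
    """Figure-style significance stars: * <=0.05, ** <=0.01, *** <=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    test_name: str
    adjusted_pvalue: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.adjusted_pvalue is not None and (
            self.adjusted_pvalue < self.pvalue - 1e-12
        ):
            raise ValueError("adjusted p must be >= raw p")

    @property
    def stars(self) -> str:
        p = self.pvalue if self.adjusted_pvalue is None else self.adjusted_pvalue
        return star_label(p)


@dataclass
class PopulationSummary:
    """Per-class mean, SD and SEM of profiles over N nuclei."""

    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n: int
    label: str = ""


def _values(profile) -> np.ndarray:
    if isinstance(profile, ClassProfile):
        return profile.fractions
    if isinstance(profile, EnrichmentProfile):
        return profile.points
    return np.asarray(profile, dtype=float)


def summarize_profiles(
    profiles: Sequence[ClassProfile | EnrichmentProfile | np.ndarray],
    label: str = "",
) -> PopulationSummary:
    """Mean/SD/SEM per class over a population of per-nucleus profiles.

    Sample SD (n-1 denominator); a single profile yields SD = SEM = 0
    with a logged caveat.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    rows = [_values(p) for p in profiles]
    k = len(rows[0])
    if any(len(r) != k for r in rows):
        raise ValueError("profiles have mixed numbers of classes")
    arr = np.vstack(rows)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    if n == 1:
        log.warning("single-profile summary: SD/SEM set to 0")
        sd = np.zeros(k)
    else:
        sd = arr.std(axis=0, ddof=1)
    return PopulationSummary(mean, sd, sd / np.sqrt(n), n, label)


def _wilcoxon(x: np.ndarray, y: np.ndarray) -> TestResult:
    # exact enumeration for small tie-free samples, else normal
    # approximation with continuity correction
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    if np.ptp(combined) == 0:
        # all observations identical: no evidence of any difference
        return TestResult(len(x) * len(y) / 2.0, 1.0, "wilcoxon")
    if tie_free and len(x) <= 8 and len(y) <= 8:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon")


def compare_groups(
    x: Sequence[float], y: Sequence[float], method: str = "wilcoxon"
) -> TestResult:
    """Two-sided comparison of two per-nucleus value groups.

    ``method="wilcoxon"``: rank-sum test, exact for tie-free samples with
    both n <= 8, otherwise asymptotic with continuity correction.
    ``method="t"``: two-tailed Student's t test (equal variances).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if method == "wilcoxon":
        return _wilcoxon(x, y)
    if method == "t":
        if x.size < 2 or y.size < 2:
            raise ValueError("t test needs >= 2 values per group")
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            raise ValueError("zero variance in both groups")
        res = sps.ttest_ind(x, y)
        return TestResult(float(res.statistic), float(res.pvalue), "t")
    raise ValueError("method must be 'wilcoxon' or 't'")


def pairwise_bonferroni(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> list[TestResult]:
    """All pairwise two-tailed t tests with Bonferroni correction.

    For G groups, m = G(G-1)/2 comparisons are run at a per-comparison
    level alpha/m; each result carries the adjusted p-value
    ``min(1, m * p)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 values")
    m = len(arrays) * (len(arrays) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        base = compare_groups(arrays[i], arrays[j], method="t")
        out.append(
            TestResult(
                base.statistic,
                base.pvalue,
                f"t ({i} vs {j}), per-comparison alpha={alpha / m:g}",
                adjusted_pvalue=min(1.0, m * base.pvalue),
            )
        )
    return out


class Poly2Fit(NamedTuple):
    a: float  # quadratic coefficient
    b: float  # linear coefficient
    c: float  # intercept
    r2: float


def poly2_fit(profile: ClassProfile | EnrichmentProfile | np.ndarray) -> Poly2Fit:
    """Least-squares second-order polynomial over class index k = 1..K.

    Fits ``y_k = a k^2 + b k + c``; classes are ordinal, so the class
    index serves as abscissa.  R^2 of a constant profile is defined as 1.
    """
    y = _values(profile)
    k = len(y)
    if k < 3:
        raise ValueError("polynomial fit needs K >= 3 classes")
    x = np.arange(1, k + 1, dtype=float)
    a, b, c = np.polyfit(x, y, 2)
    resid = y - (a * x**2 + b * x + c)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # an (up to rounding) constant profile is fit perfectly by c = mean
    if ss_tot <= 1e-20 * max(1.0, float(np.sum(y**2))):
        r2 = 1.0
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return Poly2Fit(float(a), float(b), float(c), r2)
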