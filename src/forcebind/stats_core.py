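"""Nonparametric statistics for paired and two-sample intensity-ratio comparisons.

The paired before/after chamber comparisons use a Wilcoxon signed-rank test.
Sample sizes in this assay are small (5-9 chambers or tethers), where the
normal approximation is unusable and the printed significance boundaries
(e.g. p = 2^(1-n) for unidirectional differences) are only reproduced by the
exact null distribution.  The exact two-sided p-value here is computed from
the full null distribution of the signed-rank sum over all 2^n sign
assignments of the ranked absolute differences, evaluated by a
generating-function recursion that is algebraically identical to explicit
enumeration.

Two-sample comparisons of intensity-ratio distributions below/above a force
threshold use the Kolmogorov-Smirnov test; cluster-count diagnostics use
mean silhouette coefficients.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps
from sklearn.metrics import silhouette_score

__all__ = [
    "PairedSample",
    "TestResult",
    "wilcoxon_signed_rank_exact",
    "ks_two_sample",
    "silhouette_scores",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired per-chamber (or per-tether) summary values.

    ``differences`` is ``values_b - values_a`` (after minus before).
    """

    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired samples must be equal-length 1-D arrays")
        if a.size < 1:
            raise ValueError("paired sample is empty")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("paired samples must be finite")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.values_b - self.values_a


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: Literal["exact", "asymptotic"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def _signed_rank_null_counts(ranks2: np.ndarray) -> np.ndarray:
    """Null distribution of the positive-rank sum over all sign assignments.

    ``ranks2`` are the (mid-)ranks doubled so they are integers even under
    ties.  Returns ``counts`` where ``counts[s]`` is the number of the 2^n
    sign assignments whose positive-rank sum (doubled) equals ``s``.
    Equivalent to brute-force enumeration of all 2^n assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(
    differences: Sequence[float],
    *,
    exact_cutoff: int = 25,
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test, exact for small samples.

    Zeros are dropped before ranking (``wilcox``, the default convention) or
    ranked with the nonzero values and then removed from the statistic
    (``pratt``).  Tied magnitudes receive mid-ranks; the exact test is then
    conditional on the realized rank multiset.  The two-sided p-value is
    twice the smaller one-sided tail, capped at 1.

    With ``n_effective <= exact_cutoff`` the p-value comes from the complete
    null distribution of the positive-rank sum (all 2^n sign assignments);
    above the cutoff scipy's normal approximation with tie correction is
    used and flagged ``asymptotic``.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a nonempty 1-D array")
    if not np.isfinite(d).all():
        raise ValueError("differences must be finite")

    nonzero = d != 0
    if not nonzero.any():
        raise ValueError("no nonzero pairs")

    if zero_method == "wilcox":
        dnz = d[nonzero]
        ranks = _sps.rankdata(np.abs(dnz))
    elif zero_method == "pratt":
        # rank zeros along with the rest, then discard their ranks
        ranks_all = _sps.rankdata(np.abs(d))
        dnz = d[nonzero]
        ranks = ranks_all[nonzero]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")

    n_eff = int(dnz.size)
    w_plus = float(ranks[dnz > 0].sum())

    if n_eff <= exact_cutoff:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        counts = _signed_rank_null_counts(ranks2)
        total = counts.sum()  # == 2**n_eff
        w2 = int(round(2 * w_plus))
        lower = int(counts[: w2 + 1].sum())
        upper = int(counts[w2:].sum())
        p = 2.0 * min(lower, upper) / int(total)
        return TestResult(w_plus, min(p, 1.0), n_eff, "exact")

    p = _signed_rank_asymptotic_p(ranks, w_plus)
    return TestResult(w_plus, p, n_eff, "asymptotic")


def _signed_rank_asymptotic_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided asymptotic p for the positive-rank sum.

    Normal approximation with continuity correction plus the Edgeworth
    kurtosis term.  Under the null W+ = sum(r_i * B_i) with B_i iid
    Bernoulli(1/2), so mean = sum(r)/2, var = sum(r^2)/4 (this absorbs the
    tie correction via the mid-ranks) and the fourth cumulant is
    -sum(r^4)/8; skewness is zero by symmetry.
    """
    r = np.asarray(ranks, dtype=float)
    mean = r.sum() / 2.0
    var = (r**2).sum() / 4.0
    k4 = -(r**4).sum() / 8.0
    gamma2 = k4 / var**2

    def cdf(x: float) -> float:
        z = x / math.sqrt(var)
        phi = math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
        return _sps.norm.cdf(z) - phi * gamma2 / 24.0 * (z**3 - 3 * z)

    lower = cdf(w_plus + 0.5 - mean)
    upper = 1.0 - cdf(w_plus - 0.5 - mean)
    return float(min(2.0 * min(lower, upper), 1.0))


def paired_test(sample: PairedSample, **kwargs) -> TestResult:
    """Wilcoxon signed-rank test on a :class:`PairedSample`."""
    return wilcoxon_signed_rank_exact(sample.differences, **kwargs)


def ks_two_sample(
    group_a: Sequence[float],
    group_b: Sequence[float],
    *,
    exact_product_cutoff: int = 10_000,
) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    Exact null when ``len(a) * len(b) <= exact_product_cutoff``, asymptotic
    otherwise; the method used is recorded in the result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    exact = a.size * b.size <= exact_product_cutoff
    res = _sps.ks_2samp(a, b, method="exact" if exact else "asymp")
    return TestResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        int(a.size + b.size),
        "exact" if exact else "asymptotic",
    )


def silhouette_scores(
    points: np.ndarray, labels_by_k: dict[int, np.ndarray]
) -> dict[int, float | None]:
    """Mean silhouette coefficient per candidate cluster count.

    ``points`` must already be in the coordinates used for clustering
    (e.g. standardized force/ratio).  A clustering in which every cluster is
    a singleton has no defined silhouette and maps to ``None``.
    """
    pts = np.asarray(points, dtype=float)
    out: dict[int, float | None] = {}
    for k, labels in labels_by_k.items():
        labels = np.asarray(labels)
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size < 2:
            raise ValueError("silhouette requires >= 2 clusters")
        if (counts == 1).all():
            out[k] = None
            continue
        out[k] = float(silhouette_score(pts, labels, metric="euclidean"))
    return out
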