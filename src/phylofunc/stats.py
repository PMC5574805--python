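"""Inferential machinery: Mantel permutation test and Pearson correlation.

The Mantel statistic is the Pearson correlation between the unordered
off-diagonal entries of two distance matrices; its null distribution is
built by jointly permuting the rows and columns of the second matrix. The
permutation p-value follows the conservative add-one convention
p = (1 + #{perm >= observed}) / (1 + n_perm), so it can never be exactly 0.
An exhaustive mode enumerates all n! label permutations (identity included,
so p >= 1/n!) for exact small-n tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skbio import DistanceMatrix

# permutations tying the observed statistic to within float round-off
# count toward the p-value
_TIE_TOL = 1e-12

__all__ = ["TestResult", "mantel_test", "pearson_correlation_test"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int  # 0 for parametric tests
    seed: int | None
    alternative: str     # "greater" | "two-sided"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "alternative": self.alternative,
        }


def _aligned_arrays(d1: DistanceMatrix, d2: DistanceMatrix):
    ids1, ids2 = set(d1.ids), set(d2.ids)
    if ids1 != ids2:
        raise ValueError(
            "species sets differ: only in first "
            f"{sorted(ids1 - ids2)}, only in second {sorted(ids2 - ids1)}"
        )
    order = list(d1.ids)
    return np.asarray(d1.data, dtype=float), np.asarray(
        d2.filter(order).data, dtype=float
    )


def _pearson_condensed(a: np.ndarray, b: np.ndarray, iu) -> float:
    x, y = a[iu], b[iu]
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / denom)


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
                seed: int | None = None, exhaustive: bool = False) -> TestResult:
    """Mantel test of matrix correlation (one-sided, greater).

    Labels are aligned by species name; a mismatch is an error, never a
    silent reordering. With ``exhaustive=True`` all n! simultaneous
    row/column permutations of ``d2`` are enumerated and ``n_perm``/``seed``
    are ignored.
    """
    a, b = _aligned_arrays(d1, d2)
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs >= 4 species")
    iu = np.triu_indices(n, k=1)
    for name, m in (("first", a), ("second", b)):
        if np.ptp(m[iu]) == 0:
            raise ValueError(f"zero variance in {name} matrix off-diagonal")
    observed = _pearson_condensed(a, b, iu)
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        stats_null = np.array(
            [_pearson_condensed(a, b[np.ix_(p, p)], iu) for p in perms]
        )
        p_value = float(np.mean(stats_null >= observed - _TIE_TOL))
        return TestResult(statistic=observed, p_value=p_value,
                          n_permutations=len(perms), seed=None,
                          alternative="greater")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if _pearson_condensed(a, b[np.ix_(p, p)], iu) >= observed - _TIE_TOL:
            count += 1
    p_value = (1 + count) / (1 + n_perm)
    return TestResult(statistic=observed, p_value=p_value,
                      n_permutations=n_perm, seed=seed, alternative="greater")


def pearson_correlation_test(x, y) -> TestResult:
    """Pearson product-moment correlation with a two-sided t-test
    (df = n - 2) p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if len(x) < 3:
        raise ValueError("Pearson test needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p),
                      n_permutations=0, seed=None, alternative="two-sided")
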