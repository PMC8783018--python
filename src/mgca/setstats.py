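"""Set-level statistics for seed-set co-expression.

The observed quantity is the within-set CEC of the seed set (e.g.
seed-seed); the null collection is the CECs of many mRand-mRand,
seed-mRand, Rand-Rand or seed-Rand set pairs.  Three complementary tests
ask whether the observed value stands outside the null collection:

* Tukey-style 3x upper fence, Q3 + 3*(Q3 - Q1);
* one-sided (maximum) Grubbs outlier test on the combined sample;
* a direct permutation p-value, #{null >= observed} / n_perm.

A chi-square 2x2 enrichment test with log2 fold enrichment scores the
overlap of a result set with a reference set, and a combined
-log10(p) score ranks strata (e.g. brain regions) by how strongly the
seed set co-expresses within each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import MgcaDataError

__all__ = [
    "SetComparison",
    "upper_fence_test",
    "grubbs_test",
    "set_permutation_test",
    "chi2_enrichment",
    "combined_rank",
    "compare_null_collections",
]

QUARTILE_METHODS = ("linear", "lower", "higher", "midpoint", "nearest")


def upper_fence_test(
    observed: float,
    null_values: np.ndarray,
    quartile_method: str = "linear",
) -> tuple[float, bool]:
    """Tukey 3x upper-fence outlier test.

    Quartiles use linear interpolation between order statistics by default
    (configurable; fence calls can flip on small null collections, so the
    convention is recorded in output metadata).  The observed value is an
    outlier only if strictly above Q3 + 3*(Q3 - Q1).
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 4:
        raise MgcaDataError("upper fence needs at least 4 null values")
    if quartile_method not in QUARTILE_METHODS:
        raise MgcaDataError(f"unknown quartile method {quartile_method!r}")
    q1, q3 = np.percentile(nulls, [25, 75], method=quartile_method)
    fence = q3 + 3.0 * (q3 - q1)
    return float(fence), bool(observed > fence)


def grubbs_test(
    observed: float,
    null_values: np.ndarray,
    two_sided: bool = False,
) -> tuple[float, float]:
    """One-sided (maximum) Grubbs outlier test on observed + nulls.

    The statistic is G = (max(x) - mean(x)) / sd(x) on the combined sample
    (sd with one delta degree of freedom).  The p-value is the standard
    t-distribution closed form

        t^2 = n (n-2) G^2 / ((n-1)^2 - n G^2),
        p   = n * P(T_{n-2} > t),

    capped at 1; ``two_sided`` doubles the tail.  Note G is driven by the
    sample maximum wherever it lies, so the observed value is only flagged
    when it is itself the maximum.
    """
    x = np.append(np.asarray(null_values, dtype=float), observed)
    n = x.size
    if n < 3:
        raise MgcaDataError("Grubbs test needs at least 3 values in total")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise MgcaDataError("Grubbs test undefined for zero-variance sample")
    g = (x.max() - x.mean()) / sd
    gmax = (n - 1) / math.sqrt(n)
    if g >= gmax:  # numerically at the attainable maximum -> p = 0
        return float(g), 0.0
    t2 = n * (n - 2) * g * g / ((n - 1) ** 2 - n * g * g)
    p = n * stats.t.sf(math.sqrt(t2), n - 2)
    if two_sided:
        p *= 2.0
    return float(g), float(min(p, 1.0))


def set_permutation_test(
    observed: float, null_values: np.ndarray, n_perm: int | None = None
) -> tuple[float, str]:
    """Permutation p-value: fraction of null set-pair CECs >= observed.

    Returns the numeric p and a report string; p = 0 is reported as
    "< 1/n_perm" because no permutation reached the observed value.
    """
    nulls = np.asarray(null_values, dtype=float)
    n = nulls.size if n_perm is None else n_perm
    if n < 1:
        raise MgcaDataError("set permutation test needs n_perm >= 1")
    if nulls.size != n:
        raise MgcaDataError("null collection size does not match n_perm")
    p = float((nulls >= observed).sum()) / n
    text = f"< {1.0 / n:g}" if p == 0.0 else f"{p:g}"
    return p, text


def chi2_enrichment(
    hits_in_set: int,
    set_size: int,
    hits_in_universe: int,
    universe_size: int,
    yates: bool = False,
) -> tuple[float, float]:
    """Fold enrichment (log2) and chi-square p for a 2x2 overlap table.

    fold = (hits_in_set/set_size) / (hits_in_universe/universe_size); the
    p-value is the 1-df chi-square test on the set/non-set x hit/non-hit
    table, without continuity correction by default.
    """
    if not (0 <= hits_in_set <= set_size <= universe_size):
        raise MgcaDataError("inconsistent 2x2 table margins")
    if not (hits_in_set <= hits_in_universe <= universe_size):
        raise MgcaDataError("hits must be drawn from the universe")
    if hits_in_universe == 0 or set_size == 0:
        raise MgcaDataError("empty hit list or set: enrichment undefined")
    fold = (hits_in_set / set_size) / (hits_in_universe / universe_size)
    log2_fold = math.log2(fold) if fold > 0 else -math.inf
    if set_size == universe_size:
        # set == universe: observed equals expected by construction
        return 0.0, 1.0
    table = np.array(
        [
            [hits_in_set, set_size - hits_in_set],
            [hits_in_universe - hits_in_set,
             universe_size - set_size - (hits_in_universe - hits_in_set)],
        ],
        dtype=float,
    )
    if (table < 0).any():
        raise MgcaDataError("negative cell in 2x2 table")
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    expected = np.outer(row, col) / universe_size
    if (expected == 0).any():
        raise MgcaDataError(
            "zero expected count in 2x2 table; an exact test would be needed"
        )
    diff = np.abs(table - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return log2_fold, p


def combined_rank(
    p_by_stratum: dict[str, tuple[float, float, float]],
    p_floor: float = 1e-5,
) -> list[tuple[str, float]]:
    """Rank strata by the sum of -log10(p) over the three matched conditions.

    p-values of exactly 0 (below the permutation resolution) are floored at
    ``p_floor`` (1/n_perm) before taking logs.  Returns (stratum, score)
    sorted by descending score; exact score ties keep dict order and are
    reported as tied by equal score values.
    """
    if p_floor <= 0:
        raise MgcaDataError("p_floor must be positive")
    scores = []
    for stratum, ps in p_by_stratum.items():
        if len(ps) != 3:
            raise MgcaDataError(f"stratum {stratum!r} needs three p-values")
        s = 0.0
        for p in ps:
            if p < 0 or p > 1:
                raise MgcaDataError(f"p-value out of range in stratum {stratum!r}")
            s += -math.log10(max(p, p_floor))
        scores.append((stratum, s))
    scores.sort(key=lambda t: -t[1])
    return scores


@dataclass
class SetComparison:
    """Observed seed-seed CEC against one null collection of set-pair CECs."""

    label: str
    observed: float
    null_values: np.ndarray
    quartile_method: str = "linear"
    q1: float = field(init=False)
    q3: float = field(init=False)
    fence: float = field(init=False)
    fence_outlier: bool = field(init=False)
    grubbs_g: float = field(init=False)
    grubbs_p: float = field(init=False)
    perm_p: float = field(init=False)
    perm_p_text: str = field(init=False)

    def __post_init__(self) -> None:
        nulls = np.asarray(self.null_values, dtype=float)
        self.null_values = nulls
        self.q1, self.q3 = (
            float(v) for v in np.percentile(nulls, [25, 75], method=self.quartile_method)
        )
        self.fence, self.fence_outlier = upper_fence_test(
            self.observed, nulls, self.quartile_method
        )
        self.grubbs_g, self.grubbs_p = grubbs_test(self.observed, nulls)
        self.perm_p, self.perm_p_text = set_permutation_test(self.observed, nulls)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "observed_cec": self.observed,
            "n_null": int(self.null_values.size),
            "null_mean": float(self.null_values.mean()),
            "q1": self.q1,
            "q3": self.q3,
            "fence": self.fence,
            "fence_outlier": self.fence_outlier,
            "grubbs_g": self.grubbs_g,
            "grubbs_p": self.grubbs_p,
            "perm_p": self.perm_p,
            "perm_p_text": self.perm_p_text,
            "quartile_method": self.quartile_method,
        }


def compare_null_collections(
    matched: np.ndarray, unmatched: np.ndarray
) -> tuple[float, float]:
    """Two-sample t-test that matched (mRand-type) CECs exceed unmatched.

    One-sided Welch-free Student t, reported for parity with the usual
    box-plot annotation; returns (t, one-sided p).
    """
    t, p = stats.ttest_ind(np.asarray(matched, float), np.asarray(unmatched, float))
    one_sided = p / 2.0 if t > 0 else 1.0 - p / 2.0
    return float(t), float(one_sided)
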