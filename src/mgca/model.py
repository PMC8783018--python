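"""Matched-gene co-expression analysis (MGCA): model and results objects.

:class:`MGCA` binds an expression matrix, a per-gene feature table and a
seed gene set, applies the standard filtering (zero-variance genes out,
genes below the least-abundant seed gene out), caches the gene-by-gene
Pearson correlation matrix, and ranks the retained genome by each of the
three confounding features.  :meth:`MGCA.fit` then runs, per feature, the
matched-set permutation test:

1. draw N feature-matched random sets (mRand), one per permutation index,
   shared by every evaluated gene;
2. for each gene, count n = #{i : CEC_i < CEC_seed}, where CEC_i is the
   gene's co-expression coefficient with the i-th mRand set and CEC_seed
   its coefficient with the seed set (self-pairs excluded on both sides);
3. the empirical p-value is (N - n)/N; a gene is significantly
   co-expressed under that condition when n > N*(1-alpha) (strictly), and
   a TriM (triple-matched) gene when significant under all three.

The defaults (N = 100,000, alpha = 1e-4, window = +/-50 ranks, seed sets
of ~101 genes) follow the analysis the method was introduced with; scale
N down for exploratory runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpression import (
    CCMatrix,
    CECProfile,
    NoiseReducedCurve,
    cc_matrix_subsample,
    cec_set_vs_set,
    cubic_fit_r2,
    noise_reduced_curve,
)
from .features import (
    MatchedSampler,
    MatchedSamplerConfig,
    RankedGeneList,
    compute_abundance,
    filter_by_seed_abundance,
    rank_genes,
    sample_random_set,
)
from .io import ExpressionMatrix, GeneFeatureTable, GeneSet, MgcaDataError
from .setstats import SetComparison, compare_null_collections

logger = logging.getLogger("mgca")

__all__ = [
    "MGCA",
    "MGCAResults",
    "CONDITIONS",
    "call_significant",
    "build_trim",
    "build_top",
    "split_overlap",
]

#: the three matched conditions, in canonical order
CONDITIONS = ("abundance", "gdna_size", "gc_content")

#: substream keys so each condition's sampler is independent of the others
_CONDITION_KEY = {name: k for k, name in enumerate(CONDITIONS)}
_RAND_KEY = 101  # substream key for non-matched Rand sets
_DECOY_KEY = 211  # substream key for FDR decoy seeds


def call_significant(n_success: np.ndarray, n_perm: int, alpha: float) -> np.ndarray:
    """Significance flags: n_success strictly above n_perm*(1-alpha).

    With N = 100,000 and alpha = 1e-4 the cut is n > 99,990; a gene exactly
    at the threshold is not significant.
    """
    threshold_n = int(round(n_perm * (1.0 - alpha)))
    if threshold_n >= n_perm:
        raise MgcaDataError(
            f"threshold n={threshold_n} >= n_perm={n_perm}: alpha too small "
            "for this permutation depth"
        )
    return np.asarray(n_success) > threshold_n


def build_trim(flags: Mapping[str, np.ndarray], gene_ids: Sequence[str]) -> GeneSet:
    """Intersection of the per-condition significant sets, in universe order."""
    missing = [c for c in CONDITIONS if c not in flags]
    if missing:
        raise MgcaDataError(f"missing conditions for TriM: {missing}")
    mask = np.logical_and.reduce([np.asarray(flags[c], bool) for c in CONDITIONS])
    members = [g for g, m in zip(gene_ids, mask) if m]
    if not members:
        raise MgcaDataError("TriM set is empty at this threshold")
    return GeneSet("TriM", members)


def build_top(profile: CECProfile, count: int) -> GeneSet:
    """The ``count`` genes with the highest CEC; cutoff ties break by gene ID."""
    if count < 1 or count > len(profile.gene_ids):
        raise MgcaDataError(f"count must be in [1, {len(profile.gene_ids)}]")
    ids = np.array(profile.gene_ids)
    lex = np.argsort(ids, kind="stable")  # secondary key: gene ID
    by_cec = lex[np.argsort(-profile.cec[lex], kind="stable")]
    cutoff_cec = profile.cec[by_cec[count - 1]]
    if count < ids.size and profile.cec[by_cec[count]] == cutoff_cec:
        logger.info("build_top: tie at the CEC cutoff broken by gene ID")
    return GeneSet("Top", [str(ids[i]) for i in by_cec[:count]])


def split_overlap(a: GeneSet, b: GeneSet) -> tuple[GeneSet | None, GeneSet | None, GeneSet | None]:
    """Partition two sets into (a_only, overlap, b_only); empty parts are None."""
    in_b = set(b.gene_ids)
    in_a = set(a.gene_ids)
    a_only = [g for g in a if g not in in_b]
    overlap = [g for g in a if g in in_b]
    b_only = [g for g in b if g not in in_a]

    def mk(name: str, ids: list[str]) -> GeneSet | None:
        return GeneSet(name, ids) if ids else None

    return (
        mk(f"{a.name}-only", a_only),
        mk(f"{a.name}&{b.name}", overlap),
        mk(f"{b.name}-only", b_only),
    )


class MGCA:
    """Matched-gene co-expression analysis of one seed set on one panel.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x samples normalized expression (RPKM-like).
    seed_set : GeneSet
        The seed genes (e.g. a risk-gene set); must survive filtering.
    features : GeneFeatureTable, optional
        Per-gene gDNA size and GC content (and optionally abundance).  By
        default abundance is (re)computed as the row mean of the expression
        matrix so the ranking axis always matches the panel analysed; pass
        ``recompute_abundance=False`` to keep a precomputed column.
    window : int
        Matching half-window in ranks (default 50).
    log_transform : bool
        Apply log2(x+1) before correlating (default off: correlations on
        the values as provided).
    filter_abundance : bool
        Drop genes less abundant than the least-abundant seed gene
        (default on, as in the standard workflow).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        seed_set: GeneSet,
        features: GeneFeatureTable,
        window: int = 50,
        log_transform: bool = False,
        filter_abundance: bool = True,
        recompute_abundance: bool = True,
    ) -> None:
        if window < 1:
            raise MgcaDataError("window must be >= 1")
        self.window = int(window)
        self.log_transform = bool(log_transform)
        self.seed_input = seed_set

        # align features to the expression matrix
        common = [g for g in expression.gene_ids if g in features]
        dropped = len(expression.gene_ids) - len(common)
        if dropped:
            logger.info("dropping %d genes without feature annotation", dropped)
        if not common:
            raise MgcaDataError("no overlap between expression matrix and feature table")
        expression = expression.subset_genes(common)
        features = features.subset(common)

        if recompute_abundance:
            tab = features.table.copy()
            tab["abundance"] = compute_abundance(expression)
            features = GeneFeatureTable(tab.reset_index(drop=True))

        # zero-variance genes have undefined correlations
        vals = np.log2(expression.values + 1.0) if log_transform else expression.values
        sd = vals.std(axis=1)
        if (sd == 0).any():
            keep = [g for g, ok in zip(expression.gene_ids, sd > 0) if ok]
            logger.info("dropping %d zero-variance genes", int((sd == 0).sum()))
            expression = expression.subset_genes(keep)
            features = features.subset(keep)

        seed_resolved, unresolved = seed_set.resolve(features)
        if unresolved:
            logger.warning("seed set: %d unresolved IDs dropped", len(unresolved))
        if filter_abundance:
            features = filter_by_seed_abundance(features, seed_resolved)
            expression = expression.subset_genes(features.gene_ids)

        self.expression = expression
        self.features = features
        self.seed_set = GeneSet(seed_set.name, seed_resolved.gene_ids)
        self.gene_ids: list[str] = list(features.gene_ids)
        self.n_genes = len(self.gene_ids)
        if len(self.seed_set) < 2:
            raise MgcaDataError("seed set must retain at least 2 genes")

        self.cc = CCMatrix.from_expression(expression, log_transform=log_transform)
        self.ranked: dict[str, RankedGeneList] = {
            name: rank_genes(features, name) for name in CONDITIONS
        }
        self.seed_profile = CECProfile.from_cc(self.cc, self.seed_set)
        self._universe_index = {g: i for i, g in enumerate(self.cc.gene_ids)}
        self._seed_idx = self.cc.indices_of(self.seed_set)

    # -- construction helpers ------------------------------------------

    @classmethod
    def from_dataframes(
        cls,
        expression: pd.DataFrame,
        features: pd.DataFrame,
        seed_genes: Iterable[str],
        samples: pd.DataFrame | None = None,
        **kwargs,
    ) -> "MGCA":
        """Build from pandas objects: expression (genes x samples, gene IDs
        as index), features (gene_id/abundance/gdna_size/gc_content columns),
        and an iterable of seed gene IDs."""
        return cls(
            ExpressionMatrix.from_dataframe(expression, samples),
            GeneSet("seed", list(seed_genes)),
            GeneFeatureTable(features),
            **kwargs,
        )

    # -- permutation machinery -----------------------------------------

    def _sampler(self, condition: str, seed: int | None, n_sets: int,
                 seed_set: GeneSet | None = None,
                 extra_exclude: frozenset[str] = frozenset()) -> MatchedSampler:
        target = seed_set if seed_set is not None else self.seed_set
        cfg = MatchedSamplerConfig(
            window=self.window,
            n_sets=n_sets,
            seed=seed,
            exclude=frozenset(target.gene_ids) | extra_exclude,
        )
        return MatchedSampler(self.ranked[condition], target, cfg,
                              key=_CONDITION_KEY[condition])

    def _cec_for_indices(self, member_idx: np.ndarray) -> np.ndarray:
        return self.cc.cec_all_genes(member_idx)

    def _count_successes(
        self,
        sampler: MatchedSampler,
        cec_ref: np.ndarray,
        n_perm: int,
    ) -> np.ndarray:
        """n_success per gene over n_perm sampled sets (order-independent sum)."""
        n_success = np.zeros(self.n_genes, dtype=np.int64)
        cc = self.cc.values
        m = len(sampler.seed_set)
        denom_full = float(m)
        for i in range(n_perm):
            idx = np.array(
                [self._universe_index[g] for g in sampler._sample_members(i)],
                dtype=np.int64,
            )
            sums = cc[:, idx].sum(axis=1)
            sums[idx] -= 1.0
            cec_i = sums / denom_full
            cec_i[idx] = sums[idx] / (m - 1)
            n_success += cec_i < cec_ref
        return n_success

    def fit(
        self,
        n_perm: int = 100_000,
        alpha: float = 1e-4,
        seed: int | None = 0,
        conditions: Sequence[str] = CONDITIONS,
        exhaustive: bool = False,
    ) -> "MGCAResults":
        """Run the matched permutation test under each condition.

        ``exhaustive=True`` replaces sampling by complete enumeration of the
        matched-set tree (toy instances only): the per-gene success fraction
        is then the exact probability P(CEC_i < CEC_seed) under the sampler's
        distribution, and n_perm is ignored.
        """
        if n_perm < 1:
            raise MgcaDataError("n_perm must be >= 1")
        unknown = [c for c in conditions if c not in CONDITIONS]
        if unknown:
            raise MgcaDataError(f"unknown conditions: {unknown}")
        cec_seed = self.seed_profile.cec
        n_succ: dict[str, np.ndarray] = {}
        frac: dict[str, np.ndarray] = {}
        for cond in conditions:
            if exhaustive:
                sampler = self._sampler(cond, seed, 1)
                prob = np.zeros(self.n_genes)
                total = 0.0
                n_leaves = 0
                for members, p in sampler.enumerate_sets():
                    idx = np.array([self._universe_index[g] for g in members])
                    m = len(idx)
                    sums = self.cc.values[:, idx].sum(axis=1)
                    sums[idx] -= 1.0
                    cec_i = sums / float(m)
                    cec_i[idx] = sums[idx] / (m - 1)
                    prob += p * (cec_i < cec_seed)
                    total += p
                    n_leaves += 1
                if abs(total - 1.0) > 1e-9:
                    raise MgcaDataError("enumeration probabilities do not sum to 1")
                frac[cond] = prob
                n_succ[cond] = np.round(prob * n_leaves).astype(np.int64)
            else:
                sampler = self._sampler(cond, seed, n_perm)
                ns = self._count_successes(sampler, cec_seed, n_perm)
                n_succ[cond] = ns
                frac[cond] = ns / float(n_perm)
        return MGCAResults(
            model=self,
            conditions=tuple(conditions),
            n_perm=n_perm,
            alpha=alpha,
            seed=seed,
            n_success=n_succ,
            frac_success=frac,
            exhaustive=exhaustive,
        )

    # -- per-gene FDR ---------------------------------------------------

    def estimate_fdr(
        self,
        n_decoy: int = 50,
        inner_n_perm: int = 1000,
        inner_alpha: float = 1e-3,
        seed: int | None = 0,
        genes: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Per-gene false-discovery frequency over decoy seed sets.

        Each decoy is an mRand set feature-matched to the real seed set
        (conditions cycled over decoys) used as a surrogate seed; the full
        three-condition analysis is rerun against it at ``inner_alpha``,
        and a gene's FDR estimate is the fraction of decoys under which
        the gene comes out significant under all three conditions.  The
        reference depth is 5,000 decoys at inner alpha 1e-3; the default
        is a reduced 50 x 1,000 run, with the depth used recorded in the
        returned frame's ``attrs``.  ``genes`` restricts the report to a
        probe subset (the computation is genome-wide regardless).
        """
        if n_decoy < 1:
            raise MgcaDataError("n_decoy must be >= 1")
        root = seed
        sel = (
            np.arange(self.n_genes)
            if genes is None
            else np.array([self._universe_index[g] for g in genes])
        )
        hit_count = np.zeros(sel.size, dtype=np.int64)
        for j in range(n_decoy):
            cond = CONDITIONS[j % len(CONDITIONS)]
            decoy_sampler = MatchedSampler(
                self.ranked[cond],
                self.seed_set,
                MatchedSamplerConfig(
                    window=self.window, n_sets=1, seed=root,
                    exclude=frozenset(self.seed_set.gene_ids),
                ),
                key=_DECOY_KEY + j,
            )
            decoy = GeneSet(f"decoy[{j}]", decoy_sampler._sample_members(0))
            decoy_profile = CECProfile.from_cc(self.cc, decoy)
            sig = np.ones(sel.size, dtype=bool)
            for cond_i in CONDITIONS:
                sampler = MatchedSampler(
                    self.ranked[cond_i],
                    decoy,
                    MatchedSamplerConfig(
                        window=self.window, n_sets=inner_n_perm,
                        seed=None if root is None else root + 7919 * (j + 1),
                        exclude=frozenset(decoy.gene_ids),
                    ),
                    key=_CONDITION_KEY[cond_i],
                )
                ns = self._count_successes(sampler, decoy_profile.cec, inner_n_perm)
                sig &= call_significant(ns, inner_n_perm, inner_alpha)[sel]
                if not sig.any():
                    break
            hit_count += sig
        out = pd.DataFrame(
            {
                "gene_id": [self.gene_ids[i] for i in sel],
                "fdr_frequency": hit_count / float(n_decoy),
            }
        )
        out.attrs["n_decoy"] = n_decoy
        out.attrs["inner_n_perm"] = inner_n_perm
        out.attrs["inner_alpha"] = inner_alpha
        return out

    # -- set-level battery ---------------------------------------------

    def set_battery(
        self,
        n_sets: int = 200,
        seed: int | None = 0,
        quartile_method: str = "linear",
    ) -> dict[str, SetComparison | dict]:
        """Seed-seed CEC against mRand/Rand null collections.

        For each matched condition: the within-set CECs of ``n_sets`` mRand
        sets (mRand-mRand) and the seed-vs-mRand cross CECs; plus the
        non-matched analogues from plain random sets (Rand-Rand,
        seed-Rand) and a one-sided t comparison of matched vs non-matched
        null collections.
        """
        observed = cec_set_vs_set(self.seed_set, self.seed_set, self.cc)
        out: dict[str, SetComparison | dict] = {"observed": observed}
        rand_within = np.empty(n_sets)
        rand_cross = np.empty(n_sets)
        exclude = frozenset(self.seed_set.gene_ids)
        for i in range(n_sets):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed or 0, spawn_key=(_RAND_KEY, i))
            )
            rs = sample_random_set(self.gene_ids, len(self.seed_set), rng,
                                   exclude=exclude, name=f"Rand[{i}]")
            rand_within[i] = cec_set_vs_set(rs, rs, self.cc)
            rand_cross[i] = cec_set_vs_set(self.seed_set, rs, self.cc)
        out["Rand-Rand"] = SetComparison("Rand-Rand", observed, rand_within,
                                         quartile_method)
        out["seed-Rand"] = SetComparison("seed-Rand", observed, rand_cross,
                                         quartile_method)
        ttests = {}
        for cond in CONDITIONS:
            sampler = self._sampler(cond, seed, n_sets)
            within = np.empty(n_sets)
            cross = np.empty(n_sets)
            for i in range(n_sets):
                ms = sampler.sample_one(i)
                within[i] = cec_set_vs_set(ms, ms, self.cc)
                cross[i] = cec_set_vs_set(self.seed_set, ms, self.cc)
            out[f"mRand-mRand[{cond}]"] = SetComparison(
                f"mRand-mRand[{cond}]", observed, within, quartile_method)
            out[f"seed-mRand[{cond}]"] = SetComparison(
                f"seed-mRand[{cond}]", observed, cross, quartile_method)
            t_w, p_w = compare_null_collections(within, rand_within)
            t_c, p_c = compare_null_collections(cross, rand_cross)
            ttests[cond] = {
                "within_t": t_w, "within_p_one_sided": p_w,
                "cross_t": t_c, "cross_p_one_sided": p_c,
            }
        out["matched_vs_random_t"] = ttests
        return out

    # -- curves and exports --------------------------------------------

    def noise_reduced_curves(
        self, ks: Sequence[int] = (10, 25, 50, 100)
    ) -> dict[str, dict[int, NoiseReducedCurve]]:
        """Noise-reduced seed-CEC curves (with cubic R^2) per condition."""
        out: dict[str, dict[int, NoiseReducedCurve]] = {}
        for cond in CONDITIONS:
            out[cond] = {}
            for k in ks:
                curve = noise_reduced_curve(self.seed_profile, self.ranked[cond], k)
                curve.r2_cubic = cubic_fit_r2(curve)
                out[cond][k] = curve
        return out

    def cc_submatrix(self, condition: str = "abundance", stride: int = 100) -> pd.DataFrame:
        """Every stride-th gene's CC block along one ranked order (heatmap input)."""
        return cc_matrix_subsample(self.cc, self.ranked[condition], stride)

    # -- stratification -------------------------------------------------

    def stratify(
        self, selector: Mapping[str, object] | Callable[[pd.DataFrame], np.ndarray]
    ) -> "MGCA":
        """Rebuild the whole model on a metadata-selected sample subset.

        ``selector`` is either a column->allowed-value(s) mapping over the
        sample metadata or a callable returning a boolean mask.  Abundance,
        filtering and correlations are all recomputed on the subset.
        """
        meta = self.expression.samples
        if callable(selector):
            mask = np.asarray(selector(meta), dtype=bool)
        else:
            mask = np.ones(len(meta), dtype=bool)
            for col, allowed in selector.items():
                if col not in meta.columns:
                    raise MgcaDataError(f"no sample metadata column {col!r}")
                vals = (allowed,) if isinstance(allowed, str) else tuple(allowed)
                mask &= meta[col].isin(vals).to_numpy()
        if mask.sum() < 2:
            raise MgcaDataError("stratum has fewer than 2 samples")
        sub = self.expression.subset_samples(mask)
        return MGCA(
            sub,
            self.seed_input,
            self.features,
            window=self.window,
            log_transform=self.log_transform,
        )


@dataclass
class MGCAResults:
    """Per-gene outcome of a fitted matched permutation analysis."""

    model: MGCA
    conditions: tuple[str, ...]
    n_perm: int
    alpha: float
    seed: int | None
    n_success: dict[str, np.ndarray]
    frac_success: dict[str, np.ndarray]
    exhaustive: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = self.model.gene_ids
        self.cec_seed = self.model.seed_profile.cec
        self.p_empirical = {
            c: 1.0 - self.frac_success[c] for c in self.conditions
        }
        self.significant = {
            c: (self.frac_success[c] > round(self.n_perm * (1 - self.alpha)) / self.n_perm)
            if self.exhaustive
            else call_significant(self.n_success[c], self.n_perm, self.alpha)
            for c in self.conditions
        }
        if set(self.conditions) >= set(CONDITIONS):
            self.trim_mask = np.logical_and.reduce(
                [self.significant[c] for c in CONDITIONS]
            )
        else:
            self.trim_mask = None

    # -- tables ---------------------------------------------------------

    @property
    def table(self) -> pd.DataFrame:
        """Per-gene results: CEC_seed, n, p and flag per condition, TriM."""
        cols: dict[str, object] = {
            "gene_id": self.gene_ids,
            "cec_seed": self.cec_seed,
        }
        floor_text = f"< {1.0 / self.n_perm:g}"
        for c in self.conditions:
            p = self.p_empirical[c]
            cols[f"n_{c}"] = self.n_success[c]
            cols[f"p_{c}"] = p
            cols[f"p_{c}_text"] = [floor_text if v == 0.0 else f"{v:g}" for v in p]
            cols[f"sig_{c}"] = self.significant[c]
        if self.trim_mask is not None:
            cols["trim"] = self.trim_mask
        return pd.DataFrame(cols)

    def summary(self) -> str:
        lines = [
            "Matched-gene co-expression analysis",
            "===================================",
            f"genes evaluated:      {len(self.gene_ids)}",
            f"seed set:             {self.model.seed_set.name} "
            f"({len(self.model.seed_set)} genes)",
            f"samples:              {self.model.expression.n_samples}",
            f"match window:         +/-{self.model.window} ranks",
            f"permutations:         {'exhaustive' if self.exhaustive else self.n_perm}",
            f"alpha (per condition): {self.alpha:g}"
            + ("" if self.exhaustive else
               f"  (significant iff n > {int(round(self.n_perm * (1 - self.alpha)))})"),
            "",
            "condition      significant",
        ]
        for c in self.conditions:
            lines.append(f"  {c:<12} {int(self.significant[c].sum()):>6}")
        if self.trim_mask is not None:
            lines.append(f"  {'TriM':<12} {int(self.trim_mask.sum()):>6}")
        return "\n".join(lines)

    # -- derived gene sets ----------------------------------------------

    def trim_set(self) -> GeneSet:
        if self.trim_mask is None:
            raise MgcaDataError("TriM requires all three conditions")
        return build_trim(self.significant, self.gene_ids)

    def top_set(self, count: int | None = None) -> GeneSet:
        if count is None:
            if self.trim_mask is None:
                raise MgcaDataError("count required when TriM is unavailable")
            count = int(self.trim_mask.sum())
        return build_top(self.model.seed_profile, count)

    def trim_top_overlap(self, count: int | None = None):
        """(TriM-only, overlap, Top-only) at matched sizes."""
        trim = self.trim_set()
        top = self.top_set(count if count is not None else len(trim))
        return split_overlap(trim, top)

    # -- FDR --------------------------------------------------------------

    def estimate_fdr(
        self,
        n_decoy: int = 50,
        inner_n_perm: int = 1000,
        inner_alpha: float = 1e-3,
        seed: int | None = None,
        genes: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Per-gene false-discovery frequency over decoy seed sets.

        Each decoy is an mRand set feature-matched to the real seed set
        (conditions cycled over decoys) used as a surrogate seed; the full
        three-condition analysis is rerun against it at ``inner_alpha``,
        and a gene's FDR estimate is the fraction of decoys for which the
        gene comes out significant under all three conditions.  The
        reference depth is 5,000 decoys at inner alpha 1e-3; the default
        here is a reduced 50 x 1,000 run, and the depth used is recorded in
        the returned frame's ``attrs``.
        """
        return self.model.estimate_fdr(
            n_decoy=n_decoy,
            inner_n_perm=inner_n_perm,
            inner_alpha=inner_alpha,
            seed=self.seed if seed is None else seed,
            genes=genes,
        )
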