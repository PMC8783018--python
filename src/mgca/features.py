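"""Feature ranking and the feature-matched random-set sampler.

Genes are ranked genome-wide by each of three confounding features — mRNA
abundance, gDNA size, GC content.  A matched random set (mRand) replaces
each seed-set gene by a gene drawn uniformly from the window of ranks
within +/- ``window`` (default 50) of that gene on one ranked list, so the
random set reproduces the seed set's profile on that feature.  Comparing a
gene's co-expression with the seed set against its co-expression with many
mRand sets isolates co-expression that the feature alone cannot explain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io import FEATURE_NAMES, ExpressionMatrix, GeneFeatureTable, GeneSet, MgcaDataError

__all__ = [
    "RankedGeneList",
    "MatchedSamplerConfig",
    "MatchedSampler",
    "compute_abundance",
    "filter_by_seed_abundance",
    "rank_genes",
    "sample_matched_set",
]


def compute_abundance(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-gene mRNA abundance: arithmetic mean expression over all samples."""
    return matrix.values.mean(axis=1)


def filter_by_seed_abundance(
    features: GeneFeatureTable, seed: GeneSet
) -> GeneFeatureTable:
    """Drop genes whose abundance is below the least-abundant seed gene.

    Every seed gene must be present in the table; all seed genes survive by
    construction.
    """
    missing = [g for g in seed if g not in features]
    if missing:
        raise MgcaDataError(f"seed genes absent from feature table: {missing}")
    abundance = features.feature("abundance")
    floor = min(abundance.loc[g] for g in seed)
    keep = features.table.index[abundance.to_numpy() >= floor]
    return features.subset(keep)


@dataclass
class RankedGeneList:
    """Genes in ascending order of one feature, with 1-based rank lookup.

    Ties are broken by gene ID (lexicographic) so the ordering is a
    deterministic bijection.
    """

    feature_name: str
    order: list[str]
    rank_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.rank_of = {g: r for r, g in enumerate(self.order, start=1)}
        if len(self.rank_of) != len(self.order):
            raise MgcaDataError("ranked list contains duplicate gene IDs")

    def __len__(self) -> int:
        return len(self.order)

    def gene_at(self, rank: int) -> str:
        """Gene at 1-based rank."""
        return self.order[rank - 1]

    def window_ranks(self, gene_id: str, window: int) -> range:
        """1-based ranks within +/- window of the gene, truncated at the ends."""
        r = self.rank_of[gene_id]
        return range(max(1, r - window), min(len(self.order), r + window) + 1)


def rank_genes(features: GeneFeatureTable, feature_name: str) -> RankedGeneList:
    """Rank all genes ascending by one feature (stable; ties by gene ID)."""
    values = features.feature(feature_name)  # validates the name
    ids = np.array(features.gene_ids)
    # secondary lexicographic key first, then stable sort on the feature
    ids_sorted = ids[np.argsort(ids, kind="stable")]
    vals_sorted = values.loc[ids_sorted].to_numpy()
    order = ids_sorted[np.argsort(vals_sorted, kind="stable")]
    return RankedGeneList(feature_name, list(order))


@dataclass
class MatchedSamplerConfig:
    """Parameters of the mRand sampler.

    window: ranks above/below a seed gene eligible as its match.
    n_sets: how many mRand sets to draw.
    seed: root RNG seed; set ``i`` uses an independent substream keyed by
        ``i`` so results do not depend on how sets are partitioned over
        workers.
    exclude: genes never sampled (always a superset of the seed set).
    """

    window: int = 50
    n_sets: int = 1
    seed: int | None = None
    exclude: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.window < 1:
            raise MgcaDataError("window must be >= 1")
        if self.n_sets < 1:
            raise MgcaDataError("n_sets must be >= 1")
        self.exclude = frozenset(self.exclude)


class MatchedSampler:
    """Draws feature-matched random gene sets for one ranked list.

    For each seed gene, the candidate pool is the +/- window of ranks around
    it minus the gene itself, minus all excluded genes.  Members are drawn
    uniformly per seed gene in seed-set order; a draw colliding with a gene
    already chosen for the set is rejected and redrawn, so a set never holds
    duplicates.
    """

    def __init__(
        self,
        ranked: RankedGeneList,
        seed_set: GeneSet,
        config: MatchedSamplerConfig,
        key: int = 0,
    ) -> None:
        if not set(config.exclude) >= set(seed_set.gene_ids):
            raise MgcaDataError("sampler exclude list must contain the seed set")
        self.ranked = ranked
        self.seed_set = seed_set
        self.config = config
        self._key = key  # distinguishes substreams across matched conditions
        self.pools: list[np.ndarray] = []
        for g in seed_set:
            if g not in ranked.rank_of:
                raise MgcaDataError(f"seed gene {g!r} has no rank on {ranked.feature_name}")
            pool = [
                ranked.gene_at(r)
                for r in ranked.window_ranks(g, config.window)
                if ranked.gene_at(r) != g and ranked.gene_at(r) not in config.exclude
            ]
            if len(pool) < 1:
                raise MgcaDataError(
                    f"empty candidate pool for seed gene {g!r} on "
                    f"{ranked.feature_name}; reduce the window exclusions or "
                    f"use a larger gene universe"
                )
            self.pools.append(np.array(pool, dtype=object))
        # pools must jointly allow a duplicate-free set
        if min(len(p) for p in self.pools) < len(seed_set):
            # cheap sufficient check is too strict; fall back to greedy check
            self._check_feasible()

    def _check_feasible(self) -> None:
        # Hall-style greedy: process pools by size, ensure enough distinct genes
        taken: set[str] = set()
        for pool in sorted(self.pools, key=len):
            avail = [g for g in pool if g not in taken]
            if not avail:
                raise MgcaDataError(
                    f"candidate pools on {self.ranked.feature_name} cannot supply "
                    "a duplicate-free matched set; use a smaller window or seed set"
                )
            taken.add(avail[0])

    def _rng(self, set_index: int) -> np.random.Generator:
        if self.config.seed is None:
            return np.random.default_rng()
        ss = np.random.SeedSequence(self.config.seed, spawn_key=(self._key, set_index))
        return np.random.default_rng(ss)

    def sample_one(self, set_index: int = 0) -> GeneSet:
        """Draw mRand set number ``set_index`` (bit-reproducible per index)."""
        chosen = self._sample_members(set_index)
        return GeneSet(f"mRand[{self.ranked.feature_name}][{set_index}]", chosen)

    def _sample_members(self, set_index: int) -> list[str]:
        rng = self._rng(set_index)
        pools = self.pools
        # one uniform draw per position up front; collisions redrawn per gene
        first = rng.random(len(pools))
        chosen: list[str] = []
        members: set[str] = set()
        for j, pool in enumerate(pools):
            g = pool[int(first[j] * len(pool))]
            tries = 0
            while g in members:
                tries += 1
                if tries > 20 * len(pool):
                    avail = [x for x in pool if x not in members]
                    if not avail:
                        raise MgcaDataError(
                            "candidate pool exhausted while resolving collisions"
                        )
                    g = avail[rng.integers(0, len(avail))]
                    break
                g = pool[rng.integers(0, len(pool))]
            chosen.append(g)
            members.add(g)
        return chosen

    def sample_indices(self, universe_index: dict[str, int], n_sets: int | None = None
                       ) -> np.ndarray:
        """Draw ``n_sets`` sets as an (n_sets, set_size) array of universe indices."""
        n = self.config.n_sets if n_sets is None else n_sets
        out = np.empty((n, len(self.seed_set)), dtype=np.int64)
        for i in range(n):
            out[i] = [universe_index[g] for g in self._sample_members(i)]
        return out

    def enumerate_sets(self):
        """Yield every reachable matched set with its sampling probability.

        Walks the sequential draw tree: position ``j`` is uniform over its
        pool, with collision rejection conditioning on genes already chosen.
        Feasible only for toy instances (product of pool sizes is small).
        """
        pools = [list(p) for p in self.pools]
        n_leaves = 1
        for p in pools:
            n_leaves *= len(p)
            if n_leaves > 2_000_000:
                raise MgcaDataError("enumeration infeasible: candidate tree too large")

        def rec(j: int, chosen: tuple[str, ...], prob: float):
            if j == len(pools):
                yield chosen, prob
                return
            avail = [g for g in pools[j] if g not in chosen]
            if not avail:
                return
            for g in avail:
                yield from rec(j + 1, chosen + (g,), prob / len(avail))

        yield from rec(0, (), 1.0)


def sample_matched_set(
    ranked: RankedGeneList,
    seed_set: GeneSet,
    config: MatchedSamplerConfig,
    set_index: int = 0,
) -> GeneSet:
    """One-shot convenience wrapper around :class:`MatchedSampler`."""
    return MatchedSampler(ranked, seed_set, config).sample_one(set_index)


def sample_random_set(
    universe: list[str],
    size: int,
    rng: np.random.Generator,
    exclude: frozenset[str] = frozenset(),
    name: str = "Rand",
) -> GeneSet:
    """A plain random (non-matched) gene set, for Rand-type baselines."""
    candidates = [g for g in universe if g not in exclude]
    if len(candidates) < size:
        raise MgcaDataError("not enough candidates for a random set")
    picks = rng.choice(len(candidates), size=size, replace=False)
    return GeneSet(name, [candidates[i] for i in picks])
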