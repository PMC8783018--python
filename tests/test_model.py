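"""The permutation engine: thresholds, TriM/Top, enumeration, stratification, FDR."""

import itertools

import numpy as np
import pytest

from mgca.coexpression import CCMatrix, CECProfile
from mgca.io import GeneSet, MgcaDataError
from mgca.model import (
    MGCA,
    build_top,
    build_trim,
    call_significant,
    split_overlap,
)

from conftest import toy_six_gene_model


class TestCallSignificant:
    def test_headline_threshold(self):
        # N = 100,000 at alpha 1e-4: significant iff n > 99,990
        n = np.array([99_990, 99_991, 100_000, 0])
        flags = call_significant(n, 100_000, 1e-4)
        assert flags.tolist() == [False, True, True, False]

    def test_reduced_depth_closed_form(self):
        # N = 1,000 at alpha 0.01 -> threshold 990 (strict)
        flags = call_significant(np.array([990, 991]), 1000, 0.01)
        assert flags.tolist() == [False, True]

    def test_threshold_must_resolve(self):
        with pytest.raises(MgcaDataError):
            call_significant(np.array([5]), 100, 1e-6)


class TestTrimTopOverlap:
    def test_trim_is_triple_intersection(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        flags = {
            c: rng.random(200) < 0.3
            for c in ("abundance", "gdna_size", "gc_content")
        }
        trim = build_trim(flags, genes)
        oracle = {
            g
            for g, a, b, c in zip(
                genes, flags["abundance"], flags["gdna_size"], flags["gc_content"]
            )
            if a and b and c
        }
        assert set(trim.gene_ids) == oracle
        # order follows the universe order
        assert trim.gene_ids == [g for g in genes if g in oracle]

    def test_missing_condition_is_error(self):
        with pytest.raises(MgcaDataError):
            build_trim({"abundance": np.array([True])}, ["g"])

    def test_top_is_argmax_for_count_one(self):
        prof = CECProfile("s", ["a", "b", "c"], np.array([0.1, 0.9, 0.4]))
        assert build_top(prof, 1).gene_ids == ["b"]

    def test_top_whole_universe(self):
        prof = CECProfile("s", ["a", "b", "c"], np.array([0.1, 0.9, 0.4]))
        assert set(build_top(prof, 3).gene_ids) == {"a", "b", "c"}

    def test_top_matches_sort_then_slice_oracle(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i:04d}" for i in range(1000)]
        cec = rng.normal(0.3, 0.1, 1000)
        prof = CECProfile("s", genes, np.clip(cec, -1, 1))
        top = build_top(prof, 237)
        oracle = [g for _, g in sorted(zip(-prof.cec, genes))][:237]
        assert set(top.gene_ids) == set(oracle)

    def test_top_cutoff_tie_broken_by_gene_id(self):
        prof = CECProfile("s", ["bb", "aa", "cc"], np.array([0.5, 0.5, 0.5]))
        assert build_top(prof, 2).gene_ids == ["aa", "bb"]

    def test_split_overlap_partition(self):
        a = GeneSet("A", ["x", "y", "z"])
        b = GeneSet("B", ["y", "z", "w"])
        a_only, overlap, b_only = split_overlap(a, b)
        assert a_only.gene_ids == ["x"]
        assert overlap.gene_ids == ["y", "z"]
        assert b_only.gene_ids == ["w"]
        assert len(a_only) + len(overlap) == len(a)

    def test_split_overlap_identical_and_disjoint(self):
        a = GeneSet("A", ["x", "y"])
        only_a, ov, only_b = split_overlap(a, GeneSet("B", ["x", "y"]))
        assert only_a is None and only_b is None and len(ov) == 2
        only_a, ov, only_b = split_overlap(a, GeneSet("C", ["q"]))
        assert ov is None

    def test_split_overlap_matches_hash_oracle(self):
        rng = np.random.default_rng(2)
        universe = [f"u{i}" for i in range(1000)]
        a = GeneSet("A", list(rng.choice(universe, 200, replace=False)))
        b = GeneSet("B", list(rng.choice(universe, 200, replace=False)))
        a_only, overlap, b_only = split_overlap(a, b)
        sa, sb = set(a.gene_ids), set(b.gene_ids)
        assert set(a_only.gene_ids if a_only else []) == sa - sb
        assert set(overlap.gene_ids if overlap else []) == sa & sb
        assert set(b_only.gene_ids if b_only else []) == sb - sa


class TestExhaustiveToy:
    """6-gene instance, window 1: the matched-set tree is fully enumerable."""

    def test_exact_probabilities_match_brute_force(self):
        model = toy_six_gene_model()
        res = model.fit(exhaustive=True, alpha=0.25)
        # oracle: candidate pools are {t1,t3} x {t4,t6}, uniform over 4 sets
        cc = model.cc
        cec_seed = model.seed_profile.cec
        pools = [["t1", "t3"], ["t4", "t6"]]
        combos = list(itertools.product(*pools))
        assert len(combos) == 4
        for gi, gene in enumerate(model.gene_ids):
            wins = 0
            for combo in combos:
                members = [m for m in combo if m != gene]
                cec_i = np.mean([cc.cc(gene, m) for m in members])
                if cec_i < cec_seed[gi]:
                    wins += 1
            assert res.frac_success["abundance"][gi] == pytest.approx(
                wins / 4, abs=1e-12
            )

    def test_sampled_run_converges_to_exact(self):
        model = toy_six_gene_model()
        exact = model.fit(exhaustive=True, alpha=0.25)
        sampled = model.fit(n_perm=4000, alpha=0.25, seed=5)
        for cond in ("abundance",):
            err = np.abs(
                sampled.frac_success[cond] - exact.frac_success[cond]
            ).max()
            assert err < 0.03  # ~4 sigma at N=4000


class TestPermutationEngine:
    def test_vectorized_counts_match_per_pair_loop(self, panel_50x20):
        """The cached-matrix evaluation equals explicit loops over the same sets."""
        matrix, features = panel_50x20
        seed = GeneSet("seed", matrix.gene_ids[5:13])
        model = MGCA(matrix, seed, features, window=6, filter_abundance=False)
        n_perm = 40
        res = model.fit(n_perm=n_perm, alpha=0.1, seed=17)
        for cond in ("abundance", "gdna_size"):
            sampler = model._sampler(cond, 17, n_perm)
            counts = np.zeros(model.n_genes, dtype=int)
            for i in range(n_perm):
                members = sampler.sample_one(i).gene_ids
                for gi, gene in enumerate(model.gene_ids):
                    ms = [m for m in members if m != gene]
                    cec_i = sum(model.cc.cc(gene, m) for m in ms) / len(ms)
                    if cec_i < model.seed_profile.cec[gi]:
                        counts[gi] += 1
            assert (res.n_success[cond] == counts).all()

    def test_monotone_in_seed_cec(self, panel_50x20):
        """Raising a gene's reference CEC never lowers its success count."""
        matrix, features = panel_50x20
        seed = GeneSet("seed", matrix.gene_ids[5:13])
        model = MGCA(matrix, seed, features, window=6, filter_abundance=False)
        sampler = model._sampler("abundance", 3, 30)
        base = model._count_successes(sampler, model.seed_profile.cec, 30)
        bumped = model._count_successes(sampler, model.seed_profile.cec + 0.05, 30)
        assert (bumped >= base).all()

    def test_fixed_seed_reproducible_and_partition_invariant(self, panel_50x20):
        matrix, features = panel_50x20
        seed = GeneSet("seed", matrix.gene_ids[:6])
        model = MGCA(matrix, seed, features, window=5, filter_abundance=False)
        r1 = model.fit(n_perm=50, alpha=0.1, seed=23)
        r2 = model.fit(n_perm=50, alpha=0.1, seed=23)
        for c in r1.conditions:
            assert (r1.n_success[c] == r2.n_success[c]).all()
        # partition invariance: counting the same indices in two chunks
        sampler = model._sampler("abundance", 23, 50)
        whole = model._count_successes(sampler, model.seed_profile.cec, 50)
        s_a = model._sampler("abundance", 23, 50)
        part = np.zeros_like(whole)
        for i in range(50):
            idx = np.array(
                [model._universe_index[g] for g in s_a._sample_members(i)]
            )
            m = len(idx)
            sums = model.cc.values[:, idx].sum(axis=1)
            sums[idx] -= 1.0
            cec_i = sums / m
            cec_i[idx] = sums[idx] / (m - 1)
            part += cec_i < model.seed_profile.cec
        assert (whole == part).all()

    def test_seed_members_evaluated_with_self_exclusion(self, panel_50x20):
        matrix, features = panel_50x20
        seed = GeneSet("seed", matrix.gene_ids[:6])
        model = MGCA(matrix, seed, features, window=5, filter_abundance=False)
        from mgca.coexpression import cec_gene_vs_set

        for g in seed.gene_ids:
            gi = model._universe_index[g]
            assert model.seed_profile.cec[gi] == pytest.approx(
                cec_gene_vs_set(g, seed, model.cc), abs=1e-12
            )


class TestStratify:
    def test_all_samples_selector_reproduces_model(self, small_synthetic):
        data = small_synthetic
        seed = GeneSet("seed", data.features.gene_ids[:20])
        model = MGCA(data.expression, seed, data.features, window=20)
        whole = model.stratify(lambda meta: np.ones(len(meta), dtype=bool))
        assert whole.gene_ids == model.gene_ids
        assert np.allclose(whole.cc.values, model.cc.values)
        r1 = model.fit(n_perm=30, alpha=0.1, seed=2)
        r2 = whole.fit(n_perm=30, alpha=0.1, seed=2)
        for c in r1.conditions:
            assert (r1.n_success[c] == r2.n_success[c]).all()

    def test_disjoint_strata_are_independent(self, small_synthetic):
        data = small_synthetic
        seed = GeneSet("seed", data.features.gene_ids[:20])
        model = MGCA(data.expression, seed, data.features, window=20)
        m1 = model.stratify({"region": "R1"})
        m2 = model.stratify({"region": "R2"})
        assert (
            m1.expression.n_samples + m2.expression.n_samples
            == data.expression.n_samples
        )
        assert not np.allclose(m1.cc.values, m2.cc.values)

    def test_stratum_specific_module_found_only_in_its_region(self):
        from mgca.synthetic import ModuleSpec, SyntheticSpec, generate

        spec = SyntheticSpec(
            n_genes=500,
            seed=41,
            modules=(ModuleSpec(size=30, target_cc=0.6, regions=("R1", "R2"),
                                with_decoy=False),),
        )
        data = generate(spec)
        mod = data.modules[0].gene_ids
        seed = GeneSet("half", mod[:15])
        held = mod[15:]
        model = MGCA(data.expression, seed, data.features, window=25)
        active = model.stratify({"region": ("R1", "R2")})
        inactive = model.stratify({"region": ("R3", "R4")})
        res_a = active.fit(n_perm=300, alpha=0.01, seed=3)
        res_i = inactive.fit(n_perm=300, alpha=0.01, seed=3)
        ta = res_a.table.set_index("gene_id")
        ti = res_i.table.set_index("gene_id")
        held_a = [g for g in held if g in ta.index]
        held_i = [g for g in held if g in ti.index]
        assert ta.loc[held_a, "trim"].mean() >= 0.8
        assert ti.loc[held_i, "trim"].mean() <= 0.2

    def test_empty_stratum_rejected(self, small_synthetic):
        data = small_synthetic
        seed = GeneSet("seed", data.features.gene_ids[:20])
        model = MGCA(data.expression, seed, data.features, window=20)
        with pytest.raises(MgcaDataError):
            model.stratify({"region": "R99"})


class TestFdr:
    def test_reduced_run_bounds_and_depth_metadata(self, module_synthetic):
        data = module_synthetic
        mod = data.modules[0].gene_ids
        seed = GeneSet("half", mod[:20])
        model = MGCA(data.expression, seed, data.features, window=25)
        probe = mod[20:24] + model.gene_ids[-4:]
        table = model.fit(n_perm=100, alpha=0.05, seed=1).estimate_fdr(
            n_decoy=6, inner_n_perm=150, inner_alpha=0.02, seed=9, genes=probe
        )
        assert table.attrs["n_decoy"] == 6
        assert ((table["fdr_frequency"] >= 0) & (table["fdr_frequency"] <= 1)).all()

    def test_invalid_decoy_count(self, module_synthetic):
        data = module_synthetic
        seed = GeneSet("half", data.modules[0].gene_ids[:20])
        model = MGCA(data.expression, seed, data.features, window=25)
        res = model.fit(n_perm=50, alpha=0.05, seed=1)
        with pytest.raises(MgcaDataError):
            res.estimate_fdr(n_decoy=0)


def test_summary_mentions_threshold(panel_50x20):
    matrix, features = panel_50x20
    seed = GeneSet("seed", matrix.gene_ids[:6])
    model = MGCA(matrix, seed, features, window=5, filter_abundance=False)
    res = model.fit(n_perm=100, alpha=0.01, seed=0)
    text = res.summary()
    assert "n > 99" in text
    assert "TriM" in text
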