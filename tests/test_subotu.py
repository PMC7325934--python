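import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplicore import subotu as so

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


def _rng_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert so.pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 1.0

    def test_single_substitution_in_ten(self):
        assert so.pairwise_identity("ACGTACGTAC", "ACGTACGTAT") == pytest.approx(0.9)

    def test_two_substitutions_in_hundred(self):
        a = _rng_seq(100, 1)
        b = _mutate(a, [30, 70])
        assert so.pairwise_identity(a, b) == pytest.approx(0.98)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            so.pairwise_identity("", "ACGT")

    @settings(max_examples=40, deadline=None)
    @given(DNA, DNA)
    def test_symmetric_and_bounded(self, a, b):
        ab = so.pairwise_identity(a, b)
        assert ab == pytest.approx(so.pairwise_identity(b, a))
        assert 0.0 <= ab <= 1.0

    @settings(max_examples=40, deadline=None)
    @given(DNA, DNA, st.sampled_from([0.8, 0.9, 0.98]))
    def test_prefilter_never_discards_a_true_hit(self, a, b, threshold):
        if so.pairwise_identity(a, b) >= threshold:
            assert so.identity_at_least(a, b, threshold)


class TestDereplicate:
    def test_counts_and_order(self):
        pool = so.dereplicate({"s1": ["AAAA", "AAAA", "AAAA", "CCCC"]})
        assert [(r.sequence, r.total_count) for r in pool] == [("AAAA", 3), ("CCCC", 1)]

    def test_case_normalization(self):
        pool = so.dereplicate({"s1": ["acgt", "ACGT"]})
        assert len(pool) == 1 and pool[0].total_count == 2

    def test_tie_broken_lexicographically(self):
        pool = so.dereplicate({"s1": ["TTTT", "AAAA"]})
        assert [r.sequence for r in pool] == ["AAAA", "TTTT"]

    def test_noiseless_simulator_pool_matches_source_amplicons(self):
        from amplicore import read_prep as rp
        from amplicore import synthetic_data as sd

        ref = sd.build_reference(8, seed=21)
        config = sd.SimulationConfig(
            reads_per_sample=400,
            substitution_error_rate=0.0,
            chambers=("DC",),
            generations=("G1",),
            rng_seed=21,
        )
        truth = sd.simulate_design(ref, config)
        reads, read_truth = sd.generate_reads(ref, truth, config)
        per_sample = {
            s: rp.prepare_sample(r, rp.PrepConfig())[0] for s, r in reads.items()
        }
        pool = so.dereplicate(per_sample)
        n_sources = read_truth["source_taxon"].nunique()
        assert len(pool) == n_sources


class TestDesignateSeeds:
    def test_threshold_of_ten(self):
        pool = so.dereplicate(
            {"s": ["A" * 20] * 12 + ["C" * 20] * 10 + ["G" * 20] * 9}
        )
        seeds = so.designate_seeds(pool, so.ClusterConfig(min_seed_count=10))
        assert [s.sequence for s in seeds] == ["A" * 20, "C" * 20]

    def test_all_singletons_give_no_seeds(self):
        pool = so.dereplicate({"s": ["ACGT", "CGTA", "GTAC"]})
        assert so.designate_seeds(pool, so.ClusterConfig()) == []

    def test_empty_pool(self):
        assert so.designate_seeds([], so.ClusterConfig()) == []

    def test_per_sample_mode(self):
        pool = so.dereplicate({"s1": ["A" * 20] * 6, "s2": ["A" * 20] * 6})
        pooled = so.designate_seeds(pool, so.ClusterConfig(min_seed_count=10))
        per_sample = so.designate_seeds(
            pool, so.ClusterConfig(min_seed_count=10, per_sample_seeds=True)
        )
        assert len(pooled) == 1 and per_sample == []


class TestClusterToFeatures:
    def _pool_with_seed_and_variant(self, n_mut, seed_count=15):
        base = _rng_seq(200, 31)
        variant = _mutate(base, list(range(0, n_mut * 10, 10))[:n_mut])
        pool = so.dereplicate({"s": [base] * seed_count + [variant] * 2})
        return pool, base, variant

    def test_close_variant_merged_into_seed(self):
        pool, base, variant = self._pool_with_seed_and_variant(2)  # 0.99
        config = so.ClusterConfig()
        table = so.cluster_to_features(pool, so.designate_seeds(pool, config), config)
        assert len(table.feature_ids) == 1
        assert table.counts.iloc[0, 0] == 17

    def test_distant_variant_kept_independent(self):
        pool, base, variant = self._pool_with_seed_and_variant(6)  # 0.97
        config = so.ClusterConfig()
        table = so.cluster_to_features(pool, so.designate_seeds(pool, config), config)
        assert len(table.feature_ids) == 2
        assert set(table.provenance.values()) == {"seed", "independent"}

    def test_tie_goes_to_more_abundant_seed(self):
        base = _rng_seq(200, 32)
        seed_a = _mutate(base, [10])
        seed_b = _mutate(base, [150])
        # query equidistant (1 substitution) from both seeds
        pool = so.dereplicate({"s": [seed_a] * 50 + [seed_b] * 20 + [base] * 2})
        config = so.ClusterConfig()
        table = so.cluster_to_features(pool, so.designate_seeds(pool, config), config)
        merged = [f for f in table.feature_ids if table.representatives[f] == seed_a]
        assert table.counts.loc[merged[0], "s"] == 52

    def test_count_conservation(self, clustered):
        pool, _, table = clustered
        assert table.grand_total() == sum(r.total_count for r in pool)

    def test_seed_features_meet_threshold(self, clustered):
        pool, seeds, table = clustered
        seed_total = {s.sequence: s.total_count for s in seeds}
        for fid, kind in table.provenance.items():
            if kind == "seed":
                assert seed_total[table.representatives[fid]] >= 10

    def test_prefilter_equals_exhaustive(self, prepared_pool):
        """Edit-distance screening must not change the table vs all-pairs."""
        _, _, pool = prepared_pool
        small = pool[:400]
        fast_cfg = so.ClusterConfig(use_prefilter=True)
        slow_cfg = so.ClusterConfig(use_prefilter=False)
        seeds = so.designate_seeds(small, fast_cfg)
        fast = so.cluster_to_features(small, seeds, fast_cfg)
        slow = so.cluster_to_features(small, seeds, slow_cfg)
        assert fast.counts.equals(slow.counts)
        assert fast.representatives == slow.representatives

    def test_raising_identity_never_reduces_features(self, prepared_pool):
        _, _, pool = prepared_pool
        small = pool[:200]
        counts = []
        for ident in (0.90, 0.95, 0.98, 0.995):
            config = so.ClusterConfig(min_identity=ident)
            seeds = so.designate_seeds(small, config)
            counts.append(
                len(so.cluster_to_features(small, seeds, config).feature_ids)
            )
        assert counts == sorted(counts)

    def test_foreign_seed_rejected(self):
        pool = so.dereplicate({"s": ["ACGT" * 10] * 3})
        alien = so.DereplicatedSequence("TTTT" * 10, {"s": 99})
        with pytest.raises(ValueError, match="subset"):
            so.cluster_to_features(pool, [alien], so.ClusterConfig())
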