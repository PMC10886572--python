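"""Motif enumeration, set building, ES/NES and the screen."""

import numpy as np
import pandas as pd
import pytest

from sevmir.io_formats import SequenceSet
from sevmir.motifs import (
    MotifScreenConfig,
    build_motif_sets,
    enrichment_score,
    enumerate_motifs,
    motif_screen,
    permutation_nes,
)
from sevmir.synthetic_data import (
    SimulationConfig,
    generate_sequences_with_motif,
    simulate_count_experiment,
)
from sevmir.differential import differential_test

from oracles import naive_enrichment_walk, naive_motif_membership


def make_ranked(metrics, ids=None):
    ids = ids or [f"g{i}" for i in range(len(metrics))]
    return pd.Series(metrics, index=ids, dtype=float)


class TestEnumerate:
    @pytest.mark.parametrize(
        "k_min,k_max,count", [(4, 4, 256), (4, 7, 21760), (5, 5, 1024)]
    )
    def test_counts(self, k_min, k_max, count):
        assert len(enumerate_motifs(k_min, k_max)) == count

    def test_lexicographic_first_and_unique(self):
        motifs = enumerate_motifs(5, 5)
        assert motifs[0] == "AAAAA"
        assert len(set(motifs)) == len(motifs)

    @pytest.mark.parametrize("k_min,k_max", [(0, 4), (5, 4)])
    def test_bad_range(self, k_min, k_max):
        with pytest.raises(ValueError):
            enumerate_motifs(k_min, k_max)


class TestBuildSets:
    def test_overlapping_occurrences_count_once(self):
        seqs = SequenceSet({f"m{i}": "AAGCGCGCAA" for i in range(6)})
        sets = build_motif_sets(["GCGC"], seqs, min_size=6)
        assert sets["GCGC"] == frozenset(seqs.ids())

    def test_min_size_filter_drops_small_sets(self):
        seqs = SequenceSet(
            {f"c{i}": "AAAAGCGCAAAA" for i in range(5)}
            | {f"n{i}": "AAAAAAAAAAAA" for i in range(6)}
        )
        sets = build_motif_sets(["GCGC", "AAAA"], seqs, min_size=6)
        assert "GCGC" not in sets  # only 5 carriers
        assert len(sets["AAAA"]) == 11

    def test_membership_equals_brute_force_scan(self):
        cfg = SimulationConfig(seed=51, n_mirnas=200)
        seqs, _ = generate_sequences_with_motif(cfg)
        motifs = enumerate_motifs(4, 4)
        fast = build_motif_sets(motifs, seqs, min_size=1)
        brute = naive_motif_membership(motifs, seqs)
        assert fast == {k: frozenset(v) for k, v in brute.items()}

    def test_bad_alphabet_rejected(self):
        seqs = SequenceSet({"m1": "ACGU" * 3})
        with pytest.raises(ValueError, match="alphabet"):
            build_motif_sets(["GCTC"], seqs)


class TestEnrichmentScore:
    def test_hand_walk_top_gene(self):
        ranked = make_ranked([2.0, 1.0, -1.0])
        score = enrichment_score(ranked, {"g0"}, weight=1.0)
        assert score.es == pytest.approx(1.0)
        assert score.leading_edge == ["g0"]

    def test_complement_symmetry_weight_zero(self):
        ranked = make_ranked([3.0, 2.0, 1.0, -1.0, -2.0])
        one = enrichment_score(ranked, {"g2"}, weight=0.0)
        rest = enrichment_score(ranked, {"g0", "g1", "g3", "g4"}, weight=0.0)
        assert abs(one.es) == pytest.approx(abs(rest.es))

    def test_weight_zero_equals_classic_ks(self, rng):
        n = 40
        metrics = np.sort(rng.normal(size=n))[::-1]
        ranked = make_ranked(metrics)
        members = {f"g{i}" for i in rng.choice(n, size=8, replace=False)}
        score = enrichment_score(ranked, members, weight=0.0)
        # classic two-sample KS-style statistic on the same ranking
        is_hit = np.array([f"g{i}" in members for i in range(n)])
        hit_cdf = np.cumsum(is_hit) / is_hit.sum()
        miss_cdf = np.cumsum(~is_hit) / (~is_hit).sum()
        dev = hit_cdf - miss_cdf
        expected = dev.max() if dev.max() >= -dev.min() else dev.min()
        assert score.es == pytest.approx(expected)

    def test_equals_naive_walk_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 80))
            metrics = np.sort(rng.normal(scale=2, size=n))[::-1]
            m = int(rng.integers(1, n))
            members = {f"g{i}" for i in rng.choice(n, size=m, replace=False)}
            weight = float(rng.choice([0.0, 1.0, 1.5]))
            ranked = make_ranked(metrics)
            score = enrichment_score(ranked, members, weight=weight)
            is_hit = np.array([f"g{i}" in members for i in range(n)])
            es_oracle, running = naive_enrichment_walk(metrics, is_hit, weight)
            assert score.es == pytest.approx(es_oracle, abs=1e-9)
            assert np.allclose(score.running, running, atol=1e-9)

    def test_reversal_negates_es_weight_zero(self, rng):
        n = 30
        metrics = np.sort(rng.normal(size=n))[::-1]
        members = {f"g{i}" for i in rng.choice(n, size=6, replace=False)}
        fwd = enrichment_score(make_ranked(metrics), members, weight=0.0)
        rev_ids = [f"g{i}" for i in range(n - 1, -1, -1)]
        rev = enrichment_score(
            make_ranked(metrics[::-1].copy(), ids=rev_ids), members, weight=0.0
        )
        assert fwd.es == pytest.approx(-rev.es, abs=1e-9)

    def test_es_bounded(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            metrics = np.sort(rng.normal(size=n))[::-1]
            members = {f"g{i}" for i in rng.choice(n, size=int(rng.integers(1, n)), replace=False)}
            score = enrichment_score(make_ranked(metrics), members)
            assert -1.0 <= score.es <= 1.0

    def test_degenerate_sets_error(self):
        ranked = make_ranked([1.0, 0.5])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"g0", "g1"})
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"absent"})

    def test_members_outside_ranked_ignored(self):
        ranked = make_ranked([2.0, 1.0, -1.0])
        a = enrichment_score(ranked, {"g0", "nope"})
        b = enrichment_score(ranked, {"g0"})
        assert a.es == b.es


class TestPermutationNes:
    def test_determinism_given_seed(self, rng):
        metrics = np.sort(rng.normal(size=50))[::-1]
        ranked = make_ranked(metrics)
        members = {f"g{i}" for i in range(0, 10)}
        a = permutation_nes(ranked, members, n_perm=200, seed=7)
        b = permutation_nes(ranked, members, n_perm=200, seed=7)
        assert (a.nes, a.p_perm) == (b.nes, b.p_perm)

    def test_extreme_es_gets_plus_one_floor(self):
        metrics = np.concatenate([np.full(10, 5.0), np.full(90, -0.01)])
        ranked = make_ranked(metrics)
        members = {f"g{i}" for i in range(10)}  # perfectly top-ranked
        res = permutation_nes(ranked, members, n_perm=500, seed=1)
        assert res.p_perm <= 1.0 / 100  # at most 1/(1+n_same_sign) scale
        assert res.es == pytest.approx(1.0)
        assert res.nes > 1.0

    def test_nes_scale_invariance_weight_one(self, rng):
        metrics = np.sort(rng.normal(size=60))[::-1]
        members = {f"g{i}" for i in rng.choice(60, size=12, replace=False)}
        a = permutation_nes(make_ranked(metrics), members, n_perm=300, seed=3)
        b = permutation_nes(make_ranked(metrics * 7.0), members, n_perm=300, seed=3)
        assert a.nes == pytest.approx(b.nes)
        assert a.p_perm == b.p_perm

    def test_random_sets_give_null_centered_nes(self, rng):
        metrics = np.sort(rng.normal(size=100))[::-1]
        ranked = make_ranked(metrics)
        nes_values, p_values = [], []
        for _ in range(100):
            members = {f"g{i}" for i in rng.choice(100, size=10, replace=False)}
            res = permutation_nes(ranked, members, n_perm=200, seed=int(rng.integers(2**31)))
            nes_values.append(abs(res.nes))
            p_values.append(res.p_perm)
        assert 0.7 < np.mean(nes_values) < 1.5
        assert 0.3 < np.mean(p_values) < 0.7

    def test_too_few_permutations_rejected(self):
        ranked = make_ranked([1.0, 0.5, -0.5])
        with pytest.raises(ValueError):
            permutation_nes(ranked, {"g0"}, n_perm=50, seed=1)


@pytest.fixture(scope="module")
def planted_screen():
    cfg = SimulationConfig(seed=61, n_mirnas=300)
    seqs, truth = generate_sequences_with_motif(cfg)
    cm, _ = simulate_count_experiment(cfg, carriers=truth.carrier_ids, mirna_ids=seqs.ids())
    diff = differential_test(cm)
    return motif_screen(
        diff, seqs, MotifScreenConfig(k_min=4, k_max=4, n_perm=500, seed=61)
    )


class TestScreen:
    def test_planted_motif_top_ranked(self, planted_screen):
        m4 = planted_screen[planted_screen["k"] == 4]
        assert list(m4.index[:1]) == ["GCGC"]
        assert m4.loc["GCGC", "direction"] == "sev_sorting"

    def test_sign_consistency_and_leading_edge_subset(self, planted_screen):
        for motif, row in planted_screen.iterrows():
            if row["es"] != 0:
                assert np.sign(row["nes"]) == np.sign(row["es"])
            leading = set(row["leading_edge"].split(","))
            assert len(leading) <= row["size"]

    def test_retention_motif_recovered_with_negative_nes(self):
        cfg = SimulationConfig(seed=62, n_mirnas=300, secretion_shift_log2=-2.0)
        seqs, truth = generate_sequences_with_motif(cfg)
        cm, _ = simulate_count_experiment(cfg, carriers=truth.carrier_ids, mirna_ids=seqs.ids())
        diff = differential_test(cm)
        result = motif_screen(
            diff, seqs, MotifScreenConfig(k_min=4, k_max=4, n_perm=500, seed=62)
        )
        assert result.loc["GCGC", "nes"] < 0
        assert result.loc["GCGC", "direction"] == "cell_retention"
        assert result.index[-1] == "GCGC"  # most negative NES sorts last

    def test_fdr_columns_present_per_k_and_joint(self, planted_screen):
        assert {"fdr_per_k", "fdr_joint"} <= set(planted_screen.columns)
        assert planted_screen["fdr_per_k"].between(0, 1).all()
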