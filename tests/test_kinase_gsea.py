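"""Kinase-target-set construction and pre-ranked KS enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phosphosig import kinase_gsea as kg
from phosphosig.errors import ConfigurationError, DegenerateSetError
from phosphosig.phosphodata import KinaseTargetRecord
from phosphosig.synthetic_data import (
    SyntheticConfig,
    default_design,
    generate_kinase_substrates,
    generate_phosphoproteome,
)
from phosphosig import significance as sg


def _ranked(n):
    """Ranked list over n dummy sites with distinct metrics."""
    keys = tuple((f"G{i:03d}", "S1") for i in range(n))
    return kg.RankedList(keys=keys, metric=np.arange(n, dtype=float))


def _brute_force_es(n, hit_positions):
    """Independent position-by-position running-sum enumeration (0-based)."""
    k = len(hit_positions)
    hits = set(hit_positions)
    run, best_hi, best_lo = 0.0, -np.inf, np.inf
    for i in range(n):
        run += 1.0 / k if i in hits else -1.0 / (n - k)
        best_hi = max(best_hi, run)
        best_lo = min(best_lo, run)
    return best_hi if best_hi >= -best_lo else best_lo


class TestEnrichmentScore:
    def test_all_hits_first(self):
        ranked = _ranked(10)
        es, _, leading = kg.enrichment_score(ranked, frozenset(ranked.keys[:2]))
        assert es == pytest.approx(1.0)
        assert set(leading) == set(ranked.keys[:2])

    def test_all_hits_last(self):
        ranked = _ranked(10)
        es, _, leading = kg.enrichment_score(ranked, frozenset(ranked.keys[-2:]))
        assert es == pytest.approx(-1.0)
        assert set(leading) == set(ranked.keys[-2:])

    def test_example_three_hits(self):
        # hits at 1-based positions {3, 7, 11} over N = 20
        ranked = _ranked(20)
        members = frozenset(ranked.keys[i] for i in (2, 6, 10))
        es, _, _ = kg.enrichment_score(ranked, members)
        assert es == pytest.approx(_brute_force_es(20, {2, 6, 10}))

    def test_degenerate_sets_raise(self):
        ranked = _ranked(5)
        with pytest.raises(DegenerateSetError):
            kg.enrichment_score(ranked, frozenset())
        with pytest.raises(DegenerateSetError):
            kg.enrichment_score(ranked, frozenset(ranked.keys))

    def test_exhaustive_oracle_small_n(self):
        """ES equals brute-force enumeration for every set of size <= 3 over
        N <= 12 (the full sweep to size 5 / N 20 runs in the acceptance suite)."""
        for n in (4, 7, 12):
            ranked = _ranked(n)
            for k in range(1, 4):
                for pos in itertools.combinations(range(n), k):
                    members = frozenset(ranked.keys[i] for i in pos)
                    es, _, _ = kg.enrichment_score(ranked, members)
                    assert es == pytest.approx(_brute_force_es(n, set(pos)), abs=1e-12)

    def test_complement_negates_running_sum(self):
        # hit/miss increments swap roles, so the complement's walk is the
        # mirror image and its ES is -ES whenever the extremum is unique
        ranked = _ranked(15)
        members = frozenset(ranked.keys[i] for i in (0, 3, 8))
        complement = frozenset(ranked.keys) - members
        es, run, _ = kg.enrichment_score(ranked, members)
        es_c, run_c, _ = kg.enrichment_score(ranked, complement)
        assert np.allclose(run_c, -run)
        if abs(run.max()) != abs(run.min()):
            assert es_c == pytest.approx(-es)

    def test_es_bounded(self, rng):
        ranked = _ranked(50)
        for _ in range(20):
            k = int(rng.integers(1, 49))
            pos = rng.choice(50, size=k, replace=False)
            es, _, _ = kg.enrichment_score(ranked, frozenset(ranked.keys[i] for i in pos))
            assert -1.0 <= es <= 1.0


class TestRanking:
    def test_orientation_reversal_negates_es(self, rng):
        df = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(40)],
                "gene": [f"G{i:02d}" for i in range(40)],
                "residue": ["S1"] * 40,
                "log2_ratio": rng.normal(0, 1, 40),
                "summed_intensity": rng.uniform(1e5, 1e8, 40),
            }
        )
        fwd = kg.rank_sites(df, "deficient_first")
        rev = kg.rank_sites(df, "proficient_first")
        members = frozenset(fwd.keys[:5])
        es_f, run_f, _ = kg.enrichment_score(fwd, members)
        es_r, run_r, _ = kg.enrichment_score(rev, members)
        if abs(run_f.max()) != abs(run_f.min()):
            assert es_r == pytest.approx(-es_f)

    def test_ties_broken_stably_by_key(self):
        df = pd.DataFrame(
            {
                "site_id": ["s3", "s1", "s2"],
                "gene": ["C", "A", "B"],
                "residue": ["S1"] * 3,
                "log2_ratio": [0.5, 0.5, 0.5],
                "summed_intensity": [1.0, 1.0, 1.0],
            }
        )
        ranked = kg.rank_sites(df)
        assert ranked.keys == (("A", "S1"), ("B", "S1"), ("C", "S1"))

    def test_unknown_orientation(self):
        with pytest.raises(ConfigurationError):
            kg.rank_sites(pd.DataFrame(), "sideways")


class TestTargetSets:
    def _records(self, pairs):
        return [
            KinaseTargetRecord(k, g, r, "mouse", "mouse") for k, g, r in pairs
        ]

    def test_zero_overlap_set_dropped(self):
        records = self._records([("KIN", "ZZZ", "S1")])
        sets, dropped = kg.build_target_sets(records, [("AAA", "S1")], min_size=1)
        assert not sets and dropped == {"KIN": 0}

    def test_duplicate_rows_collapse(self):
        records = self._records([("KIN", "AAA", "S1")] * 3 + [("KIN", "BBB", "S2")] * 2)
        sets, _ = kg.build_target_sets(
            records, [("AAA", "S1"), ("BBB", "S2")], min_size=2
        )
        assert len(sets) == 1 and sets[0].size == 2

    def test_empty_universe_is_config_error(self):
        with pytest.raises(ConfigurationError):
            kg.build_target_sets([], [], min_size=3)

    def test_planted_sets_survive_with_full_size(self, small_bundle):
        cfg, records, truth = small_bundle
        universe = sorted({r.key for r in records})
        kin, sets = generate_kinase_substrates(cfg, universe, truth)
        built, _ = kg.build_target_sets(kin, universe, min_size=3)
        by_name = {s.kinase: s for s in built}
        assert by_name["PKIN1"].members == sets["PKIN1"]


class TestPermutation:
    def test_top_block_hits_lower_bound(self):
        ranked = _ranked(100)
        tset = kg.KinaseTargetSet("TOP", frozenset(ranked.keys[:5]))
        res = kg.normalized_enrichment(ranked, [tset], n_perm=1000, seed=3)[0]
        assert res.es == pytest.approx(1.0)
        n_pos = int((res.null_es > 0).sum())
        assert res.p_perm == pytest.approx(1.0 / (1 + n_pos))
        assert res.nes > 1.5

    def test_interleaved_set_is_null_like(self):
        ranked = _ranked(100)
        tset = kg.KinaseTargetSet("FLAT", frozenset(ranked.keys[4::10]))
        res = kg.normalized_enrichment(ranked, [tset], n_perm=500, seed=3)[0]
        assert res.p_perm > 0.5
        assert abs(res.nes) < 1.3

    def test_same_seed_bit_identical(self):
        ranked = _ranked(60)
        sets = [
            kg.KinaseTargetSet("A", frozenset(ranked.keys[:5])),
            kg.KinaseTargetSet("B", frozenset(ranked.keys[20:27])),
        ]
        r1 = kg.normalized_enrichment(ranked, sets, n_perm=200, seed=9)
        r2 = kg.normalized_enrichment(ranked, sets, n_perm=200, seed=9)
        for a, b in zip(r1, r2):
            assert (a.nes, a.p_perm, a.fdr) == (b.nes, b.p_perm, b.fdr)
        r3 = kg.normalized_enrichment(ranked, sets, n_perm=200, seed=10)
        assert any(a.nes != c.nes for a, c in zip(r1, r3))

    def test_sign_invariant(self):
        ranked = _ranked(80)
        sets = [
            kg.KinaseTargetSet("EARLY", frozenset(ranked.keys[:6])),
            kg.KinaseTargetSet("LATE", frozenset(ranked.keys[-6:])),
        ]
        for res in kg.normalized_enrichment(ranked, sets, n_perm=200, seed=5):
            assert np.sign(res.nes) == np.sign(res.es)
            assert set(res.leading_edge) <= set(
                s.members for s in sets if s.kinase == res.kinase
            ).pop()

    def test_fdr_monotone_in_abs_nes(self):
        ranked = _ranked(120)
        rng = np.random.default_rng(0)
        sets = [
            kg.KinaseTargetSet(f"K{i}", frozenset(
                ranked.keys[j] for j in rng.choice(120, size=8, replace=False)
            ))
            for i in range(6)
        ]
        results = kg.normalized_enrichment(ranked, sets, n_perm=200, seed=4)
        pos = sorted((r for r in results if r.nes >= 0), key=lambda r: -abs(r.nes))
        assert all(a.fdr <= b.fdr + 1e-12 for a, b in zip(pos, pos[1:]))

    def test_single_set_fdr_falls_back_to_p(self):
        ranked = _ranked(50)
        tset = kg.KinaseTargetSet("ONLY", frozenset(ranked.keys[10:16]))
        res = kg.normalized_enrichment(ranked, [tset], n_perm=200, seed=1)[0]
        assert res.fdr == res.p_perm

    def test_n_perm_floor(self):
        ranked = _ranked(50)
        tset = kg.KinaseTargetSet("A", frozenset(ranked.keys[:5]))
        with pytest.raises(ConfigurationError):
            kg.normalized_enrichment(ranked, [tset], n_perm=10, seed=1)


class TestEndToEndRecovery:
    def test_planted_kinase_set_wins(self):
        """A set shifted down in the low-serum comparison tops the NES table
        among decoys, with small FDR; decoys do not systematically score."""
        cfg = SyntheticConfig(seed=21, n_proteins=700, n_decoy_kinase_sets=12)
        records, truth = generate_phosphoproteome(cfg)
        design = default_design()
        ratios = sg.compute_ratios(records, design, "smarcb1_low")
        ranked = kg.rank_sites(ratios)
        kin, _ = generate_kinase_substrates(cfg, sorted(set(ranked.keys)), truth)
        sets, _ = kg.build_target_sets(kin, ranked.keys, min_size=3)
        results = kg.normalized_enrichment(ranked, sets, n_perm=300, seed=21)
        assert results[0].kinase == "PKIN1"
        assert results[0].fdr < 0.05
        decoy_fdr = [r.fdr for r in results if r.kinase != "PKIN1"]
        assert np.median(decoy_fdr) > 0.2
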