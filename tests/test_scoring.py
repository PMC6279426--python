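"""Database p-values, TDA filters, search-space adjustment, pool FDR."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speclib import (
    PSM,
    SearchContext,
    adjust_search_space,
    database_p_value,
    psm_fdr_filter,
    synthetic_pool_empirical_fdr,
)
from speclib.fixtures import rng_for


def make_psm(p, decoy=False, peptide="PEPTIDEK", run="r0", scan=0, **kw):
    defaults = dict(
        run_id=run,
        scan=scan,
        dataset_id="D0",
        search_id="s0",
        peptide=peptide,
        charge=2,
        spectral_probability=min(p, 1.0),
        database_p_value=p,
        is_decoy=decoy,
    )
    defaults.update(kw)
    return PSM(**defaults)


class TestDatabasePValue:
    def test_identity_at_database_size_one(self):
        assert database_p_value(0.5, 1) == pytest.approx(0.5)

    def test_linear_regime_for_tiny_p(self):
        assert database_p_value(1e-12, 1000) == pytest.approx(1e-9, rel=1e-6)

    def test_matches_high_precision_arithmetic(self):
        # frozen from an exact 60-digit decimal evaluation of 1-(1-1e-6)^70625
        assert database_p_value(1e-6, 70625) == pytest.approx(
            0.068188777065864640041196614546, rel=1e-12
        )

    def test_extreme_underflow_regime_keeps_relative_precision(self):
        assert database_p_value(1e-300, 10) == pytest.approx(1e-299, rel=1e-9)

    @given(
        st.floats(min_value=1e-30, max_value=0.99),
        st.integers(min_value=1, max_value=10**6),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p_and_n(self, p, n):
        v = database_p_value(p, n)
        assert v >= database_p_value(p / 2, n) - 1e-18
        assert database_p_value(p, n + 1) >= v
        assert database_p_value(p, 1) == pytest.approx(p)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            database_p_value(0.0, 10)
        with pytest.raises(ValueError):
            database_p_value(0.5, 0)


def brute_force_prefix(psms, alpha):
    ordered = sorted(psms, key=lambda p: p.sort_key)
    best = 0
    for i in range(1, len(ordered) + 1):
        d = sum(1 for p in ordered[:i] if p.is_decoy)
        t = i - d
        if t and d / t <= alpha:
            best = i
    return ordered[:best]


class TestPsmFdrFilter:
    def test_all_targets_accepted(self):
        psms = [make_psm(1e-9 * (i + 1), scan=i) for i in range(10)]
        assert len(psm_fdr_filter(psms, 0.01)) == 10

    def test_all_decoys_rejected(self):
        psms = [make_psm(1e-9 * (i + 1), decoy=True, scan=i) for i in range(10)]
        assert psm_fdr_filter(psms, 0.01) == []

    def test_cut_matches_prefix_scan_oracle(self):
        # 99 targets, then 1 decoy, then 1 target in score order
        psms = [make_psm(1e-9 * (i + 1), scan=i) for i in range(99)]
        psms.append(make_psm(1e-6, decoy=True, scan=99))
        psms.append(make_psm(2e-6, scan=100))
        accepted = psm_fdr_filter(psms, 0.01)
        assert accepted == brute_force_prefix(psms, 0.01)
        # 1 decoy / 100 targets = 1% exactly, so the full prefix passes
        assert len(accepted) == 101
        assert sum(p.is_decoy for p in accepted) == 1

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_random_instances_match_oracle(self, seed):
        rng = rng_for(seed, "fdr-test")
        psms = [
            make_psm(float(rng.uniform(1e-9, 1e-3)), bool(rng.random() < 0.3), scan=i)
            for i in range(30)
        ]
        assert psm_fdr_filter(psms, 0.05) == brute_force_prefix(psms, 0.05)

    def test_pure_null_realized_decoy_fraction_bounded(self):
        rng = rng_for(0, "pure-null")
        psms = [
            make_psm(float(10 ** rng.uniform(-8, -2)), bool(i % 2), scan=i)
            for i in range(4000)
        ]
        accepted = psm_fdr_filter(psms, 0.01)
        d = sum(p.is_decoy for p in accepted)
        t = len(accepted) - d
        assert t == 0 or d / t <= 0.01 + 1e-12

    def test_empty_input_empty_output(self):
        assert psm_fdr_filter([], 0.01) == []


class TestAdjustSearchSpace:
    CTX = SearchContext("ap1", "affinity_purification", 70625)

    def test_single_peptide_protein_unadjusted(self):
        psms = [make_psm(1e-8, peptide="AAAAAAK", scan=1)]
        mapping = {"AAAAAAK": "P1"}
        out = adjust_search_space(psms, self.CTX, 1500, mapping)
        assert out[0].database_p_value == 1e-8

    def test_two_peptide_protein_p_values_decrease(self):
        psms = [
            make_psm(database_p_value(1e-12, 70625), peptide="AAAAAAK", scan=1,
                     spectral_probability=1e-12),
            make_psm(database_p_value(2e-12, 70625), peptide="CCCCCCK", scan=2,
                     spectral_probability=2e-12),
        ]
        mapping = {"AAAAAAK": "P1", "CCCCCCK": "P1"}
        out = adjust_search_space(psms, self.CTX, 1500, mapping)
        assert len(out) == 2
        for before, after in zip(psms, sorted(out, key=lambda p: p.scan)):
            assert after.database_p_value < before.database_p_value
            assert after.spectral_probability == before.spectral_probability

    def test_pooled_target_decoy_pair_both_eligible(self):
        # one decoy peptide on reverse(P1) + one target peptide on P1: pooled 2+
        psms = [
            make_psm(database_p_value(1e-12, 70625), peptide="AAAAAAK", scan=1,
                     spectral_probability=1e-12),
            make_psm(database_p_value(3e-12, 70625), peptide="CCCCCCK", scan=2,
                     spectral_probability=3e-12, decoy=True),
            make_psm(database_p_value(5e-12, 70625), peptide="DDDDDDK", scan=3,
                     spectral_probability=5e-12),
            make_psm(database_p_value(7e-12, 70625), peptide="EEEEEEK", scan=4,
                     spectral_probability=7e-12),
        ]
        mapping = {
            "AAAAAAK": "P1",
            "CCCCCCK": "XXX_P1",
            "DDDDDDK": "P2",
            "EEEEEEK": "P3",
        }
        # peptide-level FDR loose enough that the lone decoy stays in the
        # accepted prefix of this 4-record fixture (1 decoy / 3 targets)
        out = {
            p.peptide: p
            for p in adjust_search_space(
                psms, self.CTX, 1500, mapping,
                peptide_level_fdr=0.4, psm_level_fdr=0.4,
            )
        }
        # P1 pool has 2 peptides (target + decoy) -> both adjusted downward
        assert out["AAAAAAK"].database_p_value < psms[0].database_p_value
        assert out["CCCCCCK"].database_p_value < psms[1].database_p_value
        # singleton proteins stay at their original values
        assert out["DDDDDDK"].database_p_value == psms[2].database_p_value
        assert out["EEEEEEK"].database_p_value == psms[3].database_p_value

    def test_missing_mapping_names_the_peptide(self):
        with pytest.raises(KeyError, match="AAAAAAK"):
            adjust_search_space(
                [make_psm(1e-8, peptide="AAAAAAK")], self.CTX, 1500, {}
            )


class TestSyntheticPoolFdr:
    CTX = SearchContext(
        "pool", "synthetic_pool", 2000, frozenset({"bg0", "bg1"})
    )

    def test_no_decoys_means_all_accepted(self):
        psms = [make_psm(1e-10 * (i + 1), run="main", scan=i) for i in range(5)]
        _table, accepted = synthetic_pool_empirical_fdr(
            psms, self.CTX, {"PEPTIDEK"}, {}
        )
        assert len(accepted) == 5

    def test_threshold_cuts_just_below_best_decoy(self):
        psms = [
            make_psm(1e-12, run="main", scan=1),
            make_psm(1e-10, run="main", scan=2),
            make_psm(1e-9, run="main", scan=3, decoy=True),
            make_psm(1e-8, run="main", scan=4),
        ]
        table, accepted = synthetic_pool_empirical_fdr(psms, self.CTX, {"PEPTIDEK"}, {})
        assert [p.scan for p in accepted] == [1, 2]
        assert table.by_length[8] == pytest.approx(1e-10)

    def test_background_peptide_in_target_pool_not_a_decoy(self):
        psms = [
            make_psm(1e-12, run="main", scan=1),
            # background-run match to a peptide synthesized there AND in the pool
            make_psm(1e-13, run="bg0", scan=2),
        ]
        _table, accepted = synthetic_pool_empirical_fdr(
            psms, self.CTX, {"PEPTIDEK"}, {"bg0": {"PEPTIDEK"}}
        )
        assert [p.scan for p in accepted] == [1]

    def test_background_match_counts_as_decoy_otherwise(self):
        psms = [
            make_psm(1e-12, run="main", scan=1),
            make_psm(1e-10, run="bg0", scan=2, peptide="AAAAAAAK"),
            make_psm(1e-8, run="main", scan=3, peptide="CCCCCCCK"),
        ]
        _table, accepted = synthetic_pool_empirical_fdr(
            psms, self.CTX, {"PEPTIDEK", "CCCCCCCK"}, {"bg0": set()}
        )
        # the 8-long background decoy blocks the worse-scoring 8-long target
        assert [p.scan for p in accepted] == [1]

    def test_accepted_set_never_contains_decoys(self, fixture_config):
        from speclib.fixtures import generate_pool_fixture

        pool = generate_pool_fixture(fixture_config)
        _table, accepted = synthetic_pool_empirical_fdr(
            pool.psms, pool.context, pool.pool_target_peptides,
            pool.background_pool_peptides,
        )
        assert accepted
        assert all(not p.is_decoy for p in accepted)
        assert all(p.run_id not in pool.context.background_run_ids for p in accepted)

    def test_requires_background_runs(self):
        ctx = SearchContext("pool", "synthetic_pool", 2000)
        with pytest.raises(ValueError):
            synthetic_pool_empirical_fdr([], ctx, set(), {})
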