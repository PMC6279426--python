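"""Candidate ledger, representative selection, ambiguity filter, build."""

import itertools
import random

import numpy as np
import pytest

from speclib import (
    BuildConfig,
    LibraryState,
    PSM,
    SpectrumStore,
    ThresholdTable,
    build_library,
    filter_ambiguous,
    select_representative,
)
from speclib.assembly import LibraryEntry
from speclib.fixtures import rng_for
from speclib.formats import write_library_mgf
from speclib.similarity import cosine

from conftest import make_spectrum, make_unit


def make_psm(p, peptide="PEPTIDEK", dataset="D0", run=None, scan=0, decoy=False):
    return PSM(
        run_id=run or f"{dataset}_r0",
        scan=scan,
        dataset_id=dataset,
        search_id="s0",
        peptide=peptide,
        charge=2,
        spectral_probability=min(p, 1.0),
        database_p_value=p,
        is_decoy=decoy,
    )


class TestUpdateCandidates:
    def test_empty_batch_is_identity(self):
        state = LibraryState()
        state.update_candidates([make_psm(1e-9, scan=1)])
        ledger_before = dict(state.ledger)
        state.update_candidates([])
        assert state.ledger == ledger_before

    def test_batch_order_and_partition_do_not_matter(self):
        rng = rng_for(0, "order")
        psms = [
            make_psm(float(rng.uniform(1e-9, 1e-4)), dataset=f"D{i % 5}", scan=i)
            for i in range(200)
        ]
        states = []
        for perm_seed in range(3):
            shuffled = list(psms)
            random.Random(perm_seed).shuffle(shuffled)
            batches = [shuffled[:70], shuffled[70:150], shuffled[150:]]
            state = LibraryState()
            for batch in batches:
                state.update_candidates(batch)
            states.append(state)
        base = states[0]
        for other in states[1:]:
            assert other.ledger == base.ledger
            for key in base.pools:
                assert (
                    other.candidate_set(key).candidates
                    == base.candidate_set(key).candidates
                )

    def test_single_dataset_capped_at_per_dataset_limit(self):
        rng = rng_for(1, "cap")
        psms = [
            make_psm(float(rng.uniform(1e-9, 1e-4)), dataset="D1", scan=i)
            for i in range(300)
        ]
        state = LibraryState()
        state.update_candidates(psms)
        cand = state.candidate_set(("PEPTIDEK", 2))
        assert len(cand) == 20
        # the retained 20 are the best 20 under the total order
        expected = sorted(psms, key=lambda p: p.sort_key)[:20]
        assert cand.candidates == expected

    def test_many_datasets_capped_at_global_limit(self):
        rng = rng_for(2, "cap100")
        psms = [
            make_psm(float(rng.uniform(1e-9, 1e-4)), dataset=f"D{i // 10}", scan=i)
            for i in range(500)
        ]
        state = LibraryState()
        state.update_candidates(psms)
        assert len(state.candidate_set(("PEPTIDEK", 2))) == 100

    def test_duplicate_psms_merge_idempotently(self):
        psms = [make_psm(1e-9, scan=1)]
        state = LibraryState()
        state.update_candidates(psms)
        state.update_candidates(psms)
        assert len(state.candidate_set(("PEPTIDEK", 2))) == 1

    def test_missing_spectrum_reported_with_run_and_scan(self):
        state = LibraryState()
        with pytest.raises(KeyError, match="r9.*99"):
            state.update_candidates(
                [make_psm(1e-9, run="r9", scan=99)], SpectrumStore()
            )

    def test_ledger_keeps_best_psm_even_after_pool_displacement(self):
        state = LibraryState(config=BuildConfig(per_dataset_cap=2))
        psms = [make_psm(1e-9 * (i + 1), dataset="D0", scan=i) for i in range(5)]
        state.update_candidates(psms)
        assert state.ledger[("PEPTIDEK", 2)].scan == 0
        assert len(state.candidate_set(("PEPTIDEK", 2))) == 2


class TestSelectRepresentative:
    def _store(self, spectra):
        return SpectrumStore(spectra)

    def test_single_candidate_is_its_own_representative(self):
        s = make_spectrum([100.0, 200.0], [1.0, 1.0], run_id="r0", scan=1)
        state = LibraryState()
        psm = make_psm(1e-9, run="r0", scan=1)
        state.update_candidates([psm])
        chosen = select_representative(
            state.candidate_set(("PEPTIDEK", 2)), self._store([s])
        )
        assert chosen == psm

    def test_majority_of_identical_spectra_wins(self):
        common = dict(charge=2)
        s1 = make_spectrum([100.0, 200.0], [1.0, 1.0], run_id="r0", scan=1, **common)
        s2 = make_spectrum([100.0, 200.0], [1.0, 1.0], run_id="r0", scan=2, **common)
        s3 = make_spectrum([700.0, 800.0], [1.0, 1.0], run_id="r0", scan=3, **common)
        psms = [make_psm(1e-9, run="r0", scan=1), make_psm(2e-9, run="r0", scan=2),
                make_psm(3e-9, run="r0", scan=3)]
        state = LibraryState()
        state.update_candidates(psms)
        chosen = select_representative(
            state.candidate_set(("PEPTIDEK", 2)), self._store([s1, s2, s3])
        )
        # two identical spectra each average 0.5; the outlier averages 0.0;
        # the tie between the identical pair breaks to the best p-value
        assert chosen.scan == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_mean_cosine_argmax(self, seed):
        rng = rng_for(seed, "rep")
        n = int(rng.integers(2, 7))
        spectra, psms = [], []
        for i in range(n):
            k = int(rng.integers(3, 8))
            spectra.append(
                make_spectrum(
                    np.sort(rng.uniform(100, 1000, k)), rng.uniform(0.1, 1, k),
                    run_id="r0", scan=i,
                )
            )
            psms.append(make_psm(float(rng.uniform(1e-9, 1e-6)), run="r0", scan=i))
        state = LibraryState()
        state.update_candidates(psms)
        cand = state.candidate_set(("PEPTIDEK", 2))
        store = self._store(spectra)
        chosen = select_representative(cand, store)

        # independent brute force over the candidate order
        from speclib.spectrum import normalize_spectrum

        norm = {s.scan: normalize_spectrum(s) for s in spectra}
        means = []
        for p in cand.candidates:
            sims = [
                cosine(norm[p.scan], norm[q.scan])
                for q in cand.candidates
                if q.scan != p.scan
            ]
            means.append(sum(sims) / len(sims))
        best = max(range(n), key=lambda i: means[i] - 1e-12 * i)
        assert chosen == cand.candidates[best]

    def test_empty_candidates_rejected(self):
        from speclib.assembly import CandidateSet

        with pytest.raises(ValueError):
            select_representative(CandidateSet(("X", 2), []), SpectrumStore())


def entry(peptide="PEPTIDEK", charge=2):
    return LibraryEntry(
        peptide=peptide,
        charge=charge,
        representative=make_spectrum([100.0], [1.0], run_id="r0", scan=1),
        representative_p_value=1e-9,
        is_decoy=False,
        protein_accessions=frozenset({"P1"}),
        provenance=(("r0", 1),),
        datasets=frozenset({"D0"}),
        search_ids=frozenset({"s0"}),
        n_candidate_psms=1,
    )


class TestFilterAmbiguous:
    THRESHOLDS = {"s0": ThresholdTable(default=1e-6)}
    SEARCH = {("PEPTIDEK", 2): "s0"}

    def test_single_passing_annotation_retained(self):
        e = entry()
        anns = {e.key: [("PEPTIDEK", 1e-9), ("QTHERPEPK", 1e-3)]}
        assert filter_ambiguous([e], anns, self.THRESHOLDS, self.SEARCH) == [e]

    def test_localization_variants_collapse_to_one(self):
        e = entry()
        anns = {
            e.key: [("PEPS(+79.966)TIDE", 1e-9), ("PEPST(+79.966)IDE", 1e-8)]
        }
        assert filter_ambiguous([e], anns, self.THRESHOLDS, self.SEARCH) == [e]

    def test_two_distinct_passing_sequences_removed(self):
        e = entry()
        anns = {e.key: [("PEPTIDEK", 1e-9), ("QEPTIDEK", 1e-8)]}
        assert filter_ambiguous([e], anns, self.THRESHOLDS, self.SEARCH) == []

    def test_entry_without_annotation_record_retained(self):
        e = entry()
        assert filter_ambiguous([e], {}, self.THRESHOLDS, self.SEARCH) == [e]


class TestBuildLibrary:
    def test_empty_state_builds_empty_library(self):
        entries, report = build_library(
            LibraryState(), SpectrumStore(), {}, BuildConfig()
        )
        assert entries == []
        assert report.n_precursors_ledger == 0

    def test_end_to_end_matches_stagewise_oracle(self, psm_stream, universe):
        from speclib.library_fdr import (
            collapse_site_localization,
            local_precursor_fdr,
            map_precursors_to_proteins,
            picked_protein_fdr,
            retain_mapped_precursors,
            score_proteins,
        )

        store = SpectrumStore(psm_stream.spectra)
        state = LibraryState()
        state.update_candidates(psm_stream.psms, store)
        cfg = BuildConfig()
        entries, report = build_library(state, store, universe.fasta, cfg)

        records = state.precursor_records()
        _t, accepted = local_precursor_fdr(records, cfg.local_fdr_window, cfg.local_fdr)
        accepted = collapse_site_localization(accepted)
        mapping = map_precursors_to_proteins(accepted, universe.fasta)
        accs = picked_protein_fdr(score_proteins(accepted, mapping), cfg.protein_fdr)
        accepted = retain_mapped_precursors(accepted, mapping, accs)
        assert len(entries) == len(accepted)
        assert report.n_after_protein_fdr == len(accepted)

    def test_batch_permutations_yield_byte_identical_export(
        self, psm_stream, universe, tmp_path
    ):
        store = SpectrumStore(psm_stream.spectra)
        exports = []
        for i, perm in enumerate(itertools.islice(itertools.permutations(range(3)), 3)):
            psms = psm_stream.psms
            k = len(psms) // 3
            batches = [psms[:k], psms[k: 2 * k], psms[2 * k:]]
            state = LibraryState()
            for b in perm:
                state.update_candidates(batches[b], store)
            entries, _ = build_library(state, store, universe.fasta)
            out = tmp_path / f"lib{i}.mgf"
            write_library_mgf(entries, out)
            exports.append(out.read_bytes())
        assert exports[0] == exports[1] == exports[2]

    def test_adding_better_psm_never_drops_precursor(self, psm_stream, universe):
        store = SpectrumStore(psm_stream.spectra)
        state = LibraryState()
        state.update_candidates(psm_stream.psms, store)
        entries, _ = build_library(state, store, universe.fasta)
        keys = {e.key for e in entries}
        target_key = next(iter(keys))
        better = make_psm(1e-16, peptide=target_key[0], run="extra_r", scan=10_000)
        extra_spectrum = make_spectrum(
            [100.0, 200.0], [1.0, 1.0], run_id="extra_r", scan=10_000
        )
        store.add(extra_spectrum)
        state.update_candidates([better], store)
        entries2, _ = build_library(state, store, universe.fasta)
        assert target_key in {e.key for e in entries2}

    def test_representative_is_member_of_candidate_set(self, psm_stream, universe):
        store = SpectrumStore(psm_stream.spectra)
        state = LibraryState()
        state.update_candidates(psm_stream.psms, store)
        entries, _ = build_library(state, store, universe.fasta)
        assert entries
        for e in entries:
            refs = {p.spectrum_ref for p in state.candidate_set(e.key).candidates}
            assert (e.representative.run_id, e.representative.scan) in refs

    def test_decoy_entries_counted_not_dropped(self, psm_stream, universe):
        store = SpectrumStore(psm_stream.spectra)
        state = LibraryState()
        state.update_candidates(psm_stream.psms, store)
        entries, report = build_library(state, store, universe.fasta)
        assert report.n_decoy_entries == sum(e.is_decoy for e in entries)

    def test_state_round_trips_through_disk(self, psm_stream, tmp_path):
        store = SpectrumStore(psm_stream.spectra)
        state = LibraryState()
        state.update_candidates(psm_stream.psms, store)
        state.save(tmp_path / "state")
        loaded = LibraryState.load(tmp_path / "state")
        assert loaded.ledger == state.ledger
        for key in state.pools:
            assert (
                loaded.candidate_set(key).candidates
                == state.candidate_set(key).candidates
            )
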