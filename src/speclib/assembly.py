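"""Candidate ledger maintenance, representative selection and library build.

The headline property of this module is *order invariance*: merging the
same PSM stream in any batch partition and order yields a byte-identical
exported library. Two data structures make that possible:

* a precursor ledger recording, for every precursor ever observed
  (unfiltered, decoys included), the best-scoring PSM — so FDR thresholds
  can always be recomputed over the full history; and
* per-precursor candidate pools keeping the best <=20 PSMs per dataset
  (for every dataset ever seen), from which the top-100 candidate view is
  derived at read time. Both caps are prefix operations under one total
  order, so the merge is associative, commutative and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .config import BuildConfig
from .library_fdr import (
    PrecursorRecord,
    collapse_site_localization,
    local_precursor_fdr,
    map_precursors_to_proteins,
    naive_aggregate_fdr,
    picked_protein_fdr,
    retain_mapped_precursors,
    score_proteins,
)
from .peptide import PeptideSequence
from .psm import PSM, ThresholdTable
from .similarity import average_pairwise_cosine
from .spectrum import Spectrum, normalize_spectrum

PrecursorKey = tuple[str, int]


class SpectrumStore:
    """Peak lists keyed by (run_id, scan)."""

    def __init__(self, spectra: list[Spectrum] | None = None):
        self._by_key: dict[tuple[str, int], Spectrum] = {}
        for s in spectra or []:
            self.add(s)

    def add(self, spectrum: Spectrum) -> None:
        self._by_key[spectrum.key] = spectrum

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._by_key

    def get(self, run_id: str, scan: int) -> Spectrum:
        try:
            return self._by_key[(run_id, scan)]
        except KeyError:
            raise KeyError(f"no spectrum for run={run_id!r} scan={scan}") from None

    def __len__(self) -> int:
        return len(self._by_key)


@dataclass
class CandidateSet:
    """The bounded best-PSM pool for one precursor (top 100, <=20/dataset)."""

    key: PrecursorKey
    candidates: list[PSM]

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class LibraryEntry:
    """One exported library record: a representative spectrum plus provenance."""

    peptide: str
    charge: int
    representative: Spectrum
    representative_p_value: float
    is_decoy: bool
    protein_accessions: frozenset[str]
    provenance: tuple[tuple[str, int], ...]  # contributing (run, scan) refs
    datasets: frozenset[str]
    search_ids: frozenset[str]
    n_candidate_psms: int

    @property
    def key(self) -> PrecursorKey:
        return (self.peptide, self.charge)


@dataclass
class LibraryState:
    """The full, unfiltered accumulation state of a library build."""

    config: BuildConfig = field(default_factory=BuildConfig)
    ledger: dict[PrecursorKey, PSM] = field(default_factory=dict)
    pools: dict[PrecursorKey, dict[str, list[PSM]]] = field(default_factory=dict)

    def update_candidates(
        self, new_psms: list[PSM], spectra: SpectrumStore | None = None
    ) -> "LibraryState":
        """Merge a batch of quality-passing PSMs into the state (in place).

        The result is as if every PSM ever seen had been presented at
        once: ledger best-PSM per precursor, and per-(precursor, dataset)
        pools truncated to the per-dataset cap under the total order.
        Duplicate PSM identities are dropped, making the merge idempotent.
        """
        if spectra is not None:
            missing = [p.spectrum_ref for p in new_psms if p.spectrum_ref not in spectra]
            if missing:
                raise KeyError(f"PSMs reference missing spectra: {missing[:5]}")
        cap = self.config.per_dataset_cap
        for p in new_psms:
            key = p.precursor_key
            best = self.ledger.get(key)
            if best is None or p.sort_key < best.sort_key:
                self.ledger[key] = p
            pool = self.pools.setdefault(key, {}).setdefault(p.dataset_id, [])
            if any(q.identity == p.identity for q in pool):
                continue
            pool.append(p)
            pool.sort(key=lambda q: q.sort_key)
            del pool[cap:]
        return self

    def candidate_set(self, key: PrecursorKey) -> CandidateSet:
        """The top-N candidate view (per-dataset cap first, then global cap)."""
        merged: list[PSM] = []
        for pool in self.pools.get(key, {}).values():
            merged.extend(pool)
        merged.sort(key=lambda p: p.sort_key)
        return CandidateSet(key, merged[: self.config.top_candidates])

    def precursor_records(self) -> list[PrecursorRecord]:
        return [
            PrecursorRecord(pep, z, psm.database_p_value, psm.is_decoy)
            for (pep, z), psm in self.ledger.items()
        ]

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        from .psm import write_psm_tsv

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ledger_rows = [self.ledger[k] for k in sorted(self.ledger)]
        write_psm_tsv(ledger_rows, directory / "ledger.tsv")
        pool_rows: list[PSM] = []
        for key in sorted(self.pools):
            for ds in sorted(self.pools[key]):
                pool_rows.extend(self.pools[key][ds])
        write_psm_tsv(pool_rows, directory / "candidates.tsv")
        self.config.save(directory / "config.yaml")

    @classmethod
    def load(cls, directory: str | Path) -> "LibraryState":
        from .psm import read_psm_tsv

        directory = Path(directory)
        state = cls(config=BuildConfig.load(directory / "config.yaml"))
        state.update_candidates(read_psm_tsv(directory / "candidates.tsv"))
        # ledger may contain precursors whose pools were displaced; replay it
        for p in read_psm_tsv(directory / "ledger.tsv"):
            key = p.precursor_key
            best = state.ledger.get(key)
            if best is None or p.sort_key < best.sort_key:
                state.ledger[key] = p
        return state


def update_candidates(
    state: LibraryState, new_psms: list[PSM], spectra: SpectrumStore | None = None
) -> LibraryState:
    """Functional alias for :meth:`LibraryState.update_candidates`."""
    return state.update_candidates(new_psms, spectra)


def select_representative(
    candidates: CandidateSet,
    spectra: SpectrumStore,
    fragment_tolerance_da: float = 0.1,
) -> PSM:
    """The candidate whose spectrum has the highest mean cosine to the others.

    Ties (including the single-candidate case) resolve to the earliest
    candidate under the total order; candidate lists are already sorted.
    """
    if not candidates.candidates:
        raise ValueError("empty candidate set")
    psms = candidates.candidates
    if len(psms) == 1:
        return psms[0]
    specs = [
        normalize_spectrum(spectra.get(p.run_id, p.scan)) for p in psms
    ]
    means = average_pairwise_cosine(specs, fragment_tolerance_da)
    best = 0  # argmax with first-under-total-order tie-break
    for i in range(1, len(psms)):
        if means[i] > means[best] + 1e-12:
            best = i
    return psms[best]


def filter_ambiguous(
    entries: list[LibraryEntry],
    candidate_annotations: dict[PrecursorKey, list[tuple[str, float]]],
    per_search_thresholds: dict[str, ThresholdTable],
    entry_search: dict[PrecursorKey, str],
) -> list[LibraryEntry]:
    """Drop entries whose spectrum has >=2 confident distinct explanations.

    ``candidate_annotations`` supplies up to 20 alternative (peptide,
    database p-value) explanations per representative spectrum from a
    re-search. Alternatives passing the entry's *original search*
    threshold are collapsed over site-localization variants; entries with
    two or more surviving distinct annotations are removed. Entries with
    no annotation record are retained.
    """
    kept: list[LibraryEntry] = []
    for e in entries:
        alts = candidate_annotations.get(e.key)
        if alts is None:
            kept.append(e)
            continue
        table = per_search_thresholds.get(entry_search.get(e.key, ""), ThresholdTable())
        variants: dict[tuple, float] = {}
        for pep_str, p in alts:
            pep = PeptideSequence.parse(pep_str)
            if not table.accepts(len(pep.residues), p):
                continue
            gkey = (pep.residues, pep.delta_multiset)
            if gkey not in variants or p < variants[gkey]:
                variants[gkey] = p
        if len(variants) < 2:
            kept.append(e)
    return kept


@dataclass
class BuildReport:
    """Stage-by-stage accounting of one library build."""

    n_precursors_ledger: int = 0
    naive_fdr: float | None = None
    n_after_local_fdr: int = 0
    n_after_collapse: int = 0
    n_after_protein_fdr: int = 0
    n_representatives: int = 0
    n_after_ambiguity: int = 0
    n_decoy_entries: int = 0
    local_fdr_thresholds: ThresholdTable = field(default_factory=ThresholdTable)
    accepted_proteins: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "precursors_in_ledger": self.n_precursors_ledger,
            "naive_aggregate_fdr": self.naive_fdr,
            "after_local_precursor_fdr": self.n_after_local_fdr,
            "after_site_localization_collapse": self.n_after_collapse,
            "after_picked_protein_fdr": self.n_after_protein_fdr,
            "representatives_selected": self.n_representatives,
            "after_ambiguity_filter": self.n_after_ambiguity,
            "decoy_entries": self.n_decoy_entries,
            "accepted_proteins": sorted(self.accepted_proteins),
        }


def build_library(
    state: LibraryState,
    spectra: SpectrumStore,
    fasta: dict[str, str],
    config: BuildConfig | None = None,
    candidate_annotations: dict[PrecursorKey, list[tuple[str, float]]] | None = None,
    per_search_thresholds: dict[str, ThresholdTable] | None = None,
) -> tuple[list[LibraryEntry], BuildReport]:
    """Run the full library pipeline over an accumulated state.

    Stages: length-binned local precursor FDR -> site-localization
    collapse -> protein mapping -> picked protein FDR -> representative
    selection -> ambiguity filter. Entries come back sorted by
    (peptide, charge), which fixes the canonical export order.
    """
    cfg = config or state.config
    report = BuildReport()
    records = state.precursor_records()
    report.n_precursors_ledger = len(records)
    report.naive_fdr = naive_aggregate_fdr(records)
    if not records:
        return [], report

    table, accepted = local_precursor_fdr(
        records, window=cfg.local_fdr_window, alpha=cfg.local_fdr,
        window_mode=cfg.window_mode,
    )
    report.local_fdr_thresholds = table
    report.n_after_local_fdr = len(accepted)

    accepted = collapse_site_localization(accepted)
    report.n_after_collapse = len(accepted)

    mapping = map_precursors_to_proteins(accepted, fasta, cfg.il_equivalent)
    proteins = score_proteins(accepted, mapping)
    accepted_accessions = picked_protein_fdr(proteins, cfg.protein_fdr)
    report.accepted_proteins = accepted_accessions
    accepted = retain_mapped_precursors(accepted, mapping, accepted_accessions)
    report.n_after_protein_fdr = len(accepted)

    entries: list[LibraryEntry] = []
    for rec in accepted:
        cand = state.candidate_set(rec.key)
        if not cand.candidates:
            continue
        rep = select_representative(cand, spectra, cfg.fragment_tolerance_da)
        entries.append(
            LibraryEntry(
                peptide=rec.peptide,
                charge=rec.charge,
                representative=spectra.get(rep.run_id, rep.scan),
                representative_p_value=rep.database_p_value,
                is_decoy=rec.is_decoy,
                protein_accessions=frozenset(
                    mapping.get(rec.key, frozenset()) & accepted_accessions
                ),
                provenance=tuple(p.spectrum_ref for p in cand.candidates),
                datasets=frozenset(p.dataset_id for p in cand.candidates),
                search_ids=frozenset(p.search_id for p in cand.candidates),
                n_candidate_psms=len(cand.candidates),
            )
        )
    report.n_representatives = len(entries)

    if candidate_annotations is not None:
        entry_search = {
            e.key: state.ledger[e.key].search_id for e in entries if e.key in state.ledger
        }
        entries = filter_ambiguous(
            entries, candidate_annotations, per_search_thresholds or {}, entry_search
        )
    report.n_after_ambiguity = len(entries)
    entries.sort(key=lambda e: (e.peptide, e.charge))
    report.n_decoy_entries = sum(1 for e in entries if e.is_decoy)
    return entries, report
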