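"""Analyses on top of a finished library and its search provenance.

* **Proteotypic selection** — for each protein, the greedy set-cover over
  the searches in which it was observed: repeatedly pick the precursor
  covering the most not-yet-covered searches until 90% coverage or 20
  precursors.
* **Interaction detectability** — two proteins co-observed in one
  affinity-purification search are a candidate interaction; it stays
  detectable by proteotypic precursors if each member has at least one of
  its proteotypic precursors among that search's accepted precursors.
* **Novel-protein calling** — peptides of length >=9 that are not a
  single-amino-acid variant of any established (PE1) protein support a
  PE2-PE5 protein, which is called when two of its peptides occupy
  non-overlapping coordinate spans.
* **SILAC gold standard** — concordant light/heavy spectral pairs (same
  sequence modulo the label, aligned cosine > 0.6, explained intensity
  > 0.5 in both, co-elution within 1 minute) whose light members form a
  reference library with best-p-value representatives.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .config import BuildConfig
from .constants import SILAC_DELTA
from .peptide import PeptideSequence, strip_modifications
from .psm import PSM
from .similarity import aligned_cosine
from .spectrum import annotate_peaks, explained_intensity_fraction, normalize_spectrum

PrecursorKey = tuple[str, int]


# ---------------------------------------------------------------------------
# Proteotypic selection

@dataclass
class ProteotypicSet:
    """The greedy proteotypic precursors for one protein."""

    protein: str
    precursors: list[PrecursorKey]
    coverage: float
    covered_per_step: list[int] = field(default_factory=list)


def select_proteotypic(
    protein_searches: set[str],
    precursor_occurrences: dict[PrecursorKey, set[str]],
    target_coverage: float = 0.90,
    max_precursors: int = 20,
    precursor_rank: dict[PrecursorKey, float] | None = None,
    protein: str = "",
) -> ProteotypicSet:
    """Greedy set-cover of a protein's search occurrences by its precursors.

    Ties on marginal coverage break by lowest best-p-value (when
    ``precursor_rank`` is given) and then by the precursor total order.
    Every selected precursor strictly increases coverage.
    """
    if not protein_searches:
        raise ValueError(f"protein {protein!r} has no search occurrences")
    uncovered = set(protein_searches)
    remaining = dict(precursor_occurrences)
    chosen: list[PrecursorKey] = []
    steps: list[int] = []
    total = len(protein_searches)
    rank = precursor_rank or {}
    while uncovered and len(chosen) < max_precursors:
        best_key, best_gain = None, 0
        for key in sorted(remaining, key=lambda k: (rank.get(k, 1.0), k)):
            gain = len(remaining[key] & uncovered)
            if gain > best_gain:
                best_key, best_gain = key, gain
        if best_key is None:
            break
        chosen.append(best_key)
        steps.append(best_gain)
        uncovered -= remaining.pop(best_key)
        if (total - len(uncovered)) / total >= target_coverage:
            break
    coverage = (total - len(uncovered)) / total
    return ProteotypicSet(protein, chosen, coverage, steps)


# ---------------------------------------------------------------------------
# Co-observation interaction detectability

@dataclass(frozen=True)
class InteractionResult:
    co_observed: frozenset[tuple[str, str]]
    detectable: frozenset[tuple[str, str]]


def detect_interactions(
    per_search_proteins: dict[str, set[str]],
    proteotypic_sets: dict[str, ProteotypicSet],
    precursor_hits: dict[str, set[PrecursorKey]],
) -> InteractionResult:
    """Candidate interactions from co-observation in pulldown searches.

    A pair is detectable when each member has at least one proteotypic
    precursor among the search's accepted precursors in some search where
    both proteins were called.
    """
    co_observed: set[tuple[str, str]] = set()
    detectable: set[tuple[str, str]] = set()
    for search, proteins in per_search_proteins.items():
        hits = precursor_hits.get(search, set())
        called = sorted(proteins)
        seen_by_proteotypic = {
            p
            for p in called
            if p in proteotypic_sets
            and any(k in hits for k in proteotypic_sets[p].precursors)
        }
        for i, p in enumerate(called):
            for q in called[i + 1 :]:
                co_observed.add((p, q))
                if p in seen_by_proteotypic and q in seen_by_proteotypic:
                    detectable.add((p, q))
    return InteractionResult(frozenset(co_observed), frozenset(detectable))


# ---------------------------------------------------------------------------
# Novel-protein calling

def is_saav_of_pe1(
    peptide: str, pe1_sequences: list[str], il_equivalent: bool = False
) -> bool:
    """True when some PE1 protein window matches the peptide within Hamming
    distance 1 (distance 0 means the peptide maps to PE1 outright)."""
    pep = peptide.replace("I", "L") if il_equivalent else peptide
    n = len(pep)
    for seq in pe1_sequences:
        s = seq.replace("I", "L") if il_equivalent else seq
        for start in range(len(s) - n + 1):
            mismatches = 0
            for a, b in zip(pep, s[start : start + n]):
                if a != b:
                    mismatches += 1
                    if mismatches > 1:
                        break
            if mismatches <= 1:
                return True
    return False


def _occurrences(peptide: str, sequence: str) -> list[tuple[int, int]]:
    spans = []
    start = sequence.find(peptide)
    while start != -1:
        spans.append((start, start + len(peptide)))
        start = sequence.find(peptide, start + 1)
    return spans


def _max_disjoint_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedy interval scheduling: a maximum set of pairwise disjoint spans."""
    chosen: list[tuple[int, int]] = []
    last_end = -1
    for start, end in sorted(spans, key=lambda s: s[1]):
        if start >= last_end:  # end-exclusive spans: touching is disjoint
            chosen.append((start, end))
            last_end = end
    return chosen


def call_novel_proteins(
    peptides: set[str],
    fasta: dict[str, str],
    pe_levels: dict[str, int],
    min_length: int = 9,
    il_equivalent: bool = False,
) -> dict[str, list[tuple[str, int, int]]]:
    """Identify PE2-PE5 proteins supported by two non-overlapping peptides.

    ``peptides`` are bare accepted sequences (protein-level FDR already
    applied upstream). Peptides shorter than ``min_length`` or within one
    substitution of any PE1 protein are excluded. Accessions without a PE
    annotation are treated as PE1 (conservative). Returns called
    accessions mapped to supporting (peptide, start, end) spans, with the
    spans forming a maximal pairwise-disjoint set of size >= 2.
    """
    pe1_seqs = [seq for acc, seq in fasta.items() if pe_levels.get(acc, 1) == 1]
    candidates = sorted(
        pep
        for pep in peptides
        if len(pep) >= min_length and not is_saav_of_pe1(pep, pe1_seqs, il_equivalent)
    )
    called: dict[str, list[tuple[str, int, int]]] = {}
    for acc, seq in fasta.items():
        if pe_levels.get(acc, 1) < 2:
            continue
        spans_with_pep = []
        for pep in candidates:
            for start, end in _occurrences(pep, seq):
                spans_with_pep.append((start, end, pep))
        disjoint = _max_disjoint_spans([(s, e) for s, e, _ in spans_with_pep])
        if len(disjoint) >= 2:
            by_span = {(s, e): p for s, e, p in spans_with_pep}
            called[acc] = [(by_span[(s, e)], s, e) for s, e in disjoint]
    return called


# ---------------------------------------------------------------------------
# SILAC gold standard

@dataclass(frozen=True)
class SILACPair:
    """A concordant light/heavy pair with its concordance evidence."""

    light: PSM
    heavy: PSM
    aligned_cosine: float
    rt_delta: float
    light_explained: float
    heavy_explained: float


# label deltas compared at the canonical string's 3-decimal precision
_SILAC_VALUES = {round(v, 3) for v in SILAC_DELTA.values()}


def _silac_stripped_key(psm: PSM) -> tuple[str, tuple[float, ...], int]:
    """Precursor identity with SILAC label deltas removed."""
    pep = PeptideSequence.parse(psm.peptide)
    mods = tuple(
        (pos, delta)
        for pos, delta in pep.modifications
        if round(delta, 3) not in _SILAC_VALUES
    )
    deltas = tuple(sorted(round(d, 3) for _p, d in mods))
    return (pep.residues, deltas, psm.charge)


def _has_silac_label(psm: PSM) -> bool:
    pep = PeptideSequence.parse(psm.peptide)
    return any(round(d, 3) in _SILAC_VALUES for _p, d in pep.modifications)


def build_silac_gold(
    psms_light: list[PSM],
    psms_heavy: list[PSM],
    spectra,  # SpectrumStore
    config: BuildConfig | None = None,
) -> tuple[list[SILACPair], dict[PrecursorKey, PSM]]:
    """Concordant light/heavy pairing and gold-standard representative choice.

    Light and heavy PSMs pair when they share the same sequence, charge
    and non-label modifications; a pair is concordant when all four gates
    hold (aligned cosine, both explained intensities, retention-time
    delta). Per light precursor the lowest-p-value concordant spectrum
    becomes the representative. Output is independent of input ordering.
    """
    cfg = config or BuildConfig()
    heavy_by_key: dict[tuple, list[PSM]] = defaultdict(list)
    for h in sorted(psms_heavy, key=lambda p: p.sort_key):
        if _has_silac_label(h):
            heavy_by_key[_silac_stripped_key(h)].append(h)

    pairs: list[SILACPair] = []
    for light in sorted(psms_light, key=lambda p: p.sort_key):
        if _has_silac_label(light):
            continue
        key = _silac_stripped_key(light)
        for heavy in heavy_by_key.get(key, []):
            if heavy.charge != light.charge:
                continue
            rt_delta = abs(light.retention_time - heavy.retention_time)
            if rt_delta > cfg.silac_max_rt_delta_min:
                continue
            ls = normalize_spectrum(spectra.get(light.run_id, light.scan))
            hs = normalize_spectrum(spectra.get(heavy.run_id, heavy.scan))
            lpep = PeptideSequence.parse(light.peptide)
            hpep = PeptideSequence.parse(heavy.peptide)
            l_expl = explained_intensity_fraction(
                ls, annotate_peaks(ls, lpep, light.charge, cfg.fragment_tolerance_da)
            )
            h_expl = explained_intensity_fraction(
                hs, annotate_peaks(hs, hpep, heavy.charge, cfg.fragment_tolerance_da)
            )
            if l_expl <= cfg.silac_min_explained or h_expl <= cfg.silac_min_explained:
                continue
            delta = hpep.neutral_mass - lpep.neutral_mass
            score = aligned_cosine(
                ls, hs, delta, cfg.fragment_tolerance_da, max_charge=light.charge
            )
            if score <= cfg.silac_min_cosine:
                continue
            pairs.append(SILACPair(light, heavy, score, rt_delta, l_expl, h_expl))

    representatives: dict[PrecursorKey, PSM] = {}
    for pair in sorted(pairs, key=lambda p: p.light.sort_key):
        key = pair.light.precursor_key
        if key not in representatives:
            representatives[key] = pair.light
    return pairs, representatives
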