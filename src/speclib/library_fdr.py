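"""Library-level error control.

Aggregating many independently FDR-filtered searches inflates the error
rate of the union (naively merging everything can push precursor FDR to
tens of percent), so the library applies its own controls:

* a length-binned *local* precursor FDR — within each peptide-length bin,
  precursors are ranked by their best database p-value and the local FDR
  at a record is the decoy/target ratio over a sliding window of
  surrounding records (default 500); the acceptance threshold is the worst
  p-value whose window stays below the nominal level;
* collapse of site-localization variants to the best-scoring precursor;
* a *picked* protein-level FDR where each target competes only against its
  own reversed-decoy counterpart, proteins being scored by the sum of
  -log10 database p-values over uniquely mapped precursors.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .peptide import PeptideSequence, strip_modifications
from .psm import ThresholdTable
from .scoring import DECOY_PREFIX


@dataclass(frozen=True)
class PrecursorRecord:
    """A precursor (peptide string + charge) with its best PSM p-value."""

    peptide: str
    charge: int
    best_p_value: float
    is_decoy: bool

    @property
    def key(self) -> tuple[str, int]:
        return (self.peptide, self.charge)

    @property
    def length(self) -> int:
        return len(strip_modifications(self.peptide))

    @property
    def sort_key(self) -> tuple:
        return (self.best_p_value, self.is_decoy, self.peptide, self.charge)


@dataclass
class ProteinRecord:
    """A protein scored by its uniquely mapped precursors."""

    accession: str
    is_decoy: bool
    score: float = 0.0
    unique_precursors: list[tuple[str, int]] = field(default_factory=list)

    @property
    def base_accession(self) -> str:
        return (
            self.accession[len(DECOY_PREFIX):]
            if self.accession.startswith(DECOY_PREFIX)
            else self.accession
        )


def local_precursor_fdr(
    records: list[PrecursorRecord],
    window: int = 500,
    alpha: float = 0.01,
    window_mode: str = "trailing",
) -> tuple[ThresholdTable, list[PrecursorRecord]]:
    """Length-binned sliding-window local FDR filter.

    Within each length bin, records are sorted by increasing p-value. In
    the default ``trailing`` mode the window at a record consists of the
    record itself plus the up-to ``window - 1`` better-scoring records;
    ``centered`` places the window symmetrically around the record. Bins
    smaller than the window use the whole bin. The per-bin threshold is
    the highest p-value whose window has decoy/target ratio < alpha, and
    every record at or below the threshold is accepted.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if window_mode not in {"trailing", "centered"}:
        raise ValueError(f"unknown window mode {window_mode!r}")

    bins: dict[int, list[PrecursorRecord]] = defaultdict(list)
    for r in records:
        bins[r.length].append(r)

    table = ThresholdTable()
    accepted: list[PrecursorRecord] = []
    for length, recs in bins.items():
        recs.sort(key=lambda r: r.sort_key)
        n = len(recs)
        w = min(window, n)
        decoy = np.fromiter((r.is_decoy for r in recs), dtype=np.int64, count=n)
        cum = np.concatenate([[0], np.cumsum(decoy)])
        idx = np.arange(n)
        if window_mode == "trailing":
            lo = np.maximum(0, idx - w + 1)
            hi = idx + 1
        else:
            half = w // 2
            lo = np.maximum(0, idx - half)
            hi = np.minimum(n, idx + half + 1)
        d = cum[hi] - cum[lo]
        t = (hi - lo) - d
        with np.errstate(divide="ignore", invalid="ignore"):
            local = np.where(t > 0, d / np.maximum(t, 1), np.inf)
        ok = np.nonzero(local < alpha)[0]
        if ok.size == 0:
            table.by_length[length] = 0.0
            continue
        threshold = recs[int(ok.max())].best_p_value
        table.by_length[length] = threshold
        accepted.extend(r for r in recs if r.best_p_value <= threshold)

    accepted.sort(key=lambda r: r.sort_key)
    return table, accepted


def collapse_site_localization(records: list[PrecursorRecord]) -> list[PrecursorRecord]:
    """Keep the best-scoring precursor among site-localization variants.

    Variants share the bare sequence, the multiset of modification deltas
    and the charge; only the placement of the deltas differs.
    """
    groups: dict[tuple, PrecursorRecord] = {}
    for r in sorted(records, key=lambda r: r.sort_key):
        pep = PeptideSequence.parse(r.peptide)
        gkey = (pep.residues, pep.delta_multiset, r.charge)
        if gkey not in groups:
            groups[gkey] = r
    return sorted(groups.values(), key=lambda r: r.sort_key)


def map_precursors_to_proteins(
    records: list[PrecursorRecord],
    fasta: dict[str, str],
    il_equivalent: bool = False,
) -> dict[tuple[str, int], frozenset[str]]:
    """Exact substring mapping of bare peptide sequences onto protein sequences.

    Returns, for every precursor key, the (possibly empty) set of matching
    accessions; precursors matching more than one accession are shared and
    excluded from protein scoring. ``il_equivalent`` folds I onto L on both
    sides before matching.
    """
    def fold(s: str) -> str:
        return s.replace("I", "L") if il_equivalent else s

    proteins = [(acc, fold(seq)) for acc, seq in fasta.items()]
    cache: dict[str, frozenset[str]] = {}
    mapping: dict[tuple[str, int], frozenset[str]] = {}
    for r in records:
        seq = fold(strip_modifications(r.peptide))
        if seq not in cache:
            cache[seq] = frozenset(acc for acc, pseq in proteins if seq in pseq)
        mapping[r.key] = cache[seq]
    return mapping


def score_proteins(
    records: list[PrecursorRecord],
    mapping: dict[tuple[str, int], frozenset[str]],
) -> list[ProteinRecord]:
    """Score each protein by the sum of -log10 p over uniquely mapped precursors."""
    proteins: dict[str, ProteinRecord] = {}
    for r in sorted(records, key=lambda r: r.sort_key):
        accs = mapping.get(r.key, frozenset())
        if len(accs) != 1:
            continue  # unmapped or shared: excluded from protein scoring
        (acc,) = accs
        rec = proteins.setdefault(
            acc, ProteinRecord(acc, acc.startswith(DECOY_PREFIX))
        )
        rec.score += -math.log10(r.best_p_value)
        rec.unique_precursors.append(r.key)
    return sorted(proteins.values(), key=lambda p: (-p.score, p.accession))


def picked_protein_fdr(
    proteins: list[ProteinRecord], alpha: float = 0.01
) -> set[str]:
    """Picked protein-level TDA.

    Each target competes only against its own decoy counterpart; the
    higher-scoring member of every pair enters the ranking (ties go to the
    target). Competitors are sorted by decreasing score and the largest
    prefix with decoy/target ratio <= alpha is accepted. Accessions in the
    accepted prefix — including surviving decoys — are returned, so decoy
    precursors can persist into the library for downstream error estimation.
    """
    pairs: dict[str, dict[bool, ProteinRecord]] = defaultdict(dict)
    for p in proteins:
        pairs[p.base_accession][p.is_decoy] = p
    competitors: list[ProteinRecord] = []
    for members in pairs.values():
        target, decoy = members.get(False), members.get(True)
        if target is not None and decoy is not None:
            competitors.append(target if target.score >= decoy.score else decoy)
        else:
            competitors.append(target if target is not None else decoy)
    competitors.sort(key=lambda p: (-p.score, p.is_decoy, p.accession))

    best_cut = 0
    targets = decoys = 0
    for i, p in enumerate(competitors, start=1):
        if p.is_decoy:
            decoys += 1
        else:
            targets += 1
        if targets > 0 and decoys / targets <= alpha:
            best_cut = i
    return {p.accession for p in competitors[:best_cut]}


def retain_mapped_precursors(
    records: list[PrecursorRecord],
    mapping: dict[tuple[str, int], frozenset[str]],
    accepted_accessions: set[str],
) -> list[PrecursorRecord]:
    """Keep precursors whose sequence maps to >=1 accepted protein."""
    return [
        r for r in records if mapping.get(r.key, frozenset()) & accepted_accessions
    ]


def naive_aggregate_fdr(records: list[PrecursorRecord]) -> float | None:
    """Decoy/target ratio over the full unfiltered precursor ledger.

    The diagnostic that motivates library-level controls: the error rate
    one would incur by merging all per-search results without them.
    Returns None when there are no targets (undefined).
    """
    targets = sum(1 for r in records if not r.is_decoy)
    decoys = len(records) - targets
    if targets == 0:
        return None
    return decoys / targets
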