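"""Search-level statistics: database p-values, TDA FDR filtering, dynamic
search-space adjustment, and the synthetic-pool empirical FDR.

The database p-value converts a spectral probability P(S|T) — the chance
that a random peptide matches spectrum S better than the reported match —
into the chance that at least one of N database candidates does:
``1 - (1 - P(S|T))**N``. It is computed with log1p/expm1 so that the tiny
probabilities typical of good matches (1e-15 and below) survive with full
relative precision.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping

from .peptide import strip_modifications
from .psm import PSM, SearchContext, ThresholdTable

DECOY_PREFIX = "XXX_"


def database_p_value(spectral_probability: float, database_size: int) -> float:
    """Probability of >=1 random match at least as good, in a database of size N.

    Strictly increasing in both arguments; equals p at N = 1.
    """
    p = spectral_probability
    if not 0.0 < p <= 1.0:
        raise ValueError("spectral probability must be in (0, 1]")
    if database_size < 1:
        raise ValueError("database size must be >= 1")
    if p == 1.0:
        return 1.0
    # 1 - (1-p)^N = -expm1(N * log1p(-p)), stable for p down to ~1e-300
    return -math.expm1(database_size * math.log1p(-p))


def sort_psms(psms: Iterable[PSM]) -> list[PSM]:
    """Sort by the pipeline total order (p-value, targets first, run, scan)."""
    return sorted(psms, key=lambda p: p.sort_key)


def psm_fdr_filter(psms: Iterable[PSM], alpha: float = 0.01) -> list[PSM]:
    """Target-decoy FDR filter at level ``alpha``.

    PSMs are sorted by increasing database p-value and the largest prefix
    with decoy/target ratio <= alpha is accepted. Decoys inside the prefix
    are retained (flagged) so library-level error rates can be estimated
    downstream.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ordered = sort_psms(psms)
    best_cut = 0
    targets = decoys = 0
    for i, p in enumerate(ordered, start=1):
        if p.is_decoy:
            decoys += 1
        else:
            targets += 1
        if targets > 0 and decoys / targets <= alpha:
            best_cut = i
    return ordered[:best_cut]


def psm_fdr_threshold(psms: Iterable[PSM], alpha: float = 0.01) -> ThresholdTable:
    """The p-value cut realised by :func:`psm_fdr_filter`, as a threshold table."""
    accepted = psm_fdr_filter(psms, alpha)
    if not accepted:
        return ThresholdTable(default=0.0)
    return ThresholdTable(default=accepted[-1].database_p_value)


def adjust_search_space(
    psms: list[PSM],
    full_context: SearchContext,
    reduced_database_size: int,
    protein_of: Mapping[str, str],
    peptide_level_fdr: float = 0.01,
    psm_level_fdr: float = 0.01,
) -> list[PSM]:
    """Two-pass rescoring for proteome-limited (e.g. affinity purification) data.

    A protein group is eligible for the reduced search space when, at the
    given peptide-level FDR, at least two distinct peptide sequences map to
    the target protein P or to its decoy counterpart reverse(P) (pooled, so
    that TDA also models true/false peptide pairs). PSMs of eligible
    proteins have their database p-values recomputed at the reduced N; all
    other PSMs keep their original values. The result is re-sorted and
    re-filtered at the PSM-level FDR.

    ``protein_of`` maps bare peptide sequences to their protein accession;
    decoy peptides map to the decoy accession (``XXX_`` prefix).
    """
    if reduced_database_size < 1:
        raise ValueError("reduced database size must be >= 1")

    # peptide-level records: best (lowest) p-value per distinct bare sequence
    best_by_seq: dict[str, PSM] = {}
    for p in sort_psms(psms):
        seq = strip_modifications(p.peptide)
        if seq not in best_by_seq:
            best_by_seq[seq] = p
    peptide_records = psm_fdr_filter(best_by_seq.values(), peptide_level_fdr)

    # pool accepted peptides per base accession (target and decoy together)
    peptides_per_group: dict[str, set[str]] = defaultdict(set)
    for rec in peptide_records:
        seq = strip_modifications(rec.peptide)
        if seq not in protein_of:
            raise KeyError(f"no protein mapping for peptide {seq!r}")
        acc = protein_of[seq]
        base = acc[len(DECOY_PREFIX):] if acc.startswith(DECOY_PREFIX) else acc
        peptides_per_group[base].add(seq)
    eligible_groups = {g for g, seqs in peptides_per_group.items() if len(seqs) >= 2}

    adjusted: list[PSM] = []
    for p in psms:
        seq = strip_modifications(p.peptide)
        if seq not in protein_of:
            raise KeyError(f"no protein mapping for peptide {seq!r}")
        acc = protein_of[seq]
        base = acc[len(DECOY_PREFIX):] if acc.startswith(DECOY_PREFIX) else acc
        if base in eligible_groups:
            adjusted.append(
                p.with_p_value(database_p_value(p.spectral_probability, reduced_database_size))
            )
        else:
            adjusted.append(p)
    return psm_fdr_filter(adjusted, psm_level_fdr)


def synthetic_pool_empirical_fdr(
    psms: list[PSM],
    context: SearchContext,
    pool_target_peptides: set[str],
    background_pool_peptides: Mapping[str, set[str]],
) -> tuple[ThresholdTable, list[PSM]]:
    """Zero-empirical-FDR filtering for synthetic peptide-pool searches.

    A decoy PSM is (a) a main-pool spectrum matched to the decoy database,
    or (b) a background-run spectrum matched to anything — except that a
    background-run match to a peptide synthesized in that run's pool AND
    present in the target pool is excluded from decoy counting (it may be
    a genuine identification) and dropped from the analysis. Per peptide
    length, the acceptance threshold is set strictly below the best decoy
    p-value, so the accepted set contains no decoys by construction.
    """
    if context.search_type != "synthetic_pool":
        raise ValueError("empirical pool FDR requires a synthetic_pool context")
    if not context.background_run_ids:
        raise ValueError("empirical FDR undefined without background runs")

    by_length: dict[int, list[tuple[PSM, bool]]] = defaultdict(list)
    for p in psms:
        background = p.run_id in context.background_run_ids
        if background:
            seq = strip_modifications(p.peptide)
            run_pool = background_pool_peptides.get(p.run_id, set())
            if seq in run_pool and seq in pool_target_peptides:
                continue  # excluded: plausibly real, never counted as decoy
            is_decoy_psm = True
        else:
            is_decoy_psm = p.is_decoy
        by_length[p.peptide_length].append((p, is_decoy_psm))

    table = ThresholdTable()
    accepted: list[PSM] = []
    for length, entries in by_length.items():
        decoy_ps = [p.database_p_value for p, d in entries if d]
        cutoff = min(decoy_ps) if decoy_ps else math.inf
        kept = [p for p, d in entries if not d and p.database_p_value < cutoff]
        table.by_length[length] = (
            max((p.database_p_value for p in kept), default=0.0)
        )
        accepted.extend(kept)
    return table, sort_psms(accepted)
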