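"""Peptide-spectrum matches, search contexts and score-threshold tables.

The PSM is the atomic identification record flowing through the pipeline.
Its score is the database p-value derived from the search engine's
spectral probability and the effective database size; the decoy flag set
at search time is immutable and carried through to the final library.

Sorting everywhere uses one total order — (database p-value, decoy flag
with targets first, run id, scan) — so that every downstream selection is
deterministic and merges are order invariant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .peptide import PeptideSequence, strip_modifications


@dataclass(frozen=True)
class SearchContext:
    """Per-search metadata: identity, kind, and effective database size N."""

    search_id: str
    search_type: str  # "proteome" | "affinity_purification" | "synthetic_pool"
    database_size: int
    background_run_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.search_type not in {"proteome", "affinity_purification", "synthetic_pool"}:
            raise ValueError(f"unknown search type {self.search_type!r}")
        if self.database_size < 1:
            raise ValueError("database_size must be >= 1")
        if self.background_run_ids and self.search_type != "synthetic_pool":
            raise ValueError("background runs are only defined for synthetic pools")


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match with score and provenance."""

    run_id: str
    scan: int
    dataset_id: str
    search_id: str
    peptide: str  # canonical inline-modification string
    charge: int
    spectral_probability: float
    database_p_value: float
    is_decoy: bool
    retention_time: float = 0.0  # minutes

    def __post_init__(self) -> None:
        if not 0.0 < self.spectral_probability <= 1.0:
            raise ValueError("spectral probability must be in (0, 1]")
        if not 0.0 < self.database_p_value <= 1.0:
            raise ValueError("database p-value must be in (0, 1]")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def precursor_key(self) -> tuple[str, int]:
        return (self.peptide, self.charge)

    @property
    def spectrum_ref(self) -> tuple[str, int]:
        return (self.run_id, self.scan)

    @property
    def peptide_length(self) -> int:
        return len(strip_modifications(self.peptide))

    @property
    def parsed_peptide(self) -> PeptideSequence:
        return PeptideSequence.parse(self.peptide)

    @property
    def sort_key(self) -> tuple:
        """The pipeline-wide total order: better score first, targets before decoys."""
        return (self.database_p_value, self.is_decoy, self.run_id, self.scan)

    @property
    def identity(self) -> tuple:
        """Uniqueness key for deduplication on merge."""
        return (self.run_id, self.scan, self.search_id, self.peptide, self.charge)

    def with_p_value(self, p: float) -> "PSM":
        return replace(self, database_p_value=p)


@dataclass
class ThresholdTable:
    """Maximum accepted database p-value, per peptide length.

    ``default`` applies to lengths without an explicit entry (a plain
    per-search FDR cut is a table with only a default). A record passes
    when its p-value is <= the applicable threshold.
    """

    by_length: dict[int, float] = field(default_factory=dict)
    default: float | None = None

    def threshold_for(self, length: int) -> float | None:
        return self.by_length.get(length, self.default)

    def accepts(self, length: int, p_value: float) -> bool:
        t = self.threshold_for(length)
        return t is not None and p_value <= t

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["length", "max_p_value"])
            if self.default is not None:
                w.writerow(["*", f"{self.default:.6e}"])
            for length in sorted(self.by_length):
                w.writerow([length, f"{self.by_length[length]:.6e}"])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ThresholdTable":
        table = cls()
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader)
            for row in reader:
                if row[0] == "*":
                    table.default = float(row[1])
                else:
                    table.by_length[int(row[0])] = float(row[1])
        return table


PSM_TSV_COLUMNS = [
    "run_id",
    "scan",
    "dataset_id",
    "search_id",
    "peptide",
    "charge",
    "spectral_probability",
    "database_p_value",
    "is_decoy",
    "rt_min",
]


def write_psm_tsv(psms: Iterable[PSM], path: str | Path) -> None:
    """Write PSMs in the documented tab-separated dialect (lossless round trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PSM_TSV_COLUMNS)
        for p in psms:
            w.writerow(
                [
                    p.run_id,
                    p.scan,
                    p.dataset_id,
                    p.search_id,
                    p.peptide,
                    p.charge,
                    repr(p.spectral_probability),
                    repr(p.database_p_value),
                    int(p.is_decoy),
                    repr(p.retention_time),
                ]
            )


def read_psm_tsv(path: str | Path, recompute_missing_p: int | None = None) -> list[PSM]:
    """Read the PSM TSV dialect, validating ranges.

    If ``database_p_value`` is empty and ``recompute_missing_p`` gives a
    database size N, the p-value is recomputed from the spectral probability.
    """
    from .scoring import database_p_value as _dbp

    psms: list[PSM] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(PSM_TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"PSM table {path} missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            sp = float(row["spectral_probability"])
            raw_p = row["database_p_value"]
            if raw_p:
                p = float(raw_p)
            elif recompute_missing_p is not None:
                p = _dbp(sp, recompute_missing_p)
            else:
                raise ValueError(
                    f"{path}:{lineno}: database_p_value absent and no database size given"
                )
            psms.append(
                PSM(
                    run_id=row["run_id"],
                    scan=int(row["scan"]),
                    dataset_id=row["dataset_id"],
                    search_id=row["search_id"],
                    peptide=row["peptide"],
                    charge=int(row["charge"]),
                    spectral_probability=sp,
                    database_p_value=p,
                    is_decoy=bool(int(row["is_decoy"])),
                    retention_time=float(row["rt_min"]),
                )
            )
    return psms
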