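"""Readers and writers for the standard interchange formats.

MGF reading goes through pyteomics; writing is canonical — entries in a
fixed order with fixed float precision — because exported libraries must
be byte-identical across rebuilds and batch permutations. The library MGF
dialect adds ``SEQ=`` and a ``#provenance`` comment per entry; sptxt
follows the SpectraST text layout (Name:, LibID:, PrecursorMZ:, Comment:,
NumPeaks:, then peak rows).
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
from pyteomics import fasta as _fasta
from pyteomics import mgf as _mgf

from .scoring import DECOY_PREFIX
from .spectrum import Spectrum

if TYPE_CHECKING:  # pragma: no cover
    from .assembly import LibraryEntry


# ---------------------------------------------------------------------------
# MGF

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak-list file into Spectrum objects.

    TITLE is expected to carry ``run=<id> scan=<n> dataset=<id>`` tokens
    (the dialect our writer emits); SCANS/RTINSECONDS/PEPMASS/CHARGE are
    honored when present.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            title = params.get("title", "")
            fields = dict(
                tok.split("=", 1) for tok in title.split() if "=" in tok
            )
            charge = int(params["charge"][0]) if "charge" in params else 1
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            scan = int(params.get("scans", fields.get("scan", 0)))
            spectra.append(
                Spectrum(
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    retention_time=rt,
                    run_id=fields.get("run", params.get("title", "")),
                    dataset_id=fields.get("dataset", ""),
                    scan=scan,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF in canonical form (fixed precision, stable order)."""
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE=run={s.run_id} scan={s.scan} dataset={s.dataset_id}")
        lines.append(f"PEPMASS={s.precursor_mz:.5f}")
        lines.append(f"CHARGE={s.precursor_charge}+")
        lines.append(f"RTINSECONDS={s.retention_time * 60.0:.3f}")
        lines.append(f"SCANS={s.scan}")
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{mz:.5f} {inten:.6f}")
        lines.append("END IONS")
    Path(path).write_text("\n".join(lines) + "\n")


def write_library_mgf(entries: "Iterable[LibraryEntry]", path: str | Path) -> None:
    """Annotated library MGF: adds SEQ= and a provenance comment per entry."""
    lines: list[str] = []
    for e in entries:
        s = e.representative
        lines.append("BEGIN IONS")
        lines.append(
            f"#provenance datasets={','.join(sorted(e.datasets))} "
            f"psms={e.n_candidate_psms} source_run={s.run_id} source_scan={s.scan}"
        )
        lines.append(f"TITLE=run={s.run_id} scan={s.scan} dataset={s.dataset_id}")
        lines.append(f"SEQ={e.peptide}")
        lines.append(f"PEPMASS={s.precursor_mz:.5f}")
        lines.append(f"CHARGE={e.charge}+")
        lines.append(f"RTINSECONDS={s.retention_time * 60.0:.3f}")
        lines.append(f"SCANS={s.scan}")
        lines.append(f"DECOY={int(e.is_decoy)}")
        lines.append(f"PVALUE={e.representative_p_value:.6e}")
        lines.append(f"PROTEIN={';'.join(sorted(e.protein_accessions))}")
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{mz:.5f} {inten:.6f}")
        lines.append("END IONS")
    Path(path).write_text("\n".join(lines) + "\n")


def write_sptxt(entries: "Iterable[LibraryEntry]", path: str | Path) -> None:
    """Write a SpectraST-style text library with per-peak ion annotations."""
    from .peptide import PeptideSequence
    from .spectrum import annotate_peaks

    lines: list[str] = []
    for lib_id, e in enumerate(entries):
        s = e.representative
        peptide = PeptideSequence.parse(e.peptide)
        neutral = peptide.neutral_mass
        lines.append(f"Name: {e.peptide}/{e.charge}")
        lines.append(f"LibID: {lib_id}")
        lines.append(f"MW: {neutral:.5f}")
        lines.append(f"PrecursorMZ: {peptide.mz(e.charge):.5f}")
        comment = (
            f"Comment: Protein={';'.join(sorted(e.protein_accessions)) or 'unmapped'}"
            f" Decoy={int(e.is_decoy)} Pvalue={e.representative_p_value:.6e}"
            f" Datasets={','.join(sorted(e.datasets))}"
            f" SourceRun={s.run_id} SourceScan={s.scan}"
        )
        lines.append(comment)
        lines.append(f"NumPeaks: {s.n_peaks}")
        ann = {
            a.peak_index: a.label
            for a in reversed(annotate_peaks(s, peptide, e.charge))
        }
        for i, (pmz, pint) in enumerate(zip(s.mz, s.intensity)):
            lines.append(f"{pmz:.5f}\t{pint:.6f}\t{ann.get(i, '?')}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an accession -> sequence mapping."""
    records: dict[str, str] = {}
    with _fasta.FASTA(str(path)) as reader:
        for header, seq in reader:
            records[header.split()[0]] = seq
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc in records:
            fh.write(f">{acc}\n{records[acc]}\n")


def add_reversed_decoys(
    records: dict[str, str], prefix: str = DECOY_PREFIX
) -> dict[str, str]:
    """Append whole-protein-reversal decoys with a configurable prefix."""
    out = dict(records)
    for acc, seq in records.items():
        out[f"{prefix}{acc}"] = seq[::-1]
    return out
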