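"""Peptide sequences with mass modifications.

A peptide is a string over the 20 amino-acid letters plus a list of
``(position, delta_mass)`` modifications, where ``position`` is a 0-based
residue index or the string ``"N-term"``. Peptides are charge independent;
a precursor is a (peptide, charge) pair.

The canonical text form writes each modification inline after its residue
as a signed delta with three decimal places, e.g. ``PEPS(+79.966)TIDE``;
an N-terminal modification is written before the first residue, e.g.
``(+42.011)PEPTIDE``. Canonicalisation makes precursor equality plain
string equality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .constants import PROTON, RESIDUE_MASS, WATER

_MOD_RE = re.compile(r"\(([+-]\d+(?:\.\d+)?)\)")

ModPosition = int | str  # 0-based index or "N-term"


class InvalidPeptideError(ValueError):
    """Raised for residues outside the amino-acid alphabet or bad positions."""


@dataclass(frozen=True)
class PeptideSequence:
    """An amino-acid sequence with optional mass modifications."""

    residues: str
    modifications: tuple[tuple[ModPosition, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for aa in self.residues:
            if aa not in RESIDUE_MASS:
                raise InvalidPeptideError(f"unknown residue {aa!r} in {self.residues!r}")
        for pos, _delta in self.modifications:
            if pos == "N-term":
                continue
            if not isinstance(pos, int) or not 0 <= pos < len(self.residues):
                raise InvalidPeptideError(
                    f"modification position {pos!r} outside sequence of length {len(self.residues)}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic neutral mass: residue sum + water + modification deltas."""
        mass = sum(RESIDUE_MASS[aa] for aa in self.residues) + WATER
        return mass + sum(delta for _pos, delta in self.modifications)

    def mz(self, charge: int) -> float:
        if charge < 1:
            raise ValueError("charge must be >= 1")
        return (self.neutral_mass + charge * PROTON) / charge

    def canonical(self) -> str:
        """Canonical inline-modification string; equality-safe representation."""
        by_pos: dict[ModPosition, float] = {}
        for pos, delta in self.modifications:
            by_pos[pos] = by_pos.get(pos, 0.0) + delta
        out = []
        if "N-term" in by_pos:
            out.append(f"({by_pos['N-term']:+.3f})")
        for i, aa in enumerate(self.residues):
            out.append(aa)
            if i in by_pos:
                out.append(f"({by_pos[i]:+.3f})")
        return "".join(out)

    @property
    def delta_multiset(self) -> tuple[float, ...]:
        """Sorted modification deltas (3 d.p.); localization-free identity."""
        return tuple(sorted(round(d, 3) for _p, d in self.modifications))

    @classmethod
    def parse(cls, text: str) -> "PeptideSequence":
        """Parse the canonical inline-delta form back into a peptide."""
        mods: list[tuple[ModPosition, float]] = []
        residues: list[str] = []
        i = 0
        while i < len(text):
            ch = text[i]
            if ch == "(":
                m = _MOD_RE.match(text, i)
                if not m:
                    raise InvalidPeptideError(f"malformed modification in {text!r} at {i}")
                delta = float(m.group(1))
                pos: ModPosition = "N-term" if not residues else len(residues) - 1
                mods.append((pos, delta))
                i = m.end()
            else:
                residues.append(ch)
                i += 1
        return cls("".join(residues), tuple(mods))


def strip_modifications(peptide_string: str) -> str:
    """Remove inline modification annotations, leaving the bare sequence."""
    return _MOD_RE.sub("", peptide_string)


def tryptic_peptides(
    sequence: str,
    missed_cleavages: int = 1,
    min_length: int = 6,
    max_length: int = 40,
) -> list[str]:
    """Fully tryptic peptides of a protein (cleave after K/R, not before P).

    Used to recount the effective database size N when a search space is
    restricted to a protein subset; the digest convention (<=1 missed
    cleavage, length 6-40 by default) mirrors typical search settings.
    """
    sites = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            sites.append(i + 1)
    sites.append(len(sequence))
    peptides = []
    for a in range(len(sites) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(sites))):
            pep = sequence[sites[a] : sites[b]]
            if min_length <= len(pep) <= max_length:
                peptides.append(pep)
    return peptides


def count_tryptic_peptides(sequences: list[str], **kwargs) -> int:
    """Number of distinct tryptic peptides over a protein subset.

    This is the reduced database size N used when database p-values are
    recomputed for a restricted search space.
    """
    seen: set[str] = set()
    for seq in sequences:
        seen.update(tryptic_peptides(seq, **kwargs))
    return len(seen)
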