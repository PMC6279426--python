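"""Physical constants and monoisotopic mass tables.

All masses are monoisotopic and given in daltons, fixed to five decimal
places so that every build of a library is reproducible independent of
any external mass table. The table is emitted alongside every exported
library as a provenance record (see :func:`write_constants_snapshot`).
"""

from __future__ import annotations

from pathlib import Path

#: Monoisotopic residue masses (Da), 5 decimal places.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Mass of a proton (Da).
PROTON = 1.00728
#: Mass of a water molecule (Da); added to the residue sum for a neutral peptide.
WATER = 18.01056
#: Mass of an ammonia molecule (Da); neutral loss.
NH3 = 17.02655
#: Mass of carbon monoxide (Da); b -> a ion conversion.
CO = 27.99491
#: Mass difference between 13C and 12C (Da); one-isotope precursor rescue.
C13_DELTA = 1.00335

#: Common variable/fixed modification deltas (Da) used throughout.
MODIFICATION_MASS: dict[str, float] = {
    "Oxidation(M)": 15.995,
    "Acetyl(N-term)": 42.011,
    "Carbamyl(N-term)": 43.006,
    "PyroGlu(Q)": -17.027,
    "Deamidation(NQ)": 0.984,
    "Carbamidomethyl(C)": 57.021,
    "Phospho(STY)": 79.966,
    "SILAC(K)": 8.0142,
    "SILAC(R)": 10.0083,
}

#: SILAC heavy-label deltas keyed by the labelled residue.
SILAC_DELTA: dict[str, float] = {"K": 8.0142, "R": 10.0083}


def write_constants_snapshot(path: str | Path) -> None:
    """Write the mass tables to ``path`` as a plain-text provenance record."""
    lines = ["# speclib mass constants (monoisotopic, Da)"]
    lines.append(f"proton\t{PROTON:.5f}")
    lines.append(f"water\t{WATER:.5f}")
    lines.append(f"nh3\t{NH3:.5f}")
    lines.append(f"co\t{CO:.5f}")
    lines.append(f"c13_delta\t{C13_DELTA:.5f}")
    for aa in sorted(RESIDUE_MASS):
        lines.append(f"residue:{aa}\t{RESIDUE_MASS[aa]:.5f}")
    for name in sorted(MODIFICATION_MASS):
        lines.append(f"modification:{name}\t{MODIFICATION_MASS[name]:+.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
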