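"""Spectrum data model, normalization, fragment annotation and quality gates.

A :class:`Spectrum` holds a centroided peak list (ascending m/z, duplicate
m/z merged by intensity sum) plus precursor and provenance information.
Quality gates implemented here are the two used for library admission:

* at least 40% of the fragment ion current must be explained by annotated
  b/y/a ions (with +1 isotopes and H2O/NH3 losses for b/y), annotated at
  0.1 Da fragment tolerance with fragment charges up to the precursor charge;
* the observed precursor mass must lie within 50 ppm of the theoretical
  neutral mass, allowing a one-13C isotope correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import C13_DELTA, CO, NH3, PROTON, RESIDUE_MASS, WATER
from .peptide import PeptideSequence


class InvalidSpectrumError(ValueError):
    """Raised for empty or all-zero-intensity spectra."""


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS peak list with precursor and provenance fields."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    precursor_charge: int
    retention_time: float = 0.0  # minutes
    run_id: str = ""
    dataset_id: str = ""
    scan: int = 0

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("negative peak intensity")
        if mz.size and np.any(mz <= 0):
            raise ValueError("non-positive m/z")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        # sort ascending and merge duplicate m/z by summing intensity
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size:
            uniq, inverse = np.unique(mz, return_inverse=True)
            if uniq.size != mz.size:
                summed = np.zeros(uniq.size)
                np.add.at(summed, inverse, inten)
                mz, inten = uniq, summed
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        self.mz.setflags(write=False)
        self.intensity.setflags(write=False)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def key(self) -> tuple[str, int]:
        return (self.run_id, self.scan)

    @property
    def precursor_neutral_mass(self) -> float:
        return self.precursor_mz * self.precursor_charge - self.precursor_charge * PROTON

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return bool(abs(float(np.dot(self.intensity, self.intensity)) - 1.0) <= tol)


@dataclass(frozen=True)
class PeakAnnotation:
    """One theoretical fragment ion matched to one observed peak."""

    series: str  # "b", "y" or "a"
    index: int  # fragment ordinal, 1-based
    fragment_charge: int
    isotope: int  # 0 or 1
    neutral_loss: str  # "none", "H2O" or "NH3"
    peak_index: int  # index into the spectrum's peak arrays
    theoretical_mz: float

    @property
    def label(self) -> str:
        tag = f"{self.series}{self.index}"
        if self.neutral_loss != "none":
            tag += f"-{self.neutral_loss}"
        if self.isotope:
            tag += "-isotope"
        if self.fragment_charge > 1:
            tag += f"^{self.fragment_charge}"
        return tag


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Rescale peak intensities to unit Euclidean norm. Idempotent."""
    if spectrum.n_peaks == 0:
        raise InvalidSpectrumError("cannot normalize an empty spectrum")
    norm = float(np.linalg.norm(spectrum.intensity))
    if norm == 0.0:
        raise InvalidSpectrumError("cannot normalize an all-zero spectrum")
    return replace(spectrum, intensity=spectrum.intensity / norm)


def _prefix_suffix_masses(peptide: PeptideSequence) -> tuple[np.ndarray, np.ndarray]:
    """Neutral b-fragment (prefix) and y-fragment (suffix) masses, indices 1..n-1."""
    n = len(peptide.residues)
    res = np.array([RESIDUE_MASS[aa] for aa in peptide.residues])
    mod = np.zeros(n)
    for pos, delta in peptide.modifications:
        mod[0 if pos == "N-term" else pos] += delta
    cum = np.cumsum(res + mod)
    prefix = cum[:-1]  # b_i, i = 1..n-1
    suffix = cum[-1] - prefix + WATER  # y_i over suffix lengths n-1..1
    return prefix, suffix[::-1]


def theoretical_fragments(
    peptide: PeptideSequence, max_charge: int
) -> list[tuple[str, int, int, int, str, float]]:
    """All theoretical fragment ions as (series, index, charge, isotope, loss, mz).

    b and y series carry +1-isotope variants and H2O/NH3 neutral losses;
    the a series is plain. Fragment charges run 1..max_charge.
    """
    prefix, suffix = _prefix_suffix_masses(peptide)
    out: list[tuple[str, int, int, int, str, float]] = []
    losses = (("none", 0.0), ("H2O", WATER), ("NH3", NH3))
    for z in range(1, max_charge + 1):
        for i, b_neutral in enumerate(prefix, start=1):
            for loss_name, loss_mass in losses:
                for iso in (0, 1):
                    if iso and loss_name != "none":
                        continue
                    mz = (b_neutral - loss_mass + iso * C13_DELTA + z * PROTON) / z
                    out.append(("b", i, z, iso, loss_name, mz))
            out.append(("a", i, z, 0, "none", (prefix[i - 1] - CO + z * PROTON) / z))
        for i, y_neutral in enumerate(suffix, start=1):
            for loss_name, loss_mass in losses:
                for iso in (0, 1):
                    if iso and loss_name != "none":
                        continue
                    mz = (y_neutral - loss_mass + iso * C13_DELTA + z * PROTON) / z
                    out.append(("y", i, z, iso, loss_name, mz))
    return out


def annotate_peaks(
    spectrum: Spectrum,
    peptide: PeptideSequence,
    precursor_charge: int | None = None,
    fragment_tolerance_da: float = 0.1,
) -> list[PeakAnnotation]:
    """Match theoretical b/y/a ions to observed peaks within a Da tolerance.

    Every theoretical ion within tolerance of an observed peak yields one
    annotation against the nearest such peak; a peak may carry several
    annotations.
    """
    if fragment_tolerance_da <= 0:
        raise ValueError("fragment tolerance must be positive")
    z = precursor_charge if precursor_charge is not None else spectrum.precursor_charge
    if spectrum.n_peaks == 0:
        return []
    annotations: list[PeakAnnotation] = []
    mzs = spectrum.mz
    for series, index, fz, iso, loss, theo_mz in theoretical_fragments(peptide, z):
        j = int(np.searchsorted(mzs, theo_mz))
        best, best_err = -1, fragment_tolerance_da
        for k in (j - 1, j):
            if 0 <= k < mzs.size:
                err = abs(mzs[k] - theo_mz)
                if err <= best_err:
                    best, best_err = k, err
        if best >= 0:
            annotations.append(PeakAnnotation(series, index, fz, iso, loss, best, theo_mz))
    return annotations


def explained_intensity_fraction(
    spectrum: Spectrum, annotations: list[PeakAnnotation]
) -> float:
    """Fraction of total ion current carried by annotated peaks.

    Each peak counts once regardless of how many ions annotate it; the
    value is invariant under global intensity rescaling.
    """
    if spectrum.n_peaks == 0:
        raise InvalidSpectrumError("explained fraction undefined for an empty spectrum")
    total = float(spectrum.intensity.sum())
    if total == 0.0:
        raise InvalidSpectrumError("explained fraction undefined for zero total intensity")
    annotated = {a.peak_index for a in annotations}
    if not annotated:
        return 0.0
    idx = np.fromiter(annotated, dtype=int)
    return float(spectrum.intensity[idx].sum() / total)


def precursor_mass_filter(
    observed_mz: float,
    charge: int,
    peptide: PeptideSequence,
    max_ppm: float = 50.0,
    allow_c13: bool = True,
) -> bool:
    """Keep a precursor whose neutral mass is within ``max_ppm`` of theory.

    With ``allow_c13`` the observed mass may additionally be corrected by
    one 13C isotope spacing before the ppm test, so the accepted set is a
    superset of the strict test.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if max_ppm <= 0:
        raise ValueError("max_ppm must be positive")
    observed = observed_mz * charge - charge * PROTON
    theoretical = peptide.neutral_mass
    isotopes = (0, 1) if allow_c13 else (0,)
    best = min(
        abs(observed - i * C13_DELTA - theoretical) / theoretical * 1e6 for i in isotopes
    )
    return best <= max_ppm


def passes_quality(
    spectrum: Spectrum,
    peptide: PeptideSequence,
    min_explained: float = 0.40,
    max_ppm: float = 50.0,
    fragment_tolerance_da: float = 0.1,
    allow_c13: bool = True,
) -> bool:
    """Combined library-admission gate: explained intensity and precursor mass."""
    if not precursor_mass_filter(
        spectrum.precursor_mz, spectrum.precursor_charge, peptide, max_ppm, allow_c13
    ):
        return False
    ann = annotate_peaks(spectrum, peptide, fragment_tolerance_da=fragment_tolerance_da)
    return explained_intensity_fraction(spectrum, ann) >= min_explained
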