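"""Cosine similarity between spectra, plain and shift-aligned.

Both spectra must be normalized to unit Euclidean norm; the similarity is
the sum of intensity products over a one-to-one matching of peaks within
a Da fragment tolerance. The default matching is greedy by descending
intensity product (the community norm and deterministic); an optimal
maximum-weight matching mode is provided for cross-checks.

The shift-aligned variant additionally admits matches at a precursor mass
delta divided by any fragment charge 1..z, which aligns the y-ion series
of isotopically labelled (e.g. SILAC) peptide pairs. It always uses the
optimal matching, so ``aligned_cosine >= cosine`` holds structurally.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectrum import Spectrum


def _candidate_pairs(
    a: Spectrum, b: Spectrum, shifts: tuple[float, ...], tol: float
) -> list[tuple[int, int, float]]:
    """All (i, j, product) pairs with |mz_a[i] + shift - mz_b[j]| <= tol."""
    pairs: dict[tuple[int, int], float] = {}
    for shift in shifts:
        shifted = a.mz + shift
        lo = np.searchsorted(b.mz, shifted - tol, side="left")
        hi = np.searchsorted(b.mz, shifted + tol, side="right")
        for i in range(a.n_peaks):
            for j in range(int(lo[i]), int(hi[i])):
                prod = float(a.intensity[i] * b.intensity[j])
                key = (i, j)
                if prod > pairs.get(key, -1.0):
                    pairs[key] = prod
    return [(i, j, p) for (i, j), p in pairs.items()]


def _greedy_match(pairs: list[tuple[int, int, float]]) -> float:
    pairs = sorted(pairs, key=lambda t: (-t[2], t[0], t[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    for i, j, prod in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += prod
    return score


def _optimal_match(pairs: list[tuple[int, int, float]]) -> float:
    if not pairs:
        return 0.0
    rows = sorted({i for i, _j, _p in pairs})
    cols = sorted({j for _i, j, _p in pairs})
    ri = {i: r for r, i in enumerate(rows)}
    cj = {j: c for c, j in enumerate(cols)}
    w = np.zeros((len(rows), len(cols)))
    for i, j, p in pairs:
        w[ri[i], cj[j]] = max(w[ri[i], cj[j]], p)
    r, c = linear_sum_assignment(w, maximize=True)
    return float(w[r, c].sum())


def _check_normalized(*spectra: Spectrum) -> None:
    for s in spectra:
        if not s.is_normalized():
            raise ValueError(
                "cosine requires unit-norm spectra; apply normalize_spectrum first"
            )


def cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tolerance_da: float = 0.1,
    mode: str = "greedy",
) -> float:
    """Cosine similarity with one-to-one peak matching within tolerance.

    Symmetric and bounded in [0, 1] for nonnegative unit-norm intensities.
    """
    _check_normalized(a, b)
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0
    pairs = _candidate_pairs(a, b, (0.0,), fragment_tolerance_da)
    score = _optimal_match(pairs) if mode == "optimal" else _greedy_match(pairs)
    return min(score, 1.0)


def aligned_cosine(
    light: Spectrum,
    heavy: Spectrum,
    parent_mass_delta: float,
    fragment_tolerance_da: float = 0.1,
    max_charge: int | None = None,
) -> float:
    """Cosine allowing peak matches at shift 0 or parent_mass_delta / z.

    ``z`` ranges over 1..precursor charge; the optimal one-to-one matching
    over the union of admissible shifts is returned, so the result is never
    below the unshifted cosine.
    """
    _check_normalized(light, heavy)
    if light.n_peaks == 0 or heavy.n_peaks == 0:
        return 0.0
    z_max = max_charge if max_charge is not None else max(light.precursor_charge, 1)
    shifts = (0.0,) + tuple(parent_mass_delta / z for z in range(1, z_max + 1))
    pairs = _candidate_pairs(light, heavy, shifts, fragment_tolerance_da)
    return min(_optimal_match(pairs), 1.0)


def average_pairwise_cosine(
    spectra: list[Spectrum], fragment_tolerance_da: float = 0.1
) -> np.ndarray:
    """Mean cosine of each spectrum to all others; the representative criterion."""
    n = len(spectra)
    if n == 1:
        return np.array([0.0])
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = cosine(spectra[i], spectra[j], fragment_tolerance_da)
            sim[i, j] = sim[j, i] = s
    return sim.sum(axis=1) / (n - 1)
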