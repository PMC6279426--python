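"""Deterministic synthetic data for every pipeline stage.

Everything here is generated from a single integer seed through a
hierarchical pseudo-random stream keyed by (purpose, entity id), so the
content of any entity is independent of how the stream is batched or
ordered — the property the order-invariance tests rely on.

Score model defaults: true matches draw spectral probabilities
log-uniform on [1e-15, 1e-9] and random (false/decoy) matches log-uniform
on [1e-8, 1e-2] — separable but overlapping, so the FDR machinery is
exercised nontrivially. Spectra are synthesized from theoretical singly
charged b/y ions with configurable peak dropout, spurious peaks and
intensity jitter.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .constants import SILAC_DELTA
from .library_fdr import PrecursorRecord, ProteinRecord
from .peptide import PeptideSequence, tryptic_peptides
from .psm import PSM, SearchContext
from .scoring import DECOY_PREFIX, database_p_value
from .spectrum import Spectrum

_AA_NO_KR = "ACDEFGHILMNPQSTVWY"


def rng_for(seed: int, *keys) -> np.random.Generator:
    """A generator keyed by (seed, *keys); stable across runs and platforms."""
    digest = hashlib.sha256(repr((int(seed),) + keys).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


@dataclass
class FixtureConfig:
    """Parameters of the synthetic universe and PSM stream."""

    seed: int = 0
    n_proteins: int = 30
    n_peptides_per_protein: int = 8
    peptide_length_range: tuple[int, int] = (7, 14)
    n_novel_proteins: int = 2
    n_saav_traps: int = 2
    # score model (log10 bounds of the spectral-probability distributions)
    true_log_p_range: tuple[float, float] = (-15.0, -9.0)
    null_log_p_range: tuple[float, float] = (-8.0, -2.0)
    database_size: int = 10_000
    # noise model
    peak_dropout: float = 0.05
    n_spurious_peaks: int = 3
    intensity_jitter: float = 0.10
    # dataset layout
    n_datasets: int = 4
    runs_per_dataset: int = 2
    psms_per_precursor: int = 3
    decoy_precursor_fraction: float = 0.30
    # SILAC
    silac_rt_jitter_min: float = 0.0
    # synthetic pools
    pool_size: int = 100
    n_background_runs: int = 3


@dataclass
class Universe:
    """A synthetic protein universe with decoys, PE levels and planted truth."""

    fasta: dict[str, str]
    pe_levels: dict[str, int]
    target_peptides: list[str]  # tryptic peptides of PE1 proteins
    decoy_peptides: list[str]
    novel_peptides: dict[str, list[str]]  # PE2 accession -> planted peptides
    saav_traps: list[str]  # peptides at Hamming distance 1 from a PE1 window


def _random_tryptic_peptide(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    body = "".join(rng.choice(list(_AA_NO_KR), size=n - 1))
    return body + str(rng.choice(["K", "R"]))


def generate_universe(config: FixtureConfig) -> Universe:
    """Random proteins assembled from tryptic blocks, plus planted features.

    PE2 "novel" proteins carry their own unique peptides; SAAV traps are
    peptides embedded in novel proteins that sit at Hamming distance 1
    from a window of a PE1 protein, so novel-protein calling must reject
    them.
    """
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = config.peptide_length_range
    fasta: dict[str, str] = {}
    pe_levels: dict[str, int] = {}
    target_peptides: list[str] = []
    seen: set[str] = set()
    for i in range(config.n_proteins):
        acc = f"P{i:05d}"
        rng = rng_for(config.seed, "protein", acc)
        peptides = []
        while len(peptides) < config.n_peptides_per_protein:
            pep = _random_tryptic_peptide(rng, lo, hi)
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)
        fasta[acc] = "".join(peptides)
        pe_levels[acc] = 1
        target_peptides.extend(peptides)

    novel: dict[str, list[str]] = {}
    traps: list[str] = []
    pe1_accs = sorted(a for a, lvl in pe_levels.items() if lvl == 1)
    for i in range(config.n_novel_proteins):
        acc = f"N{i:05d}"
        rng = rng_for(config.seed, "novel", acc)
        peptides = []
        while len(peptides) < 4:
            pep = _random_tryptic_peptide(rng, lo, hi)
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)
        trap_peptides = []
        if i < config.n_saav_traps and pe1_accs:
            donor = fasta[pe1_accs[i % len(pe1_accs)]]
            window = donor[: max(lo, 9)]
            pos = int(rng.integers(0, len(window) - 1))
            alphabet = [a for a in _AA_NO_KR if a != window[pos]]
            trap = window[:pos] + str(rng.choice(alphabet)) + window[pos + 1 :]
            trap_peptides.append(trap)
            traps.append(trap)
        fasta[acc] = "".join(peptides + trap_peptides)
        pe_levels[acc] = 2
        novel[acc] = peptides

    decoys = {f"{DECOY_PREFIX}{acc}": seq[::-1] for acc, seq in fasta.items()}
    decoy_peptides: list[str] = []
    for acc in sorted(decoys):
        decoy_peptides.extend(tryptic_peptides(decoys[acc], min_length=lo, max_length=hi + 1))
    decoy_peptides = sorted(set(decoy_peptides) - seen)
    fasta.update(decoys)
    return Universe(fasta, pe_levels, target_peptides, decoy_peptides, novel, traps)


def synthesize_spectrum(
    peptide: PeptideSequence,
    charge: int,
    rng: np.random.Generator,
    run_id: str = "run0",
    dataset_id: str = "D0",
    scan: int = 0,
    retention_time: float = 10.0,
    peak_dropout: float = 0.0,
    n_spurious_peaks: int = 0,
    intensity_jitter: float = 0.0,
    y_shift: float = 0.0,
) -> Spectrum:
    """A theoretical b/y (singly charged) spectrum with configurable noise.

    ``y_shift`` displaces every y-ion peak, emulating an isotopic label on
    the C-terminal residue.
    """
    from .spectrum import theoretical_fragments

    frags = [
        (series, mz)
        for series, _i, z, iso, loss, mz in theoretical_fragments(peptide, 1)
        if z == 1 and iso == 0 and loss == "none" and series in ("b", "y")
    ]
    mzs, intens = [], []
    for series, mz in frags:
        if peak_dropout > 0 and rng.random() < peak_dropout:
            continue
        inten = float(rng.uniform(0.2, 1.0))
        if intensity_jitter > 0:
            inten *= float(1.0 + rng.normal(0.0, intensity_jitter))
            inten = max(inten, 1e-3)
        mzs.append(mz + (y_shift if series == "y" else 0.0))
        intens.append(inten)
    if not mzs:  # degenerate dropout; keep one peak so the spectrum is valid
        mzs, intens = [frags[0][1]], [1.0]
    base = max(intens)
    for _ in range(n_spurious_peaks):
        mzs.append(float(rng.uniform(150.0, 1300.0)))
        intens.append(float(rng.uniform(0.01, 0.06)) * base)
    return Spectrum(
        mz=np.array(mzs),
        intensity=np.array(intens),
        precursor_mz=peptide.mz(charge),
        precursor_charge=charge,
        retention_time=retention_time,
        run_id=run_id,
        dataset_id=dataset_id,
        scan=scan,
    )


@dataclass
class PSMStream:
    """Generated PSMs with their spectra and the planted ground truth."""

    psms: list[PSM]
    spectra: list[Spectrum]
    true_keys: set[tuple[str, int]]
    decoy_keys: set[tuple[str, int]]
    context: SearchContext


def generate_psm_stream(config: FixtureConfig, universe: Universe) -> PSMStream:
    """PSMs for every target peptide plus decoy PSMs, with synthetic spectra.

    True precursors draw spectral probabilities from the true-match model;
    decoy precursors from the random-match model. The stream order is
    deterministic and entity content depends only on (seed, entity id),
    so any batch partition carries identical content.
    """
    psms: list[PSM] = []
    spectra: list[Spectrum] = []
    true_keys: set[tuple[str, int]] = set()
    decoy_keys: set[tuple[str, int]] = set()
    charge = 2
    scan_counter = 0

    n_decoys = int(round(len(universe.target_peptides) * config.decoy_precursor_fraction))
    decoy_slice = universe.decoy_peptides[:n_decoys]
    entries = [(pep, False) for pep in sorted(universe.target_peptides)] + [
        (pep, True) for pep in decoy_slice
    ]
    lo_t, hi_t = config.true_log_p_range
    lo_n, hi_n = config.null_log_p_range
    for pep_seq, is_decoy in entries:
        peptide = PeptideSequence(pep_seq)
        key = (peptide.canonical(), charge)
        (decoy_keys if is_decoy else true_keys).add(key)
        rt = float(rng_for(config.seed, "rt", pep_seq).uniform(5.0, 95.0))
        for k in range(config.psms_per_precursor):
            rng = rng_for(config.seed, "psm", pep_seq, is_decoy, k)
            dataset = f"D{int(rng.integers(0, config.n_datasets))}"
            run = f"{dataset}_r{int(rng.integers(0, config.runs_per_dataset))}"
            scan_counter += 1
            scan = scan_counter
            log_p = rng.uniform(lo_n, hi_n) if is_decoy else rng.uniform(lo_t, hi_t)
            sp = float(10.0 ** log_p)
            spectrum = synthesize_spectrum(
                peptide,
                charge,
                rng_for(config.seed, "spectrum", pep_seq, is_decoy, k),
                run_id=run,
                dataset_id=dataset,
                scan=scan,
                retention_time=rt + float(rng.normal(0.0, 0.05)),
                peak_dropout=config.peak_dropout,
                n_spurious_peaks=config.n_spurious_peaks,
                intensity_jitter=config.intensity_jitter,
            )
            spectra.append(spectrum)
            psms.append(
                PSM(
                    run_id=run,
                    scan=scan,
                    dataset_id=dataset,
                    search_id=f"search_{dataset}",
                    peptide=peptide.canonical(),
                    charge=charge,
                    spectral_probability=sp,
                    database_p_value=database_p_value(sp, config.database_size),
                    is_decoy=is_decoy,
                    retention_time=spectrum.retention_time,
                )
            )
    context = SearchContext("search_all", "proteome", config.database_size)
    return PSMStream(psms, spectra, true_keys, decoy_keys, context)


def generate_silac_pairs(
    config: FixtureConfig,
    universe: Universe,
    n_pairs: int = 20,
    n_discordant_rt: int = 0,
    n_discordant_fragmentation: int = 0,
) -> tuple[list[PSM], list[PSM], list[Spectrum], int]:
    """Light/heavy PSM+spectrum pairs with a known number of concordant ones.

    Heavy spectra shift every y ion by the label delta of the terminal
    residue (+8.0142 for K, +10.0083 for R). Discordant pairs are planted
    either by a 2-minute retention-time offset or by re-randomised
    fragmentation (an unrelated peak pattern). Returns (light PSMs, heavy
    PSMs, spectra, number of planted concordant pairs).
    """
    eligible = [p for p in sorted(universe.target_peptides) if p[-1] in SILAC_DELTA]
    eligible = eligible[:n_pairs]
    lights: list[PSM] = []
    heavies: list[PSM] = []
    spectra: list[Spectrum] = []
    charge = 2
    lo_t, hi_t = config.true_log_p_range
    for i, pep_seq in enumerate(eligible):
        light_pep = PeptideSequence(pep_seq)
        delta = SILAC_DELTA[pep_seq[-1]]
        heavy_pep = PeptideSequence(pep_seq, ((len(pep_seq) - 1, delta),))
        rng = rng_for(config.seed, "silac", pep_seq)
        rt = float(rng.uniform(5.0, 95.0))
        discordant_rt = i < n_discordant_rt
        discordant_frag = n_discordant_rt <= i < n_discordant_rt + n_discordant_fragmentation
        heavy_rt = rt + (2.0 if discordant_rt else config.silac_rt_jitter_min)
        light_spec = synthesize_spectrum(
            light_pep, charge, rng_for(config.seed, "silac-light", pep_seq),
            run_id="silac_run", dataset_id="SILAC", scan=2 * i + 1, retention_time=rt,
        )
        if discordant_frag:
            heavy_spec = synthesize_spectrum(
                heavy_pep, charge, rng_for(config.seed, "silac-heavy-bad", pep_seq),
                run_id="silac_run", dataset_id="SILAC", scan=2 * i + 2,
                retention_time=heavy_rt, peak_dropout=0.85, n_spurious_peaks=30,
            )
        else:
            # heavy spectrum mirrors the light fragmentation with shifted y ions
            heavy_spec = synthesize_spectrum(
                light_pep, charge, rng_for(config.seed, "silac-light", pep_seq),
                run_id="silac_run", dataset_id="SILAC", scan=2 * i + 2,
                retention_time=heavy_rt, y_shift=delta,
            )
            heavy_spec = Spectrum(
                mz=heavy_spec.mz, intensity=heavy_spec.intensity,
                precursor_mz=heavy_pep.mz(charge), precursor_charge=charge,
                retention_time=heavy_rt, run_id="silac_run", dataset_id="SILAC",
                scan=2 * i + 2,
            )
        spectra.extend([light_spec, heavy_spec])
        for psm_list, pep, spec in (
            (lights, light_pep, light_spec),
            (heavies, heavy_pep, heavy_spec),
        ):
            sp = float(10.0 ** rng.uniform(lo_t, hi_t))
            psm_list.append(
                PSM(
                    run_id=spec.run_id, scan=spec.scan, dataset_id="SILAC",
                    search_id="silac_search", peptide=pep.canonical(), charge=charge,
                    spectral_probability=sp,
                    database_p_value=database_p_value(sp, config.database_size),
                    is_decoy=False, retention_time=spec.retention_time,
                )
            )
    n_concordant = len(eligible) - n_discordant_rt - n_discordant_fragmentation
    return lights, heavies, spectra, n_concordant


@dataclass
class PoolFixture:
    """A synthetic-pool search layout with planted decoy PSMs."""

    psms: list[PSM]
    context: SearchContext
    pool_target_peptides: set[str]
    background_pool_peptides: dict[str, set[str]]


def generate_pool_fixture(
    config: FixtureConfig,
    n_target_peptides: int | None = None,
    n_background_runs: int | None = None,
) -> PoolFixture:
    """A synthetic-pool search: main-run target/decoy PSMs plus background runs.

    Decoy PSMs (main-run decoy matches and background-run matches) are
    interleaved across the score range; a few background peptides also
    occur in the target pool and must be excluded from decoy counting.
    """
    n_pool = n_target_peptides or config.pool_size
    n_bg = n_background_runs or config.n_background_runs
    rng = rng_for(config.seed, "pool")
    lo, hi = config.peptide_length_range
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < n_pool:
        pep = _random_tryptic_peptide(rng, lo, hi)
        if pep not in seen:
            seen.add(pep)
            pool.append(pep)
    background_runs = [f"bg{j}" for j in range(n_bg)]
    background_pools: dict[str, set[str]] = {}
    for run in background_runs:
        bg_rng = rng_for(config.seed, "pool-bg", run)
        bg: set[str] = set()
        while len(bg) < max(5, n_pool // 10):
            pep = _random_tryptic_peptide(bg_rng, lo, hi)
            if pep not in seen or pep in pool:
                bg.add(pep)
        # plant overlap with the target pool (excluded-from-decoy cases)
        overlap = [pool[int(bg_rng.integers(0, n_pool))] for _ in range(2)]
        bg.update(overlap)
        background_pools[run] = bg

    lo_t, hi_t = config.true_log_p_range
    lo_n, hi_n = config.null_log_p_range
    psms: list[PSM] = []
    scan = 0

    def make_psm(run, pep_seq, is_decoy, log_p):
        nonlocal scan
        scan += 1
        sp = float(10.0 ** log_p)
        return PSM(
            run_id=run, scan=scan, dataset_id="POOL", search_id="pool_search",
            peptide=PeptideSequence(pep_seq).canonical(), charge=2,
            spectral_probability=sp,
            database_p_value=database_p_value(sp, max(2 * n_pool, 2)),
            is_decoy=is_decoy, retention_time=float(rng.uniform(5.0, 60.0)),
        )

    for i, pep in enumerate(pool):
        prng = rng_for(config.seed, "pool-psm", pep)
        psms.append(make_psm("main", pep, False, float(prng.uniform(lo_t, hi_t))))
        # interleave decoy-database matches across the whole score range
        if i % 4 == 0:
            psms.append(
                make_psm("main", pep[::-1], True, float(prng.uniform(lo_t, hi_n)))
            )
    for run in background_runs:
        for pep in sorted(background_pools[run]):
            brng = rng_for(config.seed, "pool-bgpsm", run, pep)
            psms.append(make_psm(run, pep, False, float(brng.uniform(lo_n, hi_n))))

    context = SearchContext(
        "pool_search", "synthetic_pool", max(2 * n_pool, 2),
        frozenset(background_runs),
    )
    return PoolFixture(psms, context, set(pool), background_pools)


# ---------------------------------------------------------------------------
# Null-model simulations for error-rate calibration

def null_precursor_simulation(
    seed: int,
    n_records: int = 20_000,
    decoy_fraction: float = 0.5,
    true_target_fraction: float = 0.5,
    length_range: tuple[int, int] = (8, 25),
    true_log_p_range: tuple[float, float] = (-15.0, -9.0),
    null_log_p_range: tuple[float, float] = (-8.0, -2.0),
) -> tuple[list[PrecursorRecord], set[tuple[str, int]]]:
    """Precursor records where decoys and false targets share a null score
    distribution and a planted fraction of targets scores from the true model.

    Returns the records and the set of planted-true precursor keys.
    """
    rng = rng_for(seed, "null-precursors")
    records: list[PrecursorRecord] = []
    true_keys: set[tuple[str, int]] = set()
    lo_t, hi_t = true_log_p_range
    lo_n, hi_n = null_log_p_range
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _i in range(n_records):
        is_decoy = bool(rng.random() < decoy_fraction)
        is_true = (not is_decoy) and bool(rng.random() < true_target_fraction)
        log_p = rng.uniform(lo_t, hi_t) if is_true else rng.uniform(lo_n, hi_n)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        peptide = "".join(rng.choice(alphabet, size=length))
        rec = PrecursorRecord(peptide, 2, float(10.0 ** log_p), is_decoy)
        records.append(rec)
        if is_true:
            true_keys.add(rec.key)
    return records, true_keys


def protein_fdr_simulation(
    seed: int,
    n_pairs: int = 500,
    true_protein_fraction: float = 0.5,
    precursors_per_protein: tuple[int, int] = (2, 10),
    true_log_p_range: tuple[float, float] = (-15.0, -9.0),
    null_log_p_range: tuple[float, float] = (-8.0, -2.0),
) -> tuple[list[ProteinRecord], set[str]]:
    """Target/decoy protein pairs with planted true and false targets.

    True targets accumulate unique precursors from the true score model;
    false targets and every decoy from the null model. Returns the scored
    protein records and the set of planted-false target accessions.
    """
    import math

    rng = rng_for(seed, "null-proteins")
    lo_t, hi_t = true_log_p_range
    lo_n, hi_n = null_log_p_range
    lo_k, hi_k = precursors_per_protein
    proteins: list[ProteinRecord] = []
    false_targets: set[str] = set()
    for i in range(n_pairs):
        acc = f"SIM{i:05d}"
        is_true = bool(rng.random() < true_protein_fraction)
        if not is_true:
            false_targets.add(acc)
        for decoy in (False, True):
            k = int(rng.integers(lo_k, hi_k + 1))
            use_true = is_true and not decoy
            lo, hi = (lo_t, hi_t) if use_true else (lo_n, hi_n)
            score = 0.0
            keys = []
            for j in range(k):
                p = float(10.0 ** rng.uniform(lo, hi))
                score += -math.log10(p)
                keys.append((f"{acc}_pep{j}", 2))
            name = f"{DECOY_PREFIX}{acc}" if decoy else acc
            proteins.append(ProteinRecord(name, decoy, score, keys))
    return proteins, false_targets
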