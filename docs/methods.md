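# Methods

This note records the models, conventions and open design choices behind
`speclib`, in the spirit of the methods documentation of mature
scientific packages: enough detail that every number the package
produces can be traced to a stated rule.

## Scoring model

The pipeline consumes spectral probabilities P(S|T) produced by an
upstream database search engine; it never computes them. The
search-space-aware score is the database p-value

    p_db = 1 − (1 − P(S|T))^N

with N the number of candidate peptides eligible to match the spectrum.
It is evaluated as `-expm1(N * log1p(-p))`, which preserves relative
precision down to p ≈ 1e−300 (verified against 60-digit decimal
arithmetic in the tests). The score is strictly increasing in both p and
N and equals p at N = 1.

For proteome-limited samples (affinity purification), the effective
search space is re-derived per search: a protein group becomes eligible
for the reduced space when at least two distinct peptide sequences map,
pooled, to the target protein or its reversed decoy at the peptide-level
FDR (1% default; peptide score = best PSM p-value per distinct bare
sequence, decoys inside the accepted prefix count toward eligibility).
PSMs of eligible groups are rescored at the reduced N — by convention
the number of distinct fully tryptic peptides (≤1 missed cleavage,
length 6–40) in the eligible-protein subset, mirroring typical search
settings — and everything is re-filtered at 1% PSM FDR. Singleton
proteins keep their original scores, so no PSM can promote itself.

Synthetic peptide-pool searches use an empirical zero-decoy rule
instead: a decoy PSM is either a main-pool match to the decoy database
or any background-run match, except background-run matches to peptides
both synthesized in that run's pool and present in the target pool,
which are dropped from the analysis entirely (they may be genuine). Per
peptide length the threshold sits strictly below the best-scoring decoy,
so the accepted set contains no decoys by construction.

## Spectrum processing

* Peak lists are stored sorted by m/z with duplicate m/z merged by
  intensity sum at construction, so one-to-one peak matching is well
  defined.
* Intensities are rescaled to unit Euclidean norm before any similarity
  computation (idempotent; raw intensities, not square-rooted — the
  field uses both and this package documents its choice here).
* Fragment annotation enumerates b, y (each with +1-isotope variants
  and H2O/NH3 neutral losses) and plain a ions, at fragment charges
  1..precursor charge, within a 0.1 Da tolerance. Each theoretical ion
  annotates its nearest in-tolerance peak; a peak may carry several
  annotations but its intensity counts once in the explained fraction.
* Quality gates for library admission: ≥40% of total ion current
  explained by annotated peaks, and precursor neutral mass within
  50 ppm of theory, allowing a single-13C correction (1.00335 Da).
  Neutral mass convention: `m = mz·z − z·proton`; all ppm arithmetic is
  on neutral masses.
* Monoisotopic residue masses and physical constants are fixed to five
  decimals in `speclib.constants` and written next to every exported
  library (`constants.txt`) for provenance.

## Similarity

Cosine similarity is the sum of intensity products over a one-to-one
matching of peaks within the fragment tolerance (0.1 Da everywhere, for
internal consistency). The default matching is greedy by descending
intensity product with deterministic tie-breaks; an optimal
maximum-weight assignment mode exists and is used as the oracle in
tests. The shift-aligned cosine for isotopically labelled pairs admits
matches at shift 0 or parent-mass-delta/z for z = 1..precursor charge
and always uses the optimal assignment — this makes
`aligned_cosine ≥ cosine` a structural guarantee (greedy ≤ optimal on a
subset of admissible pairs).

## Library-level error control

Each precursor (canonical peptide string + charge) is scored by its best
PSM. Within each peptide-length bin, records are ranked by increasing
p-value and the local FDR at a record is the decoy/target ratio over a
window of 500 records. Two window readings exist in the field; the
default here is the *trailing* window (the record itself plus its up-to
499 better-scoring neighbours, the record counting in its own ratio),
with `window_mode="centered"` implementing the symmetric alternative.
Bins smaller than the window use the whole bin. The per-bin threshold is
the highest p-value whose window ratio is strictly below the nominal
level; acceptance at `p ≤ T` makes the accepted set a p-value prefix of
each bin.

Site-localization variants (same bare sequence, same multiset of
modification deltas at 3-decimal precision, same charge) collapse to the
best-scoring member. Peptides map to proteins by exact substring search
(I/L distinct by default; an I=L mode exists); precursors hitting more
than one accession are shared and excluded from protein scoring but
still count for precursor retention. Protein scores are
`Σ −log10(p_db)` over uniquely mapped precursors, exactly base 10. The
picked protein FDR lets each target compete only against its own
reversed decoy (ties go to the target; unpaired accessions compete
alone), ranks the winners by decreasing score and accepts the largest
prefix with decoy/target ≤ 1%. Decoy proteins inside the prefix are kept
so decoy precursors survive into the library, where they support
downstream error estimation; the exported decoy-entry count equals the
decoy precursors surviving the FDR stages.

The *naive aggregate FDR* — the decoy/target ratio of the full
unfiltered ledger — is reported with every build as the error rate a
naive merge would have carried.

## Candidate maintenance and order invariance

For every precursor ever observed (decoys and sub-threshold precursors
included) the state keeps (a) the best PSM in a ledger and (b) for each
contributing dataset the best ≤20 PSMs, under the single total order
(p-value, targets before decoys, run id, scan). The 100-candidate view
applies the per-dataset cap first, then the global cap, both prefix
operations under the total order; duplicate PSM identities are dropped
on merge. Merging is therefore associative, commutative and idempotent,
and a build after any batch permutation exports a byte-identical library
(canonical entry order by (peptide, charge), fixed float precision in
the writers). Representative selection recomputes pairwise cosines at
build time rather than caching across builds.

The ambiguity filter consumes a re-annotation table (up to 20
alternative peptide explanations per representative spectrum from an
external re-search): alternatives passing the 1% threshold of the
entry's original search are collapsed over localization variants, and
entries with two or more surviving distinct explanations are removed.
Entries missing from the table are retained and logged. How the
original-search threshold should interact with synthetic-pool 0%
thresholds is not specified anywhere we know of; the original-search
table is applied as given.

## Downstream analyses

* **Proteotypic selection** is greedy set-cover over the searches in
  which a protein was called (by unique peptides, at the library's
  per-length minimum score): repeatedly take the precursor covering the
  most uncovered searches (ties: lowest best p-value, then precursor
  order) until 90% coverage or 20 precursors; every pick strictly
  increases coverage. On instances small enough for exhaustive search
  the tests verify the classic (1 − 1/e) greedy guarantee.
* **Interaction detectability**: proteins co-observed in one pulldown
  are a candidate pair; the pair stays detectable if each member has a
  proteotypic precursor among that search's accepted precursors.
  Shared-peptide protein inference is deliberately not modeled.
* **Novel-protein calling**: candidate peptides must have length ≥9 and
  must not match any PE1 protein window within Hamming distance ≤1 (the
  single-amino-acid-variant exclusion; modification deltas are ignored,
  I/L folding follows the global mode). A PE2–PE5 protein is called when
  a maximum disjoint set of its supporting peptide spans (end-exclusive
  coordinate intervals; touching intervals count as disjoint) has size
  ≥2. Unannotated accessions are conservatively treated as PE1.
* **SILAC gold standard**: light/heavy PSMs pair on identical sequence,
  charge and non-label modifications (+8.0142 K / +10.0083 R labels at
  the canonical 3-decimal precision); concordance requires aligned
  cosine > 0.6, explained intensity > 0.5 in both spectra and retention
  times within 1 minute. The light member with the best p-value
  represents each precursor; output is independent of input order.

## Synthetic data

The generator exists so that every stage is testable offline. Proteins
are concatenations of random tryptic blocks (7–14 residues ending K/R);
decoys are whole-protein reversals with the `XXX_` accession prefix.
Planted features include PE2 proteins with unique novel peptides and
SAAV traps (a PE1 window with one substitution embedded in a PE2
protein). Spectra are theoretical singly charged b/y ladders with
uniform intensities and configurable peak dropout (default 5%), spurious
peaks (3 per spectrum at ≤6% of base intensity) and intensity jitter
(10%), chosen so that clean spectra comfortably pass the 40% explained
gate while noise is non-trivial. Scores follow the two-component model:
true matches log-uniform on [1e−15, 1e−9], random matches log-uniform on
[1e−8, 1e−2] — separable but overlapping. All randomness flows through a
single hierarchical stream keyed by (seed, purpose, entity id), so
entity content is independent of batching and regeneration is
byte-identical.

What the generator does **not** emulate: real instrument noise shapes,
isotope envelopes, co-eluting chimeras, retention-time structure beyond
a per-peptide draw, and charge-state heterogeneity (fixtures use 2+
precursors with 1+ fragments). Passing tests therefore demonstrate the
*procedural* guarantees (calibration of the error controls, exactness of
caps and gates, order invariance) rather than identification performance
on real spectra.

## Calibration conditions

The error-control measurements use null-dominated mixtures chosen once:
20,000 precursor records per seed with half decoys and half of the
targets planted true (local FDR, 10 seeds); 500 target/decoy protein
pairs per seed with half the targets true and 2–10 unique precursors per
protein (picked FDR, 10 seeds); a 1,000-peptide pool with 10 background
runs and decoys planted across the whole score range (synthetic-pool
filter). The gate boundaries are scanned at every integer operating
point (explained intensity 0–100%, precursor deviation 0–100 ppm, the
latter constructed as negative deviations so the 13C correction cannot
rescue them). These sizes keep every measurement within seconds on one
CPU while leaving binomial standard errors well below the 1% levels
being verified.

## Known limitations

* Protein mapping is a plain substring scan per peptide with
  memoization — adequate at fixture scale, not indexed for
  proteome-scale FASTA files.
* The ambiguity re-search itself is externalized; the package only
  implements the filtering logic over a supplied annotation table.
* mzML reading is not implemented; peak lists enter via MGF (the reader
  contract would admit an mzML backend).
* No q-value monotonization beyond the stated local-FDR procedure, no
  Bayesian local FDR, no spectral-library search.
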