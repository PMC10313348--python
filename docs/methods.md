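# Methods

## Index model

The engine maintains two structures over a spectral library.

The **precursor index** assigns each library spectrum a dense 32-bit id
in stream order and ranks ids by (charge, precursor m/z), ties broken by
id for determinism. The inverse permutation `rank_of` is precomputed by
a linear scan, so a fragment's parent id resolves to its rank in O(1).
Candidate selection for a query at precursor tolerance ±tol is a binary
search inside the query's charge block, yielding a half-open rank
window; an unknown-charge query (charge 0 in MGF) is searched in every
charge block with the same m/z window.

The **fragment index** stores each in-range library peak as a triplet
*(m/z, intensity, parent id)* in the bin `floor(mz / B)` under the
half-open convention `[bB, (b+1)B)`. Intensities are stored
*post-preprocessing* (square root, unit Euclidean norm), so search
accumulation is a pure multiply-add and the accumulator of a candidate
equals its binned spectral dot product with the query. Within a bin,
triplets are sorted by parent rank, so the candidates of one precursor
window always form a contiguous run located by binary search; the run
is contributed with one vectorized multiply-add (`np.add.at` over the
run), the software contract standing in for hardware fused
multiply-add.

**Partitioning.** The fragment index is split into partitions tied to
non-overlapping precursor m/z intervals; each partition carries the
full bin range and is a complete fragment index for its slice. The
split rule is equal-count (quantile) rather than equal-width, so
partitions stay balanced regardless of how precursor masses are
distributed; degenerate inputs (fewer distinct m/z values than
requested partitions) collapse to fewer partitions with a warning.
Partitions are defined on precursor m/z only; charge separation lives
inside the precursor index ordering.

**Two-phase construction.** The library is streamed exactly once. Phase
1 preprocesses each spectrum and appends provisional triplets (bin,
m/z, intensity, parent id) to per-partition spill files, flushing
buffers whenever the total buffered triplet count exceeds a fixed
budget (32768); phase 2 builds the precursor index, then rewrites one
partition at a time with entries sorted by (bin, parent rank).
Provisional ids are remapped by full rewrite of each spill file rather
than in-place patching — simpler and crash-safe. Peak triplet memory is
therefore bounded by max(spill budget, largest partition), never by
library size; the build returns this high-water mark so the bound is
testable. On disk, a partition is a little-endian record file (float32
m/z, float32 intensity, uint32 parent id) plus an int64 bin-offset
file; a JSON manifest carries the configuration, boundaries, counts and
SHA-256 checksums, verified at load.

## Search

Queries are scheduled to every partition whose interval intersects
their tolerance window (a query on a boundary goes to both
neighbours). Per partition and query, the accumulator over the
candidate window is filled peak by peak — each query peak visits only
its own bin; intensity spread over neighbouring bins is deliberately
not done at index time, because the Gaussian rescoring recovers
cross-bin matches. The top `n_rescore` accumulator candidates (default
50 per query and partition, comfortably above the reported `top_x`) are
rescored with the full score vector; results from all partitions merge
per query, keeping the best-scoring instance of a library id, ordered
by final score with deterministic tie-breaks (higher shared peak count,
then lower library id). Queries with no candidate anywhere are reported
as explicit marker rows, never dropped. Execution is serial; a
`--threads` flag is accepted as a hint for interface parity but results
are by construction independent of it.

## Scoring

With both spectra preprocessed (square-rooted, unit-norm — applied
exactly once; the transform is not idempotent), the similarity is

    similarity(Q,R) = Σ_k max_l I_l I_k φ(mz_l, mz_k),
    φ(x,μ) = exp(−½((x−μ)/σ)²),

σ modeling the fragment tolerance (default: the bin width, 0.2 Da).
φ is truncated to exactly 0 beyond 5σ; the discarded contributions are
below 4·10⁻⁶, which keeps the sorted-merge evaluation (binary-searched
candidate windows per reference peak, segment maxima via `reduceat`)
equal to the quadratic double loop to well under 10⁻⁹ while bounding
work. The dot bias is Σt²/Σt over the per-reference-peak terms; when
the similarity is 0 the bias is defined as 1 (the formula is 0/0
there), making the bias-adjusted similarity 0. The literal max-per-k
form is used; no one-to-one pairing is enforced.

The reflection variant removes query peaks with no reference peak
within the truncation radius, renormalizes the survivors to unit norm
(so a clean sub-spectrum of its prediction scores 1.0), and reapplies
the same formulas — bias included — on the renormalized intensities.
The final score is the arithmetic mean of the plain and reflection
bias-adjusted similarities.

Auxiliary features: the binned dot product (recomputed identically for
index and oracle paths), an X!Tandem-style log-hyperscore
`ln(N_b!) + ln(N_y!) + ln(1 + Σ matched I_l I_k)` with unlabeled
matched peaks counted in one extra factorial series, a SpectraST-style
f-value `0.6·dot₁ − 0.4·(dot₁ − dot₂)` (runner-up dot 0 when absent),
the final-score delta to the next-ranked hit (0 for a lone candidate),
shared peak count, standard deviation of matched-fragment m/z
differences, absolute precursor m/z difference, and peptide length.
The hyperscore and f-value forms are not uniquely determined by their
provenance; they are emitted as rescoring features only, so the primary
results are insensitive to the exact choice. Ion labels are not stored
in the on-disk index, so hyperscores from indexed search count all
matched reference peaks in a single series; label-aware values require
the oracle path or library access. All other scores are
label-independent.

## Numerical equivalence of index and oracle

The exhaustive oracle (`oracle_search`) scores every in-tolerance
candidate with no index. To make score agreement at 10⁻⁶ meaningful
despite the index's float32 storage, the oracle scores against the same
canonical *stored view* of each library spectrum — preprocessed,
restricted to the indexed m/z range, quantized to float32 — while
sharing nothing with the indexed search path beyond the scoring module.
On the default fixture the two paths agree on every rank-1 id with zero
measured score difference. The equivalence holds whenever `n_rescore`
covers the candidate window; a smaller `n_rescore` can in principle
drop a borderline candidate that refined scoring would have promoted.

## Target-decoy and entrapment FDR

Target and decoy libraries are searched separately and merged per query
keeping the higher-scoring rank-1 hit; exact ties go to the target and
are counted. FDR(t) = N_decoy(t)/N_target(t) as printed, without the +1
correction (available behind a flag); q-values are the monotonized
minimum FDR over all thresholds at or below a PSM's score and lie in
[0, 1]. A target winner is an entrapment hit when its peptide occurs in
the entrapment set and not among true-target peptides;
FDR_trap = N_trap/N_target · R with R the target/entrapment
peptide-count ratio. Ground-truth FDR (synthetic runs) compares the
winner's peptide to the generating peptide by exact string match (I/L
distinct); FDR is computed at PSM level.

## Synthetic data generator

The generator defines the standard test conditions: random proteomes
(20-letter alphabet, K/R-enriched composition so tryptic products
average ~10 residues), trypsin digestion cleaving after K/R except
before P with up to two missed cleavages, peptide length 7–30, charges
2–4, precursor m/z confined to 400–1500, fixed cysteine
carbamidomethylation (+57.02146 Da). Reference spectra carry only
b/y-ion peaks (singly charged; doubly charged series added for
precursor charge ≥ 3) with monoisotopic masses from standard residue
masses; intensities follow a smooth position-dependent bell modulated
per ion by a hash of (peptide, charge), so patterns are distinct but
byte-reproducible independent of the session seed. Decoys are
pseudo-reversed (C-terminal residue fixed), collisions reshuffled
deterministically, irreducible cases dropped with a warning — decoys
thereby share their target's precursor m/z, giving every query a decoy
competitor.

The default fixture is a 2000-spectrum target library — 1500
sample-true plus 500 entrapment spectra from a disjoint second proteome
— with decoys for both, and 500 queries drawn from sample-true spectra
only. Query noise defaults: fragment m/z jitter SD 0.02 Da, lognormal
intensity noise CV 0.2, peak dropout 0.1, 5 uniform contaminant peaks,
precursor jitter within ±5 ppm — chosen so rank-1 recovery is high but
not saturated, leaving the FDR machinery real discrimination work. A
10% share of queries is *foreign*: generated from held-out peptides
absent from the library, with the precursor m/z planted on a random
same-charge library entry. Without the planting, a random foreign
peptide would almost never draw an in-tolerance candidate at 10 ppm and
false matches could not occur at all; with it, foreign queries present
genuine decoy-like score distributions to the competition.

What the generator does **not** emulate: learned fragment-intensity
profiles, retention time, isotope patterns, chimeric spectra, or
homologous sequences. Passing tests therefore demonstrate the
correctness and internal calibration of the indexing, scoring and FDR
machinery under controlled conditions — not identification performance
on real instrument data, where score distributions are broader and
entrapment/decoy statistics are driven by sequence homology.

## Problem sizes and defaults

The test suite and the acceptance script use the default fixture (2000
target + 2000 decoy spectra, 500 queries) for end-to-end properties,
with FDR calibration repeated across ten seeds in the suite and three
derived seeds in the acceptance script; scoring equivalences use 300 /
1000 random spectrum pairs. Engine defaults: bin width 0.2 Da, 64
partitions (4 in tests, where partition invariance is verified
explicitly against 1 and 64), 10 ppm precursor tolerance, σ = bin
width, 5σ truncation, `top_x` 1, `n_rescore` 50. Indexed fragment
range [0, 2000) Da; out-of-range fragments are dropped and counted.

## Known limitations

- MGF/MSP only; mzML/mzXML, charge deconvolution and profile-mode
  centroiding are out of scope.
- No open/mass-offset search; the precursor tolerance is applied on
  m/z, not neutral mass.
- Memory-mapped partition loading and an index-resident server mode are
  not implemented.
- Percolator itself is not run; only its input file is produced.
  Retention-time feature columns are provisioned but no RT prediction
  is bundled.
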