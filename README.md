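# specidx

A partitioned fragment-ion index and search engine for peptide spectral
libraries.

## The problem

Spectral library search identifies peptides by comparing experimental
MS/MS spectra against reference spectra (measured consensus spectra or
machine-learned predictions) rather than against theoretical fragment
masses alone. For large search spaces — metaproteomes, proteogenomics —
libraries easily reach tens of millions of spectra, and the classic
approach of scoring each query against every in-tolerance candidate one
pair at a time becomes both slow and memory-bound.

`specidx` addresses this with an *intensity-aware fragment-ion index*:
every library peak is stored as a triplet *(m/z, intensity, parent id)*
inside fragment m/z bins of width *B*, ordered within each bin by the
parent's rank in a precursor index sorted by (charge, precursor m/z).
Matching one query peak against *all* candidate spectra then reduces to
one bin lookup, one binary search for the candidate rank range, and one
batched multiply-add of intensity products — the binned spectral dot
product of every candidate accumulates simultaneously. The fragment
index is further split into partitions tied to non-overlapping precursor
m/z intervals, each independently loadable from disk, so peak memory is
bounded by the largest partition rather than the library.

## Scoring

Spectra are preprocessed once: intensities are square-rooted (to
de-emphasize dominant peaks) and scaled to unit Euclidean norm. Top
accumulator candidates are then rescored with a similarity that resolves
the m/z dimension with a Gaussian instead of fixed bins:

    similarity(Q, R) = Σ_k max_l  I_l · I_k · φ(mz_l, mz_k)
    φ(x, μ)          = exp( −½ ((x − μ)/σ)² )

with *k* over reference peaks, *l* over query peaks, and σ (the modeled
fragment tolerance) equal to the bin width by default. The *dot bias*

    bias(Q, R) = Σ_k t_k² / Σ_k t_k ,   t_k = max_l I_l I_k φ(mz_l, mz_k)

flags matches carried by few peak pairs, giving the *bias-adjusted
similarity* `similarity · (1 − bias)`. Because predicted libraries
contain only b/y ions, a *reflection* variant first discards query peaks
with no reference peak nearby, renormalizes the survivors, and applies
the same formulas. The ranking score is the mean of the two
bias-adjusted similarities. Auxiliary features (binned dot product,
log-hyperscore, SpectraST-style f-value, delta scores, shared peak
count, matched-m/z spread, precursor mass difference, peptide length)
are exported for downstream rescoring.

Error control follows separate target/decoy searches: per query the
best hit from either library survives (*target-decoy competition*), and
`FDR(t) = N_decoy(t) / N_target(t)` with monotonized q-values. An
entrapment estimate `FDR_trap(t) = N_trap(t) / N_target(t) · R` (with
*R* the target/entrapment peptide-count ratio) provides an orthogonal
check, and a Percolator-compatible pin-tab file carries all features.

## Worked example

Everything below runs from a bundled synthetic fixture generator (toy
tryptic peptides, deterministic b/y-ion spectra, pseudo-reversed decoys,
noisy queries with ground truth) — no downloads needed:

```sh
specidx fixtures --seed 1 --out fx --n-library 500 --n-queries 100
specidx build  --library fx/target.msp --out target_index --partitions 8
specidx build  --library fx/decoy.msp  --out decoy_index  --partitions 8
specidx search --index target_index --queries fx/queries.mgf \
               --out targets.tsv --pin targets.pin
specidx search --index decoy_index  --queries fx/queries.mgf --out decoys.tsv
specidx validate --targets targets.tsv --decoys decoys.tsv \
                 --out fdr.tsv --truth fx/truth.tsv
```

`targets.tsv` holds one row per PSM with the full score vector:

```
query_id  title   library_id  peptide                       is_decoy  rank  final_score  bias_adjusted  reflection_bias_adjusted
0         Q00000  136         QQLTKSKSSTEGGAAFIK            0         1     0.89373127   0.882523555    0.904938986
1         Q00001  18          FYSTPFLWSTESLIRTR             0         1     0.891910288  0.885202335    0.89861824
2         Q00002  291         IEFFDTNGKGLGAGNIAVELNALTRQER  0         1     0.765658141  0.715871132    0.81544515
```

`final_score` is the mean of the bias-adjusted similarity and its
reflection variant; a noisy-but-correct match typically scores 0.6–0.9
while a random in-tolerance candidate stays below ~0.2. `fdr.tsv`
sweeps every score threshold:

```
threshold    n_target  n_decoy  fdr  q
0.650721254  94        0        0    0
```

Here 94 of 100 queries are accepted at q ≤ 0.01 with no decoy above the
threshold; the `.true` companion file (written when `--truth` is given)
confirms against the generator's ground truth. `targets.pin` is ready
for `percolator --post-processing-tdc`.

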