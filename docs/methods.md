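# Methods

This note records how `mirfeat` defines its quantities, the defaults that
matter, what the synthetic generator does and does not emulate, and the
design decisions taken where conventions in the field diverge.

## Structure model

Secondary structures are pseudoknot-free pair tables (1-based, Vienna
convention). A **stem** is a maximal run of stacked pairs with no
intervening unpaired base, minimum one pair — this keeps the average
pairs-per-stem feature well defined and matches the helix decomposition of
standard folding engines. Loop taxonomy follows the closing-pair walk:
hairpin (no inner helix), bulge (one inner helix, unpaired bases on exactly
one side), internal (both sides), multi (two or more inner helices); the
unpaired bases outside all pairs form the exterior region. The
*cumulative internal-loop size* counts unpaired bases in internal **and**
bulge loops. Only A-U, G-C and G·U pairs are accepted; a structure pairing
anything else is rejected at decomposition rather than silently reclassified.
Sequences are normalized at ingest (T→U, case-folded); ambiguity codes are
rejected. A minimum hairpin-loop size of 3 is enforced by the validator and
by the generator, but not by the parser, so that externally supplied
structures can be inspected as-is.

The tree-graph descriptor dF takes vertices = loops plus the exterior
region and one edge per stem (from the region containing the stem's outer
pair to the loop its inner pair closes), and reports the second-smallest
eigenvalue of the graph Laplacian (algebraic connectivity). An open chain
scores 0; a plain hairpin is K₂ and scores 2.

## Backends

Folding, partition-function and thermodynamic profiles come from pluggable
backends satisfying one contract (`fold`, `ensemble`, `thermo`), so the
feature definitions are independent of any engine:

* **ViennaRNABackend** (live) — MFE and base-pair probabilities from the
  ViennaRNA bindings; Freq = exp((EFE−MFE)/kT); diversity is the
  mean base-pair distance. Thermodynamics are derived from the temperature
  dependence of the MFE: folding at 37 °C and 57 °C gives
  dS = −ΔΔG/ΔT (cal/(mol·K)), dH = ΔG(37 °C) + 310.15·dS/1000, and the
  melting temperature tm = 1000·dH/dS. This is a finite-difference estimate,
  not a melting simulation.
* **FixtureBackend** (engine-free) — replays a Vienna dot-bracket file and a
  TSV sidecar (`id efe freq_mfe diversity dH dS tm`). Base-pair
  probabilities are reconstructed by assigning `freq_mfe` to every MFE
  pair — a sharp-ensemble approximation that is exact for the synthetic
  sidecars, which are generated under the same model.

Backends report failures as explicit "no structure source" errors; no stage
ever substitutes silent zeros for a missing profile.

## Feature conventions

* MFEI1 divides dG by the G+C **percentage** (e.g. 50, not 0.5), following
  the definition lineage of the index; this scales the feature by 1/100
  relative to the fraction convention.
* Diff is signed: (MFE − EFE)/L.
* dQ uses log base 2; terms with p = 0 contribute 0.
* dD is the expected symmetric-difference distance to the MFE structure per
  base: (1/L) Σ_{i<j} [p_ij (1−δ_ij) + δ_ij (1−p_ij)], δ indicating MFE
  membership. MFE pairs absent from a sparse probability map contribute 1.
* %(X−Y)/stems divides the pair-class count by the number of stems, as the
  printed name says (not by total pairs).
* Zero denominators (no stems, no loops, no pairs, G+C = 0) yield feature
  value 0 plus a per-cell degenerate flag that survives the TSV round trip;
  downstream learners never see NaN. Pair-free negatives make this a real
  code path, not an edge case.
* Triplet windows cover the L−2 interior positions; both brackets collapse
  to one paired state; multi-loop structures are handled like any other.
* The motif alphabet distinguishes left-paired/right-paired/unpaired; the
  default 1,300-motif vocabulary (all 1- and 2-token motifs plus the first
  1,144 three-token motifs in lexicographic order) is a deterministic,
  documented stand-in — the motif list of the original motif-based
  classifier is not part of the public record — and any vocabulary can be
  supplied as a file.
* The amino-acid run scans the three forward frames by default (six
  configurable); low complexity uses a DUST-style trinucleotide statistic
  with window 64 and threshold 2.0, masking whole windows.

## Shuffle statistics

The null model is the Altschul–Erikson dinucleotide-preserving shuffle
(random Eulerian walk via the last-edge/arborescence method), which keeps
all 16 dinucleotide counts and both terminal bases exactly. z-scores use
the sample (n−1) SD over `n_shuffles` = 100 shuffles by default; the
stability p-value uses (1 + #{MFE_shuffle ≤ MFE_orig})/(n+1) with
`n_shuffles_p` = 999, the permutation-test convention that avoids p = 0.
Desk-scale tests use 19 shuffles. Each record draws its RNG stream from the
global seed and the record id, so results are independent of extraction
order. Sequences whose dinucleotide graph admits no alternative arrangement
are returned unchanged (detected by a cheap sufficient test: every vertex
has at most one distinct successor); the zero-variance z-score that results
is flagged degenerate.

## Registries and extraction

FS1 (48), FS2 (21 ⊂ FS1), FS3 (7 ⊂ FS1), FS4 (32), FS5 (|vocabulary|),
FS6 (34 = 32 triplets + MFE + stability p), FS7 (28 = FS2 + 4 stacking
triplets + low-complexity % + amino-acid run + internal-loop size), SELECT
(13, in relevance order: MFEI1, MFEI2, dG, dQ, dF, NEFE, Diff, dS, dS/L,
|G-C|/L, |G-U|/L, %(G-U)/stems, MFEI3), ALL85 (FS1 ∪ FS6 ∪ the three FS7
extras). Each definition declares its backend requirements; extraction is
lazy per record, so a set without shuffle features never folds a shuffled
sequence — the cost asymmetry between SELECT/FS3 and the shuffle-bearing
sets is structural and is asserted by call counting in the tests. Failures
are isolated per record (row zeroed, flagged, recorded) and the run
continues.

## Evaluation protocol

Metrics are on the 0–100 scale; Sp = 100·TN/(TN+FP). Undefined ratios
(empty denominators) are flagged rather than silently zeroed, with
Mcc → 0-flagged by convention. The repeated-holdout protocol draws, per
repetition, a class-balanced GEN test partition of ⌊n⁺/3⌋ per class and
balanced training sets in increments of 67 per class from the remainder;
by default the largest supported training set is used, which is where the
published design converged. SVM tuning is 5-fold CV accuracy over
C ∈ 2^{−5,−3,…,15} × γ ∈ 2^{−15,−13,…,3} with features standardized; RF
tuning minimizes OOB error over (30,40,…,450) trees ×
(0.5,0.75,1,1.25,1.5)·√d features per split. Grid ties break toward the
simpler model (smaller C then γ; fewer trees then smaller mtry). The CLI
exposes `--increment` because a desk-scale run of a few dozen records
cannot form a 67-per-class increment.

F-scores use the two-class between/within variance ratio with sample
variances; zero within-class variance yields an explicit infinite-score
flag. F-scores are not invariant under per-feature affine rescaling (the
statistic is scale-free under *joint* rescaling of both classes but changes
under shifts applied to one class); the tests pin the expected behaviour
against a brute-force re-computation rather than assuming invariance.
Permutation importance is Breiman-style: per OOB resample, the drop in the
number of correctly classified OOB vectors after permuting one column,
averaged over resamples, reported on the count scale. It is computed over
an explicit bagged-tree ensemble (`OOBForest`) that keeps per-tree OOB
membership. The density-estimation classifier that some published
comparisons used is represented only by its parameter-count identity
k(d+2)(d+1)/2 (`g2de_param_count`); its evolutionary fitting procedure is
out of scope.

## Synthetic data

The generator defines the desk-scale study conditions: 60–120 nt records,
positives with ≥ 15 designed stem pairs, 4–8 nt loops, 0–2 small bulges,
~10% G·U wobbles and per-record G+C bias in 0.40–0.65; negatives built from
non-stop codons with one planted 5–10-pair inverted repeat. Designed MFE
proxies are weighted pair counts (G-C 3.0, A-U 2.0, G·U 1.0 kcal/mol) with
loop/bulge penalties and Gaussian noise; sidecar rows are generated to be
internally consistent (EFE = MFE + kT·ln Freq; dH = MFE + T·dS/1000 at
310.15 K; tm = 1000·dH/dS). Both classes share the length distribution and
their energy distributions overlap.

What this does **not** emulate: real genomic base composition beyond codon
structure, the thermodynamic fine structure of real folding landscapes,
multi-branched precursors, and the label noise of curated repositories.
Passing tests on this data demonstrate that the pipeline computes its
definitions correctly and that the protocol recovers a planted separation;
they say nothing about classification performance on real pre-miRNAs,
which depends on corpus-specific distributions that only real data
provides. With planted separation at these defaults the synthetic task is
essentially solvable, so recovery checks assert Se/Sp ≥ 90 rather than a
match to any real-data figure.

Redundancy reduction mirrors the published preprocessing in spirit: greedy
centroid clustering, longest-first, joining a cluster at ≥ 80% identity,
one seeded-random representative per cluster. Identity is the fraction of
matching positions under the best ungapped offset seeded by shared 8-mers
(the exact metric of the published clustering tool is not re-derived), with
the shorter length as denominator.

## Problem sizes

Default test and acceptance runs use: 25+25 records for unit fixtures,
200 records for feature-oracle sweeps, 1,000 fuzzed sequences for shuffle
exactness, 400+400 records × 10 repetitions with the full SVM grid for the
recovery experiment, exhaustive confusion matrices with total ≤ 60 for the
metric oracle, and 19-or-fewer shuffles where shuffle ensembles are needed.
These sizes keep a full run in the low tens of seconds to a few minutes on
one CPU while leaving every code path exercised.

## Known limitations

* The thermodynamic backend derives dH/dS/tm from two-point MFE temperature
  dependence; engines with native melting computations will differ in
  detail. The features treat these values as inputs, so any better source
  can be plugged in via the sidecar.
* The fixture backend's sharp-ensemble base-pair probabilities understate
  dQ/dD for genuinely diffuse ensembles; use the live backend when ensemble
  fine structure matters.
* `is_forced_identity` is a sufficient, not necessary, test; rare
  near-rigid sequences shuffle to themselves and surface as degenerate
  z-scores instead.
* Pseudoknots, 6-frame ORF scanning by default, and motif discovery are out
  of scope.
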