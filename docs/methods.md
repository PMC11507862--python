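# Methods

`diaforge` builds experiment-specific *in silico* spectral libraries for
data-independent acquisition (DIA) proteomics. DIA fragments every precursor
inside wide isolation windows, so MS2 spectra are chimeric: one observed
peak can receive intensity from several co-isolated peptides. Training a
fragment-intensity predictor on such spectra without accounting for this
teaches the model the interference, not the fragmentation chemistry. The
package therefore (i) detects *shared* (interfered) fragment peaks, (ii)
masks them out of the training loss rather than zeroing them, (iii)
fine-tunes intensity and retention-time (RT) predictors on the surviving
signal, and (iv) assembles a filtered predicted library plus evaluation
tooling.

## Annotation and the fragment grid

Each detected precursor (peptidoform + charge, taken from a DIA-NN-dialect
report filtered at precursor q ≤ 0.01 and, for phosphodata, site confidence
≥ 0.75) is matched against the MS2 scan whose isolation window covers the
precursor m/z and whose RT is closest to the reported apex. b/y ions (plus
−97.9769 Da phospho neutral-loss ions when enabled) are generated at
fragment charges 1+ (and 2+ for precursors of charge ≥ 2) and matched to
the nearest peak within a mass tolerance (default 10 ppm; 30 ppm is
appropriate for TOF-like data). Observed intensities live on a fixed
(backbone position × ion column) grid; row *i* holds b_i and y_(L−i), and
the column order b1+, (b1+ loss,) b2+, … y2+ is the package's on-disk
fragment ordering everywhere (serialized examples, checkpoints, libraries).

Unmatched ions get intensity 0 — *unless* their theoretical m/z falls
outside the acquired scan range, in which case the cell is masked: absence
of evidence outside the detector range is not evidence of absence. Matched
intensities are normalized so the highest usable peak equals 1.

## Interference detection

Two complementary strategies label shared peaks; the final label is their
union (plus within-peptide ambiguity, where two ions of one peptidoform
claim the same observed peak).

**Spectrum-centric.** Within one apex scan, any observed peak claimed by
fragment ions of two or more identified peptidoforms is shared. This is
exact but blind to unidentified co-isolated species.

**Peptide-centric.** For each matched fragment, its extracted ion
chromatogram (XIC) over the reported peak boundaries is smoothed
(Savitzky-Golay, window 7, order 2; traces shorter than the window fall
back to a (1,2,1)/4 weighted moving average — the window and order are our
defaults, chosen for ~10-15-point DIA peaks). Pairwise Pearson correlations
between smoothed XICs give each fragment an aggregate co-elution score; the
top-scoring fragment anchors the peptide, and any fragment whose
correlation to it falls below 0.8 is shared. Fragments that remain
*elevated at both peak boundaries* (above the median of the peptide's
fragment XICs at that time point and above 10% of the trace's own in-peak
maximum — 25% for traces below half the brightest fragment) earn a
peak-shape score of 2 and are shared regardless of correlation; the rule is
applied to the top fragment as well. The "median/maximum of all detected
peaks" referents are read as this peptide's matched fragment XICs; peak
boundaries are snapped to the nearest scan. The peptide-centric path
requires ≥ 3 matched fragments and ≥ 4 XIC points; degenerate detections
fall back to spectrum-centric flags only.

**Spectrum rejection.** A spectrum is rejected outright when its base
(maximum-intensity matched) peak is shared, or when more than 50% of
matched peaks are shared (denominator: matched peaks, not all theoretical
cells). Rejection reasons are tallied, not raised.

## Models and the masked loss

Both predictors are scikit-learn-style estimators on a small numpy
reverse-mode autodiff core written for this package.

* **Fragment intensities** — transformer encoder over residue tokens with
  modification, charge, NCE and instrument channels; output head maps each
  adjacent hidden-state pair to the ion columns of that cleavage site.
  Desk-scale default: 2 layers, d_model 64, 4 heads (the full-scale 4-layer
  setting is a config knob).
* **RT** — residue/modification embeddings → 1-D convolution (kernel 3) →
  BiLSTM (hidden 64) → masked mean-pool → sigmoid, predicting RT normalized
  to [0, 1] by the run's maximum MS2 RT (or a user scale). Padded positions
  carry state through the recurrence, so padded-batch and single-sequence
  predictions agree exactly.

Training minimizes mean absolute error over *unmasked* cells only; the
gradient at masked cells (shared peaks, out-of-range ions, padding) is
exactly zero (finite-difference-checked in the tests). Optimization is Adam
with linear learning-rate warmup and a constant rate thereafter; warmup
epochs/epochs/rate/batch default to the fine-tuning recipe (20/10/1e-4/512
for fragments, 40/10/1e-4/1024 for RT). `ModelConfig.desk_scale()` is the
from-scratch recipe used on synthetic data (20 epochs, warmup 5, lr 1e-3,
batch 64; RT 25/5/3e-3/128) — more steps and a higher rate because there is
no pretrained initialization. Checkpoints are self-describing (config +
parameters + column layout) and reload bit-identically. Loading external
pretrained weights is an optional warm-start hook (`init=`); its absence
never affects the test path, which trains from random initialization.

## Library generation

Proteins are digested with trypsin cleaving after K/R without proline
suppression ("Trypsin/P"), ≤ 1 missed cleavage, lengths 7–35, N-terminal
methionine excision off by default. Peptides containing residues without a
defined monoisotopic mass (U/X/…) are excluded. Peptidoforms cross fixed
carbamidomethyl-C with variable-mod combinations (≤ `max_var`) and charges
2+–4+. Precursors and fragments outside the m/z ranges recorded from the
training run are dropped; per precursor the top 20 predicted fragments are
kept (ties broken b-before-y, lower index, lower charge), renormalized to
max 1 after truncation (our choice; renormalization after top-N is not
dictated by the output format), and the predicted RT is rescaled by the
training run's RT normalization factor. No masking applies at prediction
time. Output is row-per-fragment TSV (DIA-NN/Spectronaut-compatible
columns) with an identical-schema Parquet mirror.

## Evaluation

* **Unmasked Spearman** between predicted and observed grids, computed only
  over unmasked cells (≥ 3 required; average ranks for ties).
* **Entrapment FDP bounds.** Paired entrapment peptides are built by
  shuffling the non-C-terminal residues (C-terminal residue fixed, I→L
  first, ≤ 50 shuffle retries, collisions reshuffled — an approximation of
  the dedicated entrapment tool's generator). At cutoff s,
  FDP_lower = N_E/(N_T+N_E) and
  FDP_upper = (N_E + N_{E≥s>T} + 2·N_{E>T≥s})/(N_T+N_E).
  For pairs whose target is truly absent the upper bound is *exactly tight
  in expectation*; its conservatism comes from present targets outscored by
  their entrapment partner, so joint coverage of [lower, upper] is high in
  the moderate-separation regime near a realistic cutoff and degrades when
  true and null scores are nearly disjoint. The coverage simulation
  defaults (separation 1.5 sd, cutoff 1.0) reflect the former.
* **Spectral entropy similarity** (unweighted): intensities normalized to
  sum 1, peaks merged across spectra within 0.01 m/z, similarity
  1 − (2S_AB − S_A − S_B)/ln 4 of the half-sum spectrum.
* **NCE calibration**: grid search 20–40 maximizing the median entropy
  similarity between predictions and observations over *unshared* fragments
  only; ties resolve to the lowest NCE.

## Synthetic data — what it emulates and what it does not

The generator renders tryptic peptides from random protein sequences into a
windowed DIA cycle (25 × 20 m/z windows from 400, 2.5 s cycle, 30 min
gradient, 6 s Gaussian peak sigma), with log-normal abundances,
multiplicative log-normal peak noise (σ 0.05), a handful of floor noise
peaks per scan, and a matching detection report (true apexes/boundaries,
q ≈ 0, plus 10% high-q junk rows to exercise filtering).

The fragmentation rule is a deliberate closed form — flanking-residue
cleavage propensity × positional envelope, b/y balance shifting
monotonically with NCE and charge, 2+ fragments scaling with basic-residue
content — so that model training has a well-defined recoverable target. RT
is a logistic function of mean residue hydrophobicity with 0.1 min apex
jitter. Both per-residue tables are invented smooth scales, not literature
values.

Interference is injected per rendered fragment peak at a requested rate as
*anonymous* co-eluting precursors: apex offset uniform in 1.2–2.5 peak
sigmas, amplitude log-normal around 1.5× the target fragment — i.e. the
clearly offset co-elution regime the XIC-correlation detector is designed
to flag; closer or fainter interferers are increasingly indistinguishable
in principle at the fixed 0.8 correlation threshold. Ground-truth labels
are derived from the rendered spectra themselves: a fragment peak is
labeled interfered when >5% of its apex-scan intensity comes from another
precursor. Identified peptides co-eluting in one window are kept ≥ 30 ppm
apart in fragment m/z so labels stay crisp; consequently the
spectrum-centric strategy is exercised by construction only through
within-peptide ambiguity in simulation, and its cross-peptide path is
covered by targeted unit fixtures.

Not emulated: isotope envelopes, MS1-driven feature detection, ion
mobility, chromatographic tailing, inter-run variation. Passing the
simulation tests therefore shows the machinery is correct under the stated
model, not that real-data accuracy matches any particular instrument.

## Problem sizes and numerical choices

Regression tests and the acceptance script use: 500-peptide runs for
detector metrics, 2,000 rule-generated examples (10% held out at the
peptide level) for fragment-model recovery, 1,000 for RT recovery, 1,000
simulated discovery lists of 500 pairs for FDP coverage — sizes chosen so
the whole suite runs in minutes on one CPU. Tolerances: oracle equivalence
1e-10; annotation fidelity on noise-free simulations 1e-6; library fragment
m/z recomputation 1e-4. Tie-breaks are deterministic throughout
(equidistant peak → more intense; apex tie → earlier scan; q tie → lower
charge; ranking tie → b<y, lower index, lower charge; NCE tie → lower
value). All randomness flows from explicit integer seeds; two runs with the
same seed are hash-identical end to end.

## Known limitations

* The mzML writer/reader pair covers centroided spectra with the CV terms
  the pipeline needs (levels, RT, scan windows, isolation windows, float
  arrays, optional zlib); it is not a general mzML implementation.
* Single-run training only: RT examples from multiple runs are rejected
  rather than aligned.
* The entrapment generator approximates the cited pairing procedure
  (shuffle with C-terminus fixed); protein-level entrapment and multi-fold
  designs are out of scope.
* Peak boundaries are taken from the report as-is; no boundary refinement.
* The desk-scale models are small; the full-scale configuration trains but
  is not exercised in the default test path.
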