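# Methods

`smrtmod` calls DNA base modifications (5mC, 5hmC, 6mA) on single molecules
from the polymerase kinetics of single-molecule real-time (SMRT) sequencing:
inter-pulse durations (IPD) and pulse widths (PW) recorded at every
incorporated base. A modified template base slows the polymerase at and
around the incorporation site, so the signal for one site lives in a small
neighbourhood of positions, strands and channels. The package covers the full
path from per-pass subread kinetics to downstream analyses, with a synthetic
kinetics generator so that every stage is testable without instrument data.

## Data model

A *molecule* carries a consensus sequence (Watson orientation), per-strand
aggregated IPD/PW arrays, per-strand subread depth, and optional
sequencing-adapter flanks with their own kinetics. Crick-strand arrays are
stored in Watson coordinates: index *i* holds the kinetics of the Crick base
paired with Watson position *i*. Subreads are aggregated position-wise by the
mean (default) or median; depth per strand is the number of passes
aggregated. All coordinates are 0-based half-open; kinetic values are
dimensionless positive reals — every downstream statistic is
scale-invariant by normalization, so frame counts and seconds are equally
acceptable.

A modification on strand *s* perturbs the kinetic arrays stored for strand
*s* (arrays are indexed by the strand carrying the modified base, as in
tag-assigned per-base kinetics). Duplex CpG methylation perturbs both
strands.

## Measurement windows

The classifier input for one candidate site is a 21-position window (10 nt
each side; widths 5–41 supported, 21 is the default because performance
plateaus there) with channels
`[kinetics… , one-hot base, adapter flag, relative position]` — 10 channels
in duplex mode (both strands' IPD/PW, base-pair aligned), 8 in
strand-specific mode. Layouts are versioned (`duplex-v1`, `single-v1`) and
trained models refuse mismatched layouts. Crick-strand windows are extracted
in that strand's own 5'→3' orientation, so a single-strand model serves both
strands.

Windows that would run past a fragment end are completed from the flanking
adapter kinetics (adapter rows flagged); with adapters present, every target
site is callable. Without them, sites within 10 nt of an end are no-calls.

Two normalizations:

* **median50** (cytosine modifications): each kinetic channel is divided by
  its median over a 50-nt span centred on the target. The span (rather than
  the whole molecule) limits bias from molecule-length-dependent kinetic
  drift.
* **thymine-median** (6mA): all kinetic values in the window are divided by
  the median kinetic value of thymines on the same strand within the same
  50-nt span, separately per channel. Unmodified adenines and thymines share
  one kinetic law, so normalized uA values centre at 1. Declared
  *confounding sites* — neighbouring modified adenines inside the window —
  are then set to exactly 1, the value that maximally resembles the uA
  distribution, which makes windows with one or many 6mA sites comparable.
  If the span holds no thymine the molecule-wide thymine median is used; a
  molecule with no thymine at all is an error.

Numerical choices: divisors are floored at `epsilon = 1e-3`; normalized
kinetics are clamped to [0, 10] to bound outliers; the confounder mask is
applied after clamping and never covers the target itself. A missing
normalization divisor cannot occur because the span always contains the
target.

## The scorer

A hybrid CNN+transformer binary classifier maps a window to a modification
score in [0, 1]:

1. four same-padded 1-D convolutions, 64 filters, kernel 5, ReLU, with batch
   normalization between consecutive convolutions (local kinetic patterns);
2. sinusoidal positional embeddings (standard base-10000 form) added to the
   convolutional output, which keeps `d_model = 64`;
3. three pre-layer-norm transformer encoder layers: 4-head scaled
   dot-product attention, GELU feed-forward of width 128, dropout 0.1
   (global patterns across the window);
4. flatten → 128-unit ReLU layer → 2-unit softmax; the "modified"
   probability is the score.

Pre- vs post-layer-norm, head count, feed-forward width and all training
hyperparameters are open choices; we use pre-LN for training stability and
record every hyperparameter in the checkpoint. Training uses balanced
two-class cross-entropy, Adam at 1e-3, batch 256, up to 20 epochs with early
stopping on validation AUC (patience 3), all driven by one seed; the
checkpoint with the best validation AUC is kept. One binary model is trained
per task (uC/5mC, uC/5xC, 5mC/5hmC, uA/6mA).

The network is implemented directly on numpy with hand-written backward
passes (conv via im2col, batch/layer norm, multi-head attention, dropout,
Adam), in float32; analytic gradients are checked against central finite
differences (in float64) in the test suite. Desk-scale models train on one
CPU in minutes.

## Calling workflows

* **5mC**: one call per CpG cytosine, duplex or strand-specific; label =
  modified iff score > cutoff (default 0.5). Cutoff changes relabel, never
  rescore. Molecules with a zero-depth strand cannot be called in duplex
  mode and are emitted as no-calls with a notice.
* **5hmC (two-stage)**: stage 1 scores unmodified-vs-modified cytosine
  (uC vs 5xC); only sites above the cutoff proceed to stage 2 (5mC vs
  5hmC). Both scores are retained; stage-specific cutoffs are configurable.
* **6mA (iterative)**: round 1 scores every adenine of one strand with an
  empty confounder set; subsequent rounds re-normalize with the provisional
  modified set (excluding each target itself) as confounders, until labels
  are stable or `max_6mA_iterations` (default 3) is reached. During
  *training*, confounders are the known truth sites; at inference the truth
  is unknown, and this provisional-call iteration is our resolution of that
  gap — it is a documented interpretation, not a claim about how any
  particular production pipeline does it.

  The recommended 6mA *training* data are all-adenine libraries of mixed
  modification density (e.g. p = 0.5/0.1/1.0/0.0) with per-site truth
  labels, not only an all-modified/all-unmodified pair. The mixed densities
  supply the decisive hard negatives: unmodified adenines lying inside a
  modified neighbour's kinetic footprint, whose own centre kinetics are
  genuinely elevated. A model trained only on the pure pair has never seen
  such a case and false-calls the majority of them on sparse data; with the
  mixed recipe plus iterative masking, sparse-library calling reaches ~90%
  sensitivity at ~1% false-positive rate in our simulations.
* **Cutoff calibration**: the default cutoff is 0.5 everywhere, but both
  stages of the 5hmC cascade accept their own cutoff; for quantitative
  three-way resolution we calibrate each stage at its equal-error rate on a
  held-out labelled library, which removes the skew of the raw softmax
  scores.
* Aggregations: per-region modification level (modified / called; regions
  with no covered site are missing, not 0) and per-molecule ordered CpG
  methylation profiles.

## Synthetic data

The generator emulates the kinetic phenomenology the caller relies on, not
an instrument:

* per-base-identity baselines, log-normal by default (median 0.22 for A/T
  IPD — A and T intentionally share one law — 0.25/0.28 for C/G; per-site
  log-scale 0.2 for sequence-context variability that does not average out
  with depth);
* a multiplicative footprint per modification, Gaussian-decaying in log
  space over ±5 nt. The 6mA central IPD factor 4.1 is anchored to the
  observed uA/6mA IPD medians (0.22 vs 0.90); the off-centre shape and the
  other defaults (5mC 1.6, 5hmC 1.3 on IPD; 1.3/1.2/1.1 on PW) are generator
  choices, config-overridable, and not claims about chemistry. Overlapping
  footprints multiply, so dense modification inflates single-site statistics
  — precisely the confounding that the thymine-median masking addresses;
* per-pass multiplicative log-normal noise (σ = 0.5), so aggregated kinetics
  sharpen with subread depth and depth-stratified accuracy rises;
* adapters flanking every molecule with unmodified baseline kinetics;
* placement rules: per-CpG Bernoulli, all-adenine (whole-genome-amplified
  6mA libraries), Dam-style GATC (defaults 95% at GATC, 1% background,
  mirroring printed levels), jagged 5' overhangs whose fill-in carries 6mA
  at every adenine of the repaired segment, and accessibility-driven 6mA
  whose probability follows a raised cosine of distance to the nearest
  anchor (default period 180 bp, the nucleosomal repeat) within a
  configurable span.

A truncated-normal "symmetric" preset exists to verify the thymine-median
centring property. Everything is drawn from one seeded generator; the same
seed yields byte-identical fixture files.

What the generator does **not** model: sequencing errors (the consensus is
taken as correct), polymerase pausing artifacts, context-specific footprint
shapes, real genome composition, or correlated noise between IPD and PW.
Passing tests therefore demonstrate that the machinery is correct and that
the method behaves as designed under the stated kinetic model — not that any
particular accuracy will be attained on instrument data.

## Problem sizes used in the checks

The self-contained checks run at desk scale, chosen to make each property
measurable with comfortable statistical margin: ~20k windows for the 5mC
training experiment (deeper results only saturate), ~100k adenine sites for
the motif and centring checks, hundreds of molecules for the jagged-end and
periodicity recoveries. `scripts/acceptance.py` reports the exact `n` it
used for each quantity.

## Known limitations

* The molecule-origin score implements the quoted comparison principle (a
  per-molecule Bernoulli log-likelihood ratio against two reference classes,
  logistic-mapped and averaged per CpG); the exact production scoring of the
  cohort study it gestures at is defined elsewhere and may differ. Sample
  aggregation is a plain mean over molecules.
* De novo motif discovery is exhaustive short-word (+ gapped-pair)
  enrichment with parsimony reduction and IUPAC merging — sufficient for
  methyltransferase-style motifs, not a general PWM learner.
* Multiclass (uC/5mC/5hmC in one softmax) is not implemented; the two-stage
  cascade covers the use case.
* BAM support covers per-read kinetics tags on consensus reads; raw trace
  files and subread→consensus alignment are upstream concerns.
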