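# Methods

## Immune-visibility metric

A presentation predictor is any deterministic map from a peptide (8–10
canonical residues, optionally containing the unknown symbol `X`) to
`True`/`False`/`UNCLEAR`.  The absolute visibility of a sequence is the
number of its 8/9/10-mer windows called `True`; windows are enumerated with
0-based half-open coordinates, overlaps count separately, and allele
multiplicity never inflates the count because the predictor interface is
already allele-pooled.  Windows containing `X` are `UNCLEAR`: they never add
to visibility but are reported so callers can flag low-confidence designs.
Relative visibility is design/template; a zero-visibility template makes the
ratio undefined and is reported as `NaN` rather than an error, because a
zero-visibility template is a legitimate (and desirable) edge case.
Multi-chain inputs are scanned per chain and summed — no window spans a
chain break, since the proteasome does not splice chains.

Residue annotation follows the usual rendering convention: *anchor* = second
or terminal residue of at least one presented window, *epitope* = inside at
least one presented window, *unclear* = covered only by `X`-containing
windows, with precedence anchor > epitope > unclear > none.

## PWM presentation classifier

One 20×L log-probability matrix per length L ∈ {8, 9, 10}, estimated from
the presented peptides of a reference-labeled random set; all patient
alleles are pooled into the single per-length matrix.  Entries are
`log[(count + c)/(n + 20c)]` with pseudocount `c = 0.5` per amino acid
(default): the reference labeling is silent about unobserved residue/position
combinations and a zero count would otherwise produce a −∞ entry that makes
every containing peptide unscorable.  `c = 0` is accepted for exact
textbook-style hand computations.

Calibration sets, per length, the threshold to the k-th highest calibration
score where `k = round(f_L · n_L)` and `f_L` is the fraction of the
calibration set the reference predictor labels presented.  The boundary
convention is `score ≥ threshold`: with ties at the boundary the classifier
admits the whole tied group (it can only overshoot the target count, never
undershoot), and the achieved count, target count and tie count are stored
in the calibration metadata.  `f_L = 0` puts the threshold above the maximum
score and emits a warning.  Peptides containing `X` are excluded from both
fitting and calibration and receive `UNCLEAR` at prediction time.

## Synthetic reference predictor and toy backbones

The motif oracle presents a peptide iff position 2 lies in a hydrophobic
anchor set ({L, M, I, V} by default) and the C-terminus in {V, L, F, Y} —
the anchor-position structure of real MHC-I motifs.  Under uniform random
peptides the presented fraction is (4/20)² = 4%, between the conventional
strong-binder (0.5% rank) and weak-binder (2% rank) regimes; shrinking the
anchor sets emulates stricter cutoffs.  The oracle was chosen over a random
labeling so that preference tuning has a learnable mechanism — a model can
reduce visibility by avoiding anchor residues — mirroring what a full-scale
pipeline exploits.  What the oracle does **not** emulate: allele-specific
score distributions, length-dependent binding preferences, or any
correlation structure beyond the two anchor positions.  Passing tests
therefore demonstrate that the machinery optimizes the metric it is given,
not that tuned designs would evade real MHC-I presentation.

Toy backbones are single chains of ideal helix (1.5 Å rise, 100° twist,
3.8 Å CA–CA), extended strand (3.3 Å axial step with ±0.95 Å pleat), or a
helix+strand concatenation, with N/C/O placed from the local CA tangent and
normal at standard bond lengths, optional seeded Gaussian coordinate noise
(default study condition 0.1 Å), and a native sequence drawn from natural
(Swiss-Prot bulk) amino-acid frequencies.  They are geometrically plausible
conditioning prompts, not foldable proteins.

## Mini inverse-folding model

The model keeps the interface of message-passing fixed-backbone design
networks: an encoder builds per-residue node embeddings and per-neighbor
edge embeddings over a k-nearest-neighbor CA graph (defaults: 16 neighbors,
feature dimension 64, 2 encoder layers; the published full-scale values —
128 features, 48 neighbors — ship as a config preset), and an
arbitrary-order autoregressive decoder emits a 21-way distribution (20 amino
acids plus input-only `X`, masked at sampling) per position, conditioning on
structure, on already-decoded tokens through their edge-gated embeddings,
and on a mask symbol for not-yet-decoded neighbors.  All geometric features
are pairwise distances, local angles/pseudo-dihedrals and sequence
separations, so every output is invariant to rigid motions (and reflections)
of the input.

Two deliberate design choices keep the model trainable on one CPU with no
deep-learning dependency:

* the trunk (encoder + decoder context builder) is a **frozen random-feature
  network** — weights drawn once from a seeded generator, never trained;
* the trainable state is a two-layer softmax readout head whose gradients
  are exact and hand-derived.  The output layer initializes to zero, so a
  fresh model is exactly uniform (1/21 per symbol).

Because the trunk is frozen, the teacher-forced decoder contexts of a fixed
(structure, sequence, order) triple can be cached and reused across
training steps, which makes both pretraining and preference tuning fast.
Decoding-order likelihoods condition on a single uniformly sampled order per
example; the same order is used for the policy and the reference model of
one response so the likelihood ratios in the preference loss are
well-defined.  The orders of the two responses of a pair are independent and
persisted with the pair.

Supervised pretraining (the "foundation" stage) minimizes per-token
cross-entropy of native sequences under a fresh random order per epoch —
study conditions: 20 backbones of length 60, 150 epochs, Adam at 1e-2.
The pretrained mini model reaches ~10% sequence recovery, mostly by learning
composition and local context.  A consequence worth knowing: at the low
design temperature (0.1) its samples are strongly sharpened toward the few
highest-probability residues — which are common, anchor-heavy amino acids —
so the *base* model's relative visibility on toy templates is well above 1,
unlike a full-scale network whose base designs sit near 1.  The alignment
trend (visibility down, recovery down) is the meaningful desk-scale
observable, not the absolute level.

## Preference alignment

One preference pair per training backbone per refresh: the current model
samples two full-length designs at the preference-sampling temperature
(a tuning hyperparameter, distinct from the fixed 0.1 design temperature),
the PWM classifier scores their visibility, the lower-visibility design
becomes y_w.  Equal-visibility pairs are dropped — the loss needs a strict
preference, and random assignment would inject label noise.  Reference
log-likelihoods come from the frozen base model under each design's own
decoding order and never change across refreshes.  The loss is
`−log σ(β(Δ_w − Δ_l))`, `Δ = log π_θ − log π_ref`, estimated by minibatch
means (default 8 pairs per batch, under a 10 000-token budget; both the pair
count and token cap are recorded).  Optimization is plain Adam at the stated
learning rate with global gradient-norm clipping at 1.0.  The preference set
is regenerated from the *current* model every `epochs_per_refresh` (default
2) epochs, so the policy keeps moving away from its own outputs rather than
from the base model's.

Divergence handling: a non-finite loss, or ten consecutive sampled designs
that are >90% a single amino acid (the constant-chain failure mode), aborts
the run with the results flagged `diverged` — recorded, not fatal, in
sweeps.  A saturated preference signal (every candidate pair tied, typically
at zero visibility) is not divergence: the epoch simply passes without
updates.

Mini-model default hyperparameters — β = 0.05, sampling temperature 0.5,
learning rate 2e-2 — are sized for the readout head.  The two published
full-scale configurations (`458340e4`: β 3.43e-2, temperature 0.759, lr
2.86e-6; `e32b8ed0`: β 4.48e-3, temperature 0.500, lr 4.62e-7) are shipped
as named presets for use with full-scale weights, and the sweep draws β ~
log-uniform(0.001, 0.2), temperature ~ uniform(0.01, 1.0), lr ~
log-uniform(1e-7, 1e-3).

The KL-anchoring property of β is assessed on a *fixed* preference dataset
trained to saturation: a larger β reaches a saturated preference margin with
a smaller policy displacement, so the mean per-token KL from the reference
shrinks monotonically in β.  Under periodic refresh the comparison is not
meaningful at matched small step counts, because refreshing resets margins
and sustains drift regardless of β.

## Design generation and evaluation

Specific-template protocol: 3 candidates at temperature 0.1; drop candidates
with <10 distinct amino-acid types; predict a structure per survivor
(failed predictions score TM = 0); choose the minimum-visibility candidate
among TM > 0.9, else the maximum-TM candidate.  "Above" is read strictly at
both the 0.9 gate and the 2% rank cutoff.  Large general sets use the
single-sample protocol.  Checkpoint-level means are means of per-structure
ratios (not ratios of means), with per-structure rows retained.

The built-in TM-score assumes positional correspondence (appropriate for
fixed-backbone design), superimposes CA traces by iterative Kabsch
refinement — re-fitting on the sub-d0-ish subset until it stabilizes — and
normalizes by the template length with `d0 = max(0.5, 1.24·(L−15)^⅓ − 1.8)`.
It is cross-checked in the tests against an independent TM implementation
after an independent superposition; an external TMalign adapter (with output
parser) handles structures needing an alignment search.  An unavailable
backend raises — 0 is reserved for failed structure predictions.  The
desk-scale structure-prediction backend perturbs the template with seeded
Gaussian noise (default σ 0.3 Å, giving TM ≈ 0.97 on 60-mers) and can
simulate prediction failures; it exercises the gate and failure paths but
says nothing about whether a designed sequence actually folds.

## Numerical and testing choices

Seeded `numpy` generators everywhere; any derived seeds stay below 2³¹.
Calibration thresholds use `np.partition` (exact k-th statistics, no
interpolation).  The toy-model normalization check uses a head biased to two
effective tokens (−45 on the rest), so the residual probability mass is
below 1e-15 and the 8-sequence sum matches 1 within 1e-6.  Statistical
assertions use 5σ binomial bounds.  Desk-scale problem sizes (50 000-peptide
calibration sets, 20 backbones of length 60, 12-epoch alignments) were fixed
once as the package's study conditions; the full suite runs in well under a
minute.

## Known limitations

* The PWM is position-independent within a length and allele-pooled; it
  cannot represent residue-pair dependencies or allele-specific motifs.
* The frozen-trunk mini model adapts only its readout head; it demonstrates
  the alignment mechanics, not full-scale design quality, and its
  low-temperature samples are more composition-biased than a full network's.
* The Gaussian structure backend and the motif oracle make the end-to-end
  results a mechanism demonstration on synthetic conditions; real-data use
  requires the netMHCpan adapter, a folding pipeline behind the structure
  backend interface, and pretrained full-scale weights behind the model
  interface.
* Multi-chain assemblies, hetero-complexes and ligand conditioning are out
  of scope for the mini model (single-chain synthetic data only).
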