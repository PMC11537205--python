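# Methods

## Gating model

Phenotyping by marker gating treats each segmented instance as a bag of
pixels: for every stain channel the instance's arithmetic mean intensity is
compared to a per-channel, per-slide threshold, and the resulting boolean call
vector is passed through an ordered rule cascade. A rule is a class name plus
required-positive and required-negative channel sets; the first rule whose
requirements hold assigns its class, and an instance matching no rule is
`"unclassified"`. Positivity is a *strict* inequality (mean > threshold) so
the boundary case is deterministic.

The packaged default table encodes 14 classes through 17 key stains. DAPI
anchors every nucleus class (goblets are the exception: they are identified by
their Muc2-high goblet, not a nucleus, so the goblet rule requires Muc2
alone). Specific markers precede lineage-generic ones — goblet,
enteroendocrine (CgA), progenitor (Sox9 or OLFM4, two adjacent rules),
enterocyte (PanCK and NaKATPase jointly, config-selectable to a disjunction),
then the immune cascade (helper T, cytotoxic T, generic CD3d+ T, B,
macrophage, monocyte, myeloid other, leukocyte other), then fibroblast (SMA)
and stromal undetermined (Vimentin) — so "other" labels only catch cells
nothing more specific explained. The T-cell block is a pure cascade with no
negative markers: order alone performs the CD4/CD8 exclusion, which makes a
CD4+CD8+ double positive resolve to helper T under the default policy;
`double_positive_policy="demote_to_parent"` instead prepends an explicit rule
sending double positives to the generic T label. Re-ordering rules can change
outputs (first-match-wins); the packaged order is fixed, serialized with the
table, and overridable via YAML/JSON.

## Synthetic tissue

The generator emulates the *structure* of a gated MxIF cohort rather than its
photometry. Cells are drawn multinomially from a 14-class mixture (uniform by
default), placed by rejection sampling with a minimum centre distance of 95%
of the sum of the two semi-major axes, and painted as rotated ellipses whose
radius and eccentricity are drawn per class from configured ranges
(area-preserving parameterization, so eccentricity does not change size).
Each gating channel receives the class's on-intensity (1.0 on marker
channels; a class-specific value on DAPI) plus zero-mean Gaussian pixel noise,
a background noise floor, and clipping at zero; nuisance channels carry only
noise. Default conditions: 1024×1024 px at 0.32 µm/px, 600 cells, noise SD
0.08, threshold 0.5 on every channel, three nuisance channels. All randomness
flows through a single `numpy` generator seeded from the config, so equal
seeds give bit-identical slides.

Each class's profile is positive for exactly the channels its gating rule
requires (DAPI for all nucleus classes, CD3d for the T lineage, plus the
class's own key stains), which makes the zero-noise round trip exact: gating a
noiseless slide recovers every true class. Under noise, accuracy degrades
through two mechanisms — mean-level jitter across the threshold and,
dominantly, the clipped background noise whose positive mean pushes
off-channels toward the threshold — giving the monotone noise ladder the
property suite checks.

What the generator does **not** model: real marker intensity distributions
(the Gaussian on/off model is an assumption, not a claim about MxIF
photometry), autofluorescence, spatial tissue architecture (crypts, immune
aggregates), segmentation errors in the truth masks, or staining batch
effects beyond the per-site affine color shifts of the parent-labeled sets.
Passing tests therefore demonstrate the correctness and statistical behaviour
of the pipeline, not performance on real tissue.

## Pseudo-H&E rendering and designed learnability

The rendering is a fixed analytic color map: background/stroma a pale pink
wash, goblet pixels pale, nucleus pixels mixed toward a hematoxylin-like
purple-blue with a weight increasing in DAPI intensity. It preserves instance
geometry and DAPI brightness — exactly the information H&E could plausibly
carry — and nothing else.

The default profile gives six classes a unique signature in (size,
eccentricity, brightness) space — goblet (large, pale), enteroendocrine
(tiny), progenitor (medium, round, brightest), enterocyte (large, elongated),
macrophage (large, round, dim), fibroblast (extreme spindle) — the
*designed-separable* set. Helper T and cytotoxic T are drawn from identical
morphology and brightness distributions and differ only in CD4 vs CD8, which
the rendering never sees: the *designed-unlearnable* pair, a negative control
mirroring the fact that only a subset of marker-defined classes is learnable
from H&E. The remaining six classes have deliberately overlapping middling
morphologies and carry no separability claim.

Chance level for an unlearnable twin is defined as its prevalence among the
instances the model assigns to the pair: because the model's choice *within*
the pair is statistically independent of the truth, an input-blind tie-break
attains exactly that PPV, and the recovery experiment checks the trained
model does no better (mean PPV − chance within 2 SE over 5 seeds) while the
separable classes sit far above it.

## Classifier

The classifier is a compact two-layer fully-connected network over the
flattened 41×41×3 patch: per-sample input standardization, a hidden layer
(64 units by default) with layer normalization and ReLU, and a linear output
head. Every internal normalization is computed from the sample alone, and
prediction processes samples one at a time, so inference is exactly invariant
to batch composition and size — the property the contract tests assert
bitwise. Training uses class-balanced batches (each batch slot samples a
class uniformly, then an example uniformly within the class, with
replacement), Adam at learning rate 1e-3, cross-entropy, and a one-cycle
schedule (linear warmup over the first 30% of steps from peak/25, cosine
anneal to 1e-4·peak); the checkpoint with the lowest validation loss is
returned. Defaults: 2,000 steps at batch 256 (a full-scale 20,000-step
configuration remains selectable), validation every 100 steps.

Problem sizes for the recovery experiments were chosen to keep a full run in
the low minutes on a single CPU: the desk experiment uses 8/2/4
train/val/test slides of 330 cells at 768² px (≈4,600 patches); the five-seed
negative-control replicate uses 4/1/2 slides of 300 cells at 640² px and 600
steps, since chance-level behaviour needs no converged model.

## Evaluation

**Matching.** Candidate (pred, gt) pairs with IoU strictly above the
threshold (default 0.25 — lenient, absorbing systematic differences in how
tightly label sources crop boundaries) are accepted greedily in descending
IoU order, ties broken by smaller gt id then pred id; each id joins at most
one pair. Greedy matching is the contract; on random small fixtures it
coincides with exhaustive optimal one-to-one matching, which the suite
verifies on 200 fixtures.

**Classification metrics** operate on aligned (pred, gt) class pairs — either
matched pairs only (predicted-centroid regime) or all ground-truth instances
with unmatched ones scored as unclassified (ground-truth-centroid regime).
Unclassified ground truth is excluded from classification metrics but
retained in detection metrics.

**Bounded metrics.** With parent-level ground truth, `ppv_upper` credits any
parent-level agreement; over the negatives of class c, rows with a different
parent are definite true negatives (`npv_lower`), and rows with c's parent
are ambiguous — `npv_upper` additionally credits those predicted as a
*sibling* of c. The contract is the validity ordering (true PPV ≤ ppv_upper,
npv_lower ≤ true NPV, npv_lower ≤ npv_upper), not any particular numeric
value; `npv_upper`'s sibling-credit construction is this package's
definition. `ppv_upper / prevalence` reads as a fold-enrichment over chance.

**DQ+.** Fine mode uses the full panoptic detection-quality term
TP/(TP + FP/2 + FN/2). Parent mode is an upper bound by construction: TP and
FP are parent-credited and the FN term is dropped, because an unexplained
parent-class instance cannot be attributed to any specific fine class; this
guarantees parent-mode DQ+ dominates fine-mode DQ+ wherever fine ground truth
refines the parent labels. The matching threshold defaults to the module-wide
0.25 and is configurable (0.5 is a common external convention).

**Friedman test.** Implemented directly (within-block average ranks, the
standard tie correction, chi-square upper tail with k−1 degrees of freedom)
so that k = 2 is supported and the all-tied degenerate case returns statistic
0 with p = 1; on untied k ≥ 3 input it agrees with the scipy implementation,
which the tests use as an independent cross-check.

## Folds and patches

Patient-level folds prevent leakage: patients are shuffled within
stratification-tag groups and dealt round-robin into n groups; fold i tests
on group i, validates on group i+1 (mod n), trains on the rest. With 20
patients and 5 folds every fold is 12/4/4 and every patient is tested exactly
once; slides inherit their patient's split. Patch extraction rounds centroids
to the nearest pixel (ties to even), replicates edges rather than zero-filling
(zero corners would mimic dark nuclei), normalizes each patch jointly across
its three channels to [0, 1], and maps constant patches to zero (denominator
guard 1e-12). Per-channel normalization is available as a config choice but
joint is the default reading of per-patch intensity normalization.

## Known limitations

- The fallback segmenter is a classical pipeline with no claim of parity with
  learned instance segmenters; it exists so the toolchain runs end-to-end
  without pretrained weights, and external masks can be ingested instead.
- The pseudo-H&E renderer is not photorealistic and is not meant to be; it
  carries a controlled class signal for the learnability experiments.
- Bounded-metric values depend on the fine→parent mapping; classes dropped
  from the mapping (goblet) silently leave the evaluated population.
- The classifier backbone is deliberately small; the contract under test is
  the training/evaluation procedure, not architecture-dependent accuracy.
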