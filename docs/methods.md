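# Methods

## Problem and pipeline

The package stages Alzheimer's disease from 3-D FDG-PET intensity volumes.
The disease signal is regional hypometabolism: multiplicatively reduced
tracer uptake in bilateral parieto-temporal cortex and posterior cingulate,
with frontal involvement at advanced stages. The pipeline has two trained
stages with a deliberately narrow interface (an n_studies × d feature
matrix) between them:

1. **Preprocessing** — resample to a fixed grid (trilinear), min–max
   intensity normalisation, removal of the maximal runs of all-zero axial
   slices at the two z-ends only (interior zero slices are retained), and
   partition of the kept slices into equal-sized groups.
2. **Grouped slice CNN** — supervised feature learner over slice groups,
   used afterwards as a frozen extractor.
3. **EBLS head** — broad-learning classifier solved in closed form, with
   exact incremental growth.

## Slice grouping

"Equal intervals" is implemented as interleaved stride assignment: retained
slice *i* goes to group *i* mod *n*. Every group then samples the full
cranio-caudal extent at equal spacing, so each of the CNN's group-specific
subnetworks sees whole-brain context; `grouping="contiguous"` gives quartile
blocks instead for comparison. When the retained count is not divisible by
*n*, trailing slices are dropped to the largest multiple with a logged
warning — robustness to variable brain extent was preferred over a hard
error, and equal group size is required downstream. Group size is always
derived from the data (96 slices − 2×2 zero end slices → 23 per group on
the default grid), never hard-coded.

## Stage 1: grouped CNN

The architecture is the smallest standard design that honours the grouping
contract: three blocks of 3×3 grouped convolution (per-group widths 16 / 32
/ 64), batch-norm, ReLU and 2×2 max-pooling; a grouped 1×1 projection to
`feature_dim_per_group` (default 32) channels per group; global average
pooling; and a temporary linear softmax head used only during training.
Because every convolution is grouped with group count = n_groups, zeroing
one slice group provably changes only that group's feature block — a
property the tests assert directly.

Each group's slices enter as the channels of a single 2-D image; there are
no per-slice models and no 3-D convolutions. Training is Adam (lr 1e-3,
batch 8) on softmax cross-entropy; the head is discarded afterwards. The
network is implemented directly in NumPy (im2col + BLAS matmul with
hand-written backpropagation), which is entirely adequate at this model
size and keeps the dependency footprint small; the backward pass is
verified against finite differences to 1e-6 relative error in the tests.
Initialisation, batch order and therefore the trained weights are exact
functions of the configured seed.

## Stage 2: broad learning

Feature nodes are linear, Z = [X|1]W_f, with W_f drawn i.i.d. uniform[−1,1]
(bias column included) and optionally refined by an L1 sparse-autoencoding
fit (ISTA with exact Lipschitz step, so the objective is monotone
non-increasing; off by default). Enhancement nodes are
H = tanh(s·[Z|1]W_e) with W_e orthonormalised by QR (sign-fixed for
determinism) and shrink scale s = 0.8. One block contributes [Z | H] —
60 + 60 columns by default — and the default model starts with two blocks.

Output weights use the ridge solution W = (AᵀA + λI)⁻¹AᵀY. The default
λ = 2⁻³⁰ is treated as the pseudoinverse path: the state keeps A⁺ cached
and the incrementally maintained W = A⁺Y is used directly for prediction.
For λ > 1e-8 an exact ridge head is recomputed in closed form after every
structural change instead, because the incremental update algebra is exact
only for the pseudoinverse limit.

### Incremental updates

Appending columns H to A with cached A⁺ uses the Greville recursion,
**one column at a time**:

    d = A⁺h,  c = h − Ad
    b = cᵀ/(cᵀc)             if ‖c‖∞ > 1e-10·max(1, ‖h‖∞)
        dᵀA⁺/(1 + dᵀd)        otherwise
    A⁺ ← [A⁺ − db ; b],  W ← [W − d(bY) ; bY]

Row (new-study) addition is the same recursion applied to Aᵀ, which reduces
to W ← W + bᵀ(y − aW): the old solution is corrected by the new study's own
prediction error. A whole-block variant (B = C⁺ when the residual block C is
nonzero) is algebraically equivalent only when C is full column rank or
exactly zero; in this model a later block's *linear* feature nodes always
lie in the span of [X|1] already covered by the first block, so added blocks
routinely mix dependent and independent columns, and pseudo-inverting a
numerically near-singular C amplifies rounding error catastrophically. The
per-column recursion has no such failure mode — the two branches are
exhaustive for every single column — and the tests confirm agreement with
one-shot batch pseudoinverse solves to ~1e-8 for arbitrary interleavings of
block and sample additions, including rank-deficient ones. The degeneracy
threshold 1e-10 (relative to the column's magnitude) sits many orders below
genuinely new directions (O(1) residuals) and many above the rounding floor
(~1e-13) at these problem sizes.

### Label handling

Labels are one-hot encoded with class order fixed by first appearance in
the training data and recorded in the model file; the class set is frozen
at fit time (`add_samples` rejects unseen codes). Prediction takes the
softmax of the regression scores and the argmax label; exact ties resolve
to the lowest class index with a logged warning. The 0.5 decision threshold
enters only the one-vs-rest metric computation, not the argmax label.

## Evaluation

One class at a time is treated as positive, the rest negative; a study is
predicted-positive when its positive-class probability is ≥ the threshold.
Sensitivity tp/(tp+fn), specificity tn/(tn+fp), precision tp/(tp+fp) and
F1 2tp/(2tp+fp+fn) are kept at full precision internally and rounded to two
decimals only at serialisation; a metric with a zero denominator is
reported as NA, never 0 (reporting 0 would silently inflate apparent
specificity for absent classes). The ROC curve groups tied scores into
single threshold steps, which makes the trapezoidal AUC equal the
Mann–Whitney pairwise-ranking probability with half credit for ties — an
identity the tests check to 1e-12 against explicit pair enumeration.

## Synthetic phantoms

`bladnet.phantom` generates an ellipsoidal "brain" of baseline uptake 1.0
on a 160×160×96 grid at 1.5 mm isotropic spacing. Stage is encoded as
multiplicative uptake reduction inside fixed ellipsoidal regions: bilateral
parieto-temporal, a posterior-cingulate-like midline region, and a frontal
region involved only at the most advanced stage of each class set.
Default severities are MCI 0.15 / AD 0.30 and EMCI 0.10 / LMCI 0.20, chosen
once as a graded, configurable ground truth; they are declared tunables,
not estimates of real effect sizes. The volume is smoothed with a Gaussian
kernel of 8 mm FWHM (σ = FWHM / (2√(2 ln 2) · voxel size)), Gaussian noise
(σ = 0.03) is added and clipped at zero to preserve non-negativity, and a
fixed number of axial end slices (default 2 per side) is forced to zero so
end-trimming is exercised. With these defaults the between-stage severity
step (0.15 three-class, 0.10 two-class) is 5× and 3.3× the noise σ.

What the phantoms do *not* model: anatomy (no atlas, no gyri, no
ventricles), scanner point-spread functions, attenuation or reconstruction
artifacts, inter-subject anatomical variability, or label noise. Passing
the end-to-end tests therefore demonstrates that the pipeline's mechanics —
grouping, feature isolation, closed-form fitting, incremental growth,
split hygiene — work and that it can recover a spatially structured,
stage-graded metabolic signal from noise; it says nothing about accuracy on
clinical data.

Phantoms can be written to NIfTI with a manifest CSV, or addressed by
virtual `phantom:<label>:<seed>` manifest paths resolved on demand, which
lets whole-dataset runs stream volumes without touching disk.

## Problem sizes and numerical choices

- Whole-pipeline defaults resample volumes in-plane to 48×48 (keeping all
  96 slices so trimming and grouping behave exactly as on the full grid)
  and train the CNN for 6 epochs. These defaults were chosen so a complete
  150-study experiment — generation, preprocessing, CNN training, EBLS fit,
  evaluation — runs in about a minute on one CPU core; the full 160×160
  in-plane grid remains the preprocessing module's own default and is what
  the slice-count worked example uses.
- Trilinear resampling places sample points endpoint-aligned
  (`np.linspace(0, n−1, target)`), so constant and linear profiles are
  reproduced exactly and interpolation can never overshoot; spacing is
  rescaled to preserve physical extent.
- Min–max normalisation of a constant volume returns all zeros
  (denominator guard) so the operation is total.
- Batch pseudoinverse and ridge solves delegate to `numpy.linalg.pinv` and
  `scipy.linalg.solve`; every cached pseudoinverse satisfies the four
  Moore–Penrose conditions to 1e-8 on well-conditioned fixtures (tested).
- Model checkpoints are HDF5 written with `track_times=False`, making
  artifacts byte-deterministic; the no-leakage test exploits this by
  asserting bit-identical files when the test split is permuted.
- All randomness flows through explicitly threaded integer seeds
  (`numpy.random.default_rng`); per-phantom and per-block seeds are derived
  from the master seed, never from global state.

## Known limitations

- The EBLS head stores A and A⁺ densely; memory grows as
  O(n_samples × n_columns). Adequate for thousands of studies, not for
  millions.
- The incremental path assumes the pseudoinverse (λ→0) solution; exact
  positive-λ equivalence is obtained by closed-form recomputation, not by
  an incremental ridge update.
- `add_block` requires the cached training features (blocks map the
  original X), so models must be grown from their own training context or
  a checkpoint that includes it.
- Stage-1 training is full-batch-shuffled mini-batch SGD on CPU; no
  augmentation, early stopping or validation-based tuning is built in.
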