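# Methods

`mvhic` enhances low-coverage Hi-C contact matrices with a conditional
denoising diffusion model operating on a five-channel stack of
chromatin-feature views, and evaluates the result with HiCCUPS-style loop
calling and convergent-CTCF validation. This note records the model, the
constants that matter, and the design choices made where the design was
genuinely open.

## Problem setting

For a chromosome binned at resolution Δ (default 10 kb), a contact matrix
X ∈ ℕ^(n×n) counts read pairs between bin pairs. Given a low-coverage
matrix X with γ-fold fewer reads than a high-coverage matrix Y (default
γ = 16), the task is to predict Y from X. Enhancement is restricted to the
near-diagonal band |i − j| ≤ 200 bins (2 Mb), cut into non-overlapping
40 × 40 tiles whose full extent lies inside the band; almost all
biologically interpretable focal structure (loops, domain corners) lives
there. Bins are 0-based and half-open: bin i covers [iΔ, (i+1)Δ).

Preprocessing clamps the high-coverage matrix to [0, 255] and the
low-coverage matrix to [0, 100], then rescales each to [0, 1]. Both caps
are configurable. Normalization is applied per chromosome before tiling
(flag to swap), so derived views see whole-chromosome context.

## Multiview stack

Each matrix is expanded into five aligned channels, all computed from the
same coverage level (the low stack is a pure function of X — no leakage
from Y into the inputs):

1. **primary** — the clamp-normalized matrix.
2. **O/E** — counts divided by the mean count at the same distance
   (computed over bins with nonzero marginals), clipped at 4.0. Removes
   the dominant distance decay.
3. **TAD insulation** — per-bin insulation score IS(i), the mean count in
   the square window [i−w, i) × (i, i+w] with w = 50 bins (500 kb),
   log2-normalized by the chromosome-mean IS and broadcast to 2-D as the
   anchor mean (ISnorm(i) + ISnorm(j))/2. The anchor-mean encoding is
   symmetric and pixel-aligned with the other channels; boundary bins
   without a full window contribute 0.
4. **loop-p** — min(−log10 p_donut, 10)/10, the donut-kernel Poisson
   significance (below). The −log10 transform with cap 10 keeps the
   channel in [0, 1]; raw p-values are numerically degenerate near 0.
5. **loop-r** — min(ratio_donut, 4)/4, the donut enrichment ratio.

Channel order is fixed; ablation modes keep the primary channel only, or
feed all five in while predicting the primary channel only.

## Loop statistics and calling

Every banded pixel with w < j − i ≤ 200 whose kernel footprint fits inside
the matrix is tested against four local background estimates in the
HiCCUPS geometry (peak radius p = 2, outer radius w = 5 at 10 kb): donut
annulus (minus peak square and the row/column cross), lower-left quadrant,
and horizontal/vertical stripes. For kernel k,

    λ_k(i,j) = E[|i−j|] · Σ_footprint O / Σ_footprint E,

ratio_k = O(i,j)/λ_k, and p_k = P(Poisson(λ_k) ≥ O(i,j)). Zero-marginal
bins are masked; pixels whose footprint leaves the matrix are skipped.
Statistics require count-scale input; generated (normalized) matrices are
rescaled by the cap (×255) and rounded first, since the Poisson model
needs counts.

A pixel is called a loop when every kernel clears its enrichment threshold
(donut and lower-left > 1.75, stripes > 1.5) *and* every kernel's p-value
is significant. Significance defaults to Benjamini–Hochberg at q = 0.1
applied within λ-chunks (geometric bins of width 2^(1/3)), the correction
used by the original HiCCUPS implementation. A raw per-pixel p < 0.1 mode
is available (`fdr_q=None`). The λ-chunked correction is the default
because raw per-pixel thresholds are only meaningful on very deep maps: at
moderate depth the Poisson discreteness at small λ lets {p < 0.1, ratio >
1.75} fire on up to a few percent of null pixels, which floods any
moderate-depth matrix with false calls; the chunked correction adapts the
threshold to the local λ regime and keeps the null call rate near zero at
every depth. Optional 8-connected clustering merges adjacent calls to
their maximum-ratio pixel.

## Two-stage view weighting

The channels have very different scales, so a weight vector ω ∈ ℝ₊⁵
multiplies both inputs and targets (and divides generated outputs).
Stage 1: ω0[c] = std(primary)/std(channel c) over the training low-coverage
stacks, making every weighted channel match the primary's standard
deviation (primary weight ≡ 1). Stage 2: after a reduced-epoch end-to-end
run with ω0 (`tuning_epochs`), per-view validation MSEs m_c refine the
weights as ω[c] = ω0[c]·sqrt(m_0/m_c), renormalized so ω[0] = 1. The
square root is chosen because scaling a channel by s scales its MSE by s²,
so this equalizes per-view difficulty to first order; the refinement is
scale-equivariant in the MSE vector.

## Conditional diffusion backbone

A T-step schedule (default: cosine ᾱ profile with offset 0.008, T = 50 at
desk scale; linear 1e-4→0.02, T = 1000 configs provided) defines the
forward chain y_t = sqrt(ᾱ_t)·y_0 + sqrt(1−ᾱ_t)·ε. The denoiser is a
small conditional convolutional network in pure numpy with hand-written
backprop: the noisy target stack is concatenated channel-wise with the
condition stack (10 input channels), passed through three 3×3
convolutions (base width 32) with FiLM time conditioning from a sinusoidal
embedding and one residual connection, plus a per-timestep scalar-gated
linear skip from y_t. Training is Adam with a half-cosine learning-rate
schedule (peak 3e-3), batch size 2, uniform t, MSE over all channels of
the stack so every view supervises the model.

Numerical choices that matter, found necessary at desk scale:

- **x0-parameterization.** The network predicts the clean stack y_0
  rather than ε (ε mode is retained as a config option). The two
  objectives are affinely related, but the ε loss weights the
  condition-driven structure by ᾱ(t) — nearly zero at the high-noise steps
  where the reverse chain must first establish structure. At this budget
  the ε model provably knows the structure (teacher-forced predictions are
  near-exact) yet loses it in free-running generation; the x0 objective
  (equivalently, the SNR-reweighted ε loss) preserves it.
- **Unit-scale standardization.** Weighted stacks have standard deviation
  ≪ 1 while the diffusion noise is N(0, 1); a single global scalar brings
  the training targets (and condition) to unit standard deviation and is
  inverted after sampling. Channel-relative weighting is untouched. The
  scalar is recorded in the run manifest and checkpoint.
- **x0 clipping.** During ancestral sampling the implied clean stack is
  clipped to the training-data range each step (the standard DDPM
  stabilization); without it the 1/sqrt(ᾱ) factor near t = T amplifies
  model error unboundedly (measured ~35× MSE inflation).

Sampling is ancestral with the standard posterior variance
β_t(1−ᾱ_{t−1})/(1−ᾱ_t); a deterministic variant (posterior noise zeroed)
is available. After sampling, outputs are divided by the data scale,
un-weighted by ω, and all channels except the primary are discarded; the
primary tile is clipped to [0, 1] and tiles are reassembled into a
symmetric banded matrix.

## Evaluation

MSE is reported per banded pixel (a mean, not a sum, so tile counts do not
change the scale); for enhanced maps the mean runs over the tiled
coverage region, identically for the method and the baseline. The
low-coverage baseline is the low map scaled by γ = 16 and clamp-normalized
with the high cap.

Loop F1 uses set-membership matching with a closed ±5-bin square: a
predicted loop is a true positive if any truth loop falls in its window
(one truth loop may validate several predictions), a truth loop with no
prediction in range is a false negative, and F1 = TP/(TP + (FP+FN)/2).
Matching is deliberately not symmetric in its arguments; a strict
one-to-one mode exists behind a flag.

## CTCF validation

A called loop is *peak-associated* when both anchor windows — the anchor
bin, symmetrically expanded to at least 15 kb — overlap at least one
ChIP-seq peak from **each** of CTCF, SMC3 and RAD21 (any replicate
satisfies a factor). Each anchor of a peak-associated loop is assigned the
highest-scoring CTCF motif (FIMO-style table, p ≤ 1e-4) within a 10 kb
region (ties break to the leftmost start), and the loop is *validated*
when the left-anchor motif is on + and the right-anchor motif on −
(convergent, inward-facing). The per-anchor window reading (rather than
searching the whole [i, j] span) follows the established loop-validation
protocol; a `span` mode is provided. Intervals are BED semantics (0-based
half-open); FIMO coordinates are converted from 1-based inclusive on load.

## Synthetic data

The generator emulates the features the method exploits — distance decay,
domains, focal loops, count noise, coverage thinning — with planted ground
truth. The Poisson intensity is

    λ(i,j) = s · (1+d)^(−1) · tad(i,j) · (1 + 4·exp(−r²/2)),

band-limited at 2 Mb, with s set so the expected upper-triangle total is
`depth` = 1e6 reads over 400 bins. Defaults: decay exponent 1.0 (the
qualitative Hi-C diagonal dominance); 1 Mb domains (multiplier 1.2 within,
0.6 across, the average human TAD scale); ten 5-fold Gaussian loops of
σ = 1 bin planted at anchor spans of 15–100 bins (150 kb–1 Mb, where real
chromatin-loop spans concentrate; spans much beyond 1 Mb leave ~1 read of
evidence in a 1/16-coverage map and make enhancement ill-posed); loops are
pairwise separated by ≥15 bins and anchor bins are distinct, so the
planted convergent/divergent motif labels are unambiguous. The
high-coverage map is a Poisson draw; the low map is binomial thinning at
1/16. Matched annotations place CTCF/SMC3/RAD21 peaks at every anchor,
planted motifs (convergent (+,−) or divergent (−,+)) that outscore
scattered decoys, and configurable decoy densities.

What the generator does **not** emulate: A/B compartment checkerboards,
mappability artifacts, copy-number variation, KR/ICE balancing biases,
polymer-physics correlations beyond the multiplicative TAD/loop structure,
and shared anchors between loops. Passing tests therefore show the
machinery is correct and the method recovers planted structure under
realistic counting noise — not that real-data performance numbers are
reproduced.

## Problem sizes

The default end-to-end run trains on 200 tile pairs (five 400-bin training
chromosomes), tunes ω on one validation chromosome, and tests on one
held-out chromosome, with T = 50, width 32, 10 epochs — a desk-scale
configuration that completes in a few minutes on one CPU and leaves a
clear margin over the low-coverage baseline in both MSE and loop F1.
Full-scale configs (T = 1000, linear schedule) are provided but not
exercised by the test suite.

## Known limitations

- The numpy backbone is intentionally small; it demonstrates the method
  end to end but is not a GPU-scale generative model, and generated maps
  still shrink weak long-range enrichments toward the conditional mean.
- The loop caller is pixel-level; it does not reproduce centroid
  clustering or multi-resolution merging of production HiCCUPS.
- Real-data I/O covers dense and sparse-COO NPZ; multi-resolution cooler
  stores are out of scope.
- The CTCF module consumes motif tables; it does not run a motif scanner.
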