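# Methods

This note documents the models, the analysis pipeline, the numerical
choices behind them, and what the synthetic benchmarks do and do not
demonstrate.

## Generative circuit model

**Stimulus.** Binary white-noise checkers: every pixel independently
black (−0.5) or white (+0.5) per frame. Frame duration defaults to
10 ms; the value is a free parameter of the simulator (the analysis only
sees frames and spike times). A spatially correlated Gaussian surrogate
(i.i.d. field smoothed with an isotropic Gaussian of σ =
`correlation_length` pixels, per-frame min–max rescaled to [−0.5, 0.5])
stands in for natural-image patches when a stimulus with realistic
spatial correlations is wanted; it reproduces second-order spatial
statistics only — no phase structure, edges or objects.

**Layer-1 cells (LNP).** Space–time separable filter k = spatial ⊗
temporal. Temporal kernel: difference of two raised-power lobes,
k_t(τ) = −[(τ/τ₁)ⁿ e^{n(1−τ/τ₁)} − b (τ/τ₂)ⁿ e^{n(1−τ/τ₂)}] with n = 4,
τ₁ = 40 ms, τ₂ = 80 ms, b = 0.5, sampled at 15 lags of 10 ms and
L2-normalized — a biphasic shape with a negative dominant lobe. Spatial
filters are 2×2 pixel blocks on an 8×8 grid, non-negative for OFF cells
and non-positive for ON cells, so the full filter is negative for OFF
and positive for ON. Firing: rate = gain · max(0, k∗s(t)) spikes per
frame, Poisson counts, spike times uniform within the frame (a
deterministic frame-midpoint mode exists for exact-reproducibility
tests). Gains are set per preset so layer-1 cells fire `lnp_rate` = 0.2
expected spikes/frame (20 Hz): since the white-noise generator signal
has unit variance by construction, gain = lnp_rate·√(2π).

**Deeper cells (LIF).** τ_m dV/dt = −(V − V_rest) + R·I(t) + V_noise,
with τ_m = 10 ms, R = 1, V_rest = V_reset = 0 mV, Gaussian noise of
0.02 mV per step, 2 ms refractory, Euler integration at dt = 1 ms
(τ_m = τ₀ = 10 ms make the 1-ms Euler error negligible at the tested
tolerances; the constant-drive interspike interval matches the closed
form within 2·dt). Each presynaptic spike injects a current
A e^{−Δt/τ₀} (A = 1, τ₀ = 10 ms) scaled by the synaptic weight; weights
are 1 except where a scenario specifies otherwise. LIF-to-LIF edges —
feedforward, recurrent or feedback alike — deliver with a one-step
(1 ms) delay, which keeps the joint update explicit and causal even for
cyclic edges; currents from precomputed LNP trains enter at the step
containing the spike.

**Operating point.** The firing thresholds of downstream cells are the
one genuinely free design choice, and they matter. Each preset sets
per-layer thresholds (1.3–2.2 mV) such that every LIF cell sits below
threshold on average and fires at ~5–40 Hz on presynaptic bursts. Two
failure modes bracket this regime: with thresholds far below the
synaptic drive the cell fires tonically and its spikes carry almost no
stimulus information (subunit recovery collapses); with thresholds far
above it the cell becomes a coincidence detector whose spike
probability grows faster than linearly with synaptic weight, which
biases the recovered weights toward the strong synapses (measured:
~11% worst-case weight bias at 2.5 mV vs ~2–5% at 1.4 mV in the
four-cell circuit, with module recovery equal). The defaults sit where
the weight transfer is close to linear. The four-layer preset gives its
single deep edge weight 3: a lone weight-1 afferent cannot drive a LIF
cell over any workable threshold (its peak depolarization is A·e⁻¹).

## Analysis pipeline

**Ensemble and STA.** A spike at time t is attributed to frame
⌊t/frame_duration⌋; its segment is the L = 15 most recent frames
(spikes without full history are dropped and counted). The STA is the
ensemble mean; SVD of the lag × pixel matrix yields the temporal and
spatial components, signed so the temporal dominant lobe is negative,
plus a separability index σ₁²/Σσ².

**Degeneracy and the complex-cell fallback.** The STA is flagged
degenerate when max|STA| < 5·(0.5/√N), the standard error of a binary
stimulus mean — the situation of a complex cell, whose polarity-opposed
inputs cancel the average. Collapse weights then come from
spike-triggered second-order *products*: same-lag neighboring-pixel
products estimate the filter's energy per lag (~k_t²), and adjacent-lag
same-pixel products estimate k_t(τ)k_t(τ+1), fixing the relative signs.
Note the per-pixel variance itself carries no information for binary
stimuli — (±0.5)² is constant under any conditioning — which is why
products across pixels/lags are used.

**Collapse sign convention.** Effective images are produced with the
*positive-dominant* copy of the temporal vector. With the field's
negative-dominant filter convention this makes effective images
negative over an OFF cell's receptive field and positive over an ON
cell's, which is exactly what the downstream row-extremum rules
(minimum → OFF spike, maximum → ON spike) assume.

**Sparse semi-NMF.** Objective
F = (1/N)‖S − WM‖²_F + λ Σⱼ‖Mⱼ‖₁², λ = 0.1, with W free-sign and M ≥ 0.
Two normalizations make this well-posed. The fit is averaged over
spikes so λ is independent of the recording length (the convention
scikit-learn uses to scale its NMF regularizers). The rows of M are
kept at unit L2 norm with scale folded into W: without that constraint
the penalty can be evaded entirely by shrinking M and growing W. Under
unit rows the squared column-L1 penalty equals K plus twice the
pairwise overlap of the modules, i.e. it penalizes modules claiming the
same pixels — this is what selects the localized, disjoint
receptive-field basis among the continuum of rotations of WM with equal
fit. Optimization alternates an exact ridge-stabilized least-squares
step in W (ridge 1e−8) with exact coordinate-wise minimization of each
row of M (closed form including the sparsity term) followed by row
renormalization; a row whose exact update is zero is left unchanged.
Every step solves its subproblem exactly, so the objective trace is
non-increasing. Convergence: relative change < 1e−7 over a 10-iteration
window, max 500 iterations. Epsilon floors of 1e−12 guard
denominators.

**Initialization and the growth scheme.** Effective images of strongly
driven spikes lie near single-subunit directions, so the init clusters
the directions of rank-(K+1)-denoised, mean-centered rows (k-means on
the unit sphere, top-40%-energy rows, ≤30 000 subsampled rows) and
takes |cluster means| as modules. Requesting K far above the true
source count fragments this clustering, and converged modules then
split single receptive fields into disjoint halves — a failure the
overlap penalty cannot see and the objective barely distinguishes. The
solver therefore works in two phases: `n_restarts` (default 5) seeded
runs optimize a *base* of min(K, 8) modules and the lowest-objective
base wins — the restarts cycle four init variants (row-energy cut
0.3–0.6, denoising rank K+1 to K+3) so that their failure modes are not
correlated; the base is then grown to K in rungs of ≤8 modules seeded by
clustering the residual rows, with already-converged modules frozen.
The set of recovered sources is thus independent of K by construction;
excess modules settle on noise. For circuits expected to contain many
more than 8 subunits, raise `base_K` (the 16-cell benchmark uses
base_K = 16).

**Module significance.** A module is meaningful iff its Moran's I
(rook adjacency) exceeds the 99th percentile of 1000 pixel-permutation
nulls. The level is per-module and deliberately *not* corrected by K: a
K-dependent threshold would flip borderline modules between runs with
different K, breaking the K-independence just established; at the K
values used the expected false-positive count is ~0.1–0.2 modules.

**Dissection.** Synaptic weight of module j = mean of W column j
(magnitude, up to the common scale removed by mean-rescaling when
compared to ground truth). Spike assignment: all-OFF circuits use the
row minimum; mixed circuits compare |min| with max per row; the dual
mode collects both extrema per row, yielding 2n trains for n
polarity-paired subunits. Inferred presynaptic spike *times* are the
postsynaptic times relabeled — no latency deconvolution; the 10-ms
correlation bin absorbs the integrate-and-fire lag. Module polarity:
sign of the summed row-dominant extreme weights per module (negative →
OFF). Middle layers are recovered by pooling (sorted, deduplicated
union) the member subunit trains. Per-subunit temporal filters and
nonlinearities come from the STA of the assigned train and a
20-bin ±4 sd ratio histogram rate·P(g|spike)/P(g); fewer than 50
assigned spikes sets a low-confidence flag.

**Evaluation.** Correlation: Pearson on binned counts, one stimulus
frame per bin (zero-variance trains give 0 with a warning). Mutual
information: projection s_k histogrammed at 0.1 sd bin width; plug-in
MI on spike subsets of 80–100% (step 5%, 3 random subsets averaged,
full set once); straight-line extrapolation of MI against 1/n_spikes to
the infinite-data intercept. Subunit counting: Hungarian assignment on
|cosine| between |true RFs| and modules; "recovered" means a meaningful
module matched at cosine ≥ 0.8 (0.7/0.9 shift counts by at most one
cell in the tested scenarios).

## Benchmark sizes

The scenario tests use 50k–200k frames (8–33 minutes of simulated
recording): 100k for the four-cell circuit, 200k for the three-layer,
complex-cell and recurrence/feedback variants, 50k–120k for the
five-seed attribution sweeps. These sizes put every analyzed cell at
several thousand usable spikes.

## What the synthetic benchmarks show — and don't

The generator and the analysis share no code path (the analysis never
reads the network spec), but the benchmarks are still idealized: exact
LNP/LIF dynamics, rank-1 filters, non-overlapping 2×2 receptive fields,
binary white noise, stationary gains, no adaptation, no correlated
noise across cells. Passing them shows the inference machinery is
correct and robust in its intended regime, not that it will resolve
subunits in arbitrary recordings. Known limitations: heavily
overlapping receptive fields (the dedicated overlap preset) and the
four-layer cascade are only partially recovered — deep, diluted signals
are where the method degrades first; the natural-image surrogate tests
robustness to spatial correlation, not to natural-scene structure; and
recovered synaptic weights are meaningful up to a common scale only.
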