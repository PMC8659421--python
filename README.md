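# stnmflab

Simulation and dissection of layered spiking visual circuits with
spike-triggered non-negative matrix factorization (STNMF).

A downstream neuron — an LGN relay cell, a V1 simple or complex cell —
emits spikes that mix the activity of several presynaptic cells, each
with its own receptive field. Given only the downstream spike train and
the stimulus movie, `stnmflab` recovers that hidden presynaptic
structure: the subunit receptive fields, the synaptic weights, each
presynaptic cell's spike train, and ON/OFF polarities. The package is
aimed at computational and systems neuroscientists who want to study or
extend subunit-recovery methods on fully known ground-truth circuits,
and at experimentalists who want to run the same analysis on recorded
spike trains.

## The method

For every output spike at time *t*ᵢ the preceding stimulus segment
*s*(τ)ⁱ = *s*(*t*ᵢ − τ), τ = 0…L−1 frames, is collected. Averaging the
ensemble gives the spike-triggered average (STA); its rank-1 SVD
separates a temporal filter *k*ₜ and a spatial receptive field. Each
segment is then collapsed over time into an *effective stimulus image*
s̄ᵢ = Σ_τ *k*ₜ(τ) *s*(τ)ⁱ, and the N × P matrix S of effective images
(one row per spike, one column per pixel) is factorized as

    S ≈ W M,   minimize  (1/N)‖S − WM‖²_F + λ Σⱼ ‖Mⱼ‖₁²,   λ = 0.1,

with free-sign weights W (N × K) and non-negative modules M (K × P,
unit-norm rows; Mⱼ is the j-th pixel column). Each module, reshaped to
the stimulus grid, is one presynaptic cell's spatial receptive field.
The weight matrix is read twice: column averages estimate the synaptic
weights, and each row's extreme entry attributes that spike to one
presynaptic cell (minimum → OFF cell, maximum → ON cell). Inference
quality is scored by spike-train correlation matrices and by per-spike
mutual information MI_k = ∫ ds P(s_k|spk) log₂ [P(s_k|spk)/P(s_k)]
with finite-sampling bias removed by subsampling and extrapolation.

The generative side simulates the same circuits the analysis is tested
on: layer-1 cells are linear–nonlinear–Poisson units (rate
∝ ⌊k∗s(t)⌋₊), deeper cells are leaky integrate-and-fire neurons
(τ_m dV/dt = −(V−V_rest) + RI + V_noise) driven by exponentially
decaying synaptic currents A e^{−Δt/τ₀}, wired in presets that cover
shared afferents, three and four layers, mixed ON/OFF populations, a
complex cell, overlapping receptive fields, and weak recurrent or
feedback edges.

## Worked example

```bash
python examples/02_stnmf_subunit_recovery.py
```

```
22440 relay spikes factorized into 4 modules
matched cosine per ganglion cell: [0.98  0.987 0.961 0.953]
recovered weights (mean-rescaled): [2.065 1.503 1.802 1.23 ]
ground-truth weights:              [2.  1.5 1.8 1.3]
```

Four retinal ganglion cells with synaptic weights [2, 1.5, 1.8, 1.3]
drive one relay cell; from the relay spikes alone, STNMF returns four
modules that match the true receptive fields at cosine ≥ 0.95 and a
weight vector within a few percent of the ground truth. The other
examples show spike attribution (`03`), complex-cell dissection with a
blank STA (`04`), and bias-corrected mutual information (`05`).

A thin CLI wraps the same pipeline:

```bash
stnmflab reproduce fig3 --frames 200000 --seed 1   # full scenario bundle
stnmflab simulate --preset fig1 --frames 50000     # stimulus + spikes only
stnmflab stnmf stimulus.h5 spikes.txt lgn --k 4    # analyze a recording
```

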