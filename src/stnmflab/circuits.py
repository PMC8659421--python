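"""Layered feedforward spiking circuits: LNP input cells and LIF readouts.

Layer 1 cells are linear-nonlinear-Poisson (LNP) units: a space-time
separable receptive-field filter k = spatial (x) temporal, a half-wave
rectifier f, and Poisson spike generation with rate gain * f(k * s(t)).
All deeper cells are leaky integrate-and-fire (LIF) neurons,

    tau_m dV/dt = -(V - V_rest) + R I(t) + V_noise,

driven by exponentially decaying synaptic currents
I_syn(t) = A exp(-(t - t_spk)/tau0) for t >= t_spk, summed over afferent
spikes with per-synapse weights. The polarity convention follows the
retina: temporal filters have a negative dominant lobe, OFF cells carry
non-negative spatial filters (full filter negative) and ON cells
non-positive ones (full filter positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .stimulus import StimulusMovie

__all__ = [
    "SpatioTemporalFilter",
    "biphasic_temporal_filter",
    "block_spatial_filter",
    "LNPCell",
    "LIFParams",
    "SynapseSpec",
    "NetworkSpec",
    "SpikeTrain",
    "lnp_generator_signal",
    "lnp_spikes",
    "alpha_current",
    "simulate_lif",
    "simulate_network",
    "save_spike_trains",
    "load_spike_trains",
]


def biphasic_temporal_filter(
    n_lags: int = 15,
    lag_step: float = 10.0,
    tau1: float = 40.0,
    tau2: float = 80.0,
    n: int = 4,
    b: float = 0.5,
) -> np.ndarray:
    """Biphasic temporal kernel with a negative dominant (recent) lobe.

    k_t(tau) = -[(tau/tau1)^n e^{n(1-tau/tau1)} - b (tau/tau2)^n e^{n(1-tau/tau2)}]
    sampled at lags tau = (j + 1) * lag_step, j = 0..n_lags-1 (most recent
    first), normalized to unit L2 norm.
    """
    tau = (np.arange(n_lags) + 1.0) * lag_step
    lobe = lambda t0: (tau / t0) ** n * np.exp(n * (1.0 - tau / t0))
    k = -(lobe(tau1) - b * lobe(tau2))
    return k / np.linalg.norm(k)


def block_spatial_filter(
    grid: tuple[int, int], top_left: tuple[int, int], block: tuple[int, int] = (2, 2)
) -> np.ndarray:
    """Spatial filter that is 1 on a rectangular block of pixels, 0 elsewhere."""
    h, w = grid
    r, c = top_left
    br, bc = block
    if r < 0 or c < 0 or r + br > h or c + bc > w:
        raise ValueError(f"block {block} at {top_left} does not fit grid {grid}")
    spatial = np.zeros(grid)
    spatial[r : r + br, c : c + bc] = 1.0
    return spatial


@dataclass
class SpatioTemporalFilter:
    """Rank-1 receptive-field filter: full kernel = spatial (x) temporal.

    ``spatial`` holds non-negative entries for OFF cells and non-positive
    ones for ON cells; ``temporal`` must have a negative dominant lobe.
    """

    spatial: np.ndarray
    temporal: np.ndarray
    polarity: str = "OFF"

    def __post_init__(self) -> None:
        self.spatial = np.asarray(self.spatial, dtype=float)
        self.temporal = np.asarray(self.temporal, dtype=float)
        if self.spatial.ndim != 2 or self.temporal.ndim != 1:
            raise ValueError("spatial must be 2-D, temporal 1-D")
        if self.polarity not in ("ON", "OFF"):
            raise ValueError(f"polarity must be ON or OFF, got {self.polarity!r}")
        dom = self.temporal[np.argmax(np.abs(self.temporal))]
        if dom > 0:
            raise ValueError("temporal filter must have a negative dominant lobe")
        if self.polarity == "OFF" and self.spatial.min() < 0:
            raise ValueError("OFF cell spatial filter must be non-negative")
        if self.polarity == "ON" and self.spatial.max() > 0:
            raise ValueError("ON cell spatial filter must be non-positive")

    @property
    def n_lags(self) -> int:
        return len(self.temporal)

    def full(self) -> np.ndarray:
        """The L x H x W spatiotemporal kernel, most recent lag first."""
        return self.temporal[:, None, None] * self.spatial[None, :, :]


@dataclass
class LNPCell:
    id: str
    filter: SpatioTemporalFilter
    gain: float = 1.0  # expected spikes per frame per unit rectified generator

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass
class LIFParams:
    """Leaky integrate-and-fire membrane parameters (mV, ms)."""

    id: str = "lif"
    tau_m: float = 10.0
    R: float = 1.0
    V_rest: float = 0.0
    V_thresh: float = 1.0
    V_reset: float = 0.0
    noise_sd: float = 0.02
    refractory: float = 2.0

    def __post_init__(self) -> None:
        if self.V_thresh <= self.V_rest:
            raise ValueError("V_thresh must exceed V_rest")
        if self.tau_m <= 0 or self.noise_sd < 0:
            raise ValueError("tau_m must be > 0 and noise_sd >= 0")


@dataclass
class SynapseSpec:
    pre_id: str
    post_id: str
    weight: float = 1.0
    A: float = 1.0
    tau0: float = 10.0
    kind: str = "feedforward"  # feedforward | recurrent | feedback

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.A <= 0:
            raise ValueError("tau0 and A must be positive")
        if not np.isfinite(self.weight):
            raise ValueError("weight must be finite")
        if self.kind not in ("feedforward", "recurrent", "feedback"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")


@dataclass
class NetworkSpec:
    """Layered network: layer 1 is LNP, deeper layers are LIF.

    ``layers`` lists cell ids per layer; ``cells`` maps id to an LNPCell or
    LIFParams; ``synapses`` hold the weighted edges. The feedforward graph
    (edges of kind 'feedforward') must be acyclic; recurrent/feedback edges
    are simulated with a one-step transmission delay.
    """

    layers: list[list[str]]
    cells: dict[str, object]
    synapses: list[SynapseSpec]
    dt: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        ids = [cid for layer in self.layers for cid in layer]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell ids across layers")
        for cid in self.layers[0]:
            if not isinstance(self.cells[cid], LNPCell):
                raise ValueError(f"layer-1 cell {cid} must be an LNPCell")
        for layer in self.layers[1:]:
            for cid in layer:
                if not isinstance(self.cells[cid], LIFParams):
                    raise ValueError(f"downstream cell {cid} must be LIFParams")
        for syn in self.synapses:
            for end in (syn.pre_id, syn.post_id):
                if end not in self.cells:
                    raise ValueError(f"synapse endpoint {end!r} does not exist")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        ff = [(s.pre_id, s.post_id) for s in self.synapses if s.kind == "feedforward"]
        adj: dict[str, list[str]] = {}
        for a, b in ff:
            adj.setdefault(a, []).append(b)
        state: dict[str, int] = {}

        def visit(u: str) -> None:
            state[u] = 1
            for v in adj.get(u, ()):
                if state.get(v) == 1:
                    raise ValueError(f"feedforward graph contains a cycle through {v!r}")
                if v not in state:
                    visit(v)
            state[u] = 2

        for node in list(adj):
            if node not in state:
                visit(node)

    @property
    def lnp_ids(self) -> list[str]:
        return list(self.layers[0])

    @property
    def lif_ids(self) -> list[str]:
        return [cid for layer in self.layers[1:] for cid in layer]


@dataclass
class SpikeTrain:
    """Sorted spike times (ms) of one cell over [0, duration)."""

    cell_id: str
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return self.n_spikes / (self.duration / 1000.0)


# ---------------------------------------------------------------------------
# LNP stage
# ---------------------------------------------------------------------------


def lnp_generator_signal(cell: LNPCell, movie: StimulusMovie) -> np.ndarray:
    """Per-frame generator g(t) = sum_tau sum_px spatial * temporal(tau) * s(t-tau).

    Frames t < L-1 lack full filter history and are returned as NaN.
    """
    filt = cell.filter
    if filt.spatial.shape != movie.frames.shape[1:]:
        raise ValueError(
            f"filter grid {filt.spatial.shape} does not match movie grid {movie.frames.shape[1:]}"
        )
    L = filt.n_lags
    if L > movie.n_frames:
        raise ValueError(f"filter needs {L} frames of history, movie has {movie.n_frames}")
    # spatial projection per frame, then temporal correlation over lags
    proj = np.tensordot(movie.frames, filt.spatial, axes=([1, 2], [0, 1]))
    # g[t] = sum_tau temporal[tau] * proj[t - tau]; 'valid' part starts at t = L-1
    valid = np.convolve(proj, filt.temporal, mode="full")[L - 1 : movie.n_frames]
    g = np.full(movie.n_frames, np.nan)
    g[L - 1 :] = valid
    return g


def lnp_spikes(
    cell: LNPCell,
    movie: StimulusMovie,
    seed: int = 0,
    spike_placement: str = "uniform",
) -> SpikeTrain:
    """Poisson spikes of one LNP cell driven by ``movie``.

    Per frame the spike count is Poisson(gain * f(g)) with f the half-wave
    rectifier; spike times fall uniformly within the frame (or at the frame
    midpoint with ``spike_placement='midpoint'``).
    """
    g = lnp_generator_signal(cell, movie)
    rate = cell.gain * np.clip(np.nan_to_num(g, nan=0.0), 0.0, None)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate)
    fd = movie.frame_duration
    times = []
    for t in np.nonzero(counts)[0]:
        c = counts[t]
        if spike_placement == "midpoint":
            offs = np.full(c, 0.5)
        else:
            offs = rng.random(c)
        times.append((t + np.sort(offs)) * fd)
    all_times = np.concatenate(times) if times else np.empty(0)
    # enforce strict ordering for coincident midpoint spikes
    all_times = np.unique(all_times)
    return SpikeTrain(cell.id, all_times, duration=movie.duration)


# ---------------------------------------------------------------------------
# Synapse and LIF stage
# ---------------------------------------------------------------------------


def alpha_current(t, spike_time: float, A: float = 1.0, tau0: float = 10.0):
    """Postsynaptic current A exp(-(t - t_spk)/tau0) for t >= t_spk, else 0."""
    t = np.asarray(t, dtype=float)
    dt = t - spike_time
    out = np.where(dt >= 0, A * np.exp(-np.clip(dt, 0, None) / tau0), 0.0)
    return out if out.ndim else float(out)


@njit(cache=True)
def _lif_step_loop(current, dt, tau_m, R, V_rest, V_thresh, V_reset, refrac_steps, noise):
    n = current.shape[0]
    V = np.empty(n)
    spikes = np.zeros(n, dtype=np.bool_)
    v = V_rest
    refrac = 0
    for i in range(n):
        if refrac > 0:
            refrac -= 1
            v = V_reset
        else:
            v = v + (dt / tau_m) * (-(v - V_rest) + R * current[i] + noise[i])
            if v >= V_thresh:
                spikes[i] = True
                v = V_reset
                refrac = refrac_steps
        V[i] = v
    return V, spikes


def simulate_lif(
    params: LIFParams,
    input_current: np.ndarray,
    dt: float = 1.0,
    seed: int = 0,
) -> tuple[SpikeTrain, np.ndarray]:
    """Euler integration of the LIF membrane equation under a given current.

    Returns the spike train (spike at step i stamped at time (i+1)*dt minus
    half a step, i.e. the end of the step) and the membrane trace. Noise is
    drawn per step with standard deviation ``params.noise_sd`` and enters
    the membrane equation like a current term.
    """
    if dt > 1.0:
        raise ValueError("dt must be <= 1 ms for acceptable Euler error")
    input_current = np.asarray(input_current, dtype=float)
    if not np.all(np.isfinite(input_current)):
        bad = int(np.flatnonzero(~np.isfinite(input_current))[0])
        raise FloatingPointError(f"non-finite input current at step {bad}")
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, params.noise_sd, size=input_current.shape[0])
        if params.noise_sd > 0
        else np.zeros(input_current.shape[0])
    )
    refrac_steps = int(round(params.refractory / dt))
    V, spikes = _lif_step_loop(
        input_current,
        dt,
        params.tau_m,
        params.R,
        params.V_rest,
        params.V_thresh,
        params.V_reset,
        refrac_steps,
        noise,
    )
    times = (np.flatnonzero(spikes) + 0.5) * dt
    train = SpikeTrain(params.id, times, duration=input_current.shape[0] * dt)
    return train, V


def _bin_spikes_to_steps(train: SpikeTrain, dt: float, n_steps: int) -> np.ndarray:
    counts = np.zeros(n_steps)
    if train.n_spikes:
        idx = np.minimum((train.times / dt).astype(np.int64), n_steps - 1)
        np.add.at(counts, idx, 1.0)
    return counts


def _exp_filter_current(counts: np.ndarray, A: float, tau0: float, dt: float) -> np.ndarray:
    """I[t] = decay * I[t-1] + A * counts[t], the step-sampled synaptic current."""
    from scipy.signal import lfilter

    decay = np.exp(-dt / tau0)
    return lfilter([A], [1.0, -decay], counts)


@njit(cache=True)
def _network_lif_loop(
    base_current,  # (n_cells, n_steps) current from precomputed (LNP) afferents
    W_ll,  # (n_cells, n_cells) LIF->LIF weight matrix, W_ll[post, pre]
    A_ll,
    decay_ll,
    dt,
    tau_m,
    R,
    V_rest,
    V_thresh,
    V_reset,
    refrac_steps,
    noise,  # (n_cells, n_steps)
):
    n_cells, n_steps = base_current.shape
    spikes = np.zeros((n_cells, n_steps), dtype=np.bool_)
    V = np.full(n_cells, V_rest[0])
    for c in range(n_cells):
        V[c] = V_rest[c]
    I_ll = np.zeros(n_cells)
    refrac = np.zeros(n_cells, dtype=np.int64)
    prev_spiked = np.zeros(n_cells)
    for t in range(n_steps):
        # decay LIF-sourced currents and inject spikes from the previous step
        for post in range(n_cells):
            inj = 0.0
            for pre in range(n_cells):
                if W_ll[post, pre] != 0.0 and prev_spiked[pre] > 0.0:
                    inj += W_ll[post, pre] * A_ll * prev_spiked[pre]
            I_ll[post] = I_ll[post] * decay_ll + inj
        for c in range(n_cells):
            if refrac[c] > 0:
                refrac[c] -= 1
                V[c] = V_reset[c]
                prev_spiked[c] = 0.0
                continue
            I_tot = base_current[c, t] + I_ll[c]
            V[c] = V[c] + (dt / tau_m[c]) * (-(V[c] - V_rest[c]) + R[c] * I_tot + noise[c, t])
            if V[c] >= V_thresh[c]:
                spikes[c, t] = True
                V[c] = V_reset[c]
                refrac[c] = refrac_steps[c]
                prev_spiked[c] = 1.0
            else:
                prev_spiked[c] = 0.0
    return spikes


def simulate_network(
    spec: NetworkSpec,
    movie: StimulusMovie,
    seed: int = 0,
    spike_placement: str = "uniform",
) -> dict[str, SpikeTrain]:
    """Simulate the full layered network and return every cell's spike train.

    Layer-1 LNP trains are generated first; all LIF cells are then
    integrated jointly at step ``spec.dt``. Currents from LNP afferents are
    injected at the step containing each spike; LIF-to-LIF synapses
    (feedforward, recurrent or feedback alike) deliver with a one-step
    delay, which keeps the update explicit and causal for cyclic edges.
    """
    dt = spec.dt
    n_steps = int(round(movie.duration / dt))
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(spec.lnp_ids) + 1)

    trains: dict[str, SpikeTrain] = {}
    lnp_counts: dict[str, np.ndarray] = {}
    for i, cid in enumerate(spec.lnp_ids):
        cell = spec.cells[cid]
        tr = lnp_spikes(
            cell, movie, seed=child_seeds[i].generate_state(1)[0], spike_placement=spike_placement
        )
        trains[cid] = tr
        lnp_counts[cid] = _bin_spikes_to_steps(tr, dt, n_steps)

    lif_ids = spec.lif_ids
    if not lif_ids:
        return trains
    lif_index = {cid: k for k, cid in enumerate(lif_ids)}
    n_lif = len(lif_ids)

    base = np.zeros((n_lif, n_steps))
    W_ll = np.zeros((n_lif, n_lif))
    tau0 = A = None
    for syn in spec.synapses:
        if syn.post_id not in lif_index:
            raise ValueError(f"synapse targets non-LIF cell {syn.post_id!r}")
        if tau0 is None:
            tau0, A = syn.tau0, syn.A
        elif (syn.tau0, syn.A) != (tau0, A):
            raise NotImplementedError("heterogeneous synaptic (A, tau0) not supported")
        if syn.pre_id in lnp_counts:
            base[lif_index[syn.post_id]] += syn.weight * _exp_filter_current(
                lnp_counts[syn.pre_id], syn.A, syn.tau0, dt
            )
        else:
            W_ll[lif_index[syn.post_id], lif_index[syn.pre_id]] += syn.weight
    if tau0 is None:
        tau0, A = 10.0, 1.0

    p = [spec.cells[cid] for cid in lif_ids]
    rng = np.random.default_rng(child_seeds[-1].generate_state(1)[0])
    noise_sd = np.array([q.noise_sd for q in p])
    noise = rng.standard_normal((n_lif, n_steps)) * noise_sd[:, None]
    spikes = _network_lif_loop(
        base,
        W_ll,
        A,
        np.exp(-dt / tau0),
        dt,
        np.array([q.tau_m for q in p]),
        np.array([q.R for q in p]),
        np.array([q.V_rest for q in p]),
        np.array([q.V_thresh for q in p]),
        np.array([q.V_reset for q in p]),
        np.array([int(round(q.refractory / dt)) for q in p], dtype=np.int64),
        noise,
    )
    for cid, row in zip(lif_ids, spikes):
        times = (np.flatnonzero(row) + 0.5) * dt
        trains[cid] = SpikeTrain(cid, times, duration=n_steps * dt)
    return trains


# ---------------------------------------------------------------------------
# Spike-train text I/O: two columns (cell_id, time_ms), sorted, with a
# header line "# duration_ms <value>".
# ---------------------------------------------------------------------------


def save_spike_trains(trains: dict[str, SpikeTrain], path: str) -> None:
    duration = max((t.duration for t in trains.values()), default=0.0)
    with open(path, "w") as f:
        f.write(f"# duration_ms {duration!r}\n")
        for cid in trains:
            for t in trains[cid].times:
                f.write(f"{cid}\t{float(t)!r}\n")


def load_spike_trains(path: str) -> dict[str, SpikeTrain]:
    duration = None
    rows: dict[str, list[float]] = {}
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "duration_ms":
                    duration = float(parts[1])
                continue
            cid, t = line.split("\t")
            rows.setdefault(cid, []).append(float(t))
    if duration is None:
        raise ValueError(f"missing '# duration_ms' header in {path}")
    return {
        cid: SpikeTrain(cid, np.sort(np.array(ts)), duration=duration) for cid, ts in rows.items()
    }
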