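"""Circuit dissection: from an STNMF result to synaptic weights,
per-presynaptic-cell spike trains, polarities, temporal filters and
nonlinearities.

The weight matrix W is read two ways. Column-wise, the mean of column j
estimates the synaptic weight of presynaptic cell j (up to the common
scale absorbed by the factorization). Row-wise, each output spike is
attributed to the presynaptic cell whose weight dominates its row: for
all-OFF circuits the row minimum (effective images are negative over an
OFF cell's receptive field), for mixed circuits the extremum of larger
magnitude — the minimum marks an OFF spike, the maximum an ON spike.
Inferred presynaptic spike times are the postsynaptic spike times
relabeled; no latency deconvolution is attempted. Middle-layer trains
are recovered by pooling the inferred input trains of each middle cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuits import SpikeTrain
from .factorize import STNMFResult
from .stimulus import StimulusMovie
from .trigger import build_ensemble, compute_sta, svd_separate

__all__ = [
    "DissectedCircuit",
    "infer_weights",
    "module_polarities",
    "assign_spikes_off",
    "assign_spikes_mixed",
    "pool_layer",
    "subunit_temporal_and_nonlinearity",
    "dissect",
]


@dataclass
class DissectedCircuit:
    """Recovered circuit structure for the meaningful STNMF modules."""

    module_indices: np.ndarray  # meaningful module indices into the STNMF result
    subunit_rfs: np.ndarray  # n_sub x H x W module images
    polarities: list[str]  # per subunit, ON or OFF
    weights: np.ndarray  # per-subunit column-average weight (signed)
    assigned_trains: dict  # key: (module_idx, polarity) -> SpikeTrain
    pooled_trains: dict | None = None
    subunit_temporal: dict | None = None  # module_idx -> L-vector
    nonlinearities: dict | None = None  # module_idx -> (bin_centers, rate)


def infer_weights(result: STNMFResult, modules: np.ndarray | None = None) -> np.ndarray:
    """Column averages of W: one signed weight per (meaningful) module.

    The magnitude estimates the synaptic weight up to a common scale; the
    sign follows the module's polarity (negative for OFF under the
    standard collapse convention).
    """
    W = result.W
    if modules is not None:
        W = W[:, np.asarray(modules, dtype=int)]
    return W.mean(axis=0)


def _dominant_extrema(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per row: (argmin, argmax, is_off) with is_off = |min| > max."""
    jmin = np.argmin(W, axis=1)
    jmax = np.argmax(W, axis=1)
    wmin = W[np.arange(len(W)), jmin]
    wmax = W[np.arange(len(W)), jmax]
    return jmin, jmax, np.abs(wmin) > wmax


def module_polarities(result: STNMFResult, modules: np.ndarray | None = None) -> list[str]:
    """Polarity per module from the sum of its row-dominant extreme weights.

    For each spike row the dominant extremum (min if |min| > max, else
    max) is attributed to its module; a module whose accumulated dominant
    weights sum negative is OFF, positive is ON. Modules never dominant
    fall back to the sign of their column mean.
    """
    cols = np.arange(result.W.shape[1]) if modules is None else np.asarray(modules, dtype=int)
    W = result.W[:, cols]
    jmin, jmax, is_off = _dominant_extrema(W)
    sums = np.zeros(W.shape[1])
    rows = np.arange(len(W))
    np.add.at(sums, jmin[is_off], W[rows[is_off], jmin[is_off]])
    np.add.at(sums, jmax[~is_off], W[rows[~is_off], jmax[~is_off]])
    out = []
    for k in range(W.shape[1]):
        s = sums[k] if sums[k] != 0 else W[:, k].mean()
        out.append("OFF" if s < 0 else "ON")
    return out


def _subset_train(train: SpikeTrain, usable_ids: np.ndarray, rows: np.ndarray, label: str) -> SpikeTrain:
    times = train.times[usable_ids[rows]]
    return SpikeTrain(label, np.sort(times), duration=train.duration)


def assign_spikes_off(result: STNMFResult, train: SpikeTrain, modules=None) -> dict[int, SpikeTrain]:
    """All-OFF rule: each spike goes to the module with the row-minimum weight.

    Ties break toward the lowest module index (argmin convention). The
    returned trains partition the usable postsynaptic spikes.
    """
    cols = np.arange(result.W.shape[1]) if modules is None else np.asarray(modules, dtype=int)
    W = result.W[:, cols]
    usable = result.spike_ids if result.spike_ids is not None else np.arange(len(W))
    jmin = np.argmin(W, axis=1)
    return {
        int(cols[k]): _subset_train(train, usable, np.flatnonzero(jmin == k), f"module{cols[k]}")
        for k in range(W.shape[1])
    }


def assign_spikes_mixed(
    result: STNMFResult,
    train: SpikeTrain,
    modules=None,
    dual: bool = False,
) -> dict[tuple[int, str], SpikeTrain]:
    """Mixed ON/OFF rule on the row extrema of W.

    Per spike row, both the minimum and maximum are found; the extremum of
    larger magnitude decides: |min| > max marks an OFF spike assigned to
    the argmin module, otherwise an ON spike assigned to the argmax
    module. With ``dual=True`` every row contributes both extrema (one
    OFF and one ON spike), the noise-tolerant variant: a circuit with n
    polarity-paired subunits then yields 2n trains.
    """
    cols = np.arange(result.W.shape[1]) if modules is None else np.asarray(modules, dtype=int)
    W = result.W[:, cols]
    usable = result.spike_ids if result.spike_ids is not None else np.arange(len(W))
    jmin, jmax, is_off = _dominant_extrema(W)
    out: dict[tuple[int, str], SpikeTrain] = {}
    for k in range(W.shape[1]):
        if dual:
            off_rows = np.flatnonzero(jmin == k)
            on_rows = np.flatnonzero(jmax == k)
        else:
            off_rows = np.flatnonzero((jmin == k) & is_off)
            on_rows = np.flatnonzero((jmax == k) & ~is_off)
        out[(int(cols[k]), "OFF")] = _subset_train(train, usable, off_rows, f"module{cols[k]}_OFF")
        out[(int(cols[k]), "ON")] = _subset_train(train, usable, on_rows, f"module{cols[k]}_ON")
    return out


def pool_layer(
    trains: dict, membership: dict[object, list], duration: float | None = None
) -> dict[object, SpikeTrain]:
    """Pool inferred subunit trains into middle-layer cell trains.

    ``membership`` maps each middle-layer cell to the keys of its member
    trains; the pooled train is the sorted, deduplicated union of the
    member spike times. Every member key must exist in ``trains``.
    """
    out = {}
    for cell, members in membership.items():
        for m in members:
            if m not in trains:
                raise KeyError(f"membership of {cell!r} names unknown train {m!r}")
        times = np.unique(np.concatenate([trains[m].times for m in members] or [np.empty(0)]))
        dur = duration or max(trains[m].duration for m in members)
        out[cell] = SpikeTrain(str(cell), times, duration=dur)
    return out


def subunit_temporal_and_nonlinearity(
    movie: StimulusMovie,
    train_assigned: SpikeTrain,
    module_image: np.ndarray,
    n_lags: int = 15,
    n_bins: int = 20,
    min_spikes: int = 50,
) -> dict:
    """Per-subunit temporal filter and static nonlinearity.

    The temporal vector is the SVD temporal component of the STA computed
    from the assigned train (its spatial component doubles as a check of
    the subunit RF). The nonlinearity is the ratio histogram
    f(g) = mean_rate * P(g | spike) / P(g) over the generator signal
    g(t) = sum_tau temporal(tau) * <module_image, s(t - tau)>, with
    ``n_bins`` bins spanning +/- 4 sd of g. Fewer than ``min_spikes``
    assigned spikes sets ``low_confidence``.
    """
    if train_assigned.n_spikes == 0:
        raise ValueError("assigned train is empty")
    ens = build_ensemble(movie, train_assigned, n_lags=n_lags)
    sta = compute_sta(ens)
    temporal, spatial, info = svd_separate(sta, noise_scale=0.5 / np.sqrt(ens.n_spikes))

    # generator signal of the candidate subunit filter
    proj = np.tensordot(movie.frames, module_image, axes=([1, 2], [0, 1]))
    g = np.convolve(proj, temporal, mode="full")[n_lags - 1 : movie.n_frames]
    valid_frames = np.arange(n_lags - 1, movie.n_frames)
    sd = g.std()
    edges = np.linspace(-4 * sd, 4 * sd, n_bins + 1)
    prior, _ = np.histogram(g, bins=edges)
    frame_idx = np.floor(train_assigned.times / movie.frame_duration).astype(np.int64)
    frame_idx = frame_idx[frame_idx >= n_lags - 1]
    cond, _ = np.histogram(g[frame_idx - (n_lags - 1)], bins=edges)
    mean_rate = train_assigned.n_spikes / (train_assigned.duration / 1000.0)  # spikes/s
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(prior > 0, cond / np.maximum(prior, 1) * (prior.sum() / max(cond.sum(), 1)), np.nan)
    rate_curve = mean_rate * ratio
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {
        "temporal": temporal,
        "spatial": spatial,
        "separability": info["separability"],
        "nonlinearity": (centers, rate_curve),
        "low_confidence": train_assigned.n_spikes < min_spikes,
    }


def dissect(
    result: STNMFResult,
    train: SpikeTrain,
    movie: StimulusMovie | None = None,
    mode: str = "auto",
    dual: bool = False,
    membership: dict | None = None,
) -> DissectedCircuit:
    """Full dissection of an STNMF result (meaningful modules only).

    ``mode``: 'off' forces the all-OFF row-minimum rule, 'mixed' the
    ON/OFF extremum rule, 'auto' picks 'off' when every module polarity
    comes out OFF. ``membership`` (middle cell -> list of module indices)
    triggers middle-layer pooling on the assigned trains.
    """
    if result.significance is None:
        from .factorize import classify_modules

        classify_modules(result)
    modules = result.meaningful()
    if modules.size == 0:
        raise ValueError("no meaningful modules to dissect")
    polar = module_polarities(result, modules)
    if mode == "auto":
        mode = "off" if all(p == "OFF" for p in polar) else "mixed"

    if mode == "off":
        per_mod = assign_spikes_off(result, train, modules)
        assigned = {(k, "OFF"): tr for k, tr in per_mod.items()}
    else:
        assigned = assign_spikes_mixed(result, train, modules, dual=dual)
        # drop empty polarity slots in single-assignment mode
        if not dual:
            assigned = {key: tr for key, tr in assigned.items() if tr.n_spikes > 0}

    weights = infer_weights(result, modules)
    imgs = result.module_images()[modules]

    pooled = None
    if membership is not None:
        merged = {}
        for k in modules:
            trs = [tr for (mk, _), tr in assigned.items() if mk == k]
            times = np.unique(np.concatenate([t.times for t in trs] or [np.empty(0)]))
            merged[int(k)] = SpikeTrain(f"module{k}", times, duration=train.duration)
        pooled = pool_layer(merged, membership, duration=train.duration)

    temporal = nonlin = None
    if movie is not None:
        temporal, nonlin = {}, {}
        for (k, pol), tr in assigned.items():
            if tr.n_spikes == 0:
                continue
            sub = subunit_temporal_and_nonlinearity(
                movie, tr, imgs[list(modules).index(k)]
            )
            temporal[(k, pol)] = sub["temporal"]
            nonlin[(k, pol)] = sub["nonlinearity"]

    return DissectedCircuit(
        module_indices=modules,
        subunit_rfs=imgs,
        polarities=polar,
        weights=weights,
        assigned_trains=assigned,
        pooled_trains=pooled,
        subunit_temporal=temporal,
        nonlinearities=nonlin,
    )
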