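"""Preset network topologies for the studied circuit scenarios.

Each preset reproduces one simulated scenario: layered feedforward
circuits from retinal ganglion cells (RGCs, LNP units on an 8x8 stimulus
grid with 2x2-pixel spatial receptive fields) through LGN to V1 (LIF
units), including variants with shared afferents, mixed ON/OFF
polarities, a complex cell, overlapping receptive fields, a fourth
layer, and weak recurrent or feedback edges.

The membrane, synapse and filter-shape parameters follow the model
definition in :mod:`stnmflab.circuits`. Poisson gains are set so layer-1
cells fire at ``lnp_rate`` expected spikes per frame under binary white
noise (the generator signal has unit variance by construction, so the
rectified mean is sd/sqrt(2*pi)); deeper cells then fire at comparable
rates with all synaptic weights at their default of 1.
"""

from __future__ import annotations

import numpy as np

from .circuits import (
    LIFParams,
    LNPCell,
    NetworkSpec,
    SpatioTemporalFilter,
    SynapseSpec,
    biphasic_temporal_filter,
    block_spatial_filter,
)

__all__ = ["preset_network", "PRESET_NAMES", "true_spatial_rfs", "true_filters"]

PRESET_NAMES = ("fig1", "fig2", "fig3", "fig5", "fig6", "fig7", "s2", "s3", "s4", "s5", "s6")

_GRID = (8, 8)
# non-overlapping 2x2 block anchors for 4- and 6-cell layouts
_BLOCKS4 = [(1, 1), (1, 5), (5, 1), (5, 5)]
_BLOCKS6 = [(1, 0), (1, 3), (1, 6), (5, 0), (5, 3), (5, 6)]
_BLOCKS16 = [(r, c) for r in (0, 2, 4, 6) for c in (0, 2, 4, 6)]
_BLOCKS4_OVERLAP = [(3, 1), (3, 2), (3, 3), (3, 4)]  # neighbors share 2 pixels

# layer-1 expected spikes/frame; chosen so every layer in the deepest
# presets fires well above the STNMF spike-count floor
_DEFAULT_LNP_RATE = 0.2

# firing thresholds (mV) per downstream layer, calibrated so each LIF cell
# sits below threshold on average and fires on presynaptic bursts at
# ~5-15 spikes/s — the fluctuation-driven regime in which output spikes
# remain attributable to individual presynaptic cells
_THRESHOLDS = {
    "fig1": (1.4,),
    "fig2": (1.4,),
    "fig3": (1.4, 0.9),
    "fig5": (1.5,),
    "fig6": (1.4, 0.9),
    "fig7": (1.4, 0.8),
    "s2": (2.2, 0.9),  # eight afferents per middle cell
    "s3": (1.3, 0.9),
    "s4": (1.4, 0.9, 0.9),
    "s5": (1.4, 0.9),
    "s6": (1.4, 0.9),
}


def _lnp(
    cid: str,
    top_left: tuple[int, int],
    polarity: str,
    temporal: np.ndarray,
    rate: float,
) -> LNPCell:
    spatial = block_spatial_filter(_GRID, top_left)
    if polarity == "ON":
        spatial = -spatial
    filt = SpatioTemporalFilter(spatial, temporal, polarity=polarity)
    # generator sd under binary white noise = 0.5 * ||spatial||_F * ||temporal||_2
    sd = 0.5 * np.linalg.norm(spatial) * np.linalg.norm(temporal)
    gain = rate * np.sqrt(2.0 * np.pi) / sd
    return LNPCell(cid, filt, gain=gain)


def _ff(pre: str, post: str, weight: float = 1.0) -> SynapseSpec:
    return SynapseSpec(pre, post, weight=weight, kind="feedforward")


def preset_network(
    name: str,
    lnp_rate: float = _DEFAULT_LNP_RATE,
    n_lags: int = 15,
    lag_step: float = 10.0,
    fig1_weights: tuple[float, ...] = (2.0, 1.5, 1.8, 1.3),
) -> NetworkSpec:
    """Build the named preset circuit.

    Parameters
    ----------
    name
        One of ``fig1 fig2 fig3 fig5 fig6 fig7 s2 s3 s4 s5 s6``.
    lnp_rate
        Target expected spikes per frame for layer-1 cells.
    n_lags, lag_step
        Temporal-filter length (frames) and frame step (ms).
    fig1_weights
        The unequal RGC->LGN synaptic weights of the minimal 4-cell model;
        all other presets use weight 1 throughout.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}")
    kt = biphasic_temporal_filter(n_lags=n_lags, lag_step=lag_step)
    thresholds = _THRESHOLDS[name]
    _depth = {}

    def lif(cid: str, depth: int = 0) -> LIFParams:
        _depth[cid] = depth
        return LIFParams(id=cid, V_thresh=thresholds[depth])

    def rgcs(blocks, polarities):
        return [
            _lnp(f"rgc{i + 1}", b, p, kt, lnp_rate)
            for i, (b, p) in enumerate(zip(blocks, polarities))
        ]

    if name == "fig1":
        cells1 = rgcs(_BLOCKS4, ["OFF"] * 4)
        layers = [[c.id for c in cells1], ["lgn"]]
        cells = {c.id: c for c in cells1} | {"lgn": lif("lgn")}
        syn = [_ff(c.id, "lgn", w) for c, w in zip(cells1, fig1_weights)]
    elif name == "fig5":
        cells1 = rgcs(_BLOCKS4, ["OFF", "ON", "OFF", "ON"])
        layers = [[c.id for c in cells1], ["lgn"]]
        cells = {c.id: c for c in cells1} | {"lgn": lif("lgn")}
        syn = [_ff(c.id, "lgn") for c in cells1]
    elif name in ("fig2", "fig3", "fig6", "s5", "s6"):
        pol = ["OFF", "ON"] * 3 if name == "fig6" else ["OFF"] * 6
        cells1 = rgcs(_BLOCKS6, pol)
        layers = [[c.id for c in cells1], ["lgn1", "lgn2"]]
        cells = {c.id: c for c in cells1} | {"lgn1": lif("lgn1"), "lgn2": lif("lgn2")}
        syn = [_ff(f"rgc{i}", "lgn1") for i in range(1, 5)]
        syn += [_ff(f"rgc{i}", "lgn2") for i in range(3, 7)]
        if name != "fig2":
            layers.append(["v1"])
            cells["v1"] = lif("v1", 1)
            syn += [_ff("lgn1", "v1"), _ff("lgn2", "v1")]
        if name == "s5":
            syn.append(SynapseSpec("v1", "lgn2", weight=0.1, kind="recurrent"))
        if name == "s6":
            syn.append(SynapseSpec("v1", "lgn1", weight=0.1, kind="feedback"))
    elif name == "fig7":
        # two quadruplets at the same four locations with opposite polarity:
        # layer-2 cells are phase-opposed simple cells, layer-3 a complex cell
        pol_a = ["OFF", "ON", "OFF", "ON"]
        pol_b = ["ON", "OFF", "ON", "OFF"]
        cells1 = rgcs(_BLOCKS4 + _BLOCKS4, pol_a + pol_b)
        layers = [[c.id for c in cells1], ["lgn1", "lgn2"], ["v1"]]
        cells = {c.id: c for c in cells1} | {
            "lgn1": lif("lgn1"),
            "lgn2": lif("lgn2"),
            "v1": lif("v1", 1),
        }
        syn = [_ff(f"rgc{i}", "lgn1") for i in range(1, 5)]
        syn += [_ff(f"rgc{i}", "lgn2") for i in range(5, 9)]
        syn += [_ff("lgn1", "v1"), _ff("lgn2", "v1")]
    elif name == "s2":
        cells1 = rgcs(_BLOCKS16, ["OFF"] * 16)
        layers = [[c.id for c in cells1], ["lgn1", "lgn2"], ["v1"]]
        cells = {c.id: c for c in cells1} | {
            "lgn1": lif("lgn1"),
            "lgn2": lif("lgn2"),
            "v1": lif("v1", 1),
        }
        syn = [_ff(f"rgc{i}", "lgn1") for i in range(1, 9)]
        syn += [_ff(f"rgc{i}", "lgn2") for i in range(9, 17)]
        syn += [_ff("lgn1", "v1"), _ff("lgn2", "v1")]
    elif name == "s3":
        cells1 = rgcs(_BLOCKS4_OVERLAP, ["OFF"] * 4)
        layers = [[c.id for c in cells1], ["lgn1", "lgn2"], ["v1"]]
        cells = {c.id: c for c in cells1} | {
            "lgn1": lif("lgn1"),
            "lgn2": lif("lgn2"),
            "v1": lif("v1", 1),
        }
        syn = [_ff(f"rgc{i}", "lgn1") for i in (1, 2, 3)]
        syn += [_ff(f"rgc{i}", "lgn2") for i in (2, 3, 4)]
        syn += [_ff("lgn1", "v1"), _ff("lgn2", "v1")]
    elif name == "s4":
        cells1 = rgcs(_BLOCKS6, ["OFF"] * 6)
        layers = [[c.id for c in cells1], ["lgn1", "lgn2"], ["v1"], ["l4"]]
        cells = {c.id: c for c in cells1} | {
            "lgn1": lif("lgn1"),
            "lgn2": lif("lgn2"),
            "v1": lif("v1", 1),
            "l4": lif("l4", 2),
        }
        syn = [_ff(f"rgc{i}", "lgn1") for i in range(1, 5)]
        syn += [_ff(f"rgc{i}", "lgn2") for i in range(3, 7)]
        syn += [_ff("lgn1", "v1"), _ff("lgn2", "v1")]
        # a lone afferent at weight 1 cannot drive a LIF cell over threshold,
        # so the single deep edge carries a compensating weight
        syn += [_ff("v1", "l4", 3.0)]
    spec = NetworkSpec(layers=layers, cells=cells, synapses=syn, dt=1.0, name=name)
    return spec


def true_filters(spec: NetworkSpec) -> dict[str, SpatioTemporalFilter]:
    """Ground-truth spatiotemporal filters of the layer-1 cells."""
    return {cid: spec.cells[cid].filter for cid in spec.lnp_ids}


def true_spatial_rfs(spec: NetworkSpec) -> dict[str, np.ndarray]:
    """Ground-truth spatial receptive fields (signed) of the layer-1 cells."""
    return {cid: spec.cells[cid].filter.spatial.copy() for cid in spec.lnp_ids}
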