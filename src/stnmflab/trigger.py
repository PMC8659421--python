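"""Spike-triggered stimulus analysis: ensemble, STA, SVD separation,
and temporal collapse into effective stimulus images.

For each output spike at time t_i the preceding stimulus segment
s(tau)^i = s(t_i - tau), tau = 0..L-1 frames, is collected into an
ensemble. Averaging over spikes yields the spike-triggered average
(STA); under white noise the STA estimates the cell's linear filter.
The STA is separated into temporal and spatial components by a rank-1
SVD, and each spike's segment is collapsed over time by weighting lags
with the temporal component, producing one effective image per spike —
the rows of the matrix S that the factorization stage decomposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STEnsemble",
    "EffectiveImages",
    "build_ensemble",
    "compute_sta",
    "svd_separate",
    "collapse_temporal",
    "effective_images",
    "quadratic_lag_profile",
    "EmptyEnsembleError",
]


class EmptyEnsembleError(ValueError):
    """No spike has enough stimulus history to form a segment."""


@dataclass
class STEnsemble:
    """Spike-triggered stimulus segments.

    ``segments[i, tau]`` is the frame shown ``tau`` frames before spike i's
    frame (lag 0 = the frame on screen at spike time). ``spike_ids`` index
    into the originating spike train; spikes whose history is shorter than
    L frames are dropped and counted in ``n_dropped``.
    """

    segments: np.ndarray  # N x L x H x W
    spike_ids: np.ndarray
    lag_step: float  # ms per lag (= frame duration)
    n_dropped: int = 0

    @property
    def n_spikes(self) -> int:
        return self.segments.shape[0]

    @property
    def n_lags(self) -> int:
        return self.segments.shape[1]

    @property
    def grid(self) -> tuple[int, int]:
        return self.segments.shape[2], self.segments.shape[3]


@dataclass
class EffectiveImages:
    """Per-spike stimulus segments collapsed over time.

    ``S[i]`` is the vectorized effective image of spike i:
    sum_tau k_t(tau) * s(tau)^i, with ``collapse_weights`` = k_t.
    """

    S: np.ndarray  # N x P
    spike_ids: np.ndarray
    grid: tuple[int, int]
    collapse_weights: np.ndarray
    degenerate_collapse: bool = False  # True when the STA-based weights were unusable

    @property
    def n_spikes(self) -> int:
        return self.S.shape[0]


def build_ensemble(movie, train, n_lags: int = 15) -> STEnsemble:
    """Collect the L-lag stimulus segment preceding every spike.

    A spike at time t is attributed to frame floor(t / frame_duration)
    (the frame on screen when it fired); spikes in the first L-1 frames
    are dropped.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if train.n_spikes == 0:
        raise EmptyEnsembleError(f"spike train {train.cell_id!r} is empty")
    frame_idx = np.floor(train.times / movie.frame_duration).astype(np.int64)
    frame_idx = np.minimum(frame_idx, movie.n_frames - 1)
    keep = frame_idx >= n_lags - 1
    if not np.any(keep):
        raise EmptyEnsembleError(
            f"no spike of {train.cell_id!r} has {n_lags} frames of stimulus history"
        )
    kept_idx = frame_idx[keep]
    # segment lags: frame, frame-1, ..., frame-L+1
    lag_idx = kept_idx[:, None] - np.arange(n_lags)[None, :]
    segments = movie.frames[lag_idx]  # N x L x H x W
    return STEnsemble(
        segments=segments,
        spike_ids=np.flatnonzero(keep),
        lag_step=movie.frame_duration,
        n_dropped=int(np.sum(~keep)),
    )


def compute_sta(ensemble: STEnsemble) -> np.ndarray:
    """Spike-triggered average: elementwise mean of the segments (L x H x W)."""
    if ensemble.n_spikes < 1:
        raise ValueError("ensemble holds no spikes")
    return ensemble.segments.mean(axis=0, dtype=np.float64)


def svd_separate(
    sta: np.ndarray,
    noise_scale: float | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Rank-1 space-time separation of an STA by SVD.

    Returns ``(temporal, spatial, info)`` where temporal (unit norm, sign
    fixed so its dominant lobe is negative) and spatial are the leading
    singular vectors of the lag x pixel matrix, scaled so
    temporal (x) spatial reproduces the rank-1 part of the STA.
    ``info['separability']`` is sigma_1^2 / sum(sigma^2);
    ``info['degenerate']`` flags an STA indistinguishable from noise —
    always for an all-zero STA, and, when ``noise_scale`` (the expected
    standard error of one STA entry, e.g. 0.5/sqrt(N) for binary white
    noise) is given, whenever max|STA| < 5 * noise_scale. A complex
    cell's STA, cancelled by polarity-opposed inputs, trips this flag.
    """
    L = sta.shape[0]
    grid = sta.shape[1:]
    mat = sta.reshape(L, -1)
    norm = np.linalg.norm(mat)
    if norm == 0:
        return (
            np.zeros(L),
            np.zeros(grid),
            {"separability": 0.0, "degenerate": True, "singular_values": np.zeros(min(mat.shape))},
        )
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    temporal = u[:, 0]
    spatial = (s[0] * vt[0]).reshape(grid)
    # sign convention: dominant temporal lobe negative
    if temporal[np.argmax(np.abs(temporal))] > 0:
        temporal = -temporal
        spatial = -spatial
    separability = float(s[0] ** 2 / np.sum(s**2))
    degenerate = False
    if noise_scale is not None and np.max(np.abs(sta)) < 5.0 * noise_scale:
        degenerate = True
    return temporal, spatial, {
        "separability": separability,
        "degenerate": degenerate,
        "singular_values": s,
    }


def quadratic_lag_profile(ensemble: STEnsemble) -> np.ndarray:
    """Signed temporal profile from spike-triggered second-order products.

    For a complex cell the STA cancels, but the products of stimulus
    values conditioned on a spike still carry the temporal filter:
    same-lag *neighboring-pixel* products average to ~ k_t(tau)^2 (both
    pixels of a driving subunit move together before its spikes), and
    same-pixel *adjacent-lag* products average to ~ k_t(tau) k_t(tau+1),
    which fixes the relative signs across lags. (Note the per-pixel
    variance itself is useless for binary stimuli: (+-0.5)^2 is constant
    no matter the conditioning.) The amplitude sqrt(energy) and the
    propagated signs are combined, oriented so the dominant lobe is
    negative, and normalized to unit L2 norm. Both statistics are
    baseline-corrected by their across-lag median.
    """
    seg = ensemble.segments.astype(np.float64)
    L = ensemble.n_lags
    # same-lag adjacent-pixel products: energy ~ k_t(tau)^2
    e = (seg[:, :, :, :-1] * seg[:, :, :, 1:]).mean(axis=0).sum(axis=(1, 2))
    e += (seg[:, :, :-1, :] * seg[:, :, 1:, :]).mean(axis=0).sum(axis=(1, 2))
    e -= np.median(e)
    amp = np.sqrt(np.clip(e, 0.0, None))
    if L == 1 or not np.any(amp > 0):
        return np.full(L, -1.0 / np.sqrt(L))
    # adjacent-lag same-pixel products: sign pattern ~ k_t(tau) k_t(tau+1)
    c = (seg[:, :-1] * seg[:, 1:]).mean(axis=0).sum(axis=(1, 2))
    c -= np.median(c)
    signs = np.ones(L)
    peak = int(np.argmax(amp))
    for t in range(peak, L - 1):
        signs[t + 1] = signs[t] * (1.0 if c[t] >= 0 else -1.0)
    for t in range(peak, 0, -1):
        signs[t - 1] = signs[t] * (1.0 if c[t - 1] >= 0 else -1.0)
    prof = amp * signs
    if prof[np.argmax(np.abs(prof))] > 0:
        prof = -prof
    return prof / np.linalg.norm(prof)


def collapse_temporal(ensemble: STEnsemble, temporal: np.ndarray, *, degenerate: bool = False) -> EffectiveImages:
    """Collapse each segment over lags: s_bar_i = sum_tau k_t(tau) s(tau)^i."""
    temporal = np.asarray(temporal, dtype=np.float64)
    if temporal.shape != (ensemble.n_lags,):
        raise ValueError(
            f"temporal weights have length {temporal.shape}, ensemble has {ensemble.n_lags} lags"
        )
    S = np.tensordot(ensemble.segments, temporal, axes=([1], [0]))
    return EffectiveImages(
        S=S.reshape(ensemble.n_spikes, -1),
        spike_ids=ensemble.spike_ids.copy(),
        grid=ensemble.grid,
        collapse_weights=temporal.copy(),
        degenerate_collapse=degenerate,
    )


def effective_images(movie, train, n_lags: int = 15) -> EffectiveImages:
    """Convenience pipeline: ensemble -> STA -> SVD temporal -> collapse.

    The collapse uses the sign-flipped (positive-dominant) STA temporal
    vector. With the field's convention of negative-dominant temporal
    filters, this makes effective images *negative* over an OFF cell's
    receptive field and *positive* over an ON cell's, which is what the
    downstream row-extremum spike-assignment rules (min -> OFF,
    max -> ON) assume. Falls back to the non-negative second-moment lag
    profile when the STA is degenerate (noise-level, as for complex
    cells); ``degenerate_collapse`` records which weights were used.
    """
    ens = build_ensemble(movie, train, n_lags=n_lags)
    sta = compute_sta(ens)
    noise_scale = 0.5 / np.sqrt(ens.n_spikes)
    temporal, _, info = svd_separate(sta, noise_scale=noise_scale)
    if info["degenerate"]:
        temporal = quadratic_lag_profile(ens)
    return collapse_temporal(ens, -temporal, degenerate=info["degenerate"])
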