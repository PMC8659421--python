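"""Visual stimulus generation and file I/O.

Two stimulus classes drive the simulated circuits: binary white-noise
checkerboards (each pixel independently black, -0.5, or white, +0.5, per
frame) and a spatially correlated Gaussian surrogate whose second-order
statistics mimic normalized natural-image patches. Intensities are
dimensionless contrast values confined to [-0.5, +0.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusMovie",
    "generate_white_noise",
    "generate_correlated_surrogate",
    "save_stimulus",
    "load_stimulus",
    "StimulusFormatError",
]

_KINDS = ("white_noise", "correlated_surrogate", "user_supplied")


class StimulusFormatError(ValueError):
    """Raised when a stimulus file violates the documented container layout."""


@dataclass
class StimulusMovie:
    """A time-ordered sequence of stimulus frames.

    Parameters
    ----------
    frames
        Array of shape (T, H, W); contrast values in [-0.5, +0.5].
    frame_duration
        Duration of one frame in milliseconds.
    kind
        One of ``white_noise``, ``correlated_surrogate``, ``user_supplied``.
    seed
        RNG seed used to generate the movie (-1 for user-supplied data).
    """

    frames: np.ndarray
    frame_duration: float
    kind: str = "user_supplied"
    seed: int = -1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(f"frames must be (T, H, W) with T >= 1, got {self.frames.shape}")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -0.5 - 1e-6 or hi > 0.5 + 1e-6:
            raise ValueError(f"intensities must lie in [-0.5, 0.5], found [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Total movie duration in ms."""
        return self.n_frames * self.frame_duration


def generate_white_noise(
    n_frames: int,
    grid: tuple[int, int] = (8, 8),
    frame_duration: float = 10.0,
    seed: int = 0,
) -> StimulusMovie:
    """Binary white-noise checker movie: each pixel is -0.5 or +0.5 i.i.d.

    Each pixel takes the two values with probability 1/2, independently
    across pixels and frames; the result is reproducible under ``seed``.
    """
    h, w = grid
    if n_frames < 1 or h < 1 or w < 1:
        raise ValueError(f"n_frames and grid dims must be >= 1, got {n_frames}, {grid}")
    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 2, size=(n_frames, h, w)).astype(np.float32) - 0.5
    return StimulusMovie(frames, frame_duration, kind="white_noise", seed=seed)


def generate_correlated_surrogate(
    n_frames: int,
    grid: tuple[int, int] = (32, 32),
    correlation_length: float = 2.0,
    frame_duration: float = 10.0,
    seed: int = 0,
) -> StimulusMovie:
    """Spatially correlated Gaussian surrogate for natural-image patches.

    Each frame is an i.i.d. Gaussian field convolved with an isotropic
    Gaussian kernel of standard deviation ``correlation_length`` pixels
    (periodic boundaries), then linearly rescaled per frame so its values
    span [-0.5, +0.5]. With ``correlation_length=0`` no smoothing is
    applied and pixels are independent.
    """
    h, w = grid
    if n_frames < 1 or h < 1 or w < 1:
        raise ValueError(f"n_frames and grid dims must be >= 1, got {n_frames}, {grid}")
    if correlation_length < 0:
        raise ValueError("correlation_length must be >= 0")
    rng = np.random.default_rng(seed)
    frames = rng.standard_normal(size=(n_frames, h, w))
    if correlation_length > 0:
        from scipy.ndimage import gaussian_filter

        frames = gaussian_filter(
            frames, sigma=(0.0, correlation_length, correlation_length), mode="wrap"
        )
    # per-frame min-max rescale onto [-0.5, 0.5]
    flat = frames.reshape(n_frames, -1)
    lo = flat.min(axis=1, keepdims=True)
    hi = flat.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    flat = (flat - lo) / span - 0.5
    frames = flat.reshape(n_frames, h, w).astype(np.float32)
    return StimulusMovie(frames, frame_duration, kind="correlated_surrogate", seed=seed)


# ---------------------------------------------------------------------------
# File I/O: HDF5 container (primary) and whitespace text fallback.
# HDF5 layout: /frames (T x H x W float32), /frame_duration_ms, /seed, /kind.
# Text layout: line 1 "T H W", line 2 frame_duration_ms, line 3 "kind seed",
# then T blocks of H lines with W values each.
# ---------------------------------------------------------------------------


def save_stimulus(movie: StimulusMovie, path: str) -> None:
    """Write a movie to ``path``; ``.txt`` selects the text fallback, anything
    else the HDF5 container. Round-trips bit-exactly."""
    if str(path).endswith(".txt"):
        _save_text(movie, path)
    else:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=movie.frames, dtype="float32")
            f["frame_duration_ms"] = float(movie.frame_duration)
            f["seed"] = int(movie.seed)
            f["kind"] = movie.kind


def load_stimulus(path: str) -> StimulusMovie:
    """Read a movie written by :func:`save_stimulus`, validating layout,
    shape and the [-0.5, 0.5] intensity range."""
    if str(path).endswith(".txt"):
        return _load_text(path)
    import h5py

    with h5py.File(path, "r") as f:
        for name in ("frames", "frame_duration_ms"):
            if name not in f:
                raise StimulusFormatError(f"missing dataset /{name} in {path}")
        frames = np.asarray(f["frames"], dtype=np.float32)
        frame_duration = float(f["frame_duration_ms"][()])
        seed = int(f["seed"][()]) if "seed" in f else -1
        kind = f["kind"][()] if "kind" in f else "user_supplied"
        if isinstance(kind, bytes):
            kind = kind.decode()
    return _validated_movie(frames, frame_duration, kind, seed, path)


def _validated_movie(frames, frame_duration, kind, seed, path) -> StimulusMovie:
    if frames.ndim != 3:
        raise StimulusFormatError(f"/frames must be 3-D (T,H,W), got shape {frames.shape} in {path}")
    if frames.size and (frames.min() < -0.5 - 1e-6 or frames.max() > 0.5 + 1e-6):
        raise StimulusFormatError(
            f"/frames values outside [-0.5, 0.5] in {path}: "
            f"range [{frames.min():g}, {frames.max():g}]"
        )
    if frame_duration <= 0:
        raise StimulusFormatError(f"frame_duration_ms must be > 0, got {frame_duration} in {path}")
    if kind not in _KINDS:
        kind = "user_supplied"
    return StimulusMovie(frames, frame_duration, kind=kind, seed=seed)


def _save_text(movie: StimulusMovie, path: str) -> None:
    with open(path, "w") as f:
        t, (h, w) = movie.n_frames, movie.grid
        f.write(f"{t} {h} {w}\n")
        f.write(f"{movie.frame_duration!r}\n")
        f.write(f"{movie.kind} {movie.seed}\n")
        for frame in movie.frames:
            for row in frame:
                f.write(" ".join(np.format_float_positional(v, unique=True) for v in row))
                f.write("\n")


def _load_text(path: str) -> StimulusMovie:
    with open(path) as f:
        header = f.readline().split()
        if len(header) != 3:
            raise StimulusFormatError(f"header line must be 'T H W', got {header} in {path}")
        try:
            t, h, w = (int(x) for x in header)
        except ValueError as e:
            raise StimulusFormatError(f"non-integer header field in {path}: {e}") from e
        try:
            frame_duration = float(f.readline().strip())
        except ValueError as e:
            raise StimulusFormatError(f"bad frame_duration line in {path}: {e}") from e
        meta = f.readline().split()
        kind = meta[0] if meta else "user_supplied"
        seed = int(meta[1]) if len(meta) > 1 else -1
        values = np.loadtxt(f, dtype=np.float32, ndmin=2)
    if values.size != t * h * w or values.shape[-1] != w:
        raise StimulusFormatError(
            f"frame data shape mismatch in {path}: header promises {t}x{h}x{w}, "
            f"file holds {values.shape}"
        )
    frames = values.reshape(t, h, w)
    return _validated_movie(frames, frame_duration, kind, seed, path)
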