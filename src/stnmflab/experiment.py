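"""Experiment configuration, orchestration and on-disk bundles.

An :class:`ExperimentConfig` names a preset circuit, the stimulus, the
factorization settings and an output directory; :func:`run_experiment`
executes the full pipeline — stimulus generation, network simulation,
effective-image construction, STNMF, module classification, circuit
dissection, evaluation — writing every stage product plus a manifest
with the per-stage seeds and a config hash. All stage seeds derive
deterministically from the master seed, so re-running a config
reproduces every array bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import metrics
from .circuits import save_spike_trains, simulate_network
from .dissect import dissect
from .factorize import STNMFConfig, classify_modules, semi_nmf
from .presets import PRESET_NAMES, preset_network, true_spatial_rfs
from .stimulus import generate_correlated_surrogate, generate_white_noise, save_stimulus
from .trigger import effective_images

__all__ = ["ExperimentConfig", "ConfigError", "validate_config", "run_experiment"]

# middle-layer pooling maps (true RGC index -> middle cell) for the
# three-layer presets, mirroring each preset's wiring
_POOLING = {
    "fig3": {"lgn1": [0, 1, 2, 3], "lgn2": [2, 3, 4, 5]},
    "s3": {"lgn1": [0, 1, 2], "lgn2": [1, 2, 3]},
    "s5": {"lgn1": [0, 1, 2, 3], "lgn2": [2, 3, 4, 5]},
    "s6": {"lgn1": [0, 1, 2, 3], "lgn2": [2, 3, 4, 5]},
}


class ConfigError(ValueError):
    """Invalid experiment configuration; ``errors`` lists every problem."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class ExperimentConfig:
    preset: str = "fig1"
    n_frames: int = 100_000
    grid: tuple[int, int] = (8, 8)
    frame_duration: float = 10.0
    stimulus_kind: str = "white_noise"
    correlation_length: float = 2.0  # only for correlated_surrogate
    n_lags: int = 15
    K: int = 8
    lambda_sparsity: float = 0.1
    n_restarts: int = 5
    max_iter: int = 500
    n_shuffles: int = 500
    bin_ms: float | None = None  # correlation bin; None -> one frame
    compute_mi: bool = False
    dual_extraction: bool = False
    outdir: str = "experiment_out"
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ("stimulus", "simulate", "stnmf", "classify", "evaluate")
        return {
            n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, ss.spawn(len(names)))
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(source) -> ExperimentConfig:
    """Normalize a config from a YAML/JSON file path or a dict.

    Unknown keys, bad ranges and unknown presets are aggregated into a
    single :class:`ConfigError`. Defaults are filled for missing keys.
    """
    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as f:
            data = yaml.safe_load(f) or {}
    else:
        data = dict(source)
    errors = []
    known = {f for f in ExperimentConfig.__dataclass_fields__}
    for key in data:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    data = {k: v for k, v in data.items() if k in known}
    if "grid" in data:
        data["grid"] = tuple(data["grid"])
    cfg = ExperimentConfig(**data)
    if cfg.preset not in PRESET_NAMES:
        errors.append(f"unknown preset {cfg.preset!r}; valid: {', '.join(PRESET_NAMES)}")
    if cfg.n_frames < 1:
        errors.append("n_frames must be >= 1")
    if cfg.lambda_sparsity < 0:
        errors.append("lambda_sparsity must be >= 0")
    if cfg.K < 1:
        errors.append("K must be >= 1")
    if cfg.frame_duration <= 0:
        errors.append("frame_duration must be > 0")
    if cfg.stimulus_kind not in ("white_noise", "correlated_surrogate"):
        errors.append(f"unknown stimulus_kind {cfg.stimulus_kind!r}")
    if errors:
        raise ConfigError(errors)
    return cfg


def run_experiment(config: ExperimentConfig, verbose: bool = True) -> dict:
    """Run the full pipeline for ``config`` and write an output bundle.

    Returns the manifest dict. The bundle contains the stimulus movie,
    all spike trains, the STNMF result, the dissected circuit, the
    evaluation report and a JSON manifest naming each product with the
    stage seed that produced it.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(f"[{time.strftime('%H:%M:%S')}] {msg}")
        if verbose:
            print(msg)

    manifest: dict = {"config": asdict(config), "config_hash": config.digest(), "seeds": seeds,
                      "outputs": {}}

    note(f"preset {config.preset}: building stimulus ({config.stimulus_kind}, "
         f"{config.n_frames} frames of {config.grid}, {config.frame_duration} ms)")
    if config.stimulus_kind == "white_noise":
        movie = generate_white_noise(
            config.n_frames, config.grid, config.frame_duration, seed=seeds["stimulus"]
        )
    else:
        movie = generate_correlated_surrogate(
            config.n_frames, config.grid, config.correlation_length,
            config.frame_duration, seed=seeds["stimulus"],
        )
    save_stimulus(movie, str(out / "stimulus.h5"))
    manifest["outputs"]["stimulus"] = "stimulus.h5"

    spec = preset_network(config.preset)
    note(f"simulating network ({len(spec.lnp_ids)} LNP + {len(spec.lif_ids)} LIF cells)")
    trains = simulate_network(spec, movie, seed=seeds["simulate"])
    rates = {cid: round(tr.rate(), 2) for cid, tr in trains.items()}
    note(f"firing rates (Hz): {rates}")
    save_spike_trains(trains, str(out / "spikes.txt"))
    manifest["outputs"]["spikes"] = "spikes.txt"
    manifest["rates_hz"] = rates

    # analyze every cell of the deepest layer (two LGNs in the multi-output
    # scenario, otherwise the single readout cell)
    targets = list(spec.layers[-1])
    results, dissections = {}, {}
    dual = config.dual_extraction or config.preset == "fig7"
    for t_i, target in enumerate(targets):
        note(f"building effective images from {target!r} spikes")
        eff = effective_images(movie, trains[target], n_lags=config.n_lags)
        note(f"{eff.n_spikes} usable spikes; degenerate STA collapse: {eff.degenerate_collapse}")
        stnmf_cfg = STNMFConfig(
            K=config.K, lambda_sparsity=config.lambda_sparsity, n_restarts=config.n_restarts,
            max_iter=config.max_iter, seed=seeds["stnmf"] + t_i,
        )
        note(f"running STNMF on {target!r} (K={config.K}, lambda={config.lambda_sparsity}, "
             f"{config.n_restarts} restarts)")
        result = semi_nmf(eff, stnmf_cfg)
        classify_modules(result, n_shuffles=config.n_shuffles, seed=seeds["classify"] + t_i)
        note(f"meaningful modules: {list(map(int, result.meaningful()))} of {config.K}")
        results[target] = result
        diss = dissect(result, trains[target], movie=None, dual=dual)
        dissections[target] = diss
        note(f"dissection of {target!r}: {len(diss.module_indices)} subunits, "
             f"polarities {diss.polarities}")
    _save_stnmf_bundle(results, str(out / "stnmf.h5"))
    manifest["outputs"]["stnmf"] = "stnmf.h5"
    _save_dissection_bundle(dissections, str(out / "dissection.h5"))
    manifest["outputs"]["dissection"] = "dissection.h5"

    report = evaluate_against_truth(spec, trains, movie, results, dissections, config,
                                    seeds["evaluate"])
    (out / "evaluation.json").write_text(json.dumps(report, indent=2, default=_jsonify))
    manifest["outputs"]["evaluation"] = "evaluation.json"
    note(f"evaluation: {report['n_recovered']} of {len(spec.lnp_ids)} true cells recovered "
         f"(cosine >= 0.8)")

    (out / "run.log").write_text("\n".join(log) + "\n")
    manifest["outputs"]["log"] = "run.log"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_jsonify))
    return manifest


def evaluate_against_truth(spec, trains, movie, results, dissections, config, seed) -> dict:
    """Model-vs-inference evaluation for a preset run (requires ground truth).

    With several analyzed readout cells (two LGNs), the recovered count is
    the number of distinct true cells matched by any readout's meaningful
    modules, and the trains/matrices concatenate across readouts.
    """
    bin_ms = config.bin_ms or movie.frame_duration
    true_rfs = list(true_spatial_rfs(spec).values())
    all_modules, all_keys, inferred, per_target = [], [], [], {}
    for target, diss in dissections.items():
        result = results[target]
        mods = [result.module_images()[k] for k in diss.module_indices]
        all_modules.extend(mods)
        all_keys.extend(f"{target}:{k}" for k in diss.assigned_trains)
        inferred.extend(diss.assigned_trains.values())
        per_target[target] = {
            "n_meaningful": int(len(diss.module_indices)),
            "polarities": diss.polarities,
            "weights": diss.weights,
        }
    sim = metrics.rf_similarity_matrix(true_rfs, all_modules, mode="cosine")
    rows, cols, scores = metrics.hungarian_match(sim)
    # distinct true cells matched at >= 0.8 by any meaningful module
    n_rec = int(np.sum(np.abs(scores) >= 0.8))
    model_trains = [trains[c] for c in spec.lnp_ids]
    corr = metrics.correlation_matrix(model_trains, inferred, bin_ms=bin_ms)
    report = {
        "n_meaningful": int(sum(p["n_meaningful"] for p in per_target.values())),
        "n_recovered": n_rec,
        "per_target": per_target,
        "rf_similarity": sim,
        "match": {"true_idx": rows, "module_pos": cols, "cosine": np.abs(scores)},
        "corr_matrix": corr,
        "corr_keys": all_keys,
        "bin_ms": bin_ms,
    }
    if config.compute_mi:
        filters = [spec.cells[c].filter for c in spec.lnp_ids]
        report["mi_matrix"] = metrics.mi_matrix(movie, filters, inferred, seed=seed)
    return report


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_stnmf_group(f, result) -> None:
    f["W"] = result.W
    f["M"] = result.M
    f["objective_trace"] = result.objective_trace
    f["grid"] = list(result.grid)
    f["best_restart_seed"] = result.best_restart_seed
    if result.spike_ids is not None:
        f["spike_ids"] = result.spike_ids
    f["config"] = json.dumps(asdict(result.config))
    if result.significance is not None:
        f["significance"] = json.dumps(result.significance)


def _save_stnmf(result, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        _write_stnmf_group(f, result)


def _save_stnmf_bundle(results: dict, path: str) -> None:
    """One factorization per analyzed readout cell, as HDF5 groups."""
    import h5py

    if len(results) == 1:
        _save_stnmf(next(iter(results.values())), path)
        return
    with h5py.File(path, "w") as f:
        for target, result in results.items():
            _write_stnmf_group(f.create_group(target), result)


def load_stnmf(path: str):
    """Read back an STNMF result written by :func:`run_experiment`."""
    import h5py

    from .factorize import STNMFResult

    with h5py.File(path, "r") as f:
        cfg = STNMFConfig(**json.loads(f["config"][()]))
        sig = json.loads(f["significance"][()]) if "significance" in f else None
        return STNMFResult(
            W=f["W"][()],
            M=f["M"][()],
            objective_trace=f["objective_trace"][()],
            config=cfg,
            grid=tuple(f["grid"][()]),
            best_restart_seed=int(f["best_restart_seed"][()]),
            spike_ids=f["spike_ids"][()] if "spike_ids" in f else None,
            significance=sig,
        )


def _save_dissection_bundle(dissections: dict, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for target, diss in dissections.items():
            g = f.create_group(target) if len(dissections) > 1 else f
            g["module_indices"] = diss.module_indices
            g["subunit_rfs"] = diss.subunit_rfs
            g["weights"] = diss.weights
            g["polarities"] = json.dumps(diss.polarities)
            gt = g.create_group("assigned_trains")
            for (k, pol), tr in diss.assigned_trains.items():
                gt.create_dataset(f"module{k}_{pol}", data=tr.times)


def _save_dissection(diss, trains, path: str) -> None:
    _save_dissection_bundle({"cell": diss}, path)
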