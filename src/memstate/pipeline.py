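"""End-to-end orchestration: synth -> featurize -> GMRQ scan -> landscape -> dG.

A YAML/dict configuration is validated into a :class:`RunConfig`; the
stages run in order, each one keyed by a hash of its parameters and its
upstream hashes.  Outputs live in the run directory together with a
manifest recording the config hash, per-stage checksums, wall times and
warnings; re-running an unchanged config reloads every stage from disk
(zero recomputation, identical config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .embed import EmbedConfig, embed_frames
from .featurize import FeatureMatrix, FeatureParams, FeatureSpec, assemble_features
from .landscape import (BasinDefinition, bootstrap_deltaG, compute_cv,
                        default_basins, msm_weighted_histogram,
                        FreeEnergyLandscape)
from .model_selection import (hyperparameter_search, results_to_records,
                              shuffle_split, top_featurizations, _derived_seed)
from .msm import assign, estimate_msm, fit_minibatch_kmeans
from .synthetic import (CVTrajectorySet, SyntheticConfig, WellSpec, KT_300K,
                        deep_only_config, sample_langevin, two_well_config)
from .systems import save_pdb
from .tica import fit_tica, transform_all

logger = logging.getLogger(__name__)

STAGES = ("synth", "featurize", "gmrq_scan", "refit_best", "landscape", "deltag")

T_RANGE = (0.5, 5.0)  # ns, allowed tICA lag search range
G_RANGE = (1e-10, 1e-1)  # allowed ridge strength search range


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; "
                          f"allowed: {sorted(allowed)}")


@dataclass
class RunConfig:
    """Validated, fully defaulted pipeline configuration."""

    output_dir: Path
    seed: int
    synthetic: SyntheticConfig
    embed: EmbedConfig
    featurizations: list[FeatureSpec]
    t_grid: list[float]
    g_grid: list[float]
    k_grid: list[int]
    msm_lag: float
    m: int
    n_tics: int
    test_fraction: float
    n_repeats: int
    bins: int
    kT: float
    basins: BasinDefinition | None
    bootstrap_B: int
    level: float
    top_n: int
    stages: list[str]

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "synthetic": self.synthetic.config_hash(),
            "embed": {
                "leaflet_z": self.embed.leaflet_z,
                "hydrocarbon_halfwidth": self.embed.hydrocarbon_halfwidth,
                "water_bulk_density": self.embed.water_bulk_density,
                "n_lipids_per_leaflet": self.embed.n_lipids_per_leaflet,
                "box": list(self.embed.box),
                "seed": self.embed.seed,
            },
            "featurizations": [s.label for s in self.featurizations],
            "t_grid": self.t_grid,
            "g_grid": self.g_grid,
            "k_grid": self.k_grid,
            "msm_lag": self.msm_lag,
            "m": self.m,
            "n_tics": self.n_tics,
            "test_fraction": self.test_fraction,
            "n_repeats": self.n_repeats,
            "bins": self.bins,
            "kT": self.kT,
            "basins": None if self.basins is None else
                      [list(self.basins.deep), list(self.basins.shallow)],
            "bootstrap_B": self.bootstrap_B,
            "level": self.level,
            "top_n": self.top_n,
            "stages": self.stages,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def default_config_dict() -> dict:
    """The default synthetic end-to-end run (small but two-well resolving)."""
    return {
        "output_dir": "memstate_run",
        "seed": 0,
        "synthetic": {"preset": "two_well", "n_trajectories": 12,
                      "frames_per_trajectory": 150},
        "embed": {"water_bulk_density": 3.0, "n_lipids_per_leaflet": 49,
                  "box": [6.0, 6.0, 12.0]},
        "featurizations": [
            "none+none+lipid_weighted_distance",
            "none+shell_1.0nm+none",
            "dihedrals+none+lipid_weighted_distance",
        ],
        "tica": {"t_grid": [1.0, 2.5], "g_grid": [1e-3], "n_components": 4},
        "cluster": {"k_grid": [15, 30]},
        "msm": {"lag": 4.5},
        "gmrq": {"m": 6, "test_fraction": 0.5, "repeats": 2},
        "landscape": {"bins": 32, "kT": KT_300K, "top_n": 1},
        "basins": {"deep": [0.4, 1.475, -40.0, 90.0],
                   "shallow": [1.475, 2.8, -40.0, 90.0]},
        "bootstrap": {"B": 30, "level": 0.95},
        "stages": list(STAGES),
    }


def validate_config(raw) -> RunConfig:
    """Parse and range-check a raw config (YAML text, path, or dict)."""
    import yaml

    if isinstance(raw, (str, Path)):
        text = Path(raw).read_text() if Path(str(raw)).exists() else str(raw)
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    defaults = default_config_dict()
    _check_keys(raw, set(defaults), "the top-level config")
    cfg = {**defaults, **raw}
    for key in ("synthetic", "embed", "tica", "cluster", "msm", "gmrq",
                "landscape", "bootstrap"):
        if key in raw and raw[key] is not None:
            cfg[key] = {**defaults[key], **raw[key]}

    seed = int(cfg["seed"])
    syn_raw = dict(cfg["synthetic"])
    _check_keys(syn_raw, {"preset", "n_trajectories", "frames_per_trajectory",
                          "start_fractions", "wells", "confinement_strength",
                          "confinement_center", "kT", "diffusion", "timestep",
                          "frame_interval"}, "synthetic")
    preset = syn_raw.pop("preset", "two_well")
    if "wells" in syn_raw:
        wells = tuple(WellSpec(center=tuple(w["center"]),
                               depth_amplitude=float(w["depth_amplitude"]),
                               widths=tuple(w["widths"])) for w in syn_raw.pop("wells"))
        syn = SyntheticConfig(wells=wells, seed=seed, **{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in syn_raw.items()})
    else:
        maker = {"two_well": two_well_config, "deep_only": deep_only_config}.get(preset)
        if maker is None:
            raise ConfigError(f"synthetic.preset {preset!r} not in "
                              "{'two_well', 'deep_only'}")
        extra = {k: (tuple(v) if isinstance(v, list) else v) for k, v in syn_raw.items()
                 if k in ("n_trajectories", "frames_per_trajectory", "start_fractions")}
        syn = maker(seed=seed, **extra)

    emb_raw = dict(cfg["embed"])
    _check_keys(emb_raw, {"leaflet_z", "hydrocarbon_halfwidth", "water_bulk_density",
                          "n_lipids_per_leaflet", "box", "lipid_xy_jitter",
                          "lipid_z_jitter"}, "embed")
    if "box" in emb_raw:
        emb_raw["box"] = tuple(float(v) for v in emb_raw["box"])
    emb = EmbedConfig(seed=seed + 1000, **emb_raw)

    specs = [FeatureSpec.from_label(s) if isinstance(s, str) else s
             for s in cfg["featurizations"]]

    tica_raw = dict(cfg["tica"])
    _check_keys(tica_raw, {"t_grid", "g_grid", "n_components"}, "tica")
    t_grid = [float(t) for t in tica_raw["t_grid"]]
    g_grid = [float(g) for g in tica_raw["g_grid"]]
    for t in t_grid:
        if not T_RANGE[0] <= t <= T_RANGE[1]:
            raise ConfigError(f"tica.t_grid value {t} ns outside the allowed "
                              f"range [{T_RANGE[0]}, {T_RANGE[1]}] ns")
    for g in g_grid:
        if not G_RANGE[0] <= g <= G_RANGE[1]:
            raise ConfigError(f"tica.g_grid value {g} outside the allowed "
                              f"range [{G_RANGE[0]:g}, {G_RANGE[1]:g}]")
    k_grid = [int(k) for k in cfg["cluster"]["k_grid"]]
    if any(k < 2 for k in k_grid):
        raise ConfigError("cluster.k_grid entries must be >= 2")

    msm_lag = float(cfg["msm"]["lag"])
    ratio = msm_lag / syn.frame_interval
    if abs(ratio - round(ratio)) > 1e-9:
        logger.warning("MSM lag %.4g ns is not a multiple of the frame interval "
                       "%.4g ns; it will be rounded down to %d frames",
                       msm_lag, syn.frame_interval, int(ratio))

    gmrq = cfg["gmrq"]
    _check_keys(dict(gmrq), {"m", "test_fraction", "repeats"}, "gmrq")
    land = cfg["landscape"]
    _check_keys(dict(land), {"bins", "kT", "top_n"}, "landscape")
    basins = None
    if cfg["basins"] is not None:
        b = cfg["basins"]
        _check_keys(dict(b), {"deep", "shallow"}, "basins")
        basins = BasinDefinition(deep=tuple(b["deep"]), shallow=tuple(b["shallow"]))
    stages = list(cfg["stages"])
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s) {sorted(unknown)}; allowed {STAGES}")
    if "deltag" in stages and basins is None:
        raise ConfigError("the deltag stage requires a 'basins' section "
                          "(deep and shallow rectangles in (d, theta))")

    boot = cfg["bootstrap"]
    _check_keys(dict(boot), {"B", "level"}, "bootstrap")

    return RunConfig(
        output_dir=Path(cfg["output_dir"]),
        seed=seed,
        synthetic=syn,
        embed=emb,
        featurizations=specs,
        t_grid=t_grid,
        g_grid=g_grid,
        k_grid=k_grid,
        msm_lag=msm_lag,
        m=int(gmrq["m"]),
        n_tics=int(tica_raw["n_components"]),
        test_fraction=float(gmrq["test_fraction"]),
        n_repeats=int(gmrq["repeats"]),
        bins=int(land["bins"]),
        kT=float(land["kT"]),
        basins=basins,
        bootstrap_B=int(boot["B"]),
        level=float(boot["level"]),
        top_n=int(land["top_n"]),
        stages=stages,
    )


# ---------------------------------------------------------------------------
# Stage runner with checksum caching
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Runner:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.previous = {}
        if self.manifest_path.exists():
            try:
                self.previous = json.loads(self.manifest_path.read_text())
            except json.JSONDecodeError:
                self.previous = {}
        self.manifest = {
            "config_hash": cfg.config_hash(),
            "version": __version__,
            "seed": cfg.seed,
            "stages": {},
            "warnings": [],
        }

    def stage(self, name: str, inputs_hash: str, outputs: list[str], compute):
        """Run (or reload) one stage; returns compute()'s value or None if cached."""
        paths = [self.out / o for o in outputs]
        prev = self.previous.get("stages", {}).get(name)
        cached = (
            prev is not None
            and prev.get("inputs_hash") == inputs_hash
            and all(p.exists() for p in paths)
            and all(prev.get("outputs", {}).get(o) == _sha256(self.out / o)
                    for o in outputs)
        )
        t0 = time.perf_counter()
        value = None
        if not cached:
            value = compute()
        wall = time.perf_counter() - t0
        self.manifest["stages"][name] = {
            "inputs_hash": inputs_hash,
            "outputs": {o: _sha256(self.out / o) for o in outputs
                        if (self.out / o).exists()},
            "wall_time_s": round(wall, 6),
            "cached": cached,
        }
        self._write_manifest()
        return value, cached

    def _write_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def _hash_of(*parts) -> str:
    return hashlib.sha256(repr(parts).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Stage order: synth -> featurize (embedding + all selected
    featurizations) -> gmrq_scan -> refit_best -> landscape -> deltag.
    A stage failure raises with the stage name; unchanged stages are
    reloaded from their cached outputs.
    """
    runner = _Runner(cfg)
    out = runner.out
    h_chain = cfg.config_hash()

    # --- synth -----------------------------------------------------------
    cvs: CVTrajectorySet | None = None
    h_synth = _hash_of("synth", cfg.synthetic.config_hash())
    if "synth" in cfg.stages:
        def _synth():
            c = sample_langevin(cfg.synthetic)
            c.to_csv(out / "cv_truth.csv")
            np.savez(out / "synth.npz", frame_interval=c.frame_interval,
                     **{f"traj_{i}": t for i, t in enumerate(c.trajectories)})
            return c

        value, cached = _stage_guard(runner, "synth", h_synth,
                                     ["cv_truth.csv", "synth.npz"], _synth)
        cvs = value if value is not None else _load_cvs(out / "synth.npz")

    # --- featurize (embedding + featurizers + CV recomputation) ----------
    features_by_spec: dict[FeatureSpec, list[FeatureMatrix]] = {}
    cv_arrays: list[np.ndarray] | None = None
    h_feat = _hash_of("featurize", h_synth,
                      [s.label for s in cfg.featurizations],
                      cfg.embed.seed, cfg.embed.box,
                      cfg.embed.water_bulk_density, cfg.embed.n_lipids_per_leaflet,
                      cfg.embed.leaflet_z, cfg.embed.hydrocarbon_halfwidth)
    feat_files = [f"features_{i}.npz" for i in range(len(cfg.featurizations))]
    if "featurize" in cfg.stages:
        if cvs is None:
            raise RuntimeError("stage featurize requires stage synth "
                               "(re-run with stages including 'synth')")

        def _featurize():
            topo, trajs = embed_frames(cvs, cfg.embed)
            save_pdb(out / "topology.pdb", topo, _first_frame(trajs[0]))
            params = FeatureParams(reference_xyz=trajs[0].xyz[0])
            per_spec = {}
            for i, spec in enumerate(cfg.featurizations):
                mats = [assemble_features(t, topo, spec, params) for t in trajs]
                np.savez(out / feat_files[i], frame_interval=cvs.frame_interval,
                         **{f"traj_{j}": m.values for j, m in enumerate(mats)})
                per_spec[spec] = mats
            cv_list = [compute_cv(t, topo) for t in trajs]
            arrays = [c.points for c in cv_list]
            np.savez(out / "cvs.npz", frame_interval=cvs.frame_interval,
                     **{f"traj_{j}": a for j, a in enumerate(arrays)})
            return per_spec, arrays

        value, cached = _stage_guard(runner, "featurize", h_feat,
                                     feat_files + ["cvs.npz", "topology.pdb"],
                                     _featurize)
        if value is not None:
            features_by_spec, cv_arrays = value
        else:
            fi = cvs.frame_interval
            for i, spec in enumerate(cfg.featurizations):
                data = np.load(out / feat_files[i])
                mats = []
                for j in range(len(cvs.trajectories)):
                    vals = data[f"traj_{j}"]
                    mats.append(FeatureMatrix(
                        vals, [f"f{c}" for c in range(vals.shape[1])], fi, spec))
                features_by_spec[spec] = mats
            cv_arrays = _load_arrays(out / "cvs.npz")

    # --- gmrq scan --------------------------------------------------------
    best = None
    h_scan = _hash_of("gmrq_scan", h_feat, cfg.t_grid, cfg.g_grid, cfg.k_grid,
                      cfg.msm_lag, cfg.m, cfg.n_tics, cfg.test_fraction,
                      cfg.n_repeats, cfg.seed)
    if "gmrq_scan" in cfg.stages:
        def _scan():
            import pandas as pd

            splits = shuffle_split(range(cfg.synthetic.n_trajectories),
                                   cfg.test_fraction, cfg.n_repeats,
                                   seed=cfg.seed + 1)
            results = hyperparameter_search(
                features_by_spec, cfg.t_grid, cfg.g_grid, cfg.k_grid, splits,
                msm_lag=cfg.msm_lag, m=cfg.m, n_tics=cfg.n_tics, seed=cfg.seed)
            pd.DataFrame(results_to_records(results)).to_csv(
                out / "gmrq.csv", index=False, float_format="%.10g")
            top = top_featurizations(results, n=cfg.top_n)
            chosen = []
            for spec in top:
                r = max((x for x in results if x.spec == spec),
                        key=lambda x: x.mean_test)
                chosen.append({"featurization": spec.label, "t_ns": r.lag_time,
                               "gamma": r.gamma, "k": r.k,
                               "mean_test_score": r.mean_test})
            (out / "best.json").write_text(
                json.dumps(chosen, indent=2, sort_keys=True) + "\n")
            return chosen

        value, cached = _stage_guard(runner, "gmrq_scan", h_scan,
                                     ["gmrq.csv", "best.json"], _scan)
        best = value if value is not None else json.loads((out / "best.json").read_text())

    # --- refit best models on all trajectories ---------------------------
    states_by_model: list[list[np.ndarray]] = []
    h_refit = _hash_of("refit_best", h_scan)
    if "refit_best" in cfg.stages:
        def _refit():
            models = []
            for entry in best:
                spec = FeatureSpec.from_label(entry["featurization"])
                feats = features_by_spec[spec]
                model = fit_tica(feats, entry["t_ns"], entry["gamma"],
                                 n_components=cfg.n_tics)
                tics = transform_all(model, feats)
                km_seed = _derived_seed(cfg.seed, "refit", entry["featurization"],
                                        entry["t_ns"], entry["gamma"], entry["k"])
                km = fit_minibatch_kmeans(tics, entry["k"], seed=km_seed)
                models.append(assign(km, tics))
            np.savez(out / "states.npz",
                     **{f"model_{i}_traj_{j}": s
                        for i, states in enumerate(models)
                        for j, s in enumerate(states)})
            return models

        value, cached = _stage_guard(runner, "refit_best", h_refit,
                                     ["states.npz"], _refit)
        if value is not None:
            states_by_model = value
        else:
            data = np.load(out / "states.npz")
            for i in range(len(best)):
                states_by_model.append(
                    [data[f"model_{i}_traj_{j}"]
                     for j in range(len(cv_arrays))])

    # --- landscape --------------------------------------------------------
    h_land = _hash_of("landscape", h_refit, cfg.bins, cfg.kT)
    if "landscape" in cfg.stages:
        def _landscape():
            points = np.concatenate(cv_arrays, axis=0)
            lo, hi = points.min(axis=0), points.max(axis=0)
            span = hi - lo
            d_edges = np.linspace(lo[0] - 0.05 * span[0], hi[0] + 0.05 * span[0],
                                  cfg.bins + 1)
            t_edges = np.linspace(lo[1] - 0.05 * span[1], hi[1] + 0.05 * span[1],
                                  cfg.bins + 1)
            fi = cvs.frame_interval if cvs is not None else None
            stack = []
            for i, (entry, states) in enumerate(zip(best, states_by_model)):
                msm = estimate_msm(states, cfg.msm_lag, fi, n_states=entry["k"])
                land = msm_weighted_histogram(cv_arrays, states, msm,
                                              bins=(d_edges, t_edges), kT=cfg.kT)
                land.to_csv(out / f"landscape_model_{i}.csv")
                stack.append(land.p)
            mean_p = np.mean(stack, axis=0)
            mean_p /= mean_p.sum()
            mean_land = FreeEnergyLandscape(d_edges, t_edges, mean_p, cfg.kT)
            mean_land.to_csv(out / "landscape.csv")

        files = ["landscape.csv"] + [f"landscape_model_{i}.csv" for i in range(len(best))]
        _stage_guard(runner, "landscape", h_land, files, _landscape)

    # --- deltag -----------------------------------------------------------
    h_dg = _hash_of("deltag", h_refit, cfg.basins.deep if cfg.basins else None,
                    cfg.basins.shallow if cfg.basins else None,
                    cfg.bootstrap_B, cfg.level, cfg.kT)
    if "deltag" in cfg.stages:
        def _deltag():
            fi = cvs.frame_interval
            states = states_by_model[0]
            result = bootstrap_deltaG(cv_arrays, states, cfg.basins, cfg.msm_lag,
                                      fi, kT=cfg.kT, B=cfg.bootstrap_B,
                                      level=cfg.level, seed=cfg.seed + 2000,
                                      n_states=best[0]["k"])
            result.to_json(out / "deltag.json")

        _stage_guard(runner, "deltag", h_dg, ["deltag.json"], _deltag)

    runner.manifest["stages_requested"] = cfg.stages
    runner._write_manifest()
    return runner.manifest


def _stage_guard(runner: _Runner, name: str, inputs_hash: str, outputs, compute):
    try:
        return runner.stage(name, inputs_hash, outputs, compute)
    except Exception as exc:
        raise RuntimeError(
            f"stage {name!r} failed: {exc}; fix the cause and re-run "
            f"`memstate run --config <config>` (completed stages are cached)"
        ) from exc


def _load_cvs(path: Path) -> CVTrajectorySet:
    data = np.load(path)
    fi = float(data["frame_interval"])
    keys = sorted((k for k in data.files if k.startswith("traj_")),
                  key=lambda k: int(k.split("_")[1]))
    return CVTrajectorySet([data[k] for k in keys], fi)


def _load_arrays(path: Path) -> list[np.ndarray]:
    data = np.load(path)
    keys = sorted((k for k in data.files if k.startswith("traj_")),
                  key=lambda k: int(k.split("_")[1]))
    return [data[k] for k in keys]


def _first_frame(traj):
    from .systems import Trajectory

    return Trajectory(traj.xyz[:1], traj.frame_interval, traj.box)
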