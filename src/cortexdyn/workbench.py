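"""End-to-end orchestration: simulate -> QC -> cross-location ->
intra-location -> prediction power -> repeat environment, with a JSON
run manifest recording the configuration, seeds, package versions,
input hashes and per-stage timings so any stage can be re-run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_location import contrast_layers, run_cross_location
from .data_model import (
    ActivityPanel,
    CohortMetadata,
    EnvironmentSchedule,
    LocationInfo,
    apply_missing_policy,
    read_panels,
    read_schedule,
    select_eligible_locations,
    write_panels,
    write_schedule,
)
from .engine import EngineConfig, default_feature_days
from .intra_location import contrast_intra_locations, run_intra_location
from .power import compare_profiles, run_power_profiles
from .repeat_env import (
    MIN_PAIRS,
    fit_interval_dependence,
    run_repeat_prediction,
    select_repeat_pairs,
    summarize_across_locations,
)
from .synthetic import DynamicsSpec, demo_schedule, generate_cohort

STAGES = ("simulate", "qc", "cross_location", "intra_location", "power", "repeat_env")


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient for bit-identical re-runs."""

    config: dict
    seed: int
    versions: dict[str, str] = field(default_factory=dict)
    input_hashes: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)

    def write(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config: dict | Path | str) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _build_specs(cfg: dict) -> dict[str, DynamicsSpec]:
    specs = {}
    for comp, kw in cfg.items():
        specs[comp] = DynamicsSpec(**kw)
    return specs


def run_all(
    config: dict | Path | str,
    out_dir: Path | str | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Execute the configured stages and write tidy CSVs plus a manifest.

    The config (dict or YAML path) either names input tables
    (``inputs: {activity, metadata, schedule}``) or carries a
    ``simulate`` block; stage blocks (``cross_location``,
    ``intra_location``, ``power``, ``repeat_env``) override per-stage
    parameters and ``stages`` selects which to run.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(out_dir or cfg.get("out_dir", "cortexdyn_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages", STAGES))
    engine = EngineConfig(**cfg.get("engine", {}))

    import scipy
    import sklearn

    manifest = RunManifest(
        config=cfg,
        seed=seed,
        versions={
            "cortexdyn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    )

    def _register(stage: str, *paths: Path) -> None:
        manifest.outputs.setdefault(stage, []).extend(str(p) for p in paths)

    def _run_stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # surface which stage died and with what seed
            raise RuntimeError(f"stage {name!r} failed (seed {seed}): {exc}") from exc
        manifest.timings[name] = time.perf_counter() - t0

    panels: list[ActivityPanel] = []
    schedule: EnvironmentSchedule | None = None
    compartments: list[str] = []

    # ---- inputs / simulation -------------------------------------------
    if "inputs" in cfg:
        paths = cfg["inputs"]
        for key, p in paths.items():
            manifest.input_hashes[key] = _sha256(Path(p))
        panels = read_panels(paths["activity"], paths["metadata"])
        schedule = read_schedule(paths["schedule"])
        compartments = sorted({p.compartment for p in panels})
    elif "simulate" in stages or "simulate" in cfg:
        sim = cfg.get("simulate", {})
        n_scans = int(sim.get("n_scans", 12))
        schedule = demo_schedule(
            sim.get("mouse_id", "Syn"), n_scans, int(sim.get("spacing", 3))
        )
        specs = _build_specs(
            sim.get(
                "compartments",
                {
                    "II/III": {"regime": "shared_recency"},
                    "V": {"regime": "location_specific_lag"},
                },
            )
        )
        compartments = sorted(specs)

        def _simulate() -> None:
            nonlocal panels
            panels, _truth = generate_cohort(
                int(sim.get("n_locations", 3)),
                int(sim.get("n_neurons", 1000)),
                schedule,
                specs,
                seed=seed,
            )
            write_panels(panels, out / "activity.csv", out / "metadata.csv")
            write_schedule(schedule, out / "schedule.csv")
            _register(
                "simulate",
                out / "activity.csv",
                out / "metadata.csv",
                out / "schedule.csv",
            )

        _run_stage("simulate", _simulate)
    else:
        raise ValueError("config must provide 'inputs' or a 'simulate' block")

    # ---- QC -------------------------------------------------------------
    if "qc" in stages:

        def _qc() -> None:
            nonlocal panels
            meta = CohortMetadata(
                mouse_id=panels[0].mouse_id,
                locations={
                    p.location_id: LocationInfo(p.area_type, p.hemisphere)
                    for p in panels
                },
                scanned_length_days=int(panels[0].scan_days[-1]),
                scanned_times=panels[0].n_days,
            )
            panels = [
                apply_missing_policy(p)
                for p in select_eligible_locations(panels, meta)
            ]
            summary = pd.DataFrame(
                {
                    "location": [p.location_id for p in panels],
                    "compartment": [p.compartment for p in panels],
                    "n_neurons": [p.n_neurons for p in panels],
                    "n_days": [p.n_days for p in panels],
                }
            )
            summary.to_csv(out / "qc_summary.csv", index=False)
            _register("qc", out / "qc_summary.csv")

        _run_stage("qc", _qc)

    rng = np.random.default_rng(seed)
    stage_seeds = {name: int(rng.integers(2**31)) for name in STAGES}
    manifest.config["stage_seeds"] = stage_seeds

    # ---- cross-location --------------------------------------------------
    if "cross_location" in stages and len(compartments) >= 1:

        def _cross() -> None:
            opts = cfg.get("cross_location", {})
            n_repeats = int(opts.get("n_repeats", 10))
            n_shuffles = int(opts.get("n_shuffles", 20))
            per_comp = {}
            for comp in compartments:
                mats = run_cross_location(
                    panels,
                    comp,
                    engine,
                    n_repeats=n_repeats,
                    seed=stage_seeds["cross_location"],
                    n_shuffles=n_shuffles,
                )
                per_comp[comp] = mats
                rows = []
                for m in mats:
                    for i, li in enumerate(m.locations):
                        for j, lj in enumerate(m.locations):
                            if i != j:
                                rows.append(
                                    {
                                        "compartment": comp,
                                        "repeat": m.repeat_index,
                                        "train_location": li,
                                        "test_location": lj,
                                        "kappa": m.kappa[i, j],
                                    }
                                )
                tag = comp.replace("/", "-")
                pd.DataFrame(rows).to_csv(
                    out / f"cross_location_kappa_{tag}.csv", index=False
                )
                _register("cross_location", out / f"cross_location_kappa_{tag}.csv")
            if set(per_comp) >= {"II/III", "V"}:
                lc = contrast_layers(per_comp["II/III"], per_comp["V"])
                n = len(lc.locations)
                rows = [
                    {
                        "train_location": lc.locations[i],
                        "test_location": lc.locations[j],
                        "m_kappa": lc.m_kappa[i, j],
                        "m_s": lc.m_s[i, j],
                        "p_value": lc.p_values[i, j],
                        "p_adjusted": lc.p_adjusted[i, j],
                        "significant": bool(lc.significant[i, j]),
                    }
                    for i in range(n)
                    for j in range(n)
                    if i != j
                ]
                pd.DataFrame(rows).to_csv(out / "layer_contrast.csv", index=False)
                _register("cross_location", out / "layer_contrast.csv")

        _run_stage("cross_location", _cross)

    # ---- intra-location --------------------------------------------------
    if "intra_location" in stages:

        def _intra() -> None:
            opts = cfg.get("intra_location", {})
            n_repeats = int(opts.get("n_repeats", 10))
            per_comp = {}
            rows = []
            for comp in compartments:
                outc = run_intra_location(
                    panels,
                    comp,
                    engine,
                    n_repeats=n_repeats,
                    seed=stage_seeds["intra_location"],
                )
                per_comp[comp] = outc
                for loc, runs in outc.items():
                    for k, o in enumerate(runs):
                        rows.append(
                            {
                                "compartment": comp,
                                "location": loc,
                                "repeat": k,
                                "delta_r": o.delta_r,
                                "kappa": o.kappa,
                                "r2": o.r2,
                            }
                        )
            pd.DataFrame(rows).to_csv(out / "intra_location.csv", index=False)
            _register("intra_location", out / "intra_location.csv")
            if set(per_comp) >= {"II/III", "V"} and per_comp["II/III"] and per_comp["V"]:
                common = set(per_comp["II/III"]) & set(per_comp["V"])
                if common:
                    ic = contrast_intra_locations(per_comp["II/III"], per_comp["V"])
                    pd.DataFrame(
                        {
                            "location": ic.locations,
                            "mean_kappa_II_III": ic.mean_kappa_superficial,
                            "mean_kappa_V": ic.mean_kappa_deep,
                            "p_value": ic.p_values,
                            "p_adjusted": ic.p_adjusted,
                            "significant": ic.significant,
                        }
                    ).to_csv(out / "intra_location_contrast.csv", index=False)
                    _register("intra_location", out / "intra_location_contrast.csv")

        _run_stage("intra_location", _intra)

    # ---- prediction power ------------------------------------------------
    if "power" in stages:

        def _power() -> None:
            target_day = int(panels[0].scan_days[-1])
            feature_days = default_feature_days(panels[0], target_day)
            rows = []
            for comp in compartments:
                profiles = run_power_profiles(
                    panels,
                    comp,
                    target_day,
                    feature_days,
                    engine,
                    seed=stage_seeds["power"],
                    schedule=schedule,
                )
                sims = compare_profiles(profiles)
                for prof in profiles:
                    for d, p_d, env in zip(
                        prof.feature_days,
                        prof.powers,
                        prof.environments or [""] * len(prof.feature_days),
                    ):
                        rows.append(
                            {
                                "model": prof.model_id,
                                "compartment": comp,
                                "feature_day": d,
                                "power": p_d,
                                "environment": env,
                                "mean_within_similarity": sims.mean_within_a,
                            }
                        )
            pd.DataFrame(rows).to_csv(out / "power_profiles.csv", index=False)
            _register("power", out / "power_profiles.csv")

        _run_stage("power", _power)

    # ---- repeat environment ----------------------------------------------
    if "repeat_env" in stages and schedule is not None:

        def _repeat() -> None:
            opts = cfg.get("repeat_env", {})
            n_repeats = int(opts.get("n_repeats", 100))
            min_pairs = int(opts.get("min_pairs", MIN_PAIRS))
            pairs = select_repeat_pairs(schedule)
            if len(pairs) < min_pairs:
                warnings.warn(
                    f"mouse {schedule.mouse_id}: only {len(pairs)} environment-repeat "
                    f"pairs (< {min_pairs}); excluded from the interval analysis",
                    stacklevel=2,
                )
                manifest.outputs.setdefault("repeat_env", []).append(
                    f"excluded: {len(pairs)} pairs < {min_pairs}"
                )
                return
            rows = []
            for comp in compartments:
                results = {}
                for pair in pairs:
                    res = [
                        run_repeat_prediction(
                            p,
                            pair,
                            schedule,
                            engine,
                            n_repeats=n_repeats,
                            seed=stage_seeds["repeat_env"],
                        )
                        for p in panels
                        if p.compartment == comp
                    ]
                    results[pair] = res
                ordered, means, sds = summarize_across_locations(results)
                summary = fit_interval_dependence(ordered, means, sds)
                for p, m, s, mm, ms in zip(
                    ordered, means, sds, summary.modified_mean, summary.modified_sd
                ):
                    rows.append(
                        {
                            "compartment": comp,
                            "environment": p.environment,
                            "earlier_day": p.earlier_day,
                            "later_day": p.later_day,
                            "interval": p.interval,
                            "mean_delta_r": m,
                            "sd_delta_r": s,
                            "modified_mean_delta_r": mm,
                            "modified_sd_delta_r": ms,
                            "rho_m": summary.rho_m,
                            "alpha_m": summary.alpha_m,
                            "r2_m": summary.r2_m,
                            "rho_s": summary.rho_s,
                            "alpha_s": summary.alpha_s,
                            "r2_s": summary.r2_s,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "repeat_environment.csv", index=False)
            _register("repeat_env", out / "repeat_environment.csv")

        _run_stage("repeat_env", _repeat)

    manifest.write(out / "manifest.json")
    _register("manifest", out / "manifest.json")
    return manifest
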