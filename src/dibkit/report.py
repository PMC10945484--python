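"""End-to-end study orchestration.

A study YAML declares experimental conditions (lipid system, isoflavone,
lipid:isoflavone mole ratio) with per-assay generator configs or input file
paths. ``run_study`` executes each assay per condition, computes
control-relative quantities, and writes ``pf_summary.csv``,
``dsc_summary.csv``, ``raman_summary.csv`` and a ``manifest.json`` with
seeds and output checksums. Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, dsc, io, permeability, raman, synthetic_data
from .errors import ConfigError

__all__ = ["StudyConfig", "Condition", "run_study", "load_study_config"]

ISOFLAVONES = ("none", "GEN", "DAI")


@dataclass
class Condition:
    label: str
    lipid_system: str = "DOPC"
    isoflavone: str = "none"
    mole_ratio: str = "0"  # "lipid:isoflavone", control rows carry "0"
    pf: dict[str, Any] | None = None
    dsc: dict[str, Any] | None = None
    raman: dict[str, Any] | None = None

    def __post_init__(self):
        if self.isoflavone not in ISOFLAVONES:
            raise ConfigError(
                f"isoflavone must be one of {ISOFLAVONES}, got {self.isoflavone!r}"
            )
        self.mole_ratio = str(self.mole_ratio)
        if self.isoflavone != "none":
            parts = self.mole_ratio.split(":")
            if len(parts) != 2 or any(float(p) <= 0 for p in parts):
                raise ConfigError(
                    f"mole_ratio must be 'lipid:isoflavone' with positive parts, "
                    f"got {self.mole_ratio!r}"
                )

    @property
    def is_control(self) -> bool:
        return self.isoflavone == "none"


@dataclass
class StudyConfig:
    conditions: list[Condition]
    output_dir: str | Path = "study_out"
    seed: int = 0

    def __post_init__(self):
        if not self.conditions:
            raise ConfigError("condition list is empty")
        self.conditions = [
            c if isinstance(c, Condition) else Condition(**c) for c in self.conditions
        ]
        for system in {c.lipid_system for c in self.conditions}:
            n_ctrl = sum(
                1
                for c in self.conditions
                if c.lipid_system == system and c.is_control
            )
            if n_ctrl != 1:
                raise ConfigError(
                    f"lipid system {system!r} needs exactly one control condition "
                    f"(isoflavone: none), found {n_ctrl}"
                )


def load_study_config(path: str | Path) -> StudyConfig:
    data = yaml.safe_load(Path(path).read_text())
    return StudyConfig(
        conditions=data["conditions"],
        output_dir=data.get("output_dir", "study_out"),
        seed=int(data.get("seed", 0)),
    )


def _derive_seed(global_seed: int, *parts) -> int:
    """Stable per-task seed from the global seed and a label path."""
    h = hashlib.sha256(
        ":".join([str(global_seed), *map(str, parts)]).encode()
    ).digest()
    return int.from_bytes(h[:4], "big")


def _run_pf(cond: Condition, seed: int):
    cfg = dict(cond.pf or {})
    paths = cfg.pop("trajectory_csvs", None)
    method = cfg.pop("method", "ode_fit")
    if paths:
        conditions = permeability.OsmoticConditions(
            osmolality_1=float(cfg.get("osmolality_1", 0.0)),
            osmolality_2=float(cfg.get("osmolality_2", 0.2)),
            v_w=float(cfg.get("v_w", 18.0)),
        )
        trajs = [io.read_trajectory_csv(p) for p in paths]
        mode = cfg.get("shrinkage_mode", "constant_contact_radius")
    else:
        n_rep = int(cfg.pop("n_replicates", 3))
        trajs, conditions, mode = [], None, None
        for i in range(n_rep):
            sim = synthetic_data.DIBSimConfig(
                **cfg, seed=_derive_seed(seed, cond.label, "pf", i)
            )
            trajs.append(synthetic_data.simulate_dib_trajectory(sim))
            conditions = permeability.OsmoticConditions(
                osmolality_1=sim.osmolality_1,
                osmolality_2=sim.osmolality_2,
                v_w=sim.v_w,
            )
            mode = sim.shrinkage_mode
    if method == "initial_rate":
        ests = [
            permeability.estimate_pf_initial_rate(t, conditions) for t in trajs
        ]
    else:
        ests = [
            permeability.estimate_pf_ode_fit(t, conditions, shrinkage_mode=mode)
            for t in trajs
        ]
    return permeability.aggregate_condition(ests, label=cond.label)


def _run_dsc(cond: Condition, seed: int) -> dsc.TransitionMetrics:
    cfg = dict(cond.dsc or {})
    path = cfg.pop("thermogram_csv", None)
    pre = tuple(cfg.pop("pre_window", (-38.0, -30.0)))
    post = tuple(cfg.pop("post_window", (-6.0, -1.0)))
    if path:
        tg = io.read_thermogram_csv(path)
    else:
        sim = synthetic_data.DSCSimConfig(
            **cfg, seed=_derive_seed(seed, cond.label, "dsc")
        )
        tg = synthetic_data.simulate_thermogram(sim)
    trace = dsc.heatflow_to_molar_cp(tg)
    trace = dsc.subtract_baseline(trace, pre, post)
    return dsc.transition_metrics(trace)


def _run_raman(cond: Condition, seed: int) -> raman.RatioSummary:
    cfg = dict(cond.raman or {})
    paths = cfg.pop("spectrum_csvs", None)
    if paths:
        results = [
            [raman.band_ratios(raman.baseline_correct(io.read_spectrum_csv(p)))]
            for p in paths
        ]
        return raman.summarize_ratios(results)
    n_samples = int(cfg.pop("n_samples", 3))
    n_regions = int(cfg.pop("n_regions", 3))
    bands = synthetic_data.calibrate_ch_band_amplitudes(
        float(cfg.pop("ratio_2930_2848")), float(cfg.pop("ratio_2930_2890"))
    )
    baseline = tuple(cfg.pop("baseline_poly_coeffs", ()))
    noise_sd = float(cfg.pop("noise_sd", 0.0))
    results = []
    for s in range(n_samples):
        regions = []
        for r in range(n_regions):
            sim = synthetic_data.RamanSimConfig(
                band_table=bands,
                baseline_poly_coeffs=baseline,
                noise_sd=noise_sd,
                seed=_derive_seed(seed, cond.label, "raman", s, r),
            )
            spec = synthetic_data.simulate_raman_spectrum(sim)
            spec = raman.baseline_correct(spec)
            spec = raman.normalize_at(spec)
            regions.append(raman.band_ratios(spec))
        results.append(regions)
    return raman.summarize_ratios(results)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig) -> dict:
    """Run every configured assay for every condition and write the report
    bundle. Per-condition failures are recorded and the run continues."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    controls_pf: dict[str, float] = {}
    controls_dsc: dict[str, dsc.TransitionMetrics] = {}
    errors: dict[str, str] = {}

    pf_rows, dsc_rows, raman_rows = [], [], []
    results: dict[str, dict] = {}

    ordered = sorted(config.conditions, key=lambda c: not c.is_control)
    for cond in ordered:
        res: dict[str, Any] = {}
        key = (cond.label, cond.lipid_system)
        if cond.pf is not None:
            try:
                summary = _run_pf(cond, config.seed)
                res["pf"] = summary
                if cond.is_control:
                    controls_pf[cond.lipid_system] = summary.mean_Pf
            except Exception as exc:  # recorded, run continues
                errors[f"{cond.label}/pf"] = f"{type(exc).__name__}: {exc}"
        if cond.dsc is not None:
            try:
                metrics = _run_dsc(cond, config.seed)
                res["dsc"] = metrics
                if cond.is_control:
                    controls_dsc[cond.lipid_system] = metrics
            except Exception as exc:
                errors[f"{cond.label}/dsc"] = f"{type(exc).__name__}: {exc}"
        if cond.raman is not None:
            try:
                res["raman"] = _run_raman(cond, config.seed)
            except Exception as exc:
                errors[f"{cond.label}/raman"] = f"{type(exc).__name__}: {exc}"
        results[cond.label] = res

    for cond in ordered:
        res = results[cond.label]
        base = {
            "condition": cond.label,
            "lipid_system": cond.lipid_system,
            "isoflavone": cond.isoflavone,
            "mole_ratio": cond.mole_ratio,
        }
        if "pf" in res:
            s = res["pf"]
            ctrl = controls_pf.get(cond.lipid_system)
            pct = (
                round(permeability.percent_change(s.mean_Pf, ctrl))
                if ctrl and not cond.is_control
                else 0
            )
            pf_rows.append(
                {**base, "mean_Pf_um_s": s.mean_Pf, "sem_um_s": s.sem, "n": s.n,
                 "pct_change_vs_control": pct}
            )
        if "dsc" in res:
            m = res["dsc"]
            row = {**base, "Tm_C": m.Tm, "dH_kcal_mol": m.dH, "dT_half_C": m.dT_half}
            ctrl = controls_dsc.get(cond.lipid_system)
            if ctrl is not None:
                comp = dsc.compare_to_control(m, ctrl)
                row["dTm_C"] = comp.dTm
                row["dH_ratio"] = comp.dH_ratio
            dsc_rows.append(row)
        if "raman" in res:
            r = res["raman"]
            raman_rows.append(
                {**base,
                 "ratio_2930_2848_mean": r.mean_2930_2848,
                 "ratio_2930_2848_sd": r.sd_2930_2848,
                 "ratio_2930_2890_mean": r.mean_2930_2890,
                 "ratio_2930_2890_sd": r.sd_2930_2890,
                 "n_samples": r.n_samples}
            )

    written: dict[str, str] = {}
    for name, rows in (
        ("pf_summary.csv", pf_rows),
        ("dsc_summary.csv", dsc_rows),
        ("raman_summary.csv", raman_rows),
    ):
        if rows:
            path = out / name
            pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
            written[name] = _checksum(path)

    manifest = {
        "dibkit_version": __version__,
        "seed": config.seed,
        "conditions": [c.label for c in config.conditions],
        "outputs": written,
        "errors": errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"results": results, "manifest": manifest, "output_dir": out}
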