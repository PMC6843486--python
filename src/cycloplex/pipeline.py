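"""End-to-end orchestration: simulate -> analyze -> summarize.

A :class:`RunConfig` (YAML on disk) names the binding scenarios to
simulate, the analysis windows and cutoffs, the solubility/dose-response
ground truths and the entropy inputs.  :func:`run_pipeline` executes every
stage in order and emits CSV tables (component ledger, stability constants,
thermodynamics, enhancement, IC50), PES heatmaps and trace CSVs under one
output directory.  Stages can also be run individually (the CLI maps one
subcommand to each); later stages read the artifacts of earlier ones from
the same directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assay, fes, gbsa, geometry, pdbio, solubility, synthetic
from .synthetic import ScenarioSpec, ToyHostSpec

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "STAGES"]

log = logging.getLogger("cycloplex")


class ConfigError(ValueError):
    """The run configuration is invalid; nothing was computed."""


_DEF_SCENARIOS = [
    {"name": "stable_wide", "scenario": "stable_wide", "ou_mean": 3.0},
    {"name": "stable_narrow", "scenario": "stable_narrow", "ou_mean": -3.0},
    {"name": "dissociating", "scenario": "dissociating", "ou_mean": 0.0},
]

_DEF_SOLUBILITY = {
    "S0_true_M": 9.0e-6,
    "noise_cv": 0.02,
    "temperatures_C": [30.0, 37.0, 45.0],
    "kc_true": {"host_beta": 562.0, "host_dimethyl": 2245.0,
                "host_hydroxypropyl": 684.0},
    "cd_concentrations_M": [0.0, 0.002, 0.004, 0.006, 0.008, 0.010],
}

_DEF_IC50 = {
    "ic50_true_uM": {"guest": 42.86, "complex_beta": 17.63,
                     "complex_dimethyl": 13.45, "complex_hydroxypropyl": 5.62},
    "hill": 1.0,
    "noise_sd_pct": 3.0,
    "n_replicates": 3,
}


@dataclass
class RunConfig:
    seed: int
    scenarios: list = field(default_factory=lambda: list(_DEF_SCENARIOS))
    n_replicates: int = 3
    n_frames: int = 900
    timestep_ns: float = 0.05
    window_ns: float = 20.0
    contact_cutoff: float = 3.0
    hbond_cutoff: float = 3.5
    rim_half_height: float = 3.95
    pes_temperature: float = 303.0
    gbsa_tds: dict = field(default_factory=dict)  # scenario name -> kcal/mol
    gbsa_n_snapshots: int = 100
    gbsa_systems: list = field(default_factory=lambda: ["stable_wide"])
    sasa_stride: int = 4
    sasa_points: int = 240
    solubility: dict = field(default_factory=lambda: dict(_DEF_SOLUBILITY))
    ic50: dict = field(default_factory=lambda: dict(_DEF_IC50))
    config_hash: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = Path(path).read_bytes()
        data = yaml.safe_load(raw) or {}
        if "seed" not in data:
            raise ConfigError("config must set an explicit seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.config_hash = hashlib.sha256(raw).hexdigest()
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        names = [s.get("name") for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ConfigError("scenario names must be unique")
        for name in self.gbsa_systems:
            if name not in names:
                raise ConfigError(f"gbsa system {name!r} is not a scenario")
            if name not in self.gbsa_tds:
                raise ConfigError(
                    f"dG_bind requested for {name!r} but no TdS input given"
                )

    def scenario_spec(self, entry: dict) -> ScenarioSpec:
        fields = {k: v for k, v in entry.items() if k != "name"}
        fields.setdefault("n_frames", self.n_frames)
        fields.setdefault("timestep_label", self.timestep_ns)
        fields.setdefault("seed", self.seed)
        return ScenarioSpec(**fields)


def _load_replicates(outdir: Path, name: str):
    paths = sorted(outdir.glob(f"traj_{name}_MD*.pdb"))
    if not paths:
        raise FileNotFoundError(
            f"no trajectories for scenario {name!r} under {outdir}; "
            "run the simulate stage first"
        )
    system = None
    trajs = []
    for p in paths:
        system, tr = pdbio.read_trajectory(p)
        trajs.append(tr)
    return system, trajs


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    host = ToyHostSpec(rim_half_height=cfg.rim_half_height)
    system, xyz = synthetic.build_toy_complex(host)
    artifacts = {}
    for entry in cfg.scenarios:
        name = entry["name"]
        spec = cfg.scenario_spec(entry)
        reps = synthetic.simulate_replicates(system, xyz, spec,
                                             cfg.n_replicates)
        paths = pdbio.write_replicates(system, reps, outdir / f"traj_{name}.pdb")
        artifacts[name] = [str(p) for p in paths]
        log.info("simulated %s: %d replicates x %d frames",
                 name, len(reps), spec.n_frames)
    # synthetic experimental data
    sol_cfg = cfg.solubility
    rows = []
    for i, (host_name, kc30) in enumerate(sorted(sol_cfg["kc_true"].items())):
        for j, temp_c in enumerate(sol_cfg["temperatures_C"]):
            # van't Hoff-consistent decay of Kc with temperature, anchored
            # at the 30 C value with a generic exothermic enthalpy
            t_k = temp_c + 273.15
            t0 = sol_cfg["temperatures_C"][0] + 273.15
            dh = sol_cfg.get("dH_true_kcal_mol", -20.0)
            # ln Kc(T) - ln Kc(T0) = (dH/R) (1/T0 - 1/T); exothermic dH < 0
            # makes the complex less stable as the temperature rises
            kc = kc30 * np.exp(dh / solubility.GAS_CONSTANT_KCAL
                               * (1.0 / t0 - 1.0 / t_k))
            spec = synthetic.SolubilitySimSpec(
                S0_true=sol_cfg["S0_true_M"], Kc_true=float(kc),
                cd_concentrations=tuple(sol_cfg["cd_concentrations_M"]),
                noise_cv=sol_cfg["noise_cv"], temperature=t_k,
                seed=cfg.seed + 101 * i + 13 * j,
            )
            series = synthetic.simulate_phase_solubility(spec)
            df = series.to_frame()
            df["host"] = host_name
            df["kc_true"] = kc
            rows.append(df)
    sol_path = outdir / "solubility_series.csv"
    pd.concat(rows).to_csv(sol_path, index=False)
    artifacts["solubility_series"] = str(sol_path)

    ic_cfg = cfg.ic50
    rows = []
    for i, (label, truth) in enumerate(sorted(ic_cfg["ic50_true_uM"].items())):
        for r in range(ic_cfg["n_replicates"]):
            spec = synthetic.DoseResponseSimSpec(
                ic50_true=truth, hill=ic_cfg["hill"],
                noise_sd=ic_cfg["noise_sd_pct"],
                seed=cfg.seed + 17 * i + r,
            )
            df = synthetic.simulate_dose_response(spec).to_frame()
            df["compound"] = label
            df["replicate"] = f"exp{r + 1}"
            rows.append(df)
    dr_path = outdir / "dose_response_series.csv"
    pd.concat(rows).to_csv(dr_path, index=False)
    artifacts["dose_response_series"] = str(dr_path)
    return artifacts


def stage_geometry(cfg: RunConfig, outdir: Path) -> dict:
    rows = []
    modes = []
    for entry in cfg.scenarios:
        name = entry["name"]
        system, trajs = _load_replicates(outdir, name)
        for tr in trajs:
            for ring in ("A", "Q"):
                trace = geometry.signed_ring_distance(system, tr, ring)
                df = trace.to_frame()
                df["scenario"] = name
                rows.append(df)
            whole = geometry.signed_ring_distance(system, tr, "guest")
            mode = geometry.classify_binding_mode(
                whole, tr.last_window(cfg.window_ns),
                rim_half_height=cfg.rim_half_height,
            )
            modes.append({"scenario": name, "replicate": tr.replicate_id,
                          "binding_mode": mode})
    path = outdir / "ring_distance_traces.csv"
    pd.concat(rows).to_csv(path, index=False)
    mpath = outdir / "binding_modes.csv"
    pd.DataFrame(modes).to_csv(mpath, index=False)
    return {"traces": str(path), "binding_modes": str(mpath)}


def stage_pes(cfg: RunConfig, outdir: Path) -> dict:
    artifacts = {}
    for entry in cfg.scenarios:
        name = entry["name"]
        system, trajs = _load_replicates(outdir, name)
        x = np.concatenate([geometry.rim_distances(system, t).d32.ravel()
                            for t in trajs])
        y = np.concatenate([geometry.rim_distances(system, t).d44.ravel()
                            for t in trajs])
        grid = fes.pes_2d(x, y, temperature=cfg.pes_temperature)
        basins = fes.assign_basins(grid)
        csv = outdir / f"pes_{name}.csv"
        grid.to_frame().to_csv(csv, index=False)
        png = outdir / f"pes_{name}.png"
        fes.plot_pes(grid, png)
        bas = outdir / f"pes_{name}_basins.csv"
        pd.DataFrame([b.__dict__ for b in basins]).to_csv(bas, index=False)
        artifacts[name] = {"grid": str(csv), "plot": str(png),
                           "basins": str(bas)}
    return artifacts


def stage_contacts(cfg: RunConfig, outdir: Path) -> dict:
    rows = []
    for entry in cfg.scenarios:
        name = entry["name"]
        system, trajs = _load_replicates(outdir, name)
        cs = geometry.native_contacts(system, trajs,
                                      cutoff=cfg.contact_cutoff,
                                      window_ns=cfg.window_ns)
        rows.append({
            "scenario": name, "mean_total": cs.mean_total,
            "sem_total": cs.sem_total, "mean_per_unit": cs.mean_per_unit,
            "sem_per_unit": cs.sem_per_unit, "cutoff_A": cs.cutoff,
        })
    path = outdir / "native_contacts.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return {"contacts": str(path)}


def stage_sasa(cfg: RunConfig, outdir: Path) -> dict:
    rows = []
    summary = []
    from .core import Trajectory

    for entry in cfg.scenarios:
        name = entry["name"]
        system, trajs = _load_replicates(outdir, name)
        rep_means = []
        for tr in trajs:
            win = tr.last_window(cfg.window_ns)[::cfg.sasa_stride]
            sub = Trajectory(tr.coords[win], tr.time_per_frame * cfg.sasa_stride,
                             tr.replicate_id)
            st = geometry.guest_sasa(system, sub,
                                     n_sphere_points=cfg.sasa_points)
            rep_means.append(st.values.mean())
            rows.append(pd.DataFrame({
                "frame": win, "sasa_A2": st.values, "scenario": name,
                "replicate": tr.replicate_id,
            }))
        rep_means = np.array(rep_means)
        summary.append({
            "scenario": name, "mean_sasa_A2": rep_means.mean(),
            "sem_sasa_A2": (rep_means.std(ddof=1) / np.sqrt(len(rep_means))
                            if len(rep_means) > 1 else 0.0),
        })
    pd.concat(rows).to_csv(outdir / "sasa_traces.csv", index=False)
    path = outdir / "sasa_summary.csv"
    pd.DataFrame(summary).to_csv(path, index=False)
    return {"sasa": str(path)}


def stage_gbsa(cfg: RunConfig, outdir: Path) -> dict:
    artifacts = {}
    for name in cfg.gbsa_systems:
        system, trajs = _load_replicates(outdir, name)
        ledger = gbsa.mmgbsa_single_trajectory(
            system, trajs, TdS=float(cfg.gbsa_tds[name]),
            window_ns=cfg.window_ns, n_snapshots=cfg.gbsa_n_snapshots,
            sasa_points=cfg.sasa_points,
        )
        path = outdir / f"gbsa_ledger_{name}.csv"
        ledger.to_frame().to_csv(path, index=False)
        report = gbsa.verify_ledger(ledger)
        report.to_csv(outdir / f"gbsa_identities_{name}.csv", index=False)
        if report["flagged"].any():
            raise RuntimeError(f"ledger identities violated for {name}")
        artifacts[name] = str(path)
    return artifacts


def stage_solubility(cfg: RunConfig, outdir: Path) -> dict:
    df = pd.read_csv(outdir / "solubility_series.csv")
    fits = []
    for (host_name, temp_c), sub in df.groupby(["host", "temperature_C"]):
        series = solubility.SolubilitySeries(
            sub["cd_conc_M"].to_numpy(), sub["guest_conc_M"].to_numpy(),
            temperature=float(temp_c) + 273.15,
        )
        fit = solubility.fit_isotherm(series)
        fits.append({
            "host": host_name, "temperature_C": temp_c, "slope": fit.slope,
            "S0_M": fit.s0, "Kc_M^-1": fit.kc, "r2": fit.r2,
            "diagram_type": fit.diagram_type,
            "Kc_true": sub["kc_true"].iloc[0],
        })
    path = outdir / "stability_constants.csv"
    pd.DataFrame(fits).to_csv(path, index=False)
    return {"stability_constants": str(path)}


def stage_vanthoff(cfg: RunConfig, outdir: Path) -> dict:
    fits = pd.read_csv(outdir / "stability_constants.csv")
    rows = []
    for host_name, sub in fits.groupby("host"):
        pairs = list(zip(sub["temperature_C"] + 273.15, sub["Kc_M^-1"]))
        th = solubility.vant_hoff(pairs)
        rows.append({
            "host": host_name, "dH_kcal_mol": th.dh,
            "TdS_kcal_mol": th.tds, "dG_exp_kcal_mol": th.dg_exp,
            "report_T_K": th.report_temperature, "r2": th.r2,
        })
    path = outdir / "thermodynamics.csv"
    pd.DataFrame(rows).to_csv(path, index=False)

    # solubility-enhancement table at the lowest temperature
    sol_cfg = cfg.solubility
    s0 = sol_cfg["S0_true_M"]
    enh = []
    cd_max = max(sol_cfg["cd_concentrations_M"])
    base = fits[fits["temperature_C"] == fits["temperature_C"].min()]
    for _, row in base.iterrows():
        complexed = row["S0_M"] + row["slope"] * cd_max
        ratio = solubility.enhancement_ratio(s0, complexed)
        enh.append({
            "host": row["host"], "free_solubility_M": s0,
            "max_solubility_M": complexed, "fold_change": ratio,
            "fold_label": solubility.format_fold(ratio),
        })
    epath = outdir / "enhancement.csv"
    pd.DataFrame(enh).to_csv(epath, index=False)
    return {"thermodynamics": str(path), "enhancement": str(epath)}


def stage_ic50(cfg: RunConfig, outdir: Path) -> dict:
    df = pd.read_csv(outdir / "dose_response_series.csv")
    rows = []
    for (label, rep), sub in df.groupby(["compound", "replicate"]):
        series = assay.DoseResponseSeries(
            sub["dose_uM"].to_numpy(), sub["viability_pct"].to_numpy(),
            replicate_id=str(rep),
        )
        res = assay.fit_4pl(series)
        rows.append({"compound": label, "replicate": rep,
                     "ic50_uM": res.ic50, "hill": res.hill,
                     "top": res.top, "bottom": res.bottom})
    path = outdir / "ic50_fits.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return {"ic50": str(path)}


def stage_stats(cfg: RunConfig, outdir: Path) -> dict:
    fits = pd.read_csv(outdir / "ic50_fits.csv")
    groups = {label: sub["ic50_uM"].to_numpy()
              for label, sub in fits.groupby("compound")}
    comp = assay.anova_newman_keuls(groups)
    rows = [{"pair": " vs ".join(sorted(pair)), "significant": sig}
            for pair, sig in comp.significant.items()]
    path = outdir / "ic50_group_comparison.csv"
    pd.DataFrame(rows).sort_values("pair").to_csv(path, index=False)
    (outdir / "ic50_anova.json").write_text(json.dumps({
        "F": comp.f_statistic, "df_between": comp.df_between,
        "df_within": comp.df_within, "p": comp.p_value,
    }, indent=1))
    return {"comparisons": str(path)}


def stage_report(cfg: RunConfig, outdir: Path) -> dict:
    manifest = sorted(p.name for p in outdir.iterdir() if p.is_file())
    path = outdir / "report_manifest.json"
    path.write_text(json.dumps({
        "config_hash": cfg.config_hash, "artifacts": manifest}, indent=1))
    return {"manifest": str(path)}


STAGES = {
    "simulate": stage_simulate,
    "geometry": stage_geometry,
    "pes": stage_pes,
    "contacts": stage_contacts,
    "sasa": stage_sasa,
    "gbsa": stage_gbsa,
    "solubility": stage_solubility,
    "vanthoff": stage_vanthoff,
    "ic50": stage_ic50,
    "stats": stage_stats,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute every stage in order; returns the artifact map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run config hash: %s", cfg.config_hash or "(in-memory config)")
    artifacts = {}
    for name, stage in STAGES.items():
        log.info("stage %s", name)
        try:
            artifacts[name] = stage(cfg, outdir)
        except Exception:
            log.exception("stage %s failed", name)
            raise
    return artifacts
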