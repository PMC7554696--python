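"""Config-driven orchestration of the multi-technique binding analysis.

A :class:`PipelineConfig` (YAML/JSON) names the stages to run — uvvis,
fluorescence, lifetime, itc, wham, cluster — with their input paths and
parameters.  :func:`run` executes the requested stages, isolating
failures to their stage, and assembles a report with a cross-method
comparison of association constants and binding free energies plus
consistency checks (per-method dG = -RT ln K identities and cross-method
ligand ordering).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import KT_KCAL_PER_MOL, R_KCAL_PER_MOL_K, T_STANDARD
from .exceptions import ConfigError
from . import clustering, itc, quenching, uvvis, wham

logger = logging.getLogger("dnaintercal")

KNOWN_STAGES = ("uvvis", "fluorescence", "lifetime", "itc", "wham", "cluster")


@dataclass
class PipelineConfig:
    stages: dict
    temperature_K: float = T_STANDARD
    R_kcal_per_mol_K: float = R_KCAL_PER_MOL_K
    output_dir: str | None = None
    seed: int = 0
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_dict(cls, raw: dict, base_dir=Path(".")):
        if not isinstance(raw, dict) or not raw.get("stages"):
            raise ConfigError("config must contain a non-empty 'stages' mapping")
        unknown = set(raw["stages"]) - set(KNOWN_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        g = raw.get("global", {})
        temperature = float(g.get("temperature_K", T_STANDARD))
        if temperature <= 0:
            raise ConfigError("temperature_K must be positive")
        return cls(
            stages=raw["stages"],
            temperature_K=temperature,
            R_kcal_per_mol_K=float(g.get("R_kcal_per_mol_K", R_KCAL_PER_MOL_K)),
            output_dir=g.get("output_dir"),
            seed=int(g.get("seed", 0)),
            base_dir=Path(base_dir),
        )

    @classmethod
    def from_yaml(cls, path):
        path = Path(path)
        return cls.from_dict(yaml.safe_load(path.read_text()), base_dir=path.parent)

    def resolve(self, p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p


@dataclass
class Report:
    stages: dict = field(default_factory=dict)
    comparison: dict = field(default_factory=dict)
    consistency: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def all_succeeded(self) -> bool:
        return all(s.get("status") == "ok" for s in self.stages.values())

    def as_dict(self) -> dict:
        return {
            "stages": self.stages,
            "comparison": self.comparison,
            "consistency": self.consistency,
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# stage runners

def _run_uvvis(cfg, block):
    out = {}
    for ds in block["datasets"]:
        series = uvvis.TitrationSeries.from_csv(cfg.resolve(ds["path"]))
        fit = uvvis.benesi_hildebrand_fit(
            series, temperature=cfg.temperature_K, R=cfg.R_kcal_per_mol_K
        )
        out[ds["label"]] = {
            "K_A_per_M": fit.K_A,
            "delta_G_kcal_mol": fit.delta_G,
            "r_squared": fit.r_squared,
            "n_excluded": int(len(fit.excluded_points)),
        }
    return out


def _run_fluorescence(cfg, block):
    out = {}
    for ds in block["datasets"]:
        series = quenching.QuenchSeries.from_csv(cfg.resolve(ds["path"]))
        sv = quenching.stern_volmer_fit(series, tau0=float(ds["tau0_ns"]))
        lb = quenching.lineweaver_burk_fit(series)
        dl = quenching.double_log_fit(series)
        out[ds["label"]] = {
            "K_SV_per_M": sv.K_SV,
            "k_q_per_M_s": sv.k_q,
            "mechanism": sv.mechanism,
            "K_A_LB_per_M": lb.K_A,
            "n_sites": dl.n_sites,
            "log_K_A": dl.log_K_A,
            "delta_G_LB_kcal_mol": uvvis.gibbs_from_binding_constant(
                lb.K_A, cfg.temperature_K, cfg.R_kcal_per_mol_K
            ),
        }
    return out


def _run_lifetime(cfg, block):
    out = {}
    for ds in block["datasets"]:
        decay = quenching.DecayHistogram.from_csv(cfg.resolve(ds["path"]))
        fit = quenching.lifetime_fit(decay, fit_background=ds.get("fit_background", False))
        out[ds["label"]] = {
            "tau_ns": fit.tau,
            "tau_std_err_ns": fit.tau_std_err,
            "reduced_chi2": fit.reduced_chi2,
        }
    return out


def _run_itc(cfg, block):
    out = {}
    for ds in block["datasets"]:
        data = itc.ITCData.from_csv(cfg.resolve(ds["path"]))
        sch = ds["schedule"]
        schedule = itc.InjectionSchedule(
            injection_volumes_uL=np.asarray(sch["injection_volumes_uL"], float),
            syringe_conc_mM=float(sch["syringe_conc_mM"]),
            cell_conc_mM=float(sch["cell_conc_mM"]),
            cell_volume_mL=float(sch.get("cell_volume_mL", 1.400)),
            temperature_K=cfg.temperature_K,
        )
        fit = itc.fit_single_site(
            data,
            schedule,
            discard_first=ds.get("discard_first", True),
            temperature=cfg.temperature_K,
            R=cfg.R_kcal_per_mol_K,
        )
        out[ds["label"]] = {
            "n_sites": fit.model.n,
            "K_per_M": fit.model.K,
            "logK": fit.model.logK,
            "dH_kcal_mol": fit.model.dH,
            "dG_kcal_mol": fit.dG,
            "TdS_kcal_mol": fit.TdS,
            "std_errors": fit.std_errors,
            "c_value": fit.c_value,
            "warnings": fit.warnings,
        }
    return out


def _run_wham(cfg, block):
    windows = wham.read_windows(cfg.resolve(block["metadata"]))
    bins = block.get("bins")
    profile = wham.wham_solve(
        windows,
        bins=bins,
        kT=float(block.get("kT_kcal_mol", KT_KCAL_PER_MOL)),
        tol=float(block.get("tol_kcal_mol", 1e-6)),
        max_iter=int(block.get("max_iter", 100_000)),
    )
    if "plateau_region_nm" in block:
        profile = wham.set_reference(profile, tuple(block["plateau_region_nm"]))
    minimum = wham.locate_minimum(
        profile,
        tuple(block["search_region_nm"]) if "search_region_nm" in block else None,
    )
    result = {
        "converged": profile.converged,
        "n_iterations": profile.n_iterations,
        "reference": profile.reference,
        "r_min_nm": minimum.r_min,
        "well_depth_kcal_mol": minimum.depth,
        "minimum_at_boundary": minimum.at_boundary,
    }
    if cfg.output_dir:
        out_dir = Path(cfg.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        wham.write_profile(
            profile, out_dir / "pmf.csv", out_dir / "pmf_meta.json"
        )
        result["profile_csv"] = str(out_dir / "pmf.csv")
    return result


def _run_cluster(cfg, block):
    ensemble = clustering.read_pdb_ensemble(
        cfg.resolve(block["pdb"]), block.get("selections")
    )
    superpose_on = block.get("superpose_on")
    if superpose_on:
        ensemble = clustering.superpose_ensemble(ensemble, superpose_on)
    result = clustering.cluster_kcenters_kmedoids(
        ensemble,
        block.get("cluster_selection", "ligand_heavy"),
        cutoff=float(block.get("cutoff_nm", 0.3)),
        medoid_sweeps=int(block.get("medoid_sweeps", 10)),
        seed=cfg.seed,
    )
    out = {
        "n_clusters": result.n_clusters,
        "populations": result.populations.tolist(),
        "medoid_frames": result.medoid_frames,
        "max_center_distance_nm": result.max_center_distance,
        "cutoff_nm": result.cutoff,
    }
    if "distance_pairs" in block:
        for pair in block["distance_pairs"]:
            _, mean = clustering.min_distance_series(
                ensemble, pair["from"], pair["to"]
            )
            out[f"mean_min_distance_{pair['from']}_{pair['to']}_nm"] = mean
    return out


_RUNNERS = {
    "uvvis": _run_uvvis,
    "fluorescence": _run_fluorescence,
    "lifetime": _run_lifetime,
    "itc": _run_itc,
    "wham": _run_wham,
    "cluster": _run_cluster,
}


def run(config: PipelineConfig) -> Report:
    """Execute the configured stages and assemble the report.

    Stage failures are recorded (status ``error``) without aborting
    independent stages; :attr:`Report.all_succeeded` reflects them.
    """
    report = Report(
        meta={
            "temperature_K": config.temperature_K,
            "R_kcal_per_mol_K": config.R_kcal_per_mol_K,
            "seed": config.seed,
        }
    )
    for name in KNOWN_STAGES:
        if name not in config.stages:
            continue
        logger.info("running stage %s", name)
        try:
            results = _RUNNERS[name](config, config.stages[name])
            report.stages[name] = {"status": "ok", "results": results}
        except Exception as exc:   # noqa: BLE001 — stage isolation is the contract
            logger.exception("stage %s failed", name)
            report.stages[name] = {
                "status": "error",
                "error": f"{type(exc).__name__}: {exc}",
            }
    report.comparison = _comparison_table(report)
    report.consistency = consistency_checks(report)
    if config.output_dir:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
    return report


def _comparison_table(report: Report) -> dict:
    """K_A and dG per (method, ligand label) across all fitted stages."""
    table = {}

    def add(method, label, K, dG):
        table.setdefault(method, {})[label] = {
            "K_A_per_M": K, "delta_G_kcal_mol": dG,
        }

    stage = report.stages.get("uvvis")
    if stage and stage["status"] == "ok":
        for label, r in stage["results"].items():
            add("benesi_hildebrand", label, r["K_A_per_M"], r["delta_G_kcal_mol"])
    stage = report.stages.get("fluorescence")
    if stage and stage["status"] == "ok":
        for label, r in stage["results"].items():
            add("lineweaver_burk", label, r["K_A_LB_per_M"], r["delta_G_LB_kcal_mol"])
            add("double_log", label, 10.0 ** r["log_K_A"], None)
            add("stern_volmer", label, r["K_SV_per_M"], None)
    stage = report.stages.get("itc")
    if stage and stage["status"] == "ok":
        for label, r in stage["results"].items():
            add("itc", label, r["K_per_M"], r["dG_kcal_mol"])
    return table


def consistency_checks(report: Report) -> list[dict]:
    """Cross-method sanity records: dG identities and ligand ordering."""
    records = []
    RT = report.meta.get("R_kcal_per_mol_K", R_KCAL_PER_MOL_K) * report.meta.get(
        "temperature_K", T_STANDARD
    )
    for method, by_label in report.comparison.items():
        for label, vals in by_label.items():
            if vals["delta_G_kcal_mol"] is None:
                continue
            expected = -RT * np.log(vals["K_A_per_M"])
            ok = abs(expected - vals["delta_G_kcal_mol"]) < 1e-9
            records.append(
                {
                    "check": f"dG_identity/{method}/{label}",
                    "status": "pass" if ok else "fail",
                    "detail": {
                        "reported": vals["delta_G_kcal_mol"],
                        "recomputed": expected,
                    },
                }
            )
    methods = {
        m: b for m, b in report.comparison.items() if len(b) >= 2
    }
    if len(methods) >= 2:
        orderings = {}
        for m, by_label in methods.items():
            labels = sorted(by_label)
            orderings[m] = tuple(
                sorted(labels, key=lambda lb: -by_label[lb]["K_A_per_M"])
            )
        unique = set(orderings.values())
        records.append(
            {
                "check": "cross_method_K_A_ordering",
                "status": "pass" if len(unique) == 1 else "fail",
                "detail": {m: list(o) for m, o in orderings.items()},
            }
        )
    else:
        records.append(
            {
                "check": "cross_method_K_A_ordering",
                "status": "skipped",
                "detail": "need >= 2 methods with >= 2 ligands",
            }
        )
    return records
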