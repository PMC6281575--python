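"""End-to-end orchestration: load inputs, run the enabled analyses, write a
report bundle and a manifest sufficient to reproduce the run."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import substream
from .io import load_region_map
from .meet import meet
from .regression import fit_poisson, read_covariates
from .scan import scan, scan_circular
from .sensitivity import UndiagnosedPool, diagnosis_rates, read_undiagnosed, run_sensitivity
from .standardize import expected_counts, read_strata

__all__ = ["RunConfig", "PipelineConfigError", "run_all"]


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    regions: str
    adjacency: str
    strata: str
    out_dir: str
    covariates: str | None = None
    undiagnosed: str | None = None
    confirmatory: str | None = None  # stratum,tested,diagnosed
    methods: tuple[str, ...] = ("scan", "meet", "regress")
    scan_mode: str = "flexible"
    k_max: int = 15
    lambda_grid: tuple[float, ...] = tuple(np.arange(5.0, 100.0 + 1e-9, 5.0))
    reps: int = 999
    sensitivity_runs: int = 0
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise PipelineConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        for seq_key in ("methods", "lambda_grid"):
            if seq_key in raw and raw[seq_key] is not None:
                raw[seq_key] = tuple(raw[seq_key])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("regions", "adjacency", "strata"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineConfigError(f"input file for {name!r} not found: {p}")
        for name in ("covariates", "undiagnosed", "confirmatory"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineConfigError(f"input file for {name!r} not found: {p}")
        bad = set(self.methods) - {"scan", "meet", "regress", "sensitivity"}
        if bad:
            raise PipelineConfigError(f"unknown methods {sorted(bad)}")
        if "regress" in self.methods and self.covariates is None:
            raise PipelineConfigError("regression enabled but no covariates file configured")
        if "sensitivity" in self.methods and (self.undiagnosed is None or self.confirmatory is None):
            raise PipelineConfigError("sensitivity enabled but undiagnosed/confirmatory files missing")
        if self.scan_mode not in ("flexible", "circular"):
            raise PipelineConfigError(f"unknown scan_mode {self.scan_mode!r}")
        if self.reps < 1 or self.k_max < 1:
            raise PipelineConfigError("reps and k_max must be positive")


def run_all(config: RunConfig, dry_run: bool = False) -> dict:
    """Run every enabled analysis; returns the manifest dict."""
    config.validate()
    if dry_run:
        return {"validated": True, "config": asdict(config)}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "arealscan_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {},
        "skipped": [],
    }

    def _fail(module: str, err: Exception):
        raise RuntimeError(f"pipeline failed in {module}: {err}") from err

    try:
        region_map = load_region_map(config.regions, config.adjacency)
        counts = read_strata(config.strata)
    except Exception as err:
        _fail("io", err)

    try:
        exp = expected_counts(counts)
        exp_path = out / "expected.csv"
        exp.table.rename_axis("region_id").to_csv(exp_path)
        manifest["outputs"]["expected"] = str(exp_path)
    except Exception as err:
        _fail("standardize", err)

    if "scan" in config.methods:
        try:
            fn = scan if config.scan_mode == "flexible" else scan_circular
            res = fn(
                counts.cases, exp.expected, region_map,
                k_max=config.k_max, reps=config.reps, seed=substream(config.seed, "scan"),
            )
            scan_path = out / "scan.json"
            scan_path.write_text(json.dumps(res.to_dict(), indent=2))
            manifest["outputs"]["scan"] = str(scan_path)
        except Exception as err:
            _fail("scan", err)
    else:
        manifest["skipped"].append("scan")

    if "meet" in config.methods:
        try:
            prof = meet(
                counts.cases, exp.expected, region_map,
                lambda_grid=np.asarray(config.lambda_grid), reps=config.reps,
                seed=substream(config.seed, "meet"),
            )
            meet_csv = out / "meet.csv"
            prof.to_frame().to_csv(meet_csv, index=False)
            meet_json = out / "meet.json"
            meet_json.write_text(json.dumps(prof.to_dict(), indent=2))
            manifest["outputs"]["meet"] = [str(meet_csv), str(meet_json)]
        except Exception as err:
            _fail("meet", err)
    else:
        manifest["skipped"].append("meet")

    if "regress" in config.methods:
        try:
            cov = read_covariates(config.covariates).reindex(list(region_map.region_ids))
            if cov.isna().any().any():
                missing = list(cov.columns[cov.isna().any()])
                raise PipelineConfigError(f"covariate values missing for some regions in {missing}")
            o = counts.cases.reindex(list(region_map.region_ids)).to_numpy()
            e = exp.expected.reindex(list(region_map.region_ids)).to_numpy()
            rows_c, rows_q = [], []
            for name in cov.columns:
                x = cov[name].to_numpy(dtype=float)
                fc = fit_poisson(o, e, x, form="continuous", covariate=name)
                rows_c.append(
                    {
                        "covariate": name,
                        "exp_coef": fc.rate_ratio[name],
                        "ci_lo": fc.conf_int.loc[name, "lo"],
                        "ci_hi": fc.conf_int.loc[name, "hi"],
                        "wald_p": fc.wald_p[name],
                        "residual_deviance": fc.residual_deviance,
                        "aic": fc.aic,
                    }
                )
                fq = fit_poisson(o, e, x, form="quartile", covariate=name)
                for q in (2, 3, 4):
                    key = f"{name}_Q{q}"
                    rows_q.append(
                        {
                            "covariate": name,
                            "category": f"Q{q}",
                            "exp_coef": fq.rate_ratio[key],
                            "ci_lo": fq.conf_int.loc[key, "lo"],
                            "ci_hi": fq.conf_int.loc[key, "hi"],
                            "wald_p": fq.wald_p[key],
                            "trend_p": fq.trend_p,
                            "residual_deviance": fq.residual_deviance,
                            "aic": fq.aic,
                        }
                    )
            fn0 = fit_poisson(o, e, form="null")
            rows_c.insert(
                0,
                {
                    "covariate": "(null)",
                    "exp_coef": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "wald_p": np.nan,
                    "residual_deviance": fn0.residual_deviance,
                    "aic": fn0.aic,
                },
            )
            pc = out / "regression_continuous.csv"
            pq = out / "regression_quartile.csv"
            pd.DataFrame(rows_c).to_csv(pc, index=False)
            pd.DataFrame(rows_q).to_csv(pq, index=False)
            manifest["outputs"]["regression"] = [str(pc), str(pq)]
        except Exception as err:
            _fail("regression", err)
    else:
        manifest["skipped"].append("regress")

    if "sensitivity" in config.methods:
        try:
            u = read_undiagnosed(config.undiagnosed, counts.pop.columns)
            conf = pd.read_csv(config.confirmatory).set_index("stratum")
            q = diagnosis_rates(
                conf["tested"].reindex(counts.pop.columns),
                conf["diagnosed"].reindex(counts.pop.columns),
            )
            pool = UndiagnosedPool(u=u.reindex(counts.pop.index).fillna(0).astype(int), q=q)
            cov = read_covariates(config.covariates) if config.covariates else None
            rep = run_sensitivity(
                region_map, counts, pool,
                covariates=cov,
                methods=tuple(m for m in ("scan", "meet", "regress") if m in config.methods),
                T=config.sensitivity_runs or 100,
                seed=substream(config.seed, "sensitivity"),
                k_max=config.k_max,
                reps=config.reps,
                lambda_grid=np.asarray(config.lambda_grid),
            )
            runs_path = out / "sensitivity_runs.csv"
            tbl = rep.p_values.copy()
            tbl.insert(0, "added_cases", rep.added_cases)
            tbl.rename_axis("run").to_csv(runs_path)
            summ_path = out / "sensitivity_summary.json"
            summ_path.write_text(json.dumps(rep.to_dict(), indent=2))
            manifest["outputs"]["sensitivity"] = [str(runs_path), str(summ_path)]
        except Exception as err:
            _fail("sensitivity", err)
    else:
        manifest["skipped"].append("sensitivity")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
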