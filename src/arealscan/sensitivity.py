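"""Monte Carlo sensitivity analysis for screen-positives without confirmatory testing.

Screening with two phases leaves a pool of primary-positive examinees who
never received a confirmatory diagnosis.  The procedure: (1) estimate the
stratum-specific (sex × age band) diagnosis rate q_k among the positives
who *were* confirmatory-tested, assuming no regional variation in q_k;
(2) draw hypothetical extra cases Binomial(u_ik, q_k) for the undiagnosed
pool of each region × stratum; (3) re-standardise and re-run every analysis
on the augmented counts; (4) repeat T times and summarise the p-value
distributions against the observed (unimputed) analysis.

All runs reuse one analysis seed so that, with an empty pool, every
simulated p-value equals the observed one exactly; only the imputation
seed varies across runs (paired comparisons, less Monte Carlo noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import substream
from .io import RegionMap
from .meet import meet
from .regression import fit_poisson
from .scan import scan
from .standardize import StratifiedCounts, expected_counts, stratum_label

__all__ = [
    "UndiagnosedPool",
    "SensitivityReport",
    "diagnosis_rates",
    "impute_cases",
    "run_sensitivity",
    "read_undiagnosed",
]


@dataclass(frozen=True)
class UndiagnosedPool:
    """Undiagnosed screen-positives per region × stratum with diagnosis rates.

    ``u``: DataFrame (region × stratum) of counts; ``q``: Series of
    per-stratum diagnosis probabilities among confirmatory-tested positives.
    """

    u: pd.DataFrame
    q: pd.Series

    def __post_init__(self) -> None:
        uv = self.u.to_numpy()
        if (uv < 0).any() or not np.array_equal(uv, np.floor(uv)):
            raise ValueError("undiagnosed counts must be non-negative integers")
        q = self.q.reindex(self.u.columns)
        if q.isna().any():
            raise ValueError("diagnosis rate missing for some strata")
        if ((q < 0) | (q > 1)).any():
            raise ValueError("diagnosis rates must lie in [0, 1]")
        object.__setattr__(self, "q", q.astype(float))

    @property
    def total_undiagnosed(self) -> int:
        return int(self.u.to_numpy().sum())


def diagnosis_rates(tested: pd.Series, diagnosed: pd.Series) -> pd.Series:
    """q_k = diagnosed_k / tested_k among confirmatory-tested positives."""
    tested = tested.astype(float)
    diagnosed = diagnosed.reindex(tested.index).astype(float)
    if diagnosed.isna().any():
        raise ValueError("diagnosed counts missing for some strata")
    if ((tested < 0) | (diagnosed < 0)).any():
        raise ValueError("negative counts")
    if (diagnosed > tested).any():
        bad = list(tested.index[diagnosed > tested])
        raise ValueError(f"diagnosed exceeds tested in strata {bad}")
    q = pd.Series(0.0, index=tested.index, name="q")
    nz = tested > 0
    q[nz] = diagnosed[nz] / tested[nz]
    if (~nz & (tested == 0)).any():
        import warnings

        zero = list(tested.index[~nz])
        if zero:
            warnings.warn(f"strata with zero confirmatory-tested positives get q=0: {zero}")
    return q


def impute_cases(pool: UndiagnosedPool, seed: int) -> pd.DataFrame:
    """One draw of hypothetical extra cases: Binomial(u_ik, q_k) per cell."""
    rng = np.random.default_rng(seed)
    u = pool.u.to_numpy(dtype=np.int64)
    q = pool.q.to_numpy(dtype=float)
    added = rng.binomial(u, q[None, :])
    return pd.DataFrame(added, index=pool.u.index, columns=pool.u.columns)


@dataclass(frozen=True)
class SensitivityReport:
    observed_p: pd.Series
    p_values: pd.DataFrame  # T runs × methods
    added_cases: pd.Series  # per-run totals
    seed: int
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        qs = self.p_values.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        qs.index = ["min", "q1", "median", "q3", "max"]
        object.__setattr__(self, "summary", qs.T)

    @property
    def added_median(self) -> float:
        return float(self.added_cases.median())

    @property
    def added_iqr(self) -> float:
        return float(self.added_cases.quantile(0.75) - self.added_cases.quantile(0.25))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_runs": int(len(self.p_values)),
            "added_cases_median": self.added_median,
            "added_cases_iqr": self.added_iqr,
            "observed_p": self.observed_p.to_dict(),
            "p_summary": {m: self.summary.loc[m].to_dict() for m in self.summary.index},
        }


def _augment(counts: StratifiedCounts, added: pd.DataFrame) -> StratifiedCounts:
    added = added.reindex(index=counts.pop.index, columns=counts.pop.columns).fillna(0)
    cases = counts.cases + added.sum(axis=1).astype(int)
    sc = None
    if counts.stratum_cases is not None:
        sc = counts.stratum_cases + added.sum(axis=0).astype(int)
    return StratifiedCounts(pop=counts.pop, cases=cases, stratum_cases=sc)


def run_sensitivity(
    region_map: RegionMap,
    counts: StratifiedCounts,
    pool: UndiagnosedPool,
    covariates: pd.DataFrame | None = None,
    methods: tuple[str, ...] = ("scan", "meet", "regress"),
    T: int = 100,
    seed: int = 0,
    k_max: int = 15,
    reps: int = 999,
    lambda_grid=None,
) -> SensitivityReport:
    """Impute, re-standardise, re-analyse, repeat; collect p-values.

    Regression methods contribute one Wald p per covariate column
    (continuous form, coefficient of the covariate).
    """
    if T < 1:
        raise ValueError("need at least one simulation run")
    if "regress" in methods and covariates is None:
        raise ValueError("regression requested but no covariate table supplied")
    analysis_seed = substream(seed, "analysis")

    def analyse(c: StratifiedCounts, run: int | None) -> dict[str, float]:
        tag = "observed" if run is None else f"run {run}"
        try:
            exp = expected_counts(c)
            out: dict[str, float] = {}
            if "scan" in methods:
                r = scan(
                    c.cases, exp.expected, region_map,
                    k_max=k_max, reps=reps, seed=substream(analysis_seed, "scan"),
                )
                out["scan"] = r.p_value
            if "meet" in methods:
                pr = meet(
                    c.cases, exp.expected, region_map,
                    lambda_grid=lambda_grid, reps=reps, seed=substream(analysis_seed, "meet"),
                )
                out["meet"] = pr.p_adjusted
            if "regress" in methods:
                cov = covariates.reindex(list(region_map.region_ids))
                for name in cov.columns:
                    fit = fit_poisson(
                        c.cases.reindex(list(region_map.region_ids)).to_numpy(),
                        exp.expected.reindex(list(region_map.region_ids)).to_numpy(),
                        cov[name].to_numpy(),
                        form="continuous",
                        covariate=name,
                    )
                    out[f"regress:{name}"] = float(fit.wald_p[name])
            return out
        except Exception as err:  # surface which run died
            raise RuntimeError(f"sensitivity analysis failed at {tag}: {err}") from err

    observed = analyse(counts, None)
    rows = []
    added_totals = []
    for t in range(T):
        added = impute_cases(pool, substream(seed, "impute", t))
        added_totals.append(int(added.to_numpy().sum()))
        rows.append(analyse(_augment(counts, added), t))

    return SensitivityReport(
        observed_p=pd.Series(observed),
        p_values=pd.DataFrame(rows),
        added_cases=pd.Series(added_totals, name="added_cases"),
        seed=seed,
    )


def read_undiagnosed(path, strata_columns) -> pd.DataFrame:
    """Read ``undiagnosed.csv`` (region_id,sex,age_band,count) into a
    region × stratum count table aligned to ``strata_columns``."""
    df = pd.read_csv(path, dtype={"region_id": str, "sex": str, "age_band": str})
    for col in ("region_id", "sex", "age_band", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df["stratum"] = [stratum_label(s, a) for s, a in zip(df["sex"], df["age_band"])]
    u = df.pivot(index="region_id", columns="stratum", values="count").fillna(0)
    return u.reindex(columns=list(strata_columns)).fillna(0).astype(int)
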