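"""Indirect sex/age standardisation of screening prevalence.

Each region i contributes examinee counts ``pop[i, k]`` in strata k
(sex × 5-year age band at examination) and an observed case count ``o_i``.
The prefecture-wide marginal rate of stratum k is

    pr_k = (total cases in stratum k) / (total examinees in stratum k),

the expected count under homogeneous risk is ``e_i = sum_k pop[i, k] pr_k``,
and the standardised prevalence ratio is ``spr_i = o_i / e_i``.  When the
rates are computed internally from the same table, ``sum_i e_i == sum_i o_i``
up to floating-point error — a conservation identity the tests enforce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "AGE_BANDS",
    "STRATA",
    "StratifiedCounts",
    "ExpectedTable",
    "marginal_rates",
    "expected_counts",
    "read_strata",
    "stratum_label",
]

SEXES = ("female", "male")
AGE_BANDS = ("0-4", "5-9", "10-14", "15-19", "20+")
STRATA = tuple(f"{s}:{a}" for s in SEXES for a in AGE_BANDS)


def stratum_label(sex: str, age_band: str) -> str:
    return f"{sex}:{age_band}"


@dataclass(frozen=True)
class StratifiedCounts:
    """Examinees per region × stratum, cases per region, and (optionally)
    case totals per stratum.

    ``pop`` is a DataFrame indexed by region_id with one column per stratum;
    ``cases`` a Series of observed cases per region; ``stratum_cases`` a
    Series of case totals per stratum (needed to compute marginal rates
    internally — omit it only when reference rates are supplied externally).
    """

    pop: pd.DataFrame
    cases: pd.Series
    stratum_cases: pd.Series | None = None

    def __post_init__(self) -> None:
        pop = self.pop
        if (pop.to_numpy() < 0).any():
            raise ValueError("negative examinee count")
        if not np.array_equal(pop.to_numpy(), np.floor(pop.to_numpy())):
            raise ValueError("examinee counts must be integers")
        cases = self.cases.reindex(pop.index)
        if cases.isna().any():
            raise ValueError("cases missing for some regions")
        if (cases < 0).any():
            raise ValueError("negative case count")
        object.__setattr__(self, "cases", cases.astype(int))
        if self.stratum_cases is not None:
            sc = self.stratum_cases.reindex(pop.columns)
            if sc.isna().any():
                raise ValueError("stratum_cases missing for some strata")
            if (sc < 0).any():
                raise ValueError("negative stratum case count")
            if int(sc.sum()) != int(self.cases.sum()):
                raise ValueError(
                    f"stratum case totals ({int(sc.sum())}) disagree with "
                    f"regional case totals ({int(self.cases.sum())})"
                )
            object.__setattr__(self, "stratum_cases", sc.astype(int))

    @property
    def total_cases(self) -> int:
        return int(self.cases.sum())

    @property
    def total_examinees(self) -> int:
        return int(self.pop.to_numpy().sum())


@dataclass(frozen=True)
class ExpectedTable:
    """Output of indirect standardisation.

    ``table`` has columns ``observed``, ``expected``, ``spr`` and
    ``spr_defined`` per region; spr is NaN when expected == 0 (flagged
    defined=False when observed > 0, i.e. genuinely undefined excess, and
    simply missing when observed == 0 as well).
    """

    table: pd.DataFrame
    rates: pd.Series

    @property
    def expected(self) -> pd.Series:
        return self.table["expected"]

    @property
    def observed(self) -> pd.Series:
        return self.table["observed"]

    @property
    def spr(self) -> pd.Series:
        return self.table["spr"]


def marginal_rates(counts: StratifiedCounts) -> pd.Series:
    """Prefecture-wide stratum prevalence rates pr_k = O_k / pop_k."""
    if counts.stratum_cases is None:
        raise ValueError("stratum-level case totals required to compute marginal rates")
    pop_k = counts.pop.sum(axis=0)
    o_k = counts.stratum_cases
    bad = (pop_k == 0) & (o_k > 0)
    if bad.any():
        raise ValueError(f"cases observed in strata with zero examinees: {list(o_k.index[bad])}")
    with np.errstate(invalid="ignore"):
        pr = (o_k / pop_k).fillna(0.0)
    return pr.rename("pr")


def expected_counts(counts: StratifiedCounts, rates: pd.Series | None = None) -> ExpectedTable:
    """Indirectly standardised expected counts and prevalence ratios.

    When ``rates`` is None they are computed internally with
    :func:`marginal_rates` (the default, matching a self-contained study);
    externally supplied reference rates are also accepted.
    """
    if rates is None:
        rates = marginal_rates(counts)
    rates = rates.reindex(counts.pop.columns)
    if rates.isna().any():
        raise ValueError("rates missing for some strata")
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    e = counts.pop.to_numpy(dtype=float) @ rates.to_numpy(dtype=float)
    o = counts.cases.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        spr = np.where(e > 0, o / np.where(e > 0, e, 1.0), np.nan)
    table = pd.DataFrame(
        {
            "observed": counts.cases,
            "expected": pd.Series(e, index=counts.pop.index),
            "spr": pd.Series(spr, index=counts.pop.index),
            "spr_defined": pd.Series((e > 0) | (o == 0), index=counts.pop.index),
        }
    )
    return ExpectedTable(table=table, rates=rates)


def read_strata(path) -> StratifiedCounts:
    """Read ``strata.csv`` (region_id,sex,age_band,examinees,cases)."""
    df = pd.read_csv(path, dtype={"region_id": str, "sex": str, "age_band": str})
    for col in ("region_id", "sex", "age_band", "examinees", "cases"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df["stratum"] = [stratum_label(s, a) for s, a in zip(df["sex"], df["age_band"])]
    if df.duplicated(["region_id", "stratum"]).any():
        raise ValueError(f"{path}: duplicate region × stratum rows")
    pop = df.pivot(index="region_id", columns="stratum", values="examinees").fillna(0)
    cases_rs = df.pivot(index="region_id", columns="stratum", values="cases").fillna(0)
    order = [s for s in STRATA if s in pop.columns] + [s for s in pop.columns if s not in STRATA]
    pop = pop[order]
    cases_rs = cases_rs[order]
    return StratifiedCounts(
        pop=pop,
        cases=cases_rs.sum(axis=1).astype(int),
        stratum_cases=cases_rs.sum(axis=0).astype(int),
    )
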