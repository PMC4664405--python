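"""Bound/input densitometry quantification and two-group comparison.

Co-immunoprecipitation experiments report, per replicate, a bound-band
intensity (precipitated protein) and an input-band intensity (lysate).
The association metric is the bound/input ratio, summarised per condition
as mean ± SEM (sample SD / sqrt(n)) and compared between conditions with a
two-sample Student's t-test (pooled variance by default, Welch optional).
No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_densitometry",
    "validate_densitometry",
    "bound_over_input",
    "GroupSummary",
    "students_t",
    "TTestResult",
]

_COLUMNS = ["construct", "partner", "replicate", "bound", "input"]


@dataclass(frozen=True)
class GroupSummary:
    condition: str
    n: int
    mean_ratio: float
    sem: float | None          # None (flagged) when n == 1


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    flag: str = ""


def validate_densitometry(df: pd.DataFrame) -> pd.DataFrame:
    """Check the (construct, partner, replicate, bound, input) table.

    Inputs must be strictly positive, bound signals non-negative, and
    replicate ids unique within each condition.
    """
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns: {sorted(missing)}")
    bad_input = df.index[df["input"] <= 0].tolist()
    if bad_input:
        raise ValueError(f"non-positive input signal in rows {bad_input}")
    bad_bound = df.index[df["bound"] < 0].tolist()
    if bad_bound:
        raise ValueError(f"negative bound signal in rows {bad_bound}")
    dup = df.duplicated(subset=["construct", "partner", "replicate"])
    if dup.any():
        raise ValueError(f"duplicate replicate ids in rows {df.index[dup].tolist()}")
    return df


def load_densitometry(path: str | Path) -> pd.DataFrame:
    return validate_densitometry(pd.read_csv(path, sep="\t"))


def bound_over_input(df: pd.DataFrame) -> pd.DataFrame:
    """Per-condition bound/input ratio summaries.

    Returns a DataFrame with condition (construct:partner), n, mean_ratio,
    sem and a flag column; SEM is NaN with flag 'sem_undefined_n1' for
    single-replicate conditions.
    """
    df = validate_densitometry(df)
    work = df.assign(ratio=df["bound"] / df["input"])
    rows = []
    for (construct, partner), grp in work.groupby(["construct", "partner"], sort=True):
        r = grp["ratio"].to_numpy()
        n = len(r)
        sem = float(np.std(r, ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
        rows.append(
            {
                "condition": f"{construct}:{partner}",
                "construct": construct,
                "partner": partner,
                "n": n,
                "mean_ratio": float(np.mean(r)),
                "sem": sem,
                "flag": "" if n >= 2 else "sem_undefined_n1",
            }
        )
    return pd.DataFrame(rows)


def students_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test on ratio groups; two-sided p.

    Pooled-variance Student's test by default (df = nA + nB - 2); Welch's
    unequal-variance test when ``welch``.  Zero pooled variance is
    degenerate: equal means give t=0, p=1; unequal means are flagged with
    p reported as 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if math.isclose(a.mean(), b.mean()):
            return TTestResult(0.0, a.size + b.size - 2, 1.0)
        return TTestResult(
            math.copysign(math.inf, a.mean() - b.mean()),
            a.size + b.size - 2,
            0.0,
            flag="zero_pooled_variance",
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = _welch_df(var_a, a.size, var_b, b.size)
    else:
        df = a.size + b.size - 2
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def _welch_df(va: float, na: int, vb: float, nb: int) -> float:
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    return num / den


def pairwise_tests(
    df: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]],
    welch: bool = False,
) -> pd.DataFrame:
    """t-tests between named conditions ('construct:partner' keys)."""
    work = validate_densitometry(df).assign(ratio=lambda d: d["bound"] / d["input"])
    work = work.assign(condition=work["construct"].astype(str) + ":" + work["partner"].astype(str))
    groups = {c: g["ratio"].to_numpy() for c, g in work.groupby("condition")}
    rows = []
    for ca, cb in comparisons:
        if ca not in groups or cb not in groups:
            raise KeyError(f"condition not in table: {ca if ca not in groups else cb}")
        res = students_t(groups[ca], groups[cb], welch=welch)
        rows.append(
            {"condition_a": ca, "condition_b": cb, "t": res.t, "df": res.df,
             "p": res.p, "flag": res.flag}
        )
    return pd.DataFrame(rows)
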