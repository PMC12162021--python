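"""Descriptive analyses of the switching phenotype.

Covers the standard cohort-description outputs: a baseline-characteristics
table comparing switchers with nonswitchers (chi-square for binaries,
Kruskal–Wallis for multi-level categoricals scored in display order,
Wilcoxon rank-sum for continuous variables), time-to-switch summaries,
the post-switch drug-class mix, between-centre heterogeneity of the switch
proportion, and temporal trends of switching rate and time to switch by
calendar year of the index date.

Conventions: chi-square tests are Pearson's without continuity correction
(large-sample usage; configurable); quantiles use linear interpolation
(type 7); temporal bins are calendar years with small bins dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableSpec",
    "DEFAULT_TABLE1_VARIABLES",
    "summarize_table1",
    "chi_square_from_counts",
    "time_to_switch_summary",
    "post_switch_class_table",
    "center_heterogeneity",
    "temporal_trend",
    "TrendResult",
]

MISSING_CODES = ("MISSING", "Not available", "")


@dataclass(frozen=True)
class VariableSpec:
    """How one covariate is summarised and tested.

    kind: "binary" (chi-square), "categorical" (Kruskal–Wallis on integer
    scores in the order given by ``levels``), or "continuous" (Wilcoxon
    rank-sum). ``levels`` fixes display and scoring order for categoricals.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None


DEFAULT_TABLE1_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("index_ssri", "categorical"),
    VariableSpec("sex", "binary", ("FEMALE", "MALE")),
    VariableSpec("family_history", "binary", ("NO", "YES")),
    VariableSpec("education", "categorical", ("NONE", "SECONDARY", "VOCATIONAL", "FURTHER", "DEGREE")),
    VariableSpec("income", "categorical", ("LT18K", "18_31K", "31_52K", "52_100K", "GT100K")),
    VariableSpec("tdi", "continuous"),
    VariableSpec("bmi", "continuous"),
)


def chi_square_from_counts(table: np.ndarray | Sequence[Sequence[float]], correction: bool = False):
    """Pearson chi-square on a contingency table; no continuity correction by default."""
    table = np.asarray(table, dtype=float)
    stat, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p), int(dof)


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna() | series.astype(str).isin(MISSING_CODES)


def _fmt_median_iqr(x: np.ndarray) -> str:
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q25:.1f}–{q75:.1f})"


def summarize_table1(
    pheno: pd.DataFrame,
    covariates: pd.DataFrame,
    variables: Sequence[VariableSpec] = DEFAULT_TABLE1_VARIABLES,
) -> pd.DataFrame:
    """Baseline-characteristics table: switchers vs nonswitchers.

    Returns a long-format table with one row per variable level (plus an
    "Unknown" row counting missing values, which are excluded from the
    test), and per-variable test name and p-value. Variables with a single
    observed level are skipped with a warning.
    """
    df = pheno[pheno["status"].isin(["SWITCHER", "NONSWITCHER"])].merge(
        covariates.drop(columns=[c for c in ("index_date",) if c in covariates.columns]),
        on="participant_id",
        how="left",
    )
    is_sw = df["status"] == "SWITCHER"
    rows: list[dict] = []
    for spec in variables:
        var = spec.name
        source = df if var in df.columns else None
        if source is None:
            warnings.warn(f"variable {var!r} absent; skipped")
            continue
        col = df[var]
        missing = _is_missing(col)
        obs = df[~missing]
        obs_sw = obs["status"] == "SWITCHER"
        test_name, p = None, np.nan
        if spec.kind in ("binary", "categorical"):
            levels = list(spec.levels) if spec.levels else sorted(obs[var].dropna().astype(str).unique())
            observed_levels = [l for l in levels if (obs[var].astype(str) == l).any()]
            if len(observed_levels) < 2 or obs_sw.nunique() < 2:
                warnings.warn(f"variable {var!r} has a single observed level/group; test skipped")
            elif spec.kind == "binary" or len(observed_levels) == 2:
                tab = pd.crosstab(obs[var].astype(str), obs_sw).reindex(index=observed_levels).to_numpy()
                _, p, _ = chi_square_from_counts(tab)
                test_name = "chi_square"
            else:
                scores = obs[var].astype(str).map({l: i for i, l in enumerate(levels)})
                _, p = stats.kruskal(scores[obs_sw], scores[~obs_sw])
                test_name = "kruskal_wallis"
            for level in levels:
                hit = obs[var].astype(str) == level
                n_ns = int((hit & ~obs_sw).sum())
                n_sw = int((hit & obs_sw).sum())
                d_ns = max(int((~obs_sw).sum()), 1)
                d_sw = max(int(obs_sw.sum()), 1)
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "nonswitcher": f"{n_ns} ({100 * n_ns / d_ns:.1f}%)",
                        "switcher": f"{n_sw} ({100 * n_sw / d_sw:.1f}%)",
                        "test": test_name,
                        "p_value": p,
                    }
                )
        elif spec.kind == "continuous":
            x = pd.to_numeric(obs.loc[obs_sw, var], errors="coerce").dropna().to_numpy()
            y = pd.to_numeric(obs.loc[~obs_sw, var], errors="coerce").dropna().to_numpy()
            if len(x) and len(y):
                _, p = stats.ranksums(x, y)
                test_name = "wilcoxon_rank_sum"
            else:
                warnings.warn(f"variable {var!r} lacks observations in one group; test skipped")
            rows.append(
                {
                    "variable": var,
                    "level": "median (IQR)",
                    "nonswitcher": _fmt_median_iqr(y) if len(y) else "",
                    "switcher": _fmt_median_iqr(x) if len(x) else "",
                    "test": test_name,
                    "p_value": p,
                }
            )
        else:
            raise ValueError(f"unknown variable kind {spec.kind!r}")
        n_miss = int(missing.sum())
        if n_miss:
            rows.append(
                {
                    "variable": var,
                    "level": "Unknown",
                    "nonswitcher": str(int((missing & ~is_sw).sum())),
                    "switcher": str(int((missing & is_sw).sum())),
                    "test": None,
                    "p_value": np.nan,
                }
            )
    return pd.DataFrame(rows)


def time_to_switch_summary(pheno: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Median and IQR of time to switch (days), overall or grouped.

    ``by`` may name any column of ``pheno`` (e.g. ``index_ssri``) or of a
    pre-joined covariate column (e.g. ``sex``). Quantiles use linear
    interpolation.
    """
    sw = pheno[pheno["status"] == "SWITCHER"]
    if sw.empty:
        raise ValueError("no switchers to summarise")

    def _one(g: pd.DataFrame) -> pd.Series:
        x = g["time_to_switch_days"].astype(float).to_numpy()
        q25, med, q75 = np.percentile(x, [25, 50, 75])
        return pd.Series({"n": len(x), "median": med, "q25": q25, "q75": q75})

    if by is None:
        return _one(sw).to_frame().T.assign(group="all")[["group", "n", "median", "q25", "q75"]]
    out = sw.groupby(by, observed=True).apply(_one, include_groups=False).reset_index()
    return out.rename(columns={by: "group"})


def post_switch_class_table(
    pheno: pd.DataFrame,
    by_index_ssri: bool = False,
    label_threshold: int | None = None,
) -> pd.DataFrame:
    """Counts and percentages of switchers by post-switch drug class.

    Percentages are over all switchers. With ``label_threshold`` set, classes
    with fewer switchers than the threshold are aggregated into ``"other"``
    (mirroring figure-labelling practice of only naming classes above a
    minimum size).
    """
    sw = pheno[pheno["status"] == "SWITCHER"].copy()
    total = len(sw)
    keys = ["index_ssri", "post_switch_class"] if by_index_ssri else ["post_switch_class"]
    tab = sw.groupby(keys, observed=True).size().reset_index(name="n")
    if label_threshold is not None:
        class_totals = sw.groupby("post_switch_class").size()
        small = set(class_totals[class_totals < label_threshold].index)
        tab["post_switch_class"] = tab["post_switch_class"].map(
            lambda c: "other" if c in small else c
        )
        tab = tab.groupby(keys, observed=True, as_index=False)["n"].sum()
    tab["pct"] = 100.0 * tab["n"] / total if total else np.nan
    return tab.sort_values(keys, kind="mergesort").reset_index(drop=True)


def center_heterogeneity(pheno: pd.DataFrame, covariates: pd.DataFrame) -> dict:
    """Per-centre switch proportions and a k×2 chi-square for heterogeneity."""
    df = pheno[pheno["status"].isin(["SWITCHER", "NONSWITCHER"])].merge(
        covariates[["participant_id", "center"]], on="participant_id"
    )
    tab = pd.crosstab(df["center"], df["status"] == "SWITCHER")
    counts = tab.to_numpy()
    stat, p, dof = chi_square_from_counts(counts)
    prop = tab[True] / tab.sum(axis=1) if True in tab.columns else pd.Series(0.0, index=tab.index)
    per_center = pd.DataFrame(
        {"center": tab.index, "n": tab.sum(axis=1).to_numpy(), "prop_switchers": prop.to_numpy()}
    ).reset_index(drop=True)
    return {
        "per_center": per_center,
        "chi2": stat,
        "p_value": p,
        "dof": dof,
        "min_prop": float(per_center["prop_switchers"].min()),
        "max_prop": float(per_center["prop_switchers"].max()),
    }


@dataclass
class TrendResult:
    table: pd.DataFrame
    rate_r: float
    rate_p: float
    tts_r: float
    tts_p: float


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # a constant series has undefined correlation; report r=0, p=1 by convention
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    if np.isnan(r):
        return 0.0, 1.0
    return float(r), float(p)


def temporal_trend(pheno: pd.DataFrame, min_bin_n: int = 20) -> TrendResult:
    """Correlate switch rate and median time-to-switch with index-date year.

    Participants are binned by calendar year of the index date; bins with
    fewer than ``min_bin_n`` classified participants are dropped. Requires
    at least 3 retained bins.
    """
    df = pheno[pheno["status"].isin(["SWITCHER", "NONSWITCHER"])].copy()
    df = df[df["index_date"].notna()]
    df["year"] = df["index_date"].dt.year
    grp = df.groupby("year")
    table = pd.DataFrame(
        {
            "year": grp.size().index,
            "n": grp.size().to_numpy(),
            "n_switchers": grp.apply(
                lambda g: int((g["status"] == "SWITCHER").sum()), include_groups=False
            ).to_numpy(),
        }
    )
    table["rate"] = table["n_switchers"] / table["n"]
    med_tts = grp.apply(
        lambda g: g.loc[g["status"] == "SWITCHER", "time_to_switch_days"].median(),
        include_groups=False,
    )
    table["median_tts"] = med_tts.to_numpy()
    table = table[table["n"] >= min_bin_n].reset_index(drop=True)
    if len(table) < 3:
        raise ValueError("need at least 3 time bins after the minimum-n filter")
    rate_r, rate_p = _safe_pearson(table["year"].to_numpy(float), table["rate"].to_numpy(float))
    tts_tab = table[table["median_tts"].notna()]
    tts_r, tts_p = _safe_pearson(
        tts_tab["year"].to_numpy(float), tts_tab["median_tts"].to_numpy(float)
    )
    return TrendResult(table=table, rate_r=rate_r, rate_p=rate_p, tts_r=tts_r, tts_p=tts_p)
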