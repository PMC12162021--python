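"""Covariate and polygenic-score association testing for switcher status.

Logistic regression of switcher (1) vs nonswitcher (0) on one exposure at a
time, adjusted for sex (female reference), SSRI index date (continuous,
years since 1995-01-01) and assessment centre. Polygenic-score exposures are
standardised to mean 0 / SD 1 within the analysis sample and additionally
adjusted for 10 genetic principal components. Inference is by likelihood
ratio test of the full model against the adjustment-only model; per-level
odds ratios carry 95% Wald intervals. Multiple testing uses a Bonferroni
threshold (default alpha 0.05 over 7 tests: 4 sociodemographic variables
and 3 polygenic scores, p <= .00714).

Related individuals are thinned greedily on the kinship graph before
fitting, preferentially retaining switchers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AnalysisPlan",
    "AssociationResult",
    "bonferroni_threshold",
    "prune_related",
    "fit_switch_model",
    "run_associations",
]

_EPOCH = pd.Timestamp("1995-01-01")
MISSING_CODES = ("MISSING", "Not available", "")


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


@dataclass(frozen=True)
class AnalysisPlan:
    """Adjustment set and multiplicity control for the association scan."""

    adjust: tuple[str, ...] = ("sex", "index_date", "center")
    n_pcs: int = 10
    n_tests: int = 7
    alpha: float = 0.05
    kinship_threshold: float = 0.044
    pgs_exposures: tuple[str, ...] = ("pgs_mdd", "pgs_scz", "pgs_nonremission")

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.n_tests, self.alpha)


@dataclass
class AssociationResult:
    """One exposure level's effect on switching."""

    exposure: str
    level: str | None
    odds_ratio: float
    ci_low: float
    ci_high: float
    lrt_p: float
    n_used: int
    stratum: str = "ALL"
    significant: bool = False
    estimable: bool = True


def prune_related(
    pairs: pd.DataFrame,
    statuses: dict[str, str] | pd.Series,
    threshold: float = 0.044,
) -> set[str]:
    """Greedy relatedness pruning; returns the retained participant ids.

    A pair with kinship at or above ``threshold`` is "related". Repeatedly
    delete the individual covering the most remaining related pairs,
    preferring to delete nonswitchers over switchers at every tie, with id
    order as the final tie-break. The retained set contains every phenotyped
    id not deleted and, by construction, no related pair.
    """
    statuses = dict(statuses)
    if len(pairs):
        if (pairs["id1"] == pairs["id2"]).any():
            raise ValueError("kinship table contains a self-pair")
    adj: dict[str, set[str]] = {}
    for _, row in pairs.iterrows():
        if float(row["kinship"]) >= threshold:
            a, b = str(row["id1"]), str(row["id2"])
            if a not in statuses or b not in statuses:
                continue
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    removed: set[str] = set()
    while True:
        degrees = {v: len(nb) for v, nb in adj.items() if nb}
        if not degrees:
            break
        # delete max degree; prefer deleting non-switchers; then smallest id
        victim = min(
            degrees,
            key=lambda v: (-degrees[v], statuses.get(v) == "SWITCHER", v),
        )
        removed.add(victim)
        for nb in adj.pop(victim, set()):
            adj[nb].discard(victim)
    return set(statuses) - removed


def _design(
    df: pd.DataFrame,
    exposure: str,
    plan: AnalysisPlan,
    reference: str | None,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame, list[str]]:
    """Build (y, X_full, X_reduced, exposure column names)."""
    is_pgs = exposure in plan.pgs_exposures
    cols = [exposure, *plan.adjust]
    if is_pgs:
        cols += [f"pc{i}" for i in range(1, plan.n_pcs + 1)]
    d = df.copy()
    for c in cols:
        if c not in d.columns:
            raise KeyError(f"missing column {c!r}")
    # complete cases: drop rows missing the exposure or any adjustment column
    keep = np.ones(len(d), dtype=bool)
    for c in cols:
        col = d[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            keep &= col.notna().to_numpy() & ~col.astype(str).isin(MISSING_CODES).to_numpy()
        else:
            keep &= col.notna().to_numpy()
    d = d[keep]
    y = (d["status"] == "SWITCHER").astype(float)

    parts: list[pd.DataFrame] = []

    def _dummies(col: pd.Series, ref: str | None, prefix: str) -> pd.DataFrame:
        col = col.astype(str)
        levels = sorted(col.unique())
        if ref is None:
            ref = levels[0]
        use = [l for l in levels if l != ref]
        return pd.DataFrame(
            {f"{prefix}[{l}]": (col == l).astype(float) for l in use}, index=col.index
        )

    # adjustment block
    for c in plan.adjust:
        if c == "index_date":
            parts.append(
                pd.DataFrame(
                    {"index_years": (d[c] - _EPOCH).dt.days / 365.25}, index=d.index
                )
            )
        elif c == "sex":
            parts.append(_dummies(d[c], "FEMALE", "sex"))
        else:
            parts.append(_dummies(d[c], None, c))
    if is_pgs:
        for i in range(1, plan.n_pcs + 1):
            parts.append(d[[f"pc{i}"]].astype(float))
    X_red = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=d.index)
    X_red.insert(0, "const", 1.0)

    exp_col = d[exposure]
    if exp_col.dtype == object or isinstance(exp_col.dtype, pd.CategoricalDtype):
        exp_block = _dummies(exp_col, reference, exposure)
    else:
        x = exp_col.astype(float)
        if is_pgs:
            x = (x - x.mean()) / x.std(ddof=0)  # per-SD effect within analysis sample
        exp_block = pd.DataFrame({exposure: x}, index=d.index)
    X_full = pd.concat([X_red, exp_block], axis=1)
    return y, X_full, X_red, list(exp_block.columns)


_REFERENCES = {
    "education": "NONE",
    "income": "LT18K",
    "family_history": "NO",
    "sex": "FEMALE",
}


def fit_switch_model(
    data: pd.DataFrame,
    exposure: str,
    plan: AnalysisPlan | None = None,
    reference: str | None = None,
    stratum: str = "ALL",
) -> list[AssociationResult]:
    """Fit the adjusted logistic model for one exposure.

    ``data`` holds classified participants (column ``status``) joined to
    covariates. Categorical exposures yield one result per non-reference
    level sharing the exposure-wide LRT p-value; continuous exposures yield
    one result. Complete or quasi-complete separation is flagged via
    ``estimable=False`` rather than silently corrected.
    """
    plan = plan or AnalysisPlan()
    if reference is None:
        reference = _REFERENCES.get(exposure)
    df = data[data["status"].isin(["SWITCHER", "NONSWITCHER"])]
    y, X_full, X_red, exp_cols = _design(df, exposure, plan, reference)
    if y.nunique() < 2:
        raise ValueError("outcome must contain both switchers and nonswitchers")
    n_used = int(len(y))

    def _not_estimable(msg: str) -> list[AssociationResult]:
        warnings.warn(f"{exposure}: {msg}; marked non-estimable")
        return [
            AssociationResult(
                exposure=exposure, level=(c.split("[", 1)[1][:-1] if "[" in c else None),
                odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan, lrt_p=np.nan,
                n_used=n_used, stratum=stratum, significant=False, estimable=False,
            )
            for c in exp_cols
        ]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
            red = sm.Logit(y, X_red).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        return _not_estimable(str(exc))
    if not (full.mle_retvals.get("converged", False) and red.mle_retvals.get("converged", False)):
        return _not_estimable("model did not converge (possible separation)")
    if np.any(np.abs(full.params[exp_cols]) > 15) or np.any(~np.isfinite(full.bse)):
        return _not_estimable("separation suspected (diverging exposure coefficient)")

    lrt = 2.0 * (full.llf - red.llf)
    dof = len(exp_cols)
    lrt_p = float(stats.chi2.sf(max(lrt, 0.0), dof))
    z = stats.norm.ppf(0.975)
    out = []
    for c in exp_cols:
        beta = float(full.params[c])
        se = float(full.bse[c])
        out.append(
            AssociationResult(
                exposure=exposure,
                level=(c.split("[", 1)[1][:-1] if "[" in c else None),
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - z * se)),
                ci_high=float(np.exp(beta + z * se)),
                lrt_p=lrt_p,
                n_used=n_used,
                stratum=stratum,
                significant=bool(lrt_p <= plan.threshold),
                estimable=True,
            )
        )
    return out


def run_associations(
    pheno: pd.DataFrame,
    covariates: pd.DataFrame,
    memberships: pd.DataFrame,
    exposures: tuple[str, ...] = (
        "education",
        "income",
        "family_history",
        "tdi",
        "pgs_mdd",
        "pgs_scz",
        "pgs_nonremission",
    ),
    plan: AnalysisPlan | None = None,
    kinship: pd.DataFrame | None = None,
    strata: tuple[str, ...] = ("ALL", "GE1_MDD", "GE2_MDD"),
) -> pd.DataFrame:
    """Association scan over exposures and strata; returns a tidy results table."""
    from .cohort import stratum_ids

    plan = plan or AnalysisPlan()
    classified = pheno[pheno["status"].isin(["SWITCHER", "NONSWITCHER"])]
    statuses = dict(zip(classified["participant_id"], classified["status"]))
    if kinship is not None and len(kinship):
        retained = prune_related(kinship, statuses, plan.kinship_threshold)
    else:
        retained = set(statuses)
    base = classified[classified["participant_id"].isin(retained)].merge(
        covariates, on="participant_id", how="left", suffixes=("", "_cov")
    )
    rows = []
    for stratum in strata:
        ids = stratum_ids(memberships, stratum)
        sub = base[base["participant_id"].isin(ids)]
        for exposure in exposures:
            for res in fit_switch_model(sub, exposure, plan, stratum=stratum):
                rows.append(res.__dict__)
    return pd.DataFrame(rows)
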