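"""Seeded generator of synthetic primary-care record tables.

Emulates the statistical structure the switching analysis assumes so that
every pipeline stage is testable without access-controlled biobank data:
per-participant prescription streams with ~monthly refill intervals, an
index-SSRI mix matching published nonswitcher shares, switching driven by a
logistic liability on covariates (education, income, a nonremission
polygenic score, a calendar-year trend and assessment-centre offsets)
calibrated to a target marginal prevalence of ~13%, a log-normal
time-to-switch (median 28 d, IQR 17–49 d) truncated to the 5–95-day
window, a post-switch drug-class mix (46% to another SSRI, 31% to a TCA),
depression and exclusion diagnosis codes, and kinship pairs.

The generator is a pure function of (config, seed). One RNG stream is
derived per output table from the master seed, so adding a table never
perturbs the others. A truth table records every latent draw, enabling
row-by-row audits of phenotype recovery. Optional "contaminant" histories
(augmentation overlaps, single-issue participants, non-antidepressant-only
streams) exercise the UNCLASSIFIED path and individual criterion failures;
the default configuration is contamination-free.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .model import DrugClass, DxCategory, SSRI_DRUGS, default_codeset, codes_for, write_table

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "derive_ttswitch_params",
    "derive_shifted_ttswitch_params",
    "sample_tts_pretruncation",
    "truncated_lognormal_quantile",
    "generate_cohort",
    "audit_synthetic",
]

_EPOCH = np.datetime64("1970-01-01", "D")

# drugs available per class for post-switch targets
_CLASS_DRUGS: dict[str, tuple[str, ...]] = {
    "SSRI": SSRI_DRUGS,
    "TCA": ("amitriptyline", "clomipramine", "dosulepin", "imipramine", "lofepramine", "nortriptyline"),
    "SNRI": ("venlafaxine", "duloxetine"),
    "SARI": ("trazodone", "nefazodone"),
    "NRI": ("reboxetine",),
    "MAOI": ("phenelzine", "moclobemide"),
    "OTHER_AD": ("mirtazapine", "agomelatine"),
}
_NON_AD_DRUGS = ("ibuprofen", "omeprazole", "simvastatin", "paracetamol", "zopiclone")

_DRUG_CLASS_OF = {d: c for c, drugs in _CLASS_DRUGS.items() for d in drugs}
_DRUG_CLASS_OF.update({d: DrugClass.NON_AD.value for d in _NON_AD_DRUGS})


def _days(iso: str) -> int:
    return int((np.datetime64(iso, "D") - _EPOCH).astype(int))


@dataclass
class SimulationConfig:
    """All tunable study conditions of the synthetic cohort.

    Defaults follow the published cohort description: index-SSRI mix and
    covariate marginals from the nonswitcher column of the baseline table
    (nonswitchers dominate the sample), marginal switch prevalence 0.13,
    time-to-switch median 28 d with IQR (17, 49), post-switch mix 46% SSRI /
    31% TCA with the remainder split across the minor classes, ~monthly
    refill intervals, a nonswitcher prescription count with median 18, 58% /
    38% of participants with >=1 / >=2 depression records, 75% of first
    depression records preceding the index date, 22 assessment centres with
    modest prevalence offsets, and a calendar span of 1995–2018.
    """

    n_participants: int = 20_000
    female_fraction: float = 0.67
    index_ssri_mix: dict[str, float] = field(
        default_factory=lambda: {
            "fluoxetine": 0.3348,
            "citalopram": 0.3696,
            "sertraline": 0.1385,
            "paroxetine": 0.1225,
            "escitalopram": 0.0328,
            "fluvoxamine": 0.0018,
        }
    )
    # logistic switch liability
    target_prevalence: float = 0.13
    switch_intercept: float | None = None  # solved for target_prevalence when None
    effect_degree: float = -0.31  # ~ln 0.73, university degree vs none
    effect_top_income: float = -0.42  # ~ln 0.66, >£100k vs <£18k
    effect_pgs_nonremission: float = 0.068  # ~ln 1.07 per SD
    effect_per_year: float = 0.02  # secular log-odds trend per calendar year
    center_effect_sd: float = 0.3  # log-odds SD of centre offsets
    n_centers: int = 22
    # time to switch (days): log-normal, truncated by rejection
    tts_median: float = 28.0
    tts_iqr: tuple[float, float] = (17.0, 49.0)
    tts_truncation: tuple[float, float] = (5.0, 95.0)
    post_switch_mix: dict[str, float] = field(
        default_factory=lambda: {
            "SSRI": 0.46,
            "TCA": 0.31,
            "SNRI": 0.12,
            "SARI": 0.05,
            "NRI": 0.03,
            "MAOI": 0.01,
            "OTHER_AD": 0.02,
        }
    )
    # prescription mechanics
    refill_mean_days: float = 28.0
    refill_sd_days: float = 5.0
    refill_min_days: float = 7.0
    nonswitcher_rx_median: float = 18.0
    nonswitcher_rx_iqr: tuple[float, float] = (7.0, 47.0)
    nonswitcher_rx_max: int = 60
    crosstaper_prob: float = 0.3
    drug_name_noise: float = 0.15  # fraction of raw strings with strength suffix
    # diagnoses
    dep_dx_prob_ge1: float = 0.58
    dep_dx_prob_ge2: float = 0.38
    exclusion_dx_prob: float = 0.01
    dx_precedes_index_prob: float = 0.75
    # kinship
    kinship_pair_fraction: float = 0.01  # fraction of participants in a pair
    # contamination (default off)
    contamination_fraction: float = 0.0
    contamination_mix: dict[str, float] = field(
        default_factory=lambda: {"augmentation": 1 / 3, "single_issue": 1 / 3, "non_ad_only": 1 / 3}
    )
    calendar_start: str = "1995-01-01"
    calendar_end: str = "2018-12-31"
    # covariate marginals (nonswitcher column of the baseline table)
    education_probs: dict[str, float] = field(
        default_factory=lambda: {
            "NONE": 0.1996,
            "SECONDARY": 0.2877,
            "VOCATIONAL": 0.1161,
            "FURTHER": 0.1109,
            "DEGREE": 0.2726,
            "MISSING": 0.0131,
        }
    )
    income_probs: dict[str, float] = field(
        default_factory=lambda: {
            "LT18K": 0.2617,
            "18_31K": 0.2232,
            "31_52K": 0.2104,
            "52_100K": 0.1320,
            "GT100K": 0.0242,
            "MISSING": 0.1485,
        }
    )
    family_history_probs: dict[str, float] = field(
        default_factory=lambda: {"NO": 0.783, "YES": 0.207, "MISSING": 0.010}
    )

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        for name in ("index_ssri_mix", "post_switch_mix", "education_probs", "income_probs", "family_history_probs", "contamination_mix"):
            m = getattr(self, name)
            if any(p < 0 for p in m.values()) or abs(sum(m.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a probability map summing to 1")
        if not 0 <= self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in [0, 1)")
        for p in (
            self.female_fraction, self.dep_dx_prob_ge1, self.dep_dx_prob_ge2,
            self.exclusion_dx_prob, self.dx_precedes_index_prob,
            self.kinship_pair_fraction, self.contamination_fraction, self.crosstaper_prob,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.dep_dx_prob_ge2 > self.dep_dx_prob_ge1:
            raise ValueError("dep_dx_prob_ge2 cannot exceed dep_dx_prob_ge1")
        lo, hi = self.tts_truncation
        if not 0 < lo < hi:
            raise ValueError("tts_truncation must satisfy 0 < lo < hi")
        q25, q75 = self.tts_iqr
        if not 0 < q25 <= self.tts_median <= q75:
            raise ValueError("need 0 < q25 <= median <= q75 for time to switch")


def derive_ttswitch_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """Log-normal (mu, sigma) whose median and quartiles match the inputs.

    mu = ln(median); sigma = (ln q75 - ln q25) / (2 * z_0.75) with
    z_0.75 = Phi^-1(0.75) ~= 0.67449. Equal quartiles give the degenerate
    sigma = 0. Truncation, where wanted, is applied at sampling time by
    rejection and is not part of the parameterisation.
    """
    q25, q75 = iqr
    if not (0 < q25 <= median <= q75):
        raise ValueError("need 0 < q25 <= median <= q75")
    mu = float(np.log(median))
    sigma = float((np.log(q75) - np.log(q25)) / (2.0 * norm.ppf(0.75)))
    return mu, sigma


def derive_shifted_ttswitch_params(median: float, iqr: tuple[float, float]) -> tuple[float, float, float]:
    """Shifted log-normal (shift, mu, sigma) matching all three quartiles exactly.

    A two-parameter log-normal forces log-symmetric quartiles
    (median/q25 == q75/median), which published time-to-switch quartiles need
    not satisfy; adding a location shift c gives three parameters for three
    constraints, solved in closed form:

        r = (q75 - median) / (median - q25);  sigma = ln(r) / z_0.75
        exp(mu) = (q75 - median) / (r - 1);   c = median - exp(mu)

    For log-symmetric (r <= 1) or degenerate quartiles this falls back to
    the unshifted parameterisation.
    """
    q25, q75 = iqr
    if not (0 < q25 <= median <= q75):
        raise ValueError("need 0 < q25 <= median <= q75")
    if q75 - median <= 0 or median - q25 <= 0:
        mu, sigma = derive_ttswitch_params(median, iqr)
        return 0.0, mu, sigma
    r = (q75 - median) / (median - q25)
    if r <= 1.0:
        mu, sigma = derive_ttswitch_params(median, iqr)
        return 0.0, mu, sigma
    a = float(norm.ppf(0.75))
    sigma = float(np.log(r) / a)
    scale = (q75 - median) / (r - 1.0)
    mu = float(np.log(scale))
    shift = float(median - scale)
    return shift, mu, sigma


def truncated_lognormal_quantile(
    q: float, mu: float, sigma: float, lo: float, hi: float, shift: float = 0.0
) -> float:
    """Closed-form quantile of a (shifted) log-normal truncated to [lo, hi]."""
    if sigma == 0:
        return float(shift + np.exp(mu))
    lo_, hi_ = max(lo - shift, 1e-12), hi - shift
    a = norm.cdf((np.log(lo_) - mu) / sigma)
    b = norm.cdf((np.log(hi_) - mu) / sigma)
    return float(shift + np.exp(mu + sigma * norm.ppf(a + q * (b - a))))


def _sample_tts(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Integer day gaps from the truncated shifted log-normal (rejection sampling)."""
    shift, mu, sigma = derive_shifted_ttswitch_params(cfg.tts_median, cfg.tts_iqr)
    lo, hi = cfg.tts_truncation
    if sigma == 0:
        return np.full(n, int(round(shift + np.exp(mu))))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = shift + rng.lognormal(mu, sigma, size=max(2 * (n - filled), 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return np.clip(np.round(out), lo, hi).astype(int)


def sample_tts_pretruncation(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Pre-truncation time-to-switch draws (calibration checks)."""
    shift, mu, sigma = derive_shifted_ttswitch_params(config.tts_median, config.tts_iqr)
    return shift + rng.lognormal(mu, sigma, n)


@dataclass
class SyntheticCohort:
    """In-memory synthetic tables plus the latent truth table."""

    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    covariates: pd.DataFrame
    kinship: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write reader-compatible delimited tables plus truth.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        rx = self.prescriptions[["participant_id", "issue_date", "drug_raw"]].rename(
            columns={"drug_raw": "drug"}
        )
        dx = self.diagnoses[["participant_id", "event_date", "code_raw"]].rename(
            columns={"code_raw": "code"}
        )
        for name, df in {
            "prescriptions": rx,
            "diagnoses": dx,
            "covariates": self.covariates,
            "kinship": self.kinship,
            "truth": self.truth,
        }.items():
            p = out / f"{name}.csv"
            write_table(df, p)
            paths[name] = p
        return paths


def _choice(rng: np.random.Generator, mix: dict[str, float], size: int) -> np.ndarray:
    keys = sorted(mix)
    p = np.array([mix[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(keys, dtype=object), size=size, p=p)


def generate_cohort(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate the four record tables and the truth table.

    Switchers receive 1–2 index-SSRI issues, the post-switch antidepressant
    at the sampled gap, optional cross-taper and continuation issues — all
    honouring the four phenotype criteria by construction. Nonswitchers
    receive >=3 same-SSRI issues at refill intervals. Contaminant patterns,
    when enabled, replace the history and are recorded in the truth table.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    cov_rng, rx_rng, dx_rng, kin_rng = (np.random.default_rng(s) for s in ss.spawn(4))

    n = cfg.n_participants
    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)], dtype=object)

    # --- covariates and latent switch draws (one stream) ---
    sex = np.where(cov_rng.random(n) < cfg.female_fraction, "FEMALE", "MALE").astype(object)
    education = _choice(cov_rng, cfg.education_probs, n)
    income = _choice(cov_rng, cfg.income_probs, n)
    tdi = cov_rng.normal(-1.8, 3.3, n)
    bmi = np.exp(cov_rng.normal(np.log(27.4), 0.174, n))
    family_history = _choice(cov_rng, cfg.family_history_probs, n)
    center_idx = cov_rng.integers(0, cfg.n_centers, n)
    centers = np.array([f"Centre_{10001 + i}" for i in range(cfg.n_centers)], dtype=object)
    pgs = {k: cov_rng.normal(size=n) for k in ("pgs_mdd", "pgs_scz", "pgs_nonremission")}
    pcs = {f"pc{i}": cov_rng.normal(size=n) for i in range(1, 11)}

    d_start, d_end = _days(cfg.calendar_start), _days(cfg.calendar_end)
    index_day = cov_rng.integers(d_start, d_end + 1, n)
    year_frac = index_day / 365.25 + 1970.0
    mid_year = (d_start + d_end) / 2 / 365.25 + 1970.0

    center_offsets = cov_rng.normal(0.0, cfg.center_effect_sd, cfg.n_centers)
    lp = (
        cfg.effect_degree * (education == "DEGREE")
        + cfg.effect_top_income * (income == "GT100K")
        + cfg.effect_pgs_nonremission * pgs["pgs_nonremission"]
        + cfg.effect_per_year * (year_frac - mid_year)
        + center_offsets[center_idx]
    )
    if cfg.target_prevalence == 0 and cfg.switch_intercept is None:
        p_switch = np.zeros(n)
    else:
        if cfg.switch_intercept is not None:
            c = cfg.switch_intercept
        else:
            c = brentq(lambda c_: float(np.mean(expit(c_ + lp))) - cfg.target_prevalence, -20, 10)
        p_switch = expit(c + lp)
    is_switcher = cov_rng.random(n) < p_switch

    index_ssri = _choice(cov_rng, cfg.index_ssri_mix, n)
    gap = _sample_tts(cov_rng, n, cfg)  # only used for switchers
    post_class = _choice(cov_rng, cfg.post_switch_mix, n)
    # concrete post-switch drug: for SSRI targets, a different SSRI
    post_drug = np.empty(n, dtype=object)
    u_drug = cov_rng.random(n)
    for cls, drugs_of_cls in _CLASS_DRUGS.items():
        mask = post_class == cls
        if not mask.any():
            continue
        if cls == "SSRI":
            for s in SSRI_DRUGS:
                m2 = mask & (index_ssri == s)
                opts = np.array([d for d in drugs_of_cls if d != s], dtype=object)
                post_drug[m2] = opts[(u_drug[m2] * len(opts)).astype(int)]
        else:
            opts = np.array(drugs_of_cls, dtype=object)
            post_drug[mask] = opts[(u_drug[mask] * len(opts)).astype(int)]

    if cfg.contamination_fraction > 0:
        contam_mask = cov_rng.random(n) < cfg.contamination_fraction
        patterns = _choice(cov_rng, cfg.contamination_mix, n)
        contamination = np.where(contam_mask, patterns, "").astype(object)
    else:
        contamination = np.full(n, "", dtype=object)

    # --- prescriptions (own stream) ---
    rows_pid: list[np.ndarray] = []
    rows_day: list[np.ndarray] = []
    rows_drug: list[np.ndarray] = []

    def _refill(k: int) -> np.ndarray:
        return np.maximum(
            np.round(rx_rng.normal(cfg.refill_mean_days, cfg.refill_sd_days, k)),
            cfg.refill_min_days,
        ).astype(int)

    clean = contamination == ""
    sw_idx = np.flatnonzero(is_switcher & clean)
    ns_idx = np.flatnonzero(~is_switcher & clean)

    # switchers: small per-participant loop (few thousand iterations)
    n_sw = len(sw_idx)
    n_before2 = rx_rng.random(n_sw) < 0.5
    crosstaper = rx_rng.random(n_sw) < cfg.crosstaper_prob
    n_cont = rx_rng.poisson(2.5, n_sw)
    second_refill = _refill(n_sw)
    ct_day = rx_rng.integers(1, 8, n_sw)
    cont_iv = _refill(int(n_cont.sum()))
    cont_ptr = 0
    for j, i in enumerate(sw_idx):
        d0 = int(index_day[i])
        g = int(gap[i])
        days = [d0]
        drugs = [index_ssri[i]]
        if n_before2[j] and g >= 3:
            days.append(d0 + max(1, min(int(second_refill[j]), g - 1)))
            drugs.append(index_ssri[i])
        sday = d0 + g
        days.append(sday)
        drugs.append(post_drug[i])
        if crosstaper[j]:
            days.append(sday + int(ct_day[j]))
            drugs.append(index_ssri[i])
        kc = int(n_cont[j])
        if kc:
            offs = np.cumsum(cont_iv[cont_ptr : cont_ptr + kc])
            cont_ptr += kc
            days.extend((sday + offs).tolist())
            drugs.extend([post_drug[i]] * kc)
        rows_pid.append(np.repeat(ids[i], len(days)))
        rows_day.append(np.asarray(days, dtype=np.int64))
        rows_drug.append(np.asarray(drugs, dtype=object))

    # nonswitchers: fully vectorised
    if len(ns_idx):
        mu_rx, sd_rx = derive_ttswitch_params(cfg.nonswitcher_rx_median, cfg.nonswitcher_rx_iqr)
        m = np.clip(
            np.round(rx_rng.lognormal(mu_rx, sd_rx, len(ns_idx))), 3, cfg.nonswitcher_rx_max
        ).astype(int)
        total = int(m.sum())
        iv = _refill(total)
        starts = np.concatenate(([0], np.cumsum(m)[:-1]))
        iv[starts] = 0
        cs = np.cumsum(iv)
        off = cs - np.repeat(cs[starts], m)
        rows_pid.append(np.repeat(ids[ns_idx], m))
        rows_day.append(np.repeat(index_day[ns_idx], m) + off)
        rows_drug.append(np.repeat(index_ssri[ns_idx], m))

    # contaminant histories
    aug_other = ("amitriptyline", "mirtazapine", "trazodone")
    for i in np.flatnonzero(~clean):
        d0 = int(index_day[i])
        pat = contamination[i]
        if pat == "augmentation":
            # overlapping second antidepressant within the minimum-gap window,
            # index SSRI continued: not a switch
            offs = np.concatenate(([0], np.cumsum(_refill(2))))
            days = (d0 + offs).tolist() + [d0 + int(rx_rng.integers(0, 5))]
            drugs = [index_ssri[i]] * 3 + [aug_other[int(rx_rng.integers(0, len(aug_other)))]]
        elif pat == "single_issue":
            days = [d0]
            drugs = [index_ssri[i]]
        else:  # non_ad_only
            offs = np.concatenate(([0], np.cumsum(_refill(2))))
            days = (d0 + offs).tolist()
            nd = _NON_AD_DRUGS[int(rx_rng.integers(0, len(_NON_AD_DRUGS)))]
            drugs = [nd] * 3
        rows_pid.append(np.repeat(ids[i], len(days)))
        rows_day.append(np.asarray(days, dtype=np.int64))
        rows_drug.append(np.asarray(drugs, dtype=object))

    pid_all = np.concatenate(rows_pid)
    day_all = np.concatenate(rows_day)
    drug_all = np.concatenate(rows_drug)

    # raw name noise: strength-qualified strings exercising dictionary matching
    noisy = rx_rng.random(len(drug_all)) < cfg.drug_name_noise
    doses = rx_rng.choice(np.array(["10", "20", "25", "50"], dtype=object), len(drug_all))
    raw = np.where(noisy, drug_all.astype(object) + " " + doses + "mg tablets", drug_all)

    prescriptions = pd.DataFrame(
        {
            "participant_id": pid_all,
            "issue_date": pd.to_datetime(day_all, unit="D", origin="unix"),
            "drug_raw": raw,
            "drug_canonical": drug_all,
            "drug_class": np.array([_DRUG_CLASS_OF[d] for d in drug_all], dtype=object),
        }
    )
    prescriptions = prescriptions.drop_duplicates(
        subset=["participant_id", "issue_date", "drug_canonical"]
    )
    prescriptions = prescriptions.sort_values(
        ["participant_id", "issue_date", "drug_canonical"], kind="mergesort"
    ).reset_index(drop=True)

    # --- diagnoses (own stream) ---
    codeset = default_codeset()
    dep_codes = codes_for(codeset, DxCategory.DEPRESSION)
    excl_code_lists = {
        "BIPOLAR": codes_for(codeset, DxCategory.BIPOLAR),
        "PSYCHOSIS": codes_for(codeset, DxCategory.PSYCHOSIS),
        "SUBSTANCE_ABUSE": codes_for(codeset, DxCategory.SUBSTANCE_ABUSE),
    }
    u = dx_rng.random(n)
    ge1 = u < cfg.dep_dx_prob_ge1
    ge2 = u < cfg.dep_dx_prob_ge2
    n_dep = np.where(ge2, 2 + dx_rng.poisson(1.0, n), np.where(ge1, 1, 0))
    precedes = dx_rng.random(n) < cfg.dx_precedes_index_prob
    idx = np.flatnonzero(n_dep > 0)
    k = n_dep[idx].astype(int)
    base_off = 1 + dx_rng.exponential(180.0, len(idx)).astype(int)
    first = np.where(precedes[idx], index_day[idx] - base_off, index_day[idx] + base_off)
    total_dep = int(k.sum())
    gaps = 1 + dx_rng.exponential(90.0, total_dep).astype(int)
    dstarts = np.concatenate(([0], np.cumsum(k)[:-1])) if len(k) else np.array([], dtype=int)
    gaps[dstarts] = 0
    dcs = np.cumsum(gaps)
    doff = dcs - np.repeat(dcs[dstarts], k) if len(k) else dcs
    dx_pid = list(np.repeat(ids[idx], k))
    dx_day = list(np.repeat(first, k) + doff)
    dx_code = list(dx_rng.choice(np.array(dep_codes, dtype=object), total_dep))
    excluded = dx_rng.random(n) < cfg.exclusion_dx_prob
    excl_reason = np.full(n, "", dtype=object)
    for i in np.flatnonzero(excluded):
        reason = ("BIPOLAR", "PSYCHOSIS", "SUBSTANCE_ABUSE")[int(dx_rng.integers(0, 3))]
        codes = excl_code_lists[reason]
        excl_reason[i] = reason
        dx_pid.append(ids[i])
        dx_day.append(int(dx_rng.integers(d_start, d_end + 1)))
        dx_code.append(codes[int(dx_rng.integers(0, len(codes)))])
    cats = {c: DxCategory(v).value for c, v in codeset.items()}
    diagnoses = pd.DataFrame(
        {
            "participant_id": np.array(dx_pid, dtype=object),
            "event_date": pd.to_datetime(np.array(dx_day, dtype=np.int64), unit="D", origin="unix"),
            "code_raw": np.array(dx_code, dtype=object),
        }
    )
    diagnoses["category"] = diagnoses["code_raw"].map(cats).fillna(DxCategory.OTHER.value)
    diagnoses = diagnoses.drop_duplicates(subset=["participant_id", "event_date", "code_raw"])
    diagnoses = diagnoses.sort_values(
        ["participant_id", "event_date", "code_raw"], kind="mergesort"
    ).reset_index(drop=True)

    # --- kinship (own stream) ---
    n_pairs = int(cfg.kinship_pair_fraction * n / 2)
    if n_pairs:
        perm = kin_rng.permutation(n)
        id1 = ids[perm[:n_pairs]]
        id2 = ids[perm[n_pairs : 2 * n_pairs]]
        kin_values = np.array([0.25, 0.177, 0.125, 0.088, 0.0625, 0.044, 0.03, 0.02])
        kin_probs = np.array([0.10, 0.10, 0.20, 0.15, 0.15, 0.10, 0.10, 0.10])
        kin = kin_rng.choice(kin_values, n_pairs, p=kin_probs / kin_probs.sum())
        kinship = pd.DataFrame({"id1": id1, "id2": id2, "kinship": kin})
    else:
        kinship = pd.DataFrame(columns=["id1", "id2", "kinship"])

    covariates = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sex,
            "education": education,
            "income": income,
            "tdi": tdi,
            "bmi": bmi,
            "family_history": family_history,
            "center": centers[center_idx],
            "index_date": pd.to_datetime(index_day, unit="D", origin="unix"),
            **pgs,
            **pcs,
        }
    )

    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "latent_status": np.where(is_switcher, "SWITCHER", "NONSWITCHER").astype(object),
            "p_switch": p_switch,
            "excluded": excluded,
            "exclusion_reason": excl_reason,
            "contamination": contamination,
            "index_ssri": index_ssri,
            "index_date": pd.to_datetime(index_day, unit="D", origin="unix"),
            "gap_days": np.where(is_switcher, gap, np.nan),
            "post_switch_class": np.where(is_switcher, post_class, "").astype(object),
            "post_switch_drug": np.where(is_switcher, post_drug, "").astype(object),
            "n_dep_records": n_dep,
            "dep_precedes_index": np.where(n_dep > 0, precedes, False),
        }
    )

    return SyntheticCohort(
        prescriptions=prescriptions,
        diagnoses=diagnoses,
        covariates=covariates,
        kinship=kinship,
        truth=truth,
        config=cfg,
        seed=seed,
    )


@dataclass
class AuditResult:
    confusion: pd.DataFrame
    accuracy: float
    mismatches: pd.DataFrame


def audit_synthetic(truth: pd.DataFrame, pheno: pd.DataFrame) -> AuditResult:
    """Confusion matrix of latent vs recovered status for non-excluded participants.

    Contamination-free configurations recover the latent status exactly; with
    contamination, every mismatch row carries the injected pattern label so
    misclassification is attributable record by record.
    """
    t = truth[~truth["excluded"].astype(bool)]
    merged = t.merge(
        pheno[["participant_id", "status"]], on="participant_id", how="left"
    )
    merged["status"] = merged["status"].fillna("UNCLASSIFIED")
    confusion = pd.crosstab(merged["latent_status"], merged["status"])
    accuracy = float((merged["latent_status"] == merged["status"]).mean())
    mismatches = merged[merged["latent_status"] != merged["status"]][
        ["participant_id", "latent_status", "status", "contamination"]
    ].reset_index(drop=True)
    return AuditResult(confusion=confusion, accuracy=accuracy, mismatches=mismatches)
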