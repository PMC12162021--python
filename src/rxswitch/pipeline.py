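"""Config-driven end-to-end orchestration.

One structured-text (YAML) document drives a full run: either a simulate
block (synthetic cohort) or input table paths, plus phenotype criteria,
analysis plan and strata. Every stage writes its table under the output
directory and the run closes with a single JSON + markdown report whose
content is a pure function of the config and inputs (no timestamps), so a
rerun reproduces it bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import AnalysisPlan, run_associations
from .cohort import STRATA, build_cohort, diagnosis_precedes_index
from .descriptives import (
    post_switch_class_table,
    summarize_table1,
    temporal_trend,
    time_to_switch_summary,
    center_heterogeneity,
)
from .model import (
    default_codeset,
    default_drug_dictionary,
    load_codeset,
    load_drug_dictionary,
    read_covariates,
    read_diagnoses,
    read_kinship,
    read_prescriptions,
    write_table,
)
from .phenotyper import PhenotypeCriteria, phenotype_cohort
from .simulate import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed validation; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration; exactly one of simulate/inputs is set."""

    out_dir: Path
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    criteria: PhenotypeCriteria = field(default_factory=PhenotypeCriteria)
    plan: AnalysisPlan = field(default_factory=AnalysisPlan)
    strata: tuple[str, ...] = STRATA
    date_format: str = "%Y-%m-%d"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        if ("simulate" in doc) == ("inputs" in doc):
            raise PipelineError("config", "exactly one of 'simulate' or 'inputs' must be present")
        sim = SimulationConfig(**doc["simulate"]) if "simulate" in doc else None
        inputs = doc.get("inputs")
        if inputs:
            for key in ("prescriptions", "diagnoses", "covariates"):
                if key not in inputs:
                    raise PipelineError("config", f"inputs block missing {key!r}")
                if not Path(inputs[key]).exists():
                    raise PipelineError("config", f"input file not found: {inputs[key]}")
            for key in ("kinship", "drug_dictionary", "codeset"):
                if key in inputs and not Path(inputs[key]).exists():
                    raise PipelineError("config", f"input file not found: {inputs[key]}")
        return cls(
            out_dir=Path(doc.get("out_dir", "rxswitch_run")),
            seed=int(doc.get("seed", 0)),
            simulate=sim,
            inputs=inputs,
            criteria=PhenotypeCriteria(**doc.get("criteria", {})),
            plan=AnalysisPlan(**doc.get("plan", {})),
            strata=tuple(doc.get("strata", STRATA)),
            date_format=doc.get("date_format", "%Y-%m-%d"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_tables(config: RunConfig):
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate, config.seed)
        return cohort.prescriptions, cohort.diagnoses, cohort.covariates, cohort.kinship
    inp = config.inputs
    dictionary = (
        load_drug_dictionary(inp["drug_dictionary"])
        if "drug_dictionary" in inp
        else default_drug_dictionary()
    )
    codeset = load_codeset(inp["codeset"]) if "codeset" in inp else default_codeset()
    rx = read_prescriptions(inp["prescriptions"], dictionary, date_format=config.date_format)
    dx = read_diagnoses(inp["diagnoses"], codeset, date_format=config.date_format)
    cov = read_covariates(inp["covariates"], date_format=config.date_format)
    kin = read_kinship(inp["kinship"]) if "kinship" in inp else pd.DataFrame(columns=["id1", "id2", "kinship"])
    return rx, dx, cov, kin


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load → cohort → phenotype → descriptives → associations.

    Returns the run report (also written as report.json / report.md in the
    output directory). Raises :class:`PipelineError` on stage failure, after
    writing a FAILED marker next to any partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": "rxswitch",
            "version": __version__,
            "seed": config.seed,
            "criteria": dataclasses.asdict(config.criteria),
            "plan": dataclasses.asdict(config.plan),
            "mode": "simulate" if config.simulate is not None else "inputs",
        }
    }
    stage = "load"
    try:
        rx, dx, cov, kin = _load_tables(config)
        for name, df in (("prescriptions", rx), ("diagnoses", dx)):
            write_table(df, out / f"{name}.csv")
        report["load"] = {
            "n_prescription_rows": int(len(rx)),
            "n_diagnosis_rows": int(len(dx)),
            "n_participants": int(rx["participant_id"].nunique()),
        }

        stage = "cohort"
        memberships = build_cohort(dx, set(rx["participant_id"]))
        write_table(memberships, out / "cohort.csv")
        report["cohort"] = {
            "n_participants": int(len(memberships)),
            "n_excluded": int(memberships["excluded"].sum()),
            "n_ge1_mdd": int(memberships["in_ge1_mdd"].sum()),
            "n_ge2_mdd": int(memberships["in_ge2_mdd"].sum()),
        }

        stage = "phenotype"
        pheno, counts = phenotype_cohort(rx, memberships, config.criteria)
        write_table(pheno, out / "pheno.csv")
        write_table(counts, out / "counts.csv")
        all_counts = counts[counts["stratum"] == "ALL"].set_index("status")["n"]
        report["phenotype"] = {
            "counts": {
                f"{r.stratum}:{r.status}": int(r.n) for r in counts.itertuples()
            },
            "accounting": {
                "input_participants": int(len(memberships)),
                "excluded": int(memberships["excluded"].sum()),
                "switchers": int(all_counts.get("SWITCHER", 0)),
                "nonswitchers": int(all_counts.get("NONSWITCHER", 0)),
                "unclassified": int(all_counts.get("UNCLASSIFIED", 0)),
            },
        }
        acc = report["phenotype"]["accounting"]
        if acc["excluded"] + acc["switchers"] + acc["nonswitchers"] + acc["unclassified"] != acc["input_participants"]:
            raise PipelineError("phenotype", "participant accounting is not conserved")

        stage = "descriptives"
        table1 = summarize_table1(pheno, cov)
        write_table(table1, out / "table1.csv")
        desc: dict = {}
        if (pheno["status"] == "SWITCHER").any():
            tts = time_to_switch_summary(pheno)
            desc["time_to_switch"] = {
                "median": float(tts["median"].iloc[0]),
                "q25": float(tts["q25"].iloc[0]),
                "q75": float(tts["q75"].iloc[0]),
            }
            psc = post_switch_class_table(pheno)
            write_table(psc, out / "post_switch_classes.csv")
            desc["post_switch_pct"] = {
                r.post_switch_class: round(float(r.pct), 2) for r in psc.itertuples()
            }
        if "center" in cov.columns:
            het = center_heterogeneity(pheno, cov)
            desc["center_heterogeneity"] = {
                "p_value": het["p_value"],
                "min_prop": het["min_prop"],
                "max_prop": het["max_prop"],
            }
        try:
            trend = temporal_trend(pheno)
            desc["temporal_trend"] = {
                "rate_r": trend.rate_r,
                "rate_p": trend.rate_p,
                "tts_r": trend.tts_r,
                "tts_p": trend.tts_p,
            }
        except ValueError:
            logger.info("temporal trend skipped: too few time bins")
        dpi = diagnosis_precedes_index(memberships, dx, pheno)
        write_table(dpi, out / "diagnosis_precedes_index.csv")
        desc["diagnosis_precedes_index"] = {
            r.stratum: (None if pd.isna(r.proportion) else round(float(r.proportion), 4))
            for r in dpi.itertuples()
        }
        report["descriptives"] = desc

        stage = "associate"
        exposures = tuple(
            e
            for e in ("education", "income", "family_history", "tdi", "pgs_mdd", "pgs_scz", "pgs_nonremission")
            if e in cov.columns
        )
        assoc = run_associations(
            pheno, cov, memberships, exposures=exposures, plan=config.plan,
            kinship=kin, strata=config.strata,
        )
        write_table(assoc, out / "associations.csv")
        report["associations"] = {
            "n_tests": int(len(exposures)),
            "bonferroni_threshold": config.plan.threshold,
            "n_significant": int(assoc["significant"].sum()) if len(assoc) else 0,
        }
    except PipelineError:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise
    except Exception as exc:  # wrap with stage context
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    payload = json.dumps(report, indent=2, sort_keys=True, default=str)
    (out / "report.json").write_text(payload)
    report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# rxswitch run report", ""]
    acc = report.get("phenotype", {}).get("accounting", {})
    if acc:
        lines += [
            "## Participant accounting",
            "",
            *(f"- {k}: {v}" for k, v in acc.items()),
            "",
        ]
    desc = report.get("descriptives", {})
    if "time_to_switch" in desc:
        t = desc["time_to_switch"]
        lines.append(f"Time to switch (days): median {t['median']:.0f} (IQR {t['q25']:.0f}–{t['q75']:.0f})")
    if "post_switch_pct" in desc:
        mix = ", ".join(f"{k} {v:.0f}%" for k, v in sorted(desc["post_switch_pct"].items()))
        lines.append(f"Post-switch class mix: {mix}")
    lines += ["", f"Report hash: {report.get('report_sha256', '')}", ""]
    return "\n".join(lines)
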