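"""Domain types and table I/O for primary-care prescription and diagnosis records.

Everything downstream consumes the tidy tables produced here:

* prescriptions — one row per drug issue: ``participant_id``, ``issue_date``,
  ``drug_raw``, ``drug_canonical``, ``drug_class``;
* diagnoses — one row per coded clinical event: ``participant_id``,
  ``event_date``, ``code_raw``, ``category``;
* covariates and kinship pairs (read as-is, validated lightly).

Drug names are resolved through a :class:`DrugDictionary` so that free-text,
brand- or strength-qualified prescription strings ("Fluoxetine 20mg caps")
map to a canonical generic name and a drug class. Diagnosis codes are mapped
to broad diagnostic categories through a flat code→category lookup; the code
lists shipped here are illustrative, editable defaults meant to be replaced
by validated codelists for a given EHR extract.

Dates are day-resolution everywhere; internal tables hold ``datetime64`` and
serialised tables use ISO-8601, with the input format configurable because UK
primary-care extracts commonly use day/month/year.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DrugClass",
    "DxCategory",
    "DrugDictionary",
    "DictionaryConflictError",
    "TableParseError",
    "ANTIDEPRESSANT_CLASSES",
    "EXCLUSION_CATEGORIES",
    "SSRI_DRUGS",
    "default_drug_dictionary",
    "default_codeset",
    "load_drug_dictionary",
    "load_codeset",
    "read_prescriptions",
    "read_diagnoses",
    "read_covariates",
    "read_kinship",
    "write_table",
]


class DrugClass(str, enum.Enum):
    """Drug classes used by the switching phenotype.

    ``NON_AD`` marks anything that is not an antidepressant; a switch target
    must belong to one of the antidepressant classes.
    """

    SSRI = "SSRI"
    TCA = "TCA"
    SNRI = "SNRI"
    SARI = "SARI"
    NRI = "NRI"
    MAOI = "MAOI"
    OTHER_AD = "OTHER_AD"
    NON_AD = "NON_AD"


ANTIDEPRESSANT_CLASSES = frozenset(
    c.value for c in DrugClass if c is not DrugClass.NON_AD
)


class DxCategory(str, enum.Enum):
    """Broad diagnostic categories relevant to cohort construction."""

    DEPRESSION = "DEPRESSION"
    BIPOLAR = "BIPOLAR"
    PSYCHOSIS = "PSYCHOSIS"
    SUBSTANCE_ABUSE = "SUBSTANCE_ABUSE"
    OTHER = "OTHER"


#: Diagnoses that exclude a participant from the cohort at any date.
EXCLUSION_CATEGORIES = frozenset(
    {DxCategory.BIPOLAR.value, DxCategory.PSYCHOSIS.value, DxCategory.SUBSTANCE_ABUSE.value}
)

#: The six SSRIs eligible as index drug.
SSRI_DRUGS = (
    "citalopram",
    "escitalopram",
    "fluoxetine",
    "fluvoxamine",
    "paroxetine",
    "sertraline",
)


class DictionaryConflictError(ValueError):
    """Raised when a raw drug string maps to two different targets."""


class TableParseError(ValueError):
    """Raised when an input table has a malformed row; names the offending line."""


def _norm(s: str) -> str:
    return " ".join(str(s).lower().split())


@dataclass
class DrugDictionary:
    """Total lookup from raw prescription strings to (canonical name, class).

    Matching order: exact normalized match, then longest canonical-name
    substring (so "sertraline 50mg tablets" resolves to sertraline).
    Unmapped strings fall back to ``(raw, NON_AD)`` with a logged warning, so
    lookup never fails.
    """

    entries: dict[str, tuple[str, DrugClass]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._canonicals: dict[str, DrugClass] = {}
        for canon, cls in self.entries.values():
            self._canonicals.setdefault(canon, cls)

    def add(self, raw: str, canonical: str, drug_class: DrugClass) -> None:
        key = _norm(raw)
        target = (_norm(canonical), DrugClass(drug_class))
        existing = self.entries.get(key)
        if existing is not None and existing != target:
            raise DictionaryConflictError(
                f"raw name {raw!r} maps to both {existing} and {target}"
            )
        self.entries[key] = target
        self._canonicals.setdefault(target[0], target[1])

    def lookup(self, raw: str) -> tuple[str, DrugClass]:
        key = _norm(raw)
        hit = self.entries.get(key)
        if hit is not None:
            return hit
        # longest canonical substring wins; ties broken alphabetically
        matches = sorted(
            (c for c in self._canonicals if c in key),
            key=lambda c: (-len(c), c),
        )
        if matches:
            canon = matches[0]
            return canon, self._canonicals[canon]
        logger.warning("unmapped drug string %r treated as NON_AD", raw)
        return key, DrugClass.NON_AD

    def classes(self) -> Mapping[str, DrugClass]:
        """Canonical name → drug class for every known canonical."""
        return dict(self._canonicals)


_DEFAULT_DRUGS: dict[str, DrugClass] = {
    # SSRIs (the six index-eligible drugs)
    **{d: DrugClass.SSRI for d in SSRI_DRUGS},
    # tricyclics
    **{
        d: DrugClass.TCA
        for d in (
            "amitriptyline",
            "clomipramine",
            "dosulepin",
            "doxepin",
            "imipramine",
            "lofepramine",
            "nortriptyline",
            "trimipramine",
        )
    },
    "venlafaxine": DrugClass.SNRI,
    "duloxetine": DrugClass.SNRI,
    "trazodone": DrugClass.SARI,
    "nefazodone": DrugClass.SARI,
    "reboxetine": DrugClass.NRI,
    "phenelzine": DrugClass.MAOI,
    "tranylcypromine": DrugClass.MAOI,
    "isocarboxazid": DrugClass.MAOI,
    "moclobemide": DrugClass.MAOI,
    "mirtazapine": DrugClass.OTHER_AD,
    "agomelatine": DrugClass.OTHER_AD,
    # common non-antidepressants, so typical co-prescriptions do not warn
    "ibuprofen": DrugClass.NON_AD,
    "paracetamol": DrugClass.NON_AD,
    "omeprazole": DrugClass.NON_AD,
    "simvastatin": DrugClass.NON_AD,
    "amoxicillin": DrugClass.NON_AD,
    "zopiclone": DrugClass.NON_AD,
    "diazepam": DrugClass.NON_AD,
}


def default_drug_dictionary() -> DrugDictionary:
    """Built-in antidepressant dictionary covering every representable class.

    Editable default: real deployments should load a curated mapping with
    :func:`load_drug_dictionary`.
    """
    d = DrugDictionary()
    for name, cls in _DEFAULT_DRUGS.items():
        d.add(name, name, cls)
    return d


# Illustrative READ-v2-style code lists; flat lookup tables by design.
_DEFAULT_CODES: dict[str, DxCategory] = {
    "E112.": DxCategory.DEPRESSION,
    "E1120": DxCategory.DEPRESSION,
    "E1121": DxCategory.DEPRESSION,
    "E113.": DxCategory.DEPRESSION,
    "E1131": DxCategory.DEPRESSION,
    "E2B..": DxCategory.DEPRESSION,
    "E2B0.": DxCategory.DEPRESSION,
    "E2B1.": DxCategory.DEPRESSION,
    "E110.": DxCategory.BIPOLAR,
    "E1100": DxCategory.BIPOLAR,
    "E111.": DxCategory.BIPOLAR,
    "E10..": DxCategory.PSYCHOSIS,
    "E100.": DxCategory.PSYCHOSIS,
    "E101.": DxCategory.PSYCHOSIS,
    "E23..": DxCategory.SUBSTANCE_ABUSE,
    "E230.": DxCategory.SUBSTANCE_ABUSE,
    "E24..": DxCategory.SUBSTANCE_ABUSE,
}


def default_codeset() -> dict[str, DxCategory]:
    """Illustrative default diagnosis code→category lookup (editable)."""
    return dict(_DEFAULT_CODES)


def codes_for(codeset: Mapping[str, DxCategory], category: DxCategory) -> list[str]:
    return sorted(c for c, cat in codeset.items() if DxCategory(cat) is category)


def load_drug_dictionary(path: str | Path, delimiter: str = ",") -> DrugDictionary:
    """Load a drug dictionary from a delimited file with header raw_name,canonical,class."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = {"raw_name", "canonical", "class"}
    if not required.issubset(df.columns):
        raise TableParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    d = DrugDictionary()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            cls = DrugClass(str(row[df.columns.get_loc("class")]))
        except ValueError as exc:
            raise TableParseError(f"{path}, line {i}: invalid drug class {exc}") from exc
        raw = getattr(row, "raw_name")
        canon = getattr(row, "canonical")
        if pd.isna(raw) or pd.isna(canon):
            raise TableParseError(f"{path}, line {i}: missing raw_name or canonical")
        d.add(raw, canon, cls)
    return d


def load_codeset(path: str | Path, delimiter: str = ",") -> dict[str, DxCategory]:
    """Load a flat code→category lookup from a file with header code,category."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if not {"code", "category"}.issubset(df.columns):
        raise TableParseError(f"{path}: expected columns ['code', 'category']")
    out: dict[str, DxCategory] = {}
    for i, (code, cat) in enumerate(zip(df["code"], df["category"]), start=2):
        try:
            out[str(code)] = DxCategory(str(cat))
        except ValueError as exc:
            raise TableParseError(f"{path}, line {i}: invalid category {cat!r}") from exc
    return out


def _parse_dates(raw: pd.Series, date_format: str, context: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format=date_format, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        idx = int(bad.idxmax())
        raise TableParseError(
            f"{context}: unparseable date {raw.loc[idx]!r} at input row {idx + 2} "
            f"(expected format {date_format!r})"
        )
    if parsed.isna().any():
        idx = int(parsed.isna().idxmax())
        raise TableParseError(f"{context}: missing date at input row {idx + 2}")
    return parsed


def read_prescriptions(
    path: str | Path,
    dictionary: DrugDictionary,
    column_map: Mapping[str, str] | None = None,
    date_format: str = "%Y-%m-%d",
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a prescription table into the canonical tidy form.

    ``column_map`` names the source columns for ``participant_id``,
    ``issue_date`` and ``drug`` (defaults assume those very names). Output is
    sorted by (participant_id, issue_date, drug_canonical); exact same-day
    duplicates of the same canonical drug are collapsed to a single row, with
    the collapsed count logged — duplicated EHR issues would otherwise inflate
    the prescription counts the switch criteria depend on.
    """
    cm = {"participant_id": "participant_id", "issue_date": "issue_date", "drug": "drug"}
    if column_map:
        cm.update(column_map)
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    if raw.empty:
        return pd.DataFrame(
            columns=["participant_id", "issue_date", "drug_raw", "drug_canonical", "drug_class"]
        )
    missing = [v for v in cm.values() if v not in raw.columns]
    if missing:
        raise TableParseError(f"{path}: missing columns {missing}")
    out = pd.DataFrame(
        {
            "participant_id": raw[cm["participant_id"]].astype(str),
            "issue_date": _parse_dates(raw[cm["issue_date"]], date_format, str(path)),
            "drug_raw": raw[cm["drug"]].astype(str),
        }
    )
    mapped = out["drug_raw"].map(lambda s: dictionary.lookup(s))
    out["drug_canonical"] = [m[0] for m in mapped]
    out["drug_class"] = [m[1].value for m in mapped]
    n0 = len(out)
    out = out.drop_duplicates(subset=["participant_id", "issue_date", "drug_canonical"])
    if len(out) < n0:
        logger.info("collapsed %d same-day duplicate prescription rows", n0 - len(out))
    out = out.sort_values(
        ["participant_id", "issue_date", "drug_canonical"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def read_diagnoses(
    path: str | Path,
    codeset: Mapping[str, DxCategory],
    column_map: Mapping[str, str] | None = None,
    date_format: str = "%Y-%m-%d",
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a diagnosis table; category comes solely from codeset membership."""
    cm = {"participant_id": "participant_id", "event_date": "event_date", "code": "code"}
    if column_map:
        cm.update(column_map)
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    if raw.empty:
        return pd.DataFrame(columns=["participant_id", "event_date", "code_raw", "category"])
    missing = [v for v in cm.values() if v not in raw.columns]
    if missing:
        raise TableParseError(f"{path}: missing columns {missing}")
    out = pd.DataFrame(
        {
            "participant_id": raw[cm["participant_id"]].astype(str),
            "event_date": _parse_dates(raw[cm["event_date"]], date_format, str(path)),
            "code_raw": raw[cm["code"]].astype(str),
        }
    )
    cats = {str(k): DxCategory(v).value for k, v in codeset.items()}
    out["category"] = out["code_raw"].map(cats).fillna(DxCategory.OTHER.value)
    out = out.drop_duplicates(subset=["participant_id", "event_date", "code_raw"])
    out = out.sort_values(
        ["participant_id", "event_date", "code_raw"], kind="mergesort"
    ).reset_index(drop=True)
    return out


COVARIATE_DATE_COLS = ("index_date",)


def read_covariates(path: str | Path, date_format: str = "%Y-%m-%d", delimiter: str = ",") -> pd.DataFrame:
    """Read the covariate table; parses any date columns, leaves the rest typed by pandas."""
    df = pd.read_csv(path, sep=delimiter)
    df["participant_id"] = df["participant_id"].astype(str)
    for col in COVARIATE_DATE_COLS:
        if col in df.columns:
            df[col] = _parse_dates(df[col].astype(str), date_format, str(path))
    return df


def read_kinship(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read kinship pairs (id1, id2, kinship); kinship must lie in [0, 0.5]."""
    df = pd.read_csv(path, sep=delimiter, dtype={"id1": str, "id2": str})
    if not {"id1", "id2", "kinship"}.issubset(df.columns):
        raise TableParseError(f"{path}: expected columns ['id1', 'id2', 'kinship']")
    df["kinship"] = df["kinship"].astype(float)
    if ((df["kinship"] < 0) | (df["kinship"] > 0.5)).any():
        raise TableParseError(f"{path}: kinship coefficients must lie in [0, 0.5]")
    return df


def write_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write any tidy table as delimited text with ISO-8601 dates."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep=delimiter, index=False)
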