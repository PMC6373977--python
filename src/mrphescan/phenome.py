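"""Rule-based typing and preprocessing of raw biobank fields.

Raw fields come in four showcase field types (integer, continuous,
categorical single, categorical multiple). A small decision-rule engine
assigns each to one of four scan data types (continuous, binary, ordered
categorical, unordered categorical), expands categorical-multiple fields
into one binary indicator per observed code, applies an inverse normal
rank transform to continuous outcomes, and keeps a per-stage audit of how
many fields and derived outcomes survive each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

FIELD_TYPES = ("integer", "continuous", "categorical_single", "categorical_multiple")
DATA_TYPES = ("continuous", "binary", "ordered_categorical", "unordered_categorical")


@dataclass
class RuleConfig:
    """Tunable thresholds of the typing rules.

    distinct_value_threshold: integer/continuous fields with fewer distinct
        non-missing values than this are demoted to ordered categorical
        (two values -> binary).
    min_cases: minimum count in the minor category for a binary outcome to
        be kept (guards against unstable logistic fits).
    """

    distinct_value_threshold: int = 20
    min_cases: int = 10


@dataclass
class RawField:
    field_id: str
    field_type: str
    values: pd.Series
    coding: dict | None = None  # {'ordered': bool, 'levels': [...] in order}
    excluded_a_priori: bool = False
    exposure_phenotype: bool = False

    def __post_init__(self):
        if self.field_type not in FIELD_TYPES:
            raise ValueError(f"unknown field type {self.field_type!r}")


@dataclass
class DerivedOutcome:
    outcome_id: str
    data_type: str
    values: pd.Series
    source_field: str
    provenance: list[str] = dc_field(default_factory=list)
    exposure_phenotype: bool = False

    @property
    def n_nonmissing(self) -> int:
        return int(self.values.notna().sum())


def inverse_normal_transform(values) -> pd.Series:
    """Rank-based inverse normal transform, missing entries preserved.

    Non-missing entries are replaced by ``Phi^-1((r - 0.5) / m)`` where
    ``r`` is the tie-averaged rank and ``m`` the non-missing count.
    """
    s = pd.Series(values, dtype=float, copy=True)
    mask = s.notna()
    x = s[mask].to_numpy()
    if np.unique(x).size < 2:
        raise ValueError("constant or empty vector cannot be rank-transformed")
    r = stats.rankdata(x, method="average")
    s[mask] = stats.norm.ppf((r - 0.5) / x.size)
    return s


def classify_field(field: RawField, thresholds: RuleConfig | None = None) -> str:
    """Assign a scan data type to a single raw field.

    Integer/continuous fields default to continuous unless they take only
    a few distinct values; categorical-single fields become binary with two
    levels and otherwise follow the dictionary's ordered flag;
    categorical-multiple assignment is deferred to expansion.
    """
    cfg = thresholds or RuleConfig()
    if field.excluded_a_priori:
        raise ValueError(f"field {field.field_id} is flagged excluded")
    nonmiss = field.values.dropna()
    if nonmiss.empty:
        raise ValueError(f"field {field.field_id} has no non-missing values")
    if field.field_type in ("integer", "continuous"):
        k = nonmiss.nunique()
        if k == 2:
            return "binary"
        if k < cfg.distinct_value_threshold:
            return "ordered_categorical"
        return "continuous"
    if field.field_type == "categorical_single":
        k = nonmiss.nunique()
        if k <= 2:
            return "binary"
        if field.coding is None or "ordered" not in field.coding:
            raise ValueError(
                f"categorical_single field {field.field_id} with {k} levels "
                "lacks an ordered/unordered coding (dictionary defect)"
            )
        return "ordered_categorical" if field.coding["ordered"] else "unordered_categorical"
    return "categorical_multiple"  # expanded separately


def expand_categorical_multiple(
    field: RawField, thresholds: RuleConfig | None = None
) -> tuple[list[DerivedOutcome], list[str]]:
    """One binary outcome per distinct observed code.

    ``field.values`` holds per-participant iterables (or delimited strings)
    of codes; a participant scores 1 on a code if it appears in any entry.
    Outcomes failing the minimum-case rule (including all-0/all-1
    degenerates) are dropped; their ids are returned in the log.
    """
    if field.field_type != "categorical_multiple":
        raise ValueError("expand_categorical_multiple requires a categorical_multiple field")
    cfg = thresholds or RuleConfig()

    def as_set(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return set()
        if isinstance(v, str):
            return {c for c in v.split("|") if c}
        return set(v)

    sets = field.values.map(as_set)
    codes = sorted(set().union(*sets)) if len(sets) else []
    if not codes:
        raise ValueError(f"field {field.field_id} has no observed codes")
    outcomes, dropped = [], []
    for code in codes:
        vals = sets.map(lambda s, c=code: float(c in s))
        oid = f"{field.field_id}#{code}"
        minor = int(min(vals.sum(), (1 - vals).sum()))
        if minor < cfg.min_cases:
            dropped.append(oid)
            continue
        outcomes.append(
            DerivedOutcome(
                outcome_id=oid,
                data_type="binary",
                values=vals,
                source_field=field.field_id,
                provenance=[f"expanded code {code} of categorical_multiple {field.field_id}"],
                exposure_phenotype=field.exposure_phenotype,
            )
        )
    return outcomes, dropped


def derive_outcome(field: RawField, cfg: RuleConfig) -> tuple[list[DerivedOutcome], list[str]]:
    """Apply the full rule chain to one field."""
    if field.field_type == "categorical_multiple":
        return expand_categorical_multiple(field, cfg)
    dtype = classify_field(field, cfg)
    vals = field.values.copy()
    prov = [f"classified {field.field_type} -> {dtype}"]
    if dtype == "continuous":
        vals = inverse_normal_transform(vals)
        prov.append("inverse normal rank transform")
    if dtype == "binary":
        levels = sorted(vals.dropna().unique())
        vals = vals.map({levels[0]: 0.0, levels[-1]: 1.0}, na_action="ignore")
        minor = int(min(vals.sum(), vals.notna().sum() - vals.sum()))
        if len(levels) < 2 or minor < cfg.min_cases:
            return [], [field.field_id]
        prov.append(f"binary recode {levels[0]}->0, {levels[-1]}->1")
    out = DerivedOutcome(
        outcome_id=str(field.field_id),
        data_type=dtype,
        values=vals,
        source_field=field.field_id,
        provenance=prov,
        exposure_phenotype=field.exposure_phenotype,
    )
    return [out], []


def build_outcome_dataset(
    fields: list[RawField],
    exclusions: list[str] | None = None,
    exposure_ids: list[str] | None = None,
    rule_config: RuleConfig | None = None,
) -> tuple[list[DerivedOutcome], dict]:
    """Run the rule engine over a field list with a stage-count audit.

    A-priori-excluded fields are removed; exposure-phenotype fields are
    kept and scanned but flagged so they do not enter the multiplicity
    count. Returns the derived outcomes and a dict of per-stage counts.
    """
    cfg = rule_config or RuleConfig()
    exclusions = set(exclusions or [])
    exposure_ids = set(exposure_ids or [])
    ids = [f.field_id for f in fields]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate field ids")
    missing = (exclusions | exposure_ids) - set(ids)
    if missing:
        raise ValueError(f"unknown field ids: {sorted(missing)}")

    counts = {"fields_in": len(fields), "excluded_a_priori": 0, "exposure_flagged": 0,
              "fields_scanned": 0, "derived_outcomes": 0, "dropped_degenerate": 0,
              "multiplicity_count": 0}
    outcomes: list[DerivedOutcome] = []
    dropped: list[str] = []
    for f in fields:
        if f.field_id in exclusions or f.excluded_a_priori:
            counts["excluded_a_priori"] += 1
            continue
        if f.field_id in exposure_ids:
            f.exposure_phenotype = True
        if f.exposure_phenotype:
            counts["exposure_flagged"] += 1
        counts["fields_scanned"] += 1
        outs, drops = derive_outcome(f, cfg)
        outcomes.extend(outs)
        dropped.extend(drops)
    counts["derived_outcomes"] = len(outcomes)
    counts["dropped_degenerate"] = len(dropped)
    counts["multiplicity_count"] = sum(1 for o in outcomes if not o.exposure_phenotype)
    counts["dropped_ids"] = dropped
    return outcomes, counts


def fields_from_tables(phenome: pd.DataFrame, dictionary: pd.DataFrame) -> list[RawField]:
    """Assemble RawField objects from a phenome table and its dictionary.

    The dictionary needs columns ``field_id``, ``field_type`` and
    optionally ``ordered`` (bool) plus the exclusion/exposure flags.
    """
    dic = dictionary.set_index(dictionary["field_id"].astype(str))
    if dic.index.duplicated().any():
        raise ValueError("dictionary contains duplicate field ids")
    fields = []
    for fid in phenome.columns:
        fid = str(fid)
        if fid not in dic.index:
            raise ValueError(f"phenome field {fid} missing from dictionary")
        row = dic.loc[fid]
        coding = None
        if "ordered" in dic.columns and not pd.isna(row.get("ordered")):
            coding = {"ordered": bool(row["ordered"])}
        fields.append(
            RawField(
                field_id=fid,
                field_type=str(row["field_type"]),
                values=phenome[fid],
                coding=coding,
                excluded_a_priori=bool(row.get("excluded_a_priori", False)),
                exposure_phenotype=bool(row.get("exposure_phenotype", False)),
            )
        )
    return fields
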