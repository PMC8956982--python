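"""Enrollee-year cohort construction.

Turns enrollment spans and claim lines into one weighted record per person
per calendar year:

* diagnoses are restricted to those coded by acceptable (setting,
  professional-type) pairs, with removals counted in a run report;
* each outcome is summed over the year's claims, floored at $0, top-coded at
  a global cleaning cap, deflated to a reference year, annualized to a
  12-month rate by dividing by the fraction of the year enrolled, and
  finally top-coded at an optional analysis cap;
* partial-year enrollees receive regression weight equal to their enrolled
  fraction; newborns keep their raw (unannualized) outcomes with weight 1,
  since birth-episode spending is not a rate.

The fixed order of operations is sum -> floor -> global cap -> deflate ->
annualize -> analysis cap: cleaning recodes precede analysis top-codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .chapters import canonicalize_code

ENROLLMENT_COLUMNS = [
    "person_id", "year", "months_enrolled", "age", "sex", "newborn",
]
CLAIM_COLUMNS = [
    "person_id", "year", "setting", "professional_type", "service_type",
    "diagnosis_codes", "paid_total", "paid_plan", "paid_oop",
]
COUNT_COLUMNS = ["admissions", "ip_days", "ed_visits"]

SETTINGS = ("inpatient", "outpatient", "professional", "other")


@dataclass(frozen=True)
class OutcomeSpec:
    """How one outcome is extracted and cleaned.

    ``kind`` selects the source: ``payer`` sums a paid column over all lines,
    ``service`` sums plan paid over lines of one service type, ``count``
    sums a utilization count column. Caps/floors are applied in the fixed
    order documented in the module docstring; ``analysis_cap`` acts on the
    annualized value.
    """

    name: str
    kind: str = "payer"  # payer | service | count
    source: str = "paid_total"
    floor: Optional[float] = 0.0
    global_cap: Optional[float] = 3_000_000.0
    analysis_cap: Optional[float] = None
    deflate: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("payer", "service", "count"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if (
            self.analysis_cap is not None
            and self.global_cap is not None
            and self.analysis_cap > self.global_cap
        ):
            raise ValueError(
                f"{self.name}: analysis_cap must not exceed global_cap"
            )


def default_outcome_specs() -> list[OutcomeSpec]:
    """The study's spending outcomes: total/plan (raw and $250K top-coded)
    and out-of-pocket ($500K top-code), all floored at $0 and cleaned at $3M.
    """
    return [
        OutcomeSpec("total", "payer", "paid_total"),
        OutcomeSpec("total_topcoded", "payer", "paid_total", analysis_cap=250_000.0),
        OutcomeSpec("plan", "payer", "paid_plan"),
        OutcomeSpec("plan_topcoded", "payer", "paid_plan", analysis_cap=250_000.0),
        OutcomeSpec("oop", "payer", "paid_oop", analysis_cap=500_000.0),
    ]


def count_outcome_specs() -> list[OutcomeSpec]:
    return [
        OutcomeSpec(name, "count", name, global_cap=None, deflate=False)
        for name in COUNT_COLUMNS
    ]


# ---------------------------------------------------------------------------
# diagnosis filtering
# ---------------------------------------------------------------------------

#: Single wildcard row: accept every (setting, professional_type) pair.
ALLOW_ALL_RULES = pd.DataFrame(
    [{"setting": "*", "professional_type": "*"}]
)


def explode_diagnoses(claims: pd.DataFrame) -> pd.DataFrame:
    """One row per (claim line, diagnosis code), codes canonicalized.

    ``diagnosis_codes`` may be a list/tuple or a ``;``-separated string;
    empty entries yield no rows. Syntactically invalid codes raise.
    """
    codes = claims["diagnosis_codes"]
    if codes.map(lambda v: isinstance(v, str)).any():
        codes = codes.map(
            lambda v: [c for c in str(v).split(";") if c.strip()]
            if isinstance(v, str) else list(v)
        )
    long = claims.assign(code=codes).explode("code")
    long = long[long["code"].notna() & (long["code"] != "")]
    long = long.drop(columns=["diagnosis_codes"])
    long["code"] = [canonicalize_code(c) for c in long["code"]]
    return long


def filter_diagnoses(
    claims: pd.DataFrame,
    rules: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Keep diagnoses coded by acceptable professional sources.

    ``rules`` lists allowed (setting, professional_type) pairs; ``*`` is a
    wildcard in either column. Lines with an unrecognized setting are routed
    to ``other`` before matching. Returns the surviving diagnosis-level
    frame and a report counting removals by (setting, professional_type).
    """
    required = {"setting", "professional_type"}
    if not required.issubset(rules.columns):
        raise ValueError(f"rules table must have columns {sorted(required)}")
    long = explode_diagnoses(claims)
    setting = long["setting"].where(long["setting"].isin(SETTINGS), "other")
    ptype = long["professional_type"].astype(str)

    allowed = np.zeros(len(long), dtype=bool)
    for _, rule in rules.iterrows():
        rule_setting = str(rule["setting"])
        rule_ptype = str(rule["professional_type"])
        hit = np.ones(len(long), dtype=bool)
        if rule_setting != "*":
            hit &= (setting == rule_setting).to_numpy()
        if rule_ptype != "*":
            hit &= (ptype == rule_ptype).to_numpy()
        allowed |= hit

    removed = long.loc[~allowed]
    removed_by_reason = (
        removed.assign(setting=setting[~allowed])
        .groupby(["setting", "professional_type"], observed=True)
        .size()
    )
    report = {
        "n_diagnoses_in": int(len(long)),
        "n_diagnoses_kept": int(allowed.sum()),
        "n_diagnoses_removed": int((~allowed).sum()),
        "removed_by_source": {
            f"{s}/{p}": int(n) for (s, p), n in removed_by_reason.items()
        },
    }
    return long.loc[allowed].copy(), report


# ---------------------------------------------------------------------------
# enrollee-year assembly
# ---------------------------------------------------------------------------

def _clean_series(
    raw: pd.Series,
    spec: OutcomeSpec,
    deflator: pd.Series,
    fraction: pd.Series,
    newborn: pd.Series,
) -> pd.Series:
    value = raw.astype(float)
    if spec.floor is not None:
        value = value.clip(lower=spec.floor)
    if spec.global_cap is not None:
        value = value.clip(upper=spec.global_cap)
    if spec.deflate:
        value = value * deflator
    annualize = ~newborn.astype(bool)
    value = value.where(~annualize, value / fraction)
    if spec.analysis_cap is not None:
        value = value.clip(upper=spec.analysis_cap)
    return value


def months_from_dates(start: pd.Series, end: pd.Series) -> pd.Series:
    """Whole calendar months spanned by [start, end] within one year."""
    start = pd.to_datetime(start)
    end = pd.to_datetime(end)
    if (end < start).any():
        raise ValueError("enrollment span with end date before start date")
    return (end.dt.month - start.dt.month + 1).astype(int)


def build_enrollee_years(
    enrollment: pd.DataFrame,
    claims: pd.DataFrame,
    specs: Iterable[OutcomeSpec],
    deflators: Mapping[int, float],
    filter_rules: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the enrollee-year analysis table.

    Returns ``(table, report)``. The table has one row per (person_id, year)
    with ``fraction_enrolled``, ``weight``, demographics, a ``diagnosis_set``
    tuple of distinct filtered codes, and one column per outcome spec.
    Person-years with zero enrolled months or age outside 0-64 are excluded
    and counted in the report. A missing deflator for an observed year is an
    error.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("at least one outcome spec is required")
    enrollment = enrollment.copy()
    if "months_enrolled" not in enrollment.columns:
        enrollment["months_enrolled"] = months_from_dates(
            enrollment["start_date"], enrollment["end_date"]
        )
    missing = [c for c in ENROLLMENT_COLUMNS if c not in enrollment.columns]
    if missing:
        raise ValueError(f"enrollment table missing columns {missing}")

    n_in = len(enrollment)
    zero_months = enrollment["months_enrolled"] <= 0
    bad_age = ~enrollment["age"].between(0, 64)
    keep = ~(zero_months | bad_age)
    enrollment = enrollment.loc[keep]

    years = set(enrollment["year"].unique()) | set(claims["year"].unique())
    missing_years = sorted(int(y) for y in years if y not in deflators)
    if missing_years:
        raise ValueError(f"no deflator for year(s) {missing_years}")

    index = pd.MultiIndex.from_frame(
        enrollment[["person_id", "year"]], names=["person_id", "year"]
    )
    table = pd.DataFrame(index=index)
    table["age"] = enrollment["age"].to_numpy()
    table["sex"] = enrollment["sex"].to_numpy()
    table["newborn"] = enrollment["newborn"].astype(bool).to_numpy()
    table["fraction_enrolled"] = (
        enrollment["months_enrolled"].to_numpy() / 12.0
    )
    table["weight"] = np.where(
        table["newborn"], 1.0, table["fraction_enrolled"]
    )

    deflator = pd.Series(
        [deflators[int(y)] for y in table.index.get_level_values("year")],
        index=table.index,
    )
    by_py = claims.groupby(["person_id", "year"])
    for spec in specs:
        if spec.kind == "payer":
            raw = by_py[spec.source].sum()
        elif spec.kind == "service":
            mask = claims["service_type"] == spec.source
            raw = claims.loc[mask].groupby(["person_id", "year"])["paid_plan"].sum()
        else:
            if spec.source not in claims.columns:
                raise ValueError(f"claims table lacks count column {spec.source!r}")
            raw = by_py[spec.source].sum()
        raw = raw.reindex(table.index, fill_value=0.0)
        table[spec.name] = _clean_series(
            raw, spec, deflator, table["fraction_enrolled"], table["newborn"]
        )

    rules = ALLOW_ALL_RULES if filter_rules is None else filter_rules
    diagnoses, filter_report = filter_diagnoses(claims, rules)
    code_sets = (
        diagnoses.groupby(["person_id", "year"])["code"]
        .agg(lambda codes: tuple(sorted(set(codes))))
        .reindex(table.index)
    )
    table["diagnosis_set"] = [
        cs if isinstance(cs, tuple) else () for cs in code_sets
    ]

    report = {
        "n_person_years_in": int(n_in),
        "n_person_years_kept": int(len(table)),
        "n_excluded_zero_months": int(zero_months.sum()),
        "n_excluded_age": int((bad_age & ~zero_months).sum()),
        "diagnosis_filter": filter_report,
    }
    return table, report


def split_sample(
    table: pd.DataFrame,
    validation_share: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split enrollee-years into development and validation samples by person.

    Every year of a person lands on the same side. Each person is assigned
    independently with probability ``validation_share``, so the realized
    share fluctuates binomially; the split is deterministic under ``seed``.
    """
    if not 0.0 < validation_share < 1.0:
        raise ValueError("validation_share must lie strictly between 0 and 1")
    persons = np.asarray(
        sorted(table.index.get_level_values("person_id").unique())
    )
    rng = np.random.default_rng(seed)
    in_validation = rng.random(len(persons)) < validation_share
    validation_persons = set(persons[in_validation])
    mask = np.fromiter(
        (p in validation_persons for p in table.index.get_level_values("person_id")),
        dtype=bool,
        count=len(table),
    )
    return table.loc[~mask].copy(), table.loc[mask].copy()
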