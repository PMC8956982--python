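"""Seeded synthetic claims generator with known ground truth.

Emulates the statistical structure the risk-adjustment framework assumes,
not any real population:

* a diagnosis-frequency spectrum log-uniform between roughly 1 per million
  and 1 in 10 enrollee-years, so the powers-of-10 frequency bins of the
  rare-disease residual analysis are populated;
* a multi-membership ``dxi`` mapping in which common codes get narrow
  items (optionally overlapped by broad items), and rare codes are pooled
  into rare-disease items large enough to estimate — the design feature
  the framework exists to exploit;
* comparator mappings on the same code universe: a flat ``ccsr_like``
  system whose categories mix the frequency spectrum (so rare-code effects
  are diluted away), and a coarser ``hcc_like`` system that covers only
  common codes and carries a severity hierarchy chain;
* spending from a known linear model: an age-sex base plus the sum of
  item effects, additive mean-zero heavy-tailed (lognormal-shaped) noise,
  a small share of injected negative totals (exercising the $0 floor) and
  of catastrophic episodes above the analysis top-code;
* partial-year enrollment with fraction-of-year exposure, newborns whose
  birth-episode spending is not exposure-scaled, and claim lines carrying
  settings/professional types so the diagnosis filter is exercised.

Spending truth is driven by the diagnoses surviving the default
acceptable-source filter, so a pipeline run with the default rules can
recover the generating coefficients exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import ALLOW_ALL_RULES
from .mapping import (
    Assignment,
    DxiItem,
    MappingTable,
    write_hierarchy,
    write_mapping,
)
from .chapters import CROSS_CUTTING, chapter_of

_DISEASE_LETTERS = "ACEFGIJKLMNQRS"


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults are the package's reference
    study conditions (see docs/methods.md)."""

    seed: int = 0
    n_persons: int = 100_000
    years: tuple[int, ...] = (2018,)
    # code universe and mapping structure
    n_codes: int = 2000
    n_main_items: int = 300          # narrow + rare-pool + broad dxi items
    broad_item_share: float = 0.10   # of n_main_items
    rare_item_share: float = 0.30
    overlap_rate: float = 0.30       # share of common codes that also get a broad item
    n_modifier_codes: int = 20
    freq_min_per_million: float = 1.0
    freq_max_per_million: float = 100_000.0
    rare_threshold_per_million: float = 100.0
    n_ccsr: int = 40
    n_hcc: int = 12
    hcc_coverage: float = 0.30       # top share of codes the hcc_like system maps
    # enrollment
    newborn_rate: float = 0.01
    full_year_share: float = 0.70
    # spending model
    base_intercept: float = 1000.0
    base_age_slope: float = 30.0
    base_female_20_44: float = 500.0
    newborn_base: float = 5000.0
    beta_common_median: float = 800.0
    beta_common_sigma: float = 1.0
    beta_rare_median: float = 8000.0
    beta_rare_sigma: float = 0.75
    beta_broad_median: float = 300.0
    beta_broad_sigma: float = 0.5
    noise_family: str = "lognormal"  # lognormal | gamma
    noise_scale: float = 1000.0      # left bound of the additive noise
    noise_sigma: float = 1.0
    negative_adjustment_rate: float = 0.002
    extreme_rate: float = 0.01
    extreme_base: float = 250_000.0
    extreme_median: float = 120_000.0
    extreme_sigma: float = 0.5
    # claims plumbing
    unacceptable_share: float = 0.05  # diagnosis lines from disallowed sources
    duplicate_rate: float = 0.10      # re-coded (duplicate) diagnosis lines
    oop_share: float = 0.15

    def __post_init__(self) -> None:
        rates = {
            "overlap_rate": self.overlap_rate,
            "newborn_rate": self.newborn_rate,
            "full_year_share": self.full_year_share,
            "negative_adjustment_rate": self.negative_adjustment_rate,
            "extreme_rate": self.extreme_rate,
            "unacceptable_share": self.unacceptable_share,
            "duplicate_rate": self.duplicate_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_main_items > self.n_codes:
            raise ValueError("n_main_items must not exceed n_codes")
        if self.freq_min_per_million >= self.freq_max_per_million:
            raise ValueError("frequency range must be increasing")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What the generator knows that an analyst would estimate."""

    true_beta: dict[str, float]
    code_freq_per_million: dict[str, float]
    base_params: dict[str, float]
    config: SimConfig

    def base_rate(
        self, age: np.ndarray, sex: np.ndarray, newborn: np.ndarray
    ) -> np.ndarray:
        cfg = self.config
        age = np.asarray(age, dtype=float)
        female = np.asarray(sex) == "F"
        base = cfg.base_intercept + cfg.base_age_slope * age
        base = base + np.where(female & (age >= 20) & (age < 45),
                               cfg.base_female_20_44, 0.0)
        return np.where(np.asarray(newborn, dtype=bool), cfg.newborn_base, base)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "true_beta": self.true_beta,
            "code_freq_per_million": self.code_freq_per_million,
            "base_params": self.base_params,
            "config": dataclasses.asdict(self.config),
        }
        payload["config"]["years"] = list(self.config.years)
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


@dataclass
class SyntheticMaps:
    """The three comparator mapping tables plus generation metadata."""

    tables: dict[str, MappingTable]
    code_freq_per_million: dict[str, float]
    true_beta: dict[str, float]
    rare_codes: set[str] = field(default_factory=set)
    default_filter_rules: pd.DataFrame = field(
        default_factory=lambda: ALLOW_ALL_RULES.copy()
    )


@dataclass
class SimulatedData:
    maps: SyntheticMaps
    enrollment: pd.DataFrame
    claims: pd.DataFrame
    ground_truth: GroundTruth


# Acceptable (setting, professional_type) pairs used both to label the
# generated claim lines and as the default filter-rule table.
DEFAULT_FILTER_RULES = pd.DataFrame(
    [
        {"setting": "inpatient", "professional_type": "*"},
        {"setting": "outpatient", "professional_type": "*"},
        {"setting": "professional", "professional_type": "MD"},
        {"setting": "professional", "professional_type": "NP"},
    ]
)

_SERVICE_TYPES = np.array(
    ["ip_facility_rx", "op_facility_rx", "retail_rx", "lab", "imaging",
     "preventive", "other"]
)
_SERVICE_P = np.array([0.02, 0.08, 0.25, 0.25, 0.15, 0.15, 0.10])


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# mapping generation
# ---------------------------------------------------------------------------

def gen_mapping(config: SimConfig) -> SyntheticMaps:
    """Build the dxi / ccsr_like / hcc_like tables over one code universe."""
    rng = _rng(config, 1)
    n = config.n_codes
    letters = _DISEASE_LETTERS
    # numeric part starts at 010 so every code lands inside its letter's
    # chapter range (e.g. the F chapter begins at F01)
    codes = [
        f"{letters[i % len(letters)]}{i // len(letters) + 10:03d}" for i in range(n)
    ]
    # log-uniform frequency spectrum, assigned in descending order
    lo, hi = np.log10(config.freq_min_per_million), np.log10(config.freq_max_per_million)
    freqs = np.sort(10 ** rng.uniform(lo, hi, size=n))[::-1]
    freq_pm = {c: float(f) for c, f in zip(codes, freqs)}

    n_broad = max(1, round(config.broad_item_share * config.n_main_items))
    n_rare = max(1, round(config.rare_item_share * config.n_main_items))
    n_narrow = max(1, config.n_main_items - n_broad - n_rare)

    common = [c for c in codes if freq_pm[c] >= config.rare_threshold_per_million]
    rare = [c for c in codes if freq_pm[c] < config.rare_threshold_per_million]

    items: dict[str, DxiItem] = {}
    entries: dict[str, list[str]] = {c: [] for c in codes}

    def add_item(item_id: str, chapter: str, label: str) -> None:
        items[item_id] = DxiItem(item_id, "main", label, chapter)

    # narrow items: contiguous frequency-ordered blocks of common codes
    block = max(1, -(-len(common) // n_narrow))
    narrow_ids = []
    for j in range(0, len(common), block):
        item_id = f"NARROW_{j // block:03d}"
        members = common[j: j + block]
        add_item(item_id, chapter_of(members[0]), f"narrow cluster {j // block}")
        narrow_ids.append(item_id)
        for c in members:
            entries[c].append(item_id)
    # rare-pool items: rare codes grouped widely enough to be estimable
    block = max(1, -(-len(rare) // n_rare))
    rare_ids = []
    for j in range(0, len(rare), block):
        item_id = f"RARE_{j // block:03d}"
        members = rare[j: j + block]
        add_item(item_id, chapter_of(members[0]), f"rare-disease pool {j // block}")
        rare_ids.append(item_id)
        for c in members:
            entries[c].append(item_id)
    # broad items: supersets spanning several narrow clusters; a common code
    # carries its broad item with probability overlap_rate
    broad_ids = []
    span = max(1, -(-len(narrow_ids) // n_broad))
    narrow_to_broad = {}
    for j, item_id in enumerate(narrow_ids):
        broad = f"BROAD_{j // span:03d}"
        if broad not in items:
            add_item(broad, items[item_id].chapter, f"broad cluster {j // span}")
            broad_ids.append(broad)
        narrow_to_broad[item_id] = broad
    overlap_draw = rng.random(len(common))
    for i, c in enumerate(common):
        if overlap_draw[i] < config.overlap_rate:
            entries[c].append(narrow_to_broad[entries[c][0]])

    # modifier-only Z codes and a BMI scale block
    modifier_codes = [f"Z5{i:02d}" for i in range(config.n_modifier_codes)]
    items["MOD_SURV"] = DxiItem("MOD_SURV", "modifier", "surveillance flag",
                                CROSS_CUTTING)
    items["MOD_SEV"] = DxiItem("MOD_SEV", "modifier", "severity flag",
                               CROSS_CUTTING)
    bmi_bands = [19.0, 22.0, 27.0, 32.0, 37.0, 42.0, 50.0, 60.0]
    bmi_codes = [f"Z68{i:01d}" for i in range(len(bmi_bands))]
    items["BMI"] = DxiItem("BMI", "scale", "body mass index band", CROSS_CUTTING)
    for c in modifier_codes + bmi_codes:
        freq_pm[c] = float(10 ** rng.uniform(2.0, 3.5))

    # true effects (main items only; modifiers/scales carry no spending truth)
    beta: dict[str, float] = {}
    for item_id in narrow_ids:
        beta[item_id] = float(rng.lognormal(np.log(config.beta_common_median),
                                            config.beta_common_sigma))
    for item_id in rare_ids:
        beta[item_id] = float(rng.lognormal(np.log(config.beta_rare_median),
                                            config.beta_rare_sigma))
    for item_id in broad_ids:
        beta[item_id] = float(rng.lognormal(np.log(config.beta_broad_median),
                                            config.beta_broad_sigma))

    dxi_entries = {
        c: Assignment(main_items=tuple(entries[c])) for c in codes
    }
    for c in modifier_codes:
        half = config.n_modifier_codes // 2
        mod = "MOD_SURV" if int(c[2:]) < half else "MOD_SEV"
        dxi_entries[c] = Assignment(modifier_items=(mod,))
    for c, band in zip(bmi_codes, bmi_bands):
        dxi_entries[c] = Assignment(scale_values=(("BMI", band),))
    dxi = MappingTable(
        system_name="dxi", items=items, entries=dxi_entries,
        scale_ranges={"BMI": (18.5, 70.0)},
    )

    all_codes = codes + modifier_codes + bmi_codes
    ranked = sorted(all_codes, key=lambda c: (-freq_pm[c], c))

    # flat comparator: one category per code, categories striped across the
    # frequency spectrum so each mixes common-cheap with rare-expensive codes
    ccsr_items = {
        f"CCSR_{k:03d}": DxiItem(f"CCSR_{k:03d}", "main", f"flat category {k}",
                                 CROSS_CUTTING)
        for k in range(config.n_ccsr)
    }
    ccsr = MappingTable(
        system_name="ccsr_like",
        items=ccsr_items,
        entries={
            c: Assignment(main_items=(f"CCSR_{i % config.n_ccsr:03d}",))
            for i, c in enumerate(ranked)
        },
    )

    # hierarchical comparator: covers only the common top of the spectrum,
    # with a three-level severity chain on dedicated categories
    n_cov = int(config.hcc_coverage * len(ranked))
    hcc_items = {
        f"HCC_{k:02d}": DxiItem(f"HCC_{k:02d}", "main", f"condition category {k}",
                                CROSS_CUTTING)
        for k in range(config.n_hcc)
    }
    for sev in (1, 2, 3):
        hcc_items[f"HCC_SEV{sev}"] = DxiItem(
            f"HCC_SEV{sev}", "main", f"severity tier {sev}", CROSS_CUTTING
        )
    hcc_entries: dict[str, Assignment] = {}
    for i, c in enumerate(ranked[:n_cov]):
        mains = [f"HCC_{i % config.n_hcc:02d}"]
        if i in (10, 11, 12):
            mains.append(f"HCC_SEV{i - 9}")
        hcc_entries[c] = Assignment(main_items=tuple(mains))
    hcc = MappingTable(
        system_name="hcc_like",
        items=hcc_items,
        entries=hcc_entries,
        hierarchy_rules=[("HCC_SEV3", "HCC_SEV2"), ("HCC_SEV2", "HCC_SEV1")],
    )
    for table in (dxi, ccsr, hcc):
        table.validate()

    return SyntheticMaps(
        tables={"dxi": dxi, "ccsr_like": ccsr, "hcc_like": hcc},
        code_freq_per_million=freq_pm,
        true_beta=beta,
        rare_codes=set(rare),
        default_filter_rules=DEFAULT_FILTER_RULES.copy(),
    )


# ---------------------------------------------------------------------------
# population, claims, spending
# ---------------------------------------------------------------------------

def gen_population(config: SimConfig) -> pd.DataFrame:
    """Enrollment spans: ages 0-64, partial-year fractions, newborn flags.

    Person attributes are drawn once; a person contributes one record per
    calendar year with age advancing (years past 64 drop out) and is a
    newborn only in the first year.
    """
    rng = _rng(config, 2)
    n = config.n_persons
    person_id = np.arange(n)
    newborn = rng.random(n) < config.newborn_rate
    age0 = rng.integers(0, 65, size=n)
    age0[newborn] = 0
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    rows = []
    for offset, year in enumerate(sorted(config.years)):
        age = age0 + offset
        keep = age <= 64
        months = np.where(
            rng.random(n) < config.full_year_share,
            12,
            rng.integers(1, 12, size=n),
        )
        is_newborn = newborn & (offset == 0)
        months[is_newborn] = rng.integers(1, 13, size=int(is_newborn.sum()))
        rows.append(
            pd.DataFrame(
                {
                    "person_id": person_id[keep],
                    "year": year,
                    "months_enrolled": months[keep],
                    "age": age[keep],
                    "sex": sex[keep],
                    "newborn": is_newborn[keep],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def gen_diagnosis_pairs(
    config: SimConfig, maps: SyntheticMaps, enrollment: pd.DataFrame
) -> pd.DataFrame:
    """(person_id, year, code) draws following the per-code frequencies,
    thinned by each person's enrolled fraction of the year."""
    rng = _rng(config, 3)
    out_person: list[np.ndarray] = []
    out_year: list[np.ndarray] = []
    out_code: list[np.ndarray] = []
    for year, group in enrollment.groupby("year"):
        persons = group["person_id"].to_numpy()
        fraction = (group["months_enrolled"].to_numpy() / 12.0)
        n = len(persons)
        for code in sorted(maps.code_freq_per_million):
            p = maps.code_freq_per_million[code] / 1e6
            k = rng.binomial(n, min(p, 1.0))
            if k == 0:
                continue
            sel = rng.choice(n, size=k, replace=False)
            keep = rng.random(k) < fraction[sel]
            sel = sel[keep]
            if len(sel) == 0:
                continue
            out_person.append(persons[sel])
            out_year.append(np.full(len(sel), year))
            out_code.append(np.full(len(sel), code))
    if not out_person:
        return pd.DataFrame(columns=["person_id", "year", "code"])
    pairs = pd.DataFrame(
        {
            "person_id": np.concatenate(out_person),
            "year": np.concatenate(out_year),
            "code": np.concatenate(out_code),
        }
    )
    return pairs.sort_values(["person_id", "year", "code"], ignore_index=True)


def _noise(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Additive mean-zero noise bounded below by -noise_scale, heavy right
    tail; homoscedastic in annualized terms."""
    s = config.noise_scale
    if config.noise_family == "lognormal":
        draw = rng.lognormal(0.0, config.noise_sigma, size=n)
        return s * (draw / np.exp(config.noise_sigma**2 / 2.0) - 1.0)
    if config.noise_family == "gamma":
        shape = 1.0 / max(config.noise_sigma, 1e-6) ** 2
        return s * (rng.gamma(shape, 1.0 / shape, size=n) - 1.0)
    raise ValueError(f"unknown noise family {config.noise_family!r}")


def gen_spending(
    config: SimConfig,
    maps: SyntheticMaps,
    enrollment: pd.DataFrame,
    pairs: pd.DataFrame,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Observed person-year totals from the known linear model.

    The annualized rate is base(age, sex) + sum of true item effects over
    the person-year's distinct dxi main items, plus additive noise and an
    optional catastrophic episode; the observed (raw) total is the rate
    times the enrolled fraction for non-newborns, or the full episode for
    newborns. A small share of person-years is overwritten with a negative
    adjustment total.
    """
    rng = _rng(config, 4)
    truth = GroundTruth(
        true_beta=maps.true_beta,
        code_freq_per_million=maps.code_freq_per_million,
        base_params={
            "intercept": config.base_intercept,
            "age_slope": config.base_age_slope,
            "female_20_44": config.base_female_20_44,
            "newborn_base": config.newborn_base,
        },
        config=config,
    )
    dxi = maps.tables["dxi"]
    code_items = {
        code: entry.main_items for code, entry in dxi.entries.items()
    }
    if len(pairs):
        exploded = pairs.assign(
            item=pairs["code"].map(lambda c: list(code_items.get(c, ())))
        ).explode("item")
        exploded = exploded.dropna(subset=["item"]).drop_duplicates(
            ["person_id", "year", "item"]
        )
        exploded["beta"] = exploded["item"].map(maps.true_beta)
        item_sum = exploded.groupby(["person_id", "year"])["beta"].sum()
    else:
        item_sum = pd.Series(dtype=float)

    key = pd.MultiIndex.from_frame(enrollment[["person_id", "year"]])
    base = truth.base_rate(
        enrollment["age"], enrollment["sex"], enrollment["newborn"]
    )
    rate = base + item_sum.reindex(key, fill_value=0.0).to_numpy()
    n = len(enrollment)
    annual = rate + _noise(config, rng, n)
    extreme = rng.random(n) < config.extreme_rate
    annual = annual + np.where(
        extreme,
        config.extreme_base
        + rng.lognormal(np.log(config.extreme_median), config.extreme_sigma, n),
        0.0,
    )
    fraction = enrollment["months_enrolled"].to_numpy() / 12.0
    newborn = enrollment["newborn"].to_numpy(dtype=bool)
    observed = np.where(newborn, annual, annual * fraction)
    negative = rng.random(n) < config.negative_adjustment_rate
    observed = np.where(negative, -rng.uniform(10.0, 500.0, size=n), observed)

    totals = enrollment[["person_id", "year"]].copy()
    totals["paid_total"] = observed
    totals["n_items"] = (
        exploded.groupby(["person_id", "year"]).size().reindex(key, fill_value=0).to_numpy()
        if len(pairs) else 0
    )
    return totals, truth


def gen_claims(
    config: SimConfig,
    maps: SyntheticMaps,
    enrollment: pd.DataFrame,
    pairs: pd.DataFrame,
    totals: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble claim lines: diagnosis lines with source labels (a share of
    them from disallowed sources) plus one summary line per person-year
    carrying the residual payment and utilization counts."""
    rng = _rng(config, 5)
    n_pairs = len(pairs)
    # duplicate a share of diagnosis lines to exercise set semantics
    if n_pairs:
        dup = rng.random(n_pairs) < config.duplicate_rate
        pairs = pd.concat([pairs, pairs.loc[dup]], ignore_index=True)
        n_pairs = len(pairs)
        disallowed = rng.random(n_pairs) < config.unacceptable_share
        setting = np.where(
            disallowed,
            np.where(rng.random(n_pairs) < 0.5, "other", "professional"),
            rng.choice(
                ["inpatient", "outpatient", "professional"],
                p=[0.10, 0.35, 0.55], size=n_pairs,
            ),
        )
        ptype = np.where(
            setting == "professional",
            np.where(disallowed, "XX", np.where(rng.random(n_pairs) < 0.8, "MD", "NP")),
            "FACILITY",
        )
        diag_lines = pairs.copy()
        diag_lines["setting"] = setting
        diag_lines["professional_type"] = ptype
        diag_lines["service_type"] = rng.choice(
            _SERVICE_TYPES, p=_SERVICE_P, size=n_pairs
        )
        diag_lines["diagnosis_codes"] = diag_lines.pop("code")
        diag_lines["acceptable"] = ~disallowed
    else:
        diag_lines = pd.DataFrame(
            columns=["person_id", "year", "setting", "professional_type",
                     "service_type", "diagnosis_codes", "acceptable"]
        )

    key = ["person_id", "year"]
    n_lines = (
        diag_lines.groupby(key).size() if n_pairs else pd.Series(dtype=int)
    )
    summary = totals.merge(
        enrollment[key + ["months_enrolled"]], on=key, how="left"
    )
    summary["n_lines"] = (
        n_lines.reindex(pd.MultiIndex.from_frame(summary[key]), fill_value=0).to_numpy()
    )
    fraction = summary["months_enrolled"] / 12.0
    n_diag = summary["n_lines"].to_numpy()
    summary["admissions"] = rng.poisson(fraction * (0.02 + 0.01 * n_diag))
    summary["ip_days"] = summary["admissions"] * (
        1 + rng.poisson(3.0, size=len(summary))
    )
    summary["ed_visits"] = rng.poisson(fraction * (0.08 + 0.02 * n_diag))

    # split each person-year's total equally across its lines + summary line
    share = summary["paid_total"] / (summary["n_lines"] + 1)
    share_map = dict(
        zip(zip(summary["person_id"], summary["year"]), share)
    )
    if n_pairs:
        diag_lines["paid_total"] = [
            share_map[k] for k in zip(diag_lines["person_id"], diag_lines["year"])
        ]
    summary_lines = summary[key + ["admissions", "ip_days", "ed_visits"]].copy()
    summary_lines["setting"] = "professional"
    summary_lines["professional_type"] = "MD"
    summary_lines["service_type"] = "other"
    summary_lines["diagnosis_codes"] = ""
    summary_lines["paid_total"] = share.to_numpy()

    claims = pd.concat(
        [diag_lines.drop(columns=["acceptable"], errors="ignore"), summary_lines],
        ignore_index=True,
    )
    for col in ("admissions", "ip_days", "ed_visits"):
        claims[col] = claims[col].fillna(0).astype(int)
    claims["paid_plan"] = claims["paid_total"] * (1.0 - config.oop_share)
    claims["paid_oop"] = claims["paid_total"] * config.oop_share
    return claims.sort_values(key, ignore_index=True, kind="stable")


def simulate(config: Optional[SimConfig] = None) -> SimulatedData:
    """One-shot generation of mappings, enrollment, claims and ground truth.

    Spending truth uses the diagnoses that survive the default
    acceptable-source rules, so building the cohort with
    ``maps.default_filter_rules`` recovers the generating model.
    """
    config = config or SimConfig()
    maps = gen_mapping(config)
    enrollment = gen_population(config)
    pairs = gen_diagnosis_pairs(config, maps, enrollment)
    # label lines first so truth can be computed on acceptable diagnoses
    placeholder = enrollment[["person_id", "year"]].copy()
    placeholder["paid_total"] = 0.0
    claims = gen_claims(config, maps, enrollment, pairs, placeholder)
    kept = _acceptable_pairs(claims)
    totals, truth = gen_spending(config, maps, enrollment, kept)
    claims = _attach_payments(config, claims, totals)
    return SimulatedData(
        maps=maps, enrollment=enrollment, claims=claims, ground_truth=truth
    )


def _acceptable_pairs(claims: pd.DataFrame) -> pd.DataFrame:
    mask = claims["diagnosis_codes"].astype(str) != ""
    diag = claims.loc[mask]
    allowed = np.zeros(len(diag), dtype=bool)
    for _, rule in DEFAULT_FILTER_RULES.iterrows():
        hit = np.ones(len(diag), dtype=bool)
        if rule["setting"] != "*":
            hit &= (diag["setting"] == rule["setting"]).to_numpy()
        if rule["professional_type"] != "*":
            hit &= (diag["professional_type"] == rule["professional_type"]).to_numpy()
        allowed |= hit
    kept = diag.loc[allowed, ["person_id", "year", "diagnosis_codes"]].rename(
        columns={"diagnosis_codes": "code"}
    )
    return kept.drop_duplicates(ignore_index=True)


def _attach_payments(
    config: SimConfig, claims: pd.DataFrame, totals: pd.DataFrame
) -> pd.DataFrame:
    key = ["person_id", "year"]
    n_lines = claims.groupby(key).size()
    merged = totals.set_index(key)
    idx = pd.MultiIndex.from_frame(claims[key])
    per_line = (
        merged["paid_total"].reindex(idx).to_numpy()
        / n_lines.reindex(idx).to_numpy()
    )
    claims = claims.copy()
    claims["paid_total"] = per_line
    claims["paid_plan"] = per_line * (1.0 - config.oop_share)
    claims["paid_oop"] = per_line * config.oop_share
    return claims


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(data: SimulatedData, out_dir: str | Path) -> dict[str, Path]:
    """Write the CSV/TSV artifacts a pipeline run consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "enrollment": out / "enrollment.csv",
        "claims": out / "claims.csv",
        "ground_truth": out / "ground_truth.json",
        "filter_rules": out / "filter_rules.tsv",
    }
    data.enrollment.to_csv(paths["enrollment"], index=False)
    data.claims.to_csv(paths["claims"], index=False)
    data.ground_truth.to_json(paths["ground_truth"])
    data.maps.default_filter_rules.to_csv(
        paths["filter_rules"], sep="\t", index=False
    )
    for name, table in data.maps.tables.items():
        path = out / f"mapping_{name}.tsv"
        write_mapping(table, path)
        paths[f"mapping_{name}"] = path
        if table.hierarchy_rules:
            hpath = out / f"hierarchy_{name}.tsv"
            write_hierarchy(table.hierarchy_rules, hpath)
            paths[f"hierarchy_{name}"] = hpath
    return paths
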