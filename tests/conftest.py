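"""Shared fixtures: a hand-built toy mapping, tiny claims data, and
session-scoped synthetic datasets reused by the heavier tests."""

import numpy as np
import pandas as pd
import pytest

from dxikit.cohort import build_enrollee_years, default_outcome_specs
from dxikit.mapping import load_mapping
from dxikit.synth import SimConfig, simulate

# Broad+narrow overlap on one code (STEMI alongside the broader acute-MI
# item), a modifier-only Z code, a nonbillable root stem (A12), and BMI
# scale bands: the corner cases the grouper must handle.
TOY_MAPPING_TSV = """\
code\titem_id\tkind\tscale_value\tlabel\tchapter
I214\tSTEMI_main\tmain\t\tST-elevation MI\tCIR
I214\tAMI_broad_main\tmain\t\tacute MI (broad)\tCIR
I214\tMOD_ACUTE\tmodifier\t\tacute severity\t
I2101\tSTEMI_main\tmain\t\tST-elevation MI\tCIR
A12\tTB_main\tmain\t\ttuberculosis cluster\tINF
Z590\tHOUSING_mod\tmodifier\t\thousing instability\t
Z6832\tBMI\tscale\t32\tBMI band 32\t
Z6841\tBMI\tscale\t41\tBMI band 41\t
B001\tHERPES_main\tmain\t\therpes cluster\tINF
"""

TOY_HCC_TSV = """\
code\titem_id\tkind\tscale_value\tlabel\tchapter
C100\tsev3\tmain\t\tseverity 3\tNEO
C101\tsev2\tmain\t\tseverity 2\tNEO
C102\tsev1\tmain\t\tseverity 1\tNEO
"""

TOY_HIERARCHY_TSV = """\
dominant_item\tsuppressed_item
sev3\tsev2
sev2\tsev1
"""


@pytest.fixture()
def toy_mapping_path(tmp_path):
    path = tmp_path / "toy_mapping.tsv"
    path.write_text(TOY_MAPPING_TSV, encoding="utf-8")
    return path


@pytest.fixture()
def toy_mapping(toy_mapping_path):
    return load_mapping(toy_mapping_path, system_name="dxi")


@pytest.fixture()
def toy_hcc(tmp_path):
    mpath = tmp_path / "toy_hcc.tsv"
    hpath = tmp_path / "toy_hierarchy.tsv"
    mpath.write_text(TOY_HCC_TSV, encoding="utf-8")
    hpath.write_text(TOY_HIERARCHY_TSV, encoding="utf-8")
    return load_mapping(mpath, system_name="hcc_like", hierarchy_path=hpath)


@pytest.fixture()
def tiny_claims():
    """Ten diagnoses, three of them on lines from disallowed sources."""
    rows = []
    for i, (setting, ptype, code) in enumerate(
        [
            ("professional", "MD", "I214"),
            ("professional", "MD", "B001"),
            ("inpatient", "FACILITY", "I2101"),
            ("outpatient", "FACILITY", "A1201"),
            ("professional", "NP", "Z590"),
            ("professional", "MD", "Z6832"),
            ("outpatient", "FACILITY", "I214"),
            ("other", "XX", "B001"),          # disallowed
            ("professional", "XX", "I214"),   # disallowed
            ("weird", "MD", "A1201"),         # unknown setting -> other
        ]
    ):
        rows.append(
            {
                "person_id": i % 3,
                "year": 2018,
                "setting": setting,
                "professional_type": ptype,
                "service_type": "other",
                "diagnosis_codes": code,
                "paid_total": 100.0,
                "paid_plan": 85.0,
                "paid_oop": 15.0,
                "admissions": 0,
                "ip_days": 0,
                "ed_visits": 0,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_rules():
    return pd.DataFrame(
        [
            {"setting": "professional", "professional_type": "MD"},
            {"setting": "professional", "professional_type": "NP"},
            {"setting": "inpatient", "professional_type": "*"},
            {"setting": "outpatient", "professional_type": "*"},
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """A quick default-structure dataset for structural tests."""
    return simulate(SimConfig(n_persons=3000, seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    table, report = build_enrollee_years(
        small_sim.enrollment,
        small_sim.claims,
        default_outcome_specs(),
        {2018: 1.0},
        filter_rules=small_sim.maps.default_filter_rules,
    )
    return table, report


@pytest.fixture(scope="session")
def study_sim():
    """The reference study conditions: 100,000 person-years at defaults."""
    return simulate(SimConfig(n_persons=100_000, seed=20180101 % (2**31)))


@pytest.fixture(scope="session")
def study_cohort(study_sim):
    table, _ = build_enrollee_years(
        study_sim.enrollment,
        study_sim.claims,
        default_outcome_specs(),
        {2018: 1.0},
        filter_rules=study_sim.maps.default_filter_rules,
    )
    return table
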