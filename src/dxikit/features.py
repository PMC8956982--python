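"""Sparse design matrices for concurrent risk-adjustment models.

A model is specified by an ordered list of classification systems whose
indicators enter alongside the always-present age-sex block:

* ``age_sex`` — cell-means coding of age band x sex (every cell, no
  intercept), so a diagnostically empty enrollee-year is predicted by its
  demographic cell mean and negative predictions can only arise from the
  net effect of diagnostic coefficients;
* one binary column per main-effect item of each mapping system, set when
  any diagnosis in the year maps to the item (after dominance hierarchies
  for ``hcc_like`` systems);
* optionally, modifier indicators and numeric scale columns (yearly maximum
  of the observed scale values, with a companion observed-flag column).

Columns with zero prevalence in the development sample are pruned at fit
time and logged; transform always emits the fitted column set.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .mapping import MappingTable

#: Age-band lower edges: infants, 1-4, then 5-year bands through 60-64.
DEFAULT_AGE_BAND_EDGES: tuple[int, ...] = (0, 1, *range(5, 61, 5))
AGE_SEX_SYSTEM = "age_sex"
AGE_MAX = 64


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome is predicted and which systems supply indicators."""

    outcome: str
    systems: tuple[str, ...] = (AGE_SEX_SYSTEM,)
    include_modifiers: bool = False
    include_scales: bool = False
    age_band_edges: tuple[int, ...] = DEFAULT_AGE_BAND_EDGES

    def __post_init__(self) -> None:
        if AGE_SEX_SYSTEM not in self.systems:
            object.__setattr__(self, "systems", (AGE_SEX_SYSTEM, *self.systems))

    @property
    def mapping_systems(self) -> tuple[str, ...]:
        return tuple(s for s in self.systems if s != AGE_SEX_SYSTEM)


@dataclass
class FeatureMatrix:
    """A named sparse design matrix aligned with weights and an outcome."""

    X: sp.csr_matrix
    columns: list[str]
    index: pd.MultiIndex
    y: Optional[np.ndarray] = None
    w: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column names")
        for vec, name in ((self.y, "y"), (self.w, "w")):
            if vec is not None and len(vec) != self.X.shape[0]:
                raise ValueError(f"{name} is not aligned with the matrix rows")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def column_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.columns)}
        missing = [c for c in names if c not in lookup]
        if missing:
            raise KeyError(f"columns not in matrix: {missing[:5]}")
        return np.array([lookup[c] for c in names], dtype=np.intp)

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = self.column_index(names)
        return FeatureMatrix(
            X=self.X[:, idx].tocsr(), columns=list(names),
            index=self.index, y=self.y, w=self.w,
        )


def age_sex_cells(
    age: np.ndarray,
    sex: np.ndarray,
    band_edges: Sequence[int] = DEFAULT_AGE_BAND_EDGES,
) -> tuple[np.ndarray, list[str]]:
    """Map each (age, sex) to its demographic cell.

    Returns (cell index per row, cell labels). Cells partition the
    population: exactly one is active per enrollee-year. Ages outside
    [0, 64] are an error.
    """
    age = np.asarray(age)
    if len(age) and (age.min() < 0 or age.max() > AGE_MAX):
        raise ValueError(f"age outside [0, {AGE_MAX}]")
    edges = sorted(set(band_edges))
    if edges[0] != 0:
        raise ValueError("age bands must start at 0")
    uppers = edges[1:] + [AGE_MAX + 1]
    labels = []
    for sex_code in ("F", "M"):
        for lo, hi in zip(edges, uppers):
            labels.append(f"{AGE_SEX_SYSTEM}:{sex_code}_{lo:02d}-{hi - 1:02d}")
    band = np.searchsorted(edges, age, side="right") - 1
    sex = np.asarray(sex)
    is_male = (sex == "M") | (sex == "m")
    is_female = (sex == "F") | (sex == "f")
    if len(sex) and not np.all(is_male | is_female):
        bad = sex[~(is_male | is_female)][:3]
        raise ValueError(f"sex must be F or M, got {bad!r}")
    cell = band + is_male.astype(int) * len(edges)
    return cell.astype(np.intp), labels


class DesignMatrixBuilder(BaseEstimator, TransformerMixin):
    """Fit/transform encoder from enrollee-year tables to design matrices.

    Parameters
    ----------
    mappings:
        mapping-name -> :class:`~dxikit.mapping.MappingTable`; every name in
        ``spec.systems`` other than ``age_sex`` must be present.
    spec:
        the :class:`ModelSpec` controlling which blocks enter.

    Fitted attributes
    -----------------
    columns_ : the retained column names (development-sample pruning applied)
    pruned_columns_ : zero-prevalence columns dropped at fit time
    forced_columns_ : the age-sex block (always forced into stepwise fits)
    """

    def __init__(
        self,
        mappings: Optional[Mapping[str, MappingTable]] = None,
        spec: ModelSpec = ModelSpec(outcome="total"),
    ) -> None:
        self.mappings = mappings
        self.spec = spec

    # -- encoding helpers ----------------------------------------------

    def _system_tables(self) -> dict[str, MappingTable]:
        mappings = self.mappings or {}
        missing = [s for s in self.spec.mapping_systems if s not in mappings]
        if missing:
            raise ValueError(f"no mapping table supplied for system(s) {missing}")
        return {s: mappings[s] for s in self.spec.mapping_systems}

    def _encode_full(self, table: pd.DataFrame) -> FeatureMatrix:
        n = len(table)
        cell, agesex_labels = age_sex_cells(
            table["age"].to_numpy(),
            table["sex"].to_numpy(),
            self.spec.age_band_edges,
        )
        blocks: list[sp.csr_matrix] = [
            sp.csr_matrix(
                (np.ones(n), (np.arange(n), cell)), shape=(n, len(agesex_labels))
            )
        ]
        columns: list[str] = list(agesex_labels)

        diagnosis_sets = table["diagnosis_set"].to_list()
        for system, mapping in self._system_tables().items():
            block, names = _indicator_block(
                system, mapping, diagnosis_sets,
                include_modifiers=self.spec.include_modifiers,
            )
            blocks.append(block)
            columns.extend(names)
            if self.spec.include_scales and mapping.scale_item_ids:
                block, names = _scale_block(system, mapping, diagnosis_sets)
                blocks.append(block)
                columns.extend(names)

        X = sp.hstack(blocks, format="csr") if len(blocks) > 1 else blocks[0]
        y = (
            table[self.spec.outcome].to_numpy(dtype=float)
            if self.spec.outcome in table.columns else None
        )
        w = (
            table["weight"].to_numpy(dtype=float)
            if "weight" in table.columns else None
        )
        return FeatureMatrix(X=X, columns=columns, index=table.index, y=y, w=w)

    # -- sklearn API ----------------------------------------------------

    def fit(self, table: pd.DataFrame, y: None = None) -> "DesignMatrixBuilder":
        full = self._encode_full(table)
        prevalence = np.asarray((full.X != 0).sum(axis=0)).ravel()
        keep = prevalence > 0
        self.columns_ = [c for c, k in zip(full.columns, keep) if k]
        self.pruned_columns_ = [c for c, k in zip(full.columns, keep) if not k]
        self.forced_columns_ = [
            c for c in self.columns_ if c.startswith(f"{AGE_SEX_SYSTEM}:")
        ]
        self._fit_cache = full.select(self.columns_)
        self._fit_index = table.index
        return self

    def transform(self, table: pd.DataFrame) -> FeatureMatrix:
        if not hasattr(self, "columns_"):
            raise RuntimeError("DesignMatrixBuilder must be fitted before transform")
        cache = getattr(self, "_fit_cache", None)
        if cache is not None and table.index.equals(self._fit_index):
            return cache
        return self._encode_full(table).select(self.columns_)

    def fit_transform(self, table: pd.DataFrame, y: None = None) -> FeatureMatrix:
        return self.fit(table).transform(table)


def _indicator_block(
    system: str,
    mapping: MappingTable,
    diagnosis_sets: list[tuple[str, ...]],
    include_modifiers: bool,
) -> tuple[sp.csr_matrix, list[str]]:
    item_ids = list(mapping.main_item_ids)
    if include_modifiers:
        item_ids += mapping.modifier_item_ids
    col_of = {item: j for j, item in enumerate(item_ids)}
    assign_cache: dict[str, tuple[str, ...]] = {}

    rows: list[int] = []
    cols: list[int] = []
    for i, codes in enumerate(diagnosis_sets):
        items: set[str] = set()
        for code in codes:
            cached = assign_cache.get(code)
            if cached is None:
                entry = mapping.assign(code)
                cached = entry.main_items + (
                    entry.modifier_items if include_modifiers else ()
                )
                assign_cache[code] = cached
            items.update(cached)
        items = mapping.apply_hierarchies(items)
        for item in items:
            j = col_of.get(item)
            if j is not None:
                rows.append(i)
                cols.append(j)
    block = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(diagnosis_sets), len(item_ids)),
    )
    return block, [f"{system}:{item}" for item in item_ids]


def _scale_block(
    system: str,
    mapping: MappingTable,
    diagnosis_sets: list[tuple[str, ...]],
) -> tuple[sp.csr_matrix, list[str]]:
    """Numeric scale columns: yearly maximum plus an observed flag."""
    scale_ids = mapping.scale_item_ids
    col_of = {item: j for j, item in enumerate(scale_ids)}
    cache: dict[str, tuple[tuple[str, float], ...]] = {}
    n = len(diagnosis_sets)
    values = np.zeros((n, len(scale_ids)))
    observed = np.zeros((n, len(scale_ids)))
    for i, codes in enumerate(diagnosis_sets):
        for code in codes:
            pairs = cache.get(code)
            if pairs is None:
                pairs = mapping.assign(code).scale_values
                cache[code] = pairs
            for item, value in pairs:
                j = col_of.get(item)
                if j is None:
                    continue
                if not observed[i, j] or value > values[i, j]:
                    values[i, j] = value
                observed[i, j] = 1.0
    block = sp.hstack(
        [sp.csr_matrix(values), sp.csr_matrix(observed)], format="csr"
    )
    names = [f"{system}:scale:{item}" for item in scale_ids] + [
        f"{system}:scaleobs:{item}" for item in scale_ids
    ]
    return block, names


def write_matrix(matrix: FeatureMatrix, prefix: str | Path) -> None:
    """Export as MatrixMarket text (``<prefix>.mtx``) with a column sidecar."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), matrix.X.tocoo())
    sidecar = prefix.with_suffix(".columns.txt")
    sidecar.write_text("\n".join(matrix.columns) + "\n", encoding="utf-8")


def build_indicators(
    enrollee_years: pd.DataFrame,
    mapping: MappingTable,
    system: Optional[str] = None,
    include_modifiers: bool = False,
) -> FeatureMatrix:
    """One-system indicator block (no pruning); functional convenience."""
    block, names = _indicator_block(
        system or mapping.system_name,
        mapping,
        enrollee_years["diagnosis_set"].to_list(),
        include_modifiers,
    )
    return FeatureMatrix(
        X=block, columns=names, index=enrollee_years.index,
        w=enrollee_years["weight"].to_numpy(dtype=float)
        if "weight" in enrollee_years.columns else None,
    )


def build_scales(
    enrollee_years: pd.DataFrame,
    mapping: MappingTable,
    system: Optional[str] = None,
) -> FeatureMatrix:
    block, names = _scale_block(
        system or mapping.system_name,
        mapping,
        enrollee_years["diagnosis_set"].to_list(),
    )
    return FeatureMatrix(X=block, columns=names, index=enrollee_years.index)
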