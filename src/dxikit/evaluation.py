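"""Validation-sample model assessment.

Implements the weighted goodness-of-fit battery: weighted R-squared,
weighted mean absolute error, the weighted Cumming prediction measure
(an L1 analogue of R-squared, modified so partial-year enrollee weights
carry through), predictive ratios by weighted percentile of actual
spending, and mean residuals binned by diagnostic frequency with
confidence intervals clustered at the patient level.

The frequency analysis follows the caption algorithm of the rare-disease
residual figure: each enrollee-year's residual is assigned to every
distinct diagnosis the enrollee had that year, residuals are averaged with
enrollee weights within frequency bins delimited by powers of 10 per
million enrollee-years (frequencies measured on the designated full
sample), and 95% intervals use the between-person variance of the
weighted mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimation import FittedModel
from .features import FeatureMatrix

DEFAULT_PERCENTILE_EDGES = (50.0, 75.0, 90.0, 95.0, 99.0)
Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def _check_aligned(y, yhat, w):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float).ravel()
    if not (len(y) == len(yhat) == len(w)):
        raise ValueError("y, yhat and w must be aligned")
    if len(y) == 0:
        raise ValueError("empty vectors")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return y, yhat, w


def weighted_mean(y: np.ndarray, w: np.ndarray) -> float:
    return float(np.dot(w, y) / w.sum())


def weighted_r2(y, yhat, w=None) -> float:
    """1 - sum w (y-yhat)^2 / sum w (y-ybar_w)^2; may be negative out of sample."""
    y, yhat, w = _check_aligned(y, yhat, w)
    ybar = weighted_mean(y, w)
    tss = float(np.dot(w, (y - ybar) ** 2))
    if tss <= 0:
        raise ValueError("outcome has zero weighted variance")
    rss = float(np.dot(w, (y - yhat) ** 2))
    return 1.0 - rss / tss


def weighted_mae(y, yhat, w=None) -> float:
    y, yhat, w = _check_aligned(y, yhat, w)
    return float(np.dot(w, np.abs(y - yhat)) / w.sum())


def weighted_cpm(y, yhat, w=None) -> float:
    """Weighted Cumming prediction measure: 1 - sum w|y-yhat| / sum w|y-ybar_w|.

    Negative values indicate doing worse than the weighted-mean predictor in
    absolute error.
    """
    y, yhat, w = _check_aligned(y, yhat, w)
    ybar = weighted_mean(y, w)
    tad = float(np.dot(w, np.abs(y - ybar)))
    if tad <= 0:
        raise ValueError("outcome has zero weighted absolute deviation")
    return 1.0 - float(np.dot(w, np.abs(y - yhat))) / tad


# ---------------------------------------------------------------------------
# predictive ratios by percentile of actual outcome
# ---------------------------------------------------------------------------

def _weighted_quantile_thresholds(
    y: np.ndarray, w: np.ndarray, edges: Sequence[float]
) -> np.ndarray:
    """Type-1 (interpolation-free) weighted quantiles of y at the given
    percentile edges: the smallest y with cumulative weight >= q."""
    order = np.argsort(y, kind="stable")
    ys = y[order]
    cw = np.cumsum(w[order])
    total = cw[-1]
    out = np.empty(len(edges))
    for i, q in enumerate(edges):
        pos = np.searchsorted(cw, q / 100.0 * total, side="left")
        out[i] = ys[min(pos, len(ys) - 1)]
    return out


def predictive_ratios(
    y, yhat, w=None, percentile_edges: Sequence[float] = DEFAULT_PERCENTILE_EDGES
) -> pd.DataFrame:
    """Mean actual/predicted and their ratio by weighted percentile of actual.

    Rows are binned by type-1 weighted percentiles of the actual outcome
    (lower-edge inclusive). A bin with zero mean actual reports a missing
    ratio rather than dividing by zero.
    """
    y, yhat, w = _check_aligned(y, yhat, w)
    edges = list(percentile_edges)
    if any(not 0.0 < e < 100.0 for e in edges) or edges != sorted(edges):
        raise ValueError("percentile edges must be increasing and inside (0, 100)")
    thresholds = _weighted_quantile_thresholds(y, w, edges) if edges else np.array([])
    bin_idx = np.searchsorted(thresholds, y, side="right") if edges else np.zeros(
        len(y), dtype=int
    )
    labels = (
        [f"[0,{edges[0]:g})"]
        + [f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])]
        + [f"[{edges[-1]:g},100]"]
        if edges else ["[0,100]"]
    )
    rows = []
    for b, label in enumerate(labels):
        mask = bin_idx == b
        if not mask.any():
            rows.append((label, 0.0, np.nan, np.nan, np.nan))
            continue
        wb = w[mask]
        mean_actual = weighted_mean(y[mask], wb)
        mean_pred = weighted_mean(yhat[mask], wb)
        ratio = mean_pred / mean_actual if mean_actual != 0 else np.nan
        rows.append((label, float(wb.sum()), mean_actual, mean_pred, ratio))
    return pd.DataFrame(
        rows,
        columns=["bin", "weight", "mean_actual", "mean_predicted",
                 "predictive_ratio"],
    ).set_index("bin")


# ---------------------------------------------------------------------------
# residuals by diagnostic frequency
# ---------------------------------------------------------------------------

@dataclass
class FrequencyBinning:
    """Per-code frequencies (per million enrollee-years) with power-of-10 bins.

    Each diagnosis falls in exactly one half-open bin [10^k, 10^(k+1)) per
    million. Codes missing from the table are routed to the rarest observed
    bin and logged in ``unknown_codes``.
    """

    freq_per_million: dict[str, float]
    total_enrollee_years: int = 0
    unknown_codes: list[str] = field(default_factory=list)

    def exponent_of(self, code: str) -> int:
        freq = self.freq_per_million.get(code)
        if freq is None or freq <= 0:
            self.unknown_codes.append(code)
            return self.min_exponent
        return math.floor(math.log10(freq))

    @property
    def min_exponent(self) -> int:
        positive = [f for f in self.freq_per_million.values() if f > 0]
        if not positive:
            return 0
        return math.floor(math.log10(min(positive)))

    @staticmethod
    def bin_label(exponent: int) -> str:
        return f"[1e{exponent},1e{exponent + 1})"


def compute_code_frequencies(full_table: pd.DataFrame) -> FrequencyBinning:
    """Empirical per-code frequency: enrollee-years carrying the code per
    million enrollee-years, measured on the full (pre-split) sample."""
    n = len(full_table)
    if n == 0:
        raise ValueError("empty table")
    counts: dict[str, int] = {}
    for codes in full_table["diagnosis_set"]:
        for code in set(codes):
            counts[code] = counts.get(code, 0) + 1
    return FrequencyBinning(
        freq_per_million={c: k / n * 1e6 for c, k in counts.items()},
        total_enrollee_years=n,
    )


def residuals_by_frequency(
    residuals: np.ndarray,
    diagnosis_sets: Iterable[tuple[str, ...]],
    frequencies: FrequencyBinning,
    weights: Optional[np.ndarray] = None,
    person_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Enrollee-weighted mean residual per diagnostic-frequency bin.

    Every (enrollee-year, distinct diagnosis) pair contributes the
    enrollee-year's residual with its weight to the bin of that diagnosis's
    frequency. The 95% CI uses the between-person variance of the weighted
    mean ("corrected for clustering at the patient level"): persons'
    weighted contributions are aggregated before the variance is taken.
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    sets = list(diagnosis_sets)
    if len(sets) != len(residuals):
        raise ValueError("residuals and diagnosis sets must be aligned")
    n = len(residuals)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    persons = (
        np.arange(n) if person_ids is None else np.asarray(person_ids, dtype=object)
    )

    # accumulate per (bin, person): sum of w*r and sum of w
    acc: dict[int, dict[object, list[float]]] = {}
    pair_counts: dict[int, int] = {}
    ey_counts: dict[int, set[int]] = {}
    code_exponent: dict[str, int] = {}
    for i in range(n):
        for code in set(sets[i]):
            k = code_exponent.get(code)
            if k is None:
                k = frequencies.exponent_of(code)
                code_exponent[code] = k
            per_person = acc.setdefault(k, {})
            cell = per_person.setdefault(persons[i], [0.0, 0.0])
            cell[0] += w[i] * residuals[i]
            cell[1] += w[i]
            pair_counts[k] = pair_counts.get(k, 0) + 1
            ey_counts.setdefault(k, set()).add(i)

    rows = []
    for k in sorted(acc):
        cells = acc[k]
        swr = sum(c[0] for c in cells.values())
        sw = sum(c[1] for c in cells.values())
        mean = swr / sw
        # cluster (person)-aggregated variance of the weighted mean
        var = sum((c[0] - mean * c[1]) ** 2 for c in cells.values()) / sw**2
        half = Z95 * math.sqrt(var)
        rows.append(
            (
                FrequencyBinning.bin_label(k), k, mean, mean - half, mean + half,
                pair_counts[k], len(ey_counts[k]), len(cells),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bin", "exponent", "mean_residual", "ci_low", "ci_high",
            "n_diagnoses", "n_enrollee_years", "n_persons",
        ],
    ).set_index("bin")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    model_id: str
    weighted_r2: float
    weighted_mae: float
    weighted_cpm: float
    negative_share: float
    n_rows: int
    n_variables: int
    percentile_table: Optional[pd.DataFrame] = None
    frequency_residuals: Optional[pd.DataFrame] = None
    index_fingerprint: int = 0

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "model_id": self.model_id,
            "weighted_r2": self.weighted_r2,
            "weighted_mae": self.weighted_mae,
            "weighted_cpm": self.weighted_cpm,
            "negative_share": self.negative_share,
            "n_rows": self.n_rows,
            "n_variables": self.n_variables,
            "percentile_table": (
                None if self.percentile_table is None
                else self.percentile_table.reset_index().to_dict(orient="records")
            ),
            "frequency_residuals": (
                None if self.frequency_residuals is None
                else self.frequency_residuals.reset_index().to_dict(orient="records")
            ),
        }
        text = json.dumps(payload, indent=1, default=float)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def evaluate_model(
    model: FittedModel,
    matrix: FeatureMatrix,
    model_id: Optional[str] = None,
    percentile_edges: Sequence[float] = DEFAULT_PERCENTILE_EDGES,
    frequencies: Optional[FrequencyBinning] = None,
    diagnosis_sets: Optional[Sequence[tuple[str, ...]]] = None,
    person_ids: Optional[Sequence] = None,
) -> EvaluationReport:
    """Score a fitted model on an evaluation matrix (typically validation)."""
    if matrix.y is None:
        raise ValueError("evaluation matrix must carry the outcome vector")
    y = matrix.y
    w = matrix.w if matrix.w is not None else np.ones(len(y))
    yhat = model.predict(matrix)
    freq_table = None
    if frequencies is not None:
        if diagnosis_sets is None:
            raise ValueError("diagnosis_sets required for frequency residuals")
        if person_ids is None and matrix.index is not None:
            person_ids = matrix.index.get_level_values("person_id")
        freq_table = residuals_by_frequency(
            y - yhat, diagnosis_sets, frequencies, w, person_ids
        )
    return EvaluationReport(
        model_id=model_id or model.settings.get("estimator", "model"),
        weighted_r2=weighted_r2(y, yhat, w),
        weighted_mae=weighted_mae(y, yhat, w),
        weighted_cpm=weighted_cpm(y, yhat, w),
        negative_share=float(np.dot(w, yhat < 0) / w.sum()),
        n_rows=len(y),
        n_variables=len(model.columns),
        percentile_table=predictive_ratios(y, yhat, w, percentile_edges),
        frequency_residuals=freq_table,
        index_fingerprint=(
            hash(tuple(matrix.index)) if matrix.index is not None else 0
        ),
    )


def compare_models(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Side-by-side metric table with deltas against the first (base) model.

    All reports must have been computed on the same evaluation rows.
    """
    if not reports:
        raise ValueError("no reports to compare")
    fingerprints = {(r.n_rows, r.index_fingerprint) for r in reports}
    if len(fingerprints) > 1:
        raise ValueError("reports were computed on different row sets")
    base = reports[0]
    rows = []
    for r in reports:
        rows.append(
            {
                "model": r.model_id,
                "n_variables": r.n_variables,
                "weighted_r2": r.weighted_r2,
                "weighted_mae": r.weighted_mae,
                "weighted_cpm": r.weighted_cpm,
                "negative_share": r.negative_share,
                "delta_r2_vs_base": r.weighted_r2 - base.weighted_r2,
                "delta_mae_vs_base": r.weighted_mae - base.weighted_mae,
                "delta_cpm_vs_base": r.weighted_cpm - base.weighted_cpm,
            }
        )
    return pd.DataFrame(rows).set_index("model")
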