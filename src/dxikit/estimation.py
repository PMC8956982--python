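"""Weighted least squares and forward-stepwise selection.

Models are fit by weighted normal equations with an explicit rank check:
collinear columns are dropped deterministically (first kept in column
order) and logged. Classical WLS standard errors and t-test p-values are
reported; the stepwise estimator enters the candidate with the smallest
entry p-value while it is below the entry threshold (default P < 1e-4,
SAS-style with the same stay threshold), re-checking entered columns for
removal after each entry. The demographic age-sex block is forced: always
in the model, never eligible for removal.

Selection runs entirely on the Gram matrix, so each candidate's entry
p-value is an O(k^2) Schur-complement update rather than a refit; this is
what makes stepwise over thousands of sparse indicator columns tractable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin

from .features import AGE_SEX_SYSTEM, FeatureMatrix

DROP_TOL = 1e-10
ArrayLike = Union[np.ndarray, sp.spmatrix, FeatureMatrix]


# ---------------------------------------------------------------------------
# serializable artifacts
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted (possibly stepwise-selected) WLS model, JSON-serializable."""

    columns: list[str]
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    weighted_r2: float
    df_resid: int
    n_obs: int
    dropped_columns: list[str] = field(default_factory=list)
    selection_trace: list[dict] = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    n_candidates: int = 0

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        idx = matrix.column_index(self.columns)
        return np.asarray(matrix.X[:, idx] @ self.coef).ravel()

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "columns": self.columns,
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "p_values": self.p_values.tolist(),
            "weighted_r2": self.weighted_r2,
            "df_resid": self.df_resid,
            "n_obs": self.n_obs,
            "dropped_columns": self.dropped_columns,
            "selection_trace": self.selection_trace,
            "settings": self.settings,
            "n_candidates": self.n_candidates,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        if isinstance(source, Path) or (
            "{" not in str(source) and Path(str(source)).exists()
        ):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        payload = json.loads(text)
        return cls(
            columns=payload["columns"],
            coef=np.asarray(payload["coef"], dtype=float),
            se=np.asarray(payload["se"], dtype=float),
            p_values=np.asarray(payload["p_values"], dtype=float),
            weighted_r2=payload["weighted_r2"],
            df_resid=payload["df_resid"],
            n_obs=payload["n_obs"],
            dropped_columns=payload.get("dropped_columns", []),
            selection_trace=payload.get("selection_trace", []),
            settings=payload.get("settings", {}),
            n_candidates=payload.get("n_candidates", 0),
        )


@dataclass
class PredictionSet:
    """Predictions plus the weighted share that came out negative."""

    index: object
    values: np.ndarray
    negative_share: float


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _unpack(
    X: ArrayLike,
    y: Optional[np.ndarray],
    w: Optional[np.ndarray],
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray, list[str], object]:
    if isinstance(X, FeatureMatrix):
        columns, index = list(X.columns), X.index
        if y is None:
            y = X.y
        if w is None:
            w = X.w
        X = X.X
    else:
        X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
        columns = [f"x{j}" for j in range(X.shape[1])]
        index = None
    if y is None:
        raise ValueError("no outcome vector supplied")
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot fit on zero rows")
    if y.shape[0] != n:
        raise ValueError("y is not aligned with X rows")
    w = np.ones(n) if w is None else np.asarray(w, dtype=float).ravel()
    if w.shape[0] != n:
        raise ValueError("weights are not aligned with X rows")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if not (np.isfinite(X.data).all() and np.isfinite(y).all() and np.isfinite(w).all()):
        raise ValueError("non-finite values in X, y or w")
    return X, y, w, columns, index


def _gram(X: sp.csr_matrix, y: np.ndarray, w: np.ndarray):
    Xw = X.multiply(w[:, None]).tocsr()
    G = np.asarray((X.T @ Xw).todense(), dtype=float)
    q = np.asarray(X.T @ (w * y)).ravel()
    yty = float(np.dot(w * y, y))
    return G, q, yty


def _select_independent(
    G: np.ndarray, order: Sequence[int], tol: float = DROP_TOL
) -> list[int]:
    """Greedy rank-revealing Cholesky sweep: keep columns in *order* whose
    pivot stays above ``tol`` relative to their diagonal."""
    kept: list[int] = []
    L = np.zeros((len(order), len(order)))
    for j in order:
        k = len(kept)
        gj = G[kept, j] if k else np.empty(0)
        l = solve_triangular(L[:k, :k], gj, lower=True) if k else gj
        d = G[j, j] - float(l @ l)
        if G[j, j] <= 0 or d <= tol * G[j, j]:
            continue
        L[k, :k] = l
        L[k, k] = np.sqrt(d)
        kept.append(j)
    return kept


def _solve_stats(
    G: np.ndarray, q: np.ndarray, yty: float, idx: Sequence[int], n: int
):
    """Coefficients, SEs, p-values and weighted RSS for the columns *idx*."""
    idx = list(idx)
    k = len(idx)
    Gs = G[np.ix_(idx, idx)]
    qs = q[idx]
    beta = np.linalg.solve(Gs, qs)
    rss = max(yty - float(qs @ beta), 0.0)
    df = n - k
    sigma2 = rss / df if df > 0 else np.nan
    cov_diag = np.diag(np.linalg.inv(Gs))
    se = np.sqrt(np.maximum(sigma2 * cov_diag, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta + (beta == 0)))
    p = (
        2.0 * stats.t.sf(np.abs(t), df)
        if df > 0 else np.full(k, np.nan)
    )
    return beta, se, p, rss, df


def _weighted_r2_from_rss(y: np.ndarray, w: np.ndarray, rss: float) -> float:
    ybar = float(np.dot(w, y) / w.sum())
    tss = float(np.dot(w, (y - ybar) ** 2))
    if tss <= 0:
        raise ValueError("outcome has zero weighted variance")
    return 1.0 - rss / tss


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class WeightedLeastSquares(BaseEstimator, RegressorMixin):
    """Weighted least squares via normal equations with a rank check.

    Minimizes sum_i w_i (y_i - x_i beta)^2. Collinear columns are dropped
    first-kept-in-column-order and recorded in ``dropped_columns_``.

    Accepts a :class:`~dxikit.features.FeatureMatrix` (outcome and weights
    taken from it) or a plain (sparse) matrix with explicit ``y`` and
    ``sample_weight``.
    """

    def __init__(self, drop_tol: float = DROP_TOL) -> None:
        self.drop_tol = drop_tol

    def fit(
        self,
        X: ArrayLike,
        y: Optional[np.ndarray] = None,
        sample_weight: Optional[np.ndarray] = None,
    ) -> "WeightedLeastSquares":
        Xs, yv, wv, names, _ = _unpack(X, y, sample_weight)
        G, q, yty = _gram(Xs, yv, wv)
        kept = _select_independent(G, range(len(names)), self.drop_tol)
        beta, se, p, rss, df = _solve_stats(G, q, yty, kept, Xs.shape[0])
        self.feature_names_in_ = names
        self.columns_ = [names[j] for j in kept]
        self.dropped_columns_ = [
            names[j] for j in range(len(names)) if j not in set(kept)
        ]
        self.coef_ = beta
        self.se_ = se
        self.p_values_ = p
        self.df_resid_ = df
        self.n_obs_ = Xs.shape[0]
        self.sigma2_ = rss / df if df > 0 else np.nan
        self.weighted_r2_ = _weighted_r2_from_rss(yv, wv, rss)
        self.n_candidates_ = len(names)
        self._trace: list[dict] = []
        self._settings: dict = {"estimator": "wls", "drop_tol": self.drop_tol}
        return self

    # prediction ---------------------------------------------------------

    def _aligned(self, X: ArrayLike) -> sp.csr_matrix:
        if isinstance(X, FeatureMatrix):
            idx = X.column_index(self.columns_)
            return X.X[:, idx]
        X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
        if X.shape[1] == len(self.columns_):
            return X
        if X.shape[1] == len(self.feature_names_in_):
            keep = [
                j for j, c in enumerate(self.feature_names_in_)
                if c in set(self.columns_)
            ]
            return X[:, keep]
        raise ValueError(
            f"X has {X.shape[1]} columns; expected {len(self.columns_)} "
            f"(kept) or {len(self.feature_names_in_)} (original)"
        )

    def predict(self, X: ArrayLike) -> np.ndarray:
        return np.asarray(self._aligned(X) @ self.coef_).ravel()

    def predict_set(
        self, X: ArrayLike, sample_weight: Optional[np.ndarray] = None
    ) -> PredictionSet:
        values = self.predict(X)
        index = X.index if isinstance(X, FeatureMatrix) else None
        if sample_weight is None and isinstance(X, FeatureMatrix):
            sample_weight = X.w
        w = (
            np.ones(len(values)) if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        share = float(np.dot(w, values < 0) / w.sum())
        return PredictionSet(index=index, values=values, negative_share=share)

    def score(
        self,
        X: ArrayLike,
        y: Optional[np.ndarray] = None,
        sample_weight: Optional[np.ndarray] = None,
    ) -> float:
        from .evaluation import weighted_r2

        if isinstance(X, FeatureMatrix):
            y = X.y if y is None else y
            sample_weight = X.w if sample_weight is None else sample_weight
        w = (
            np.ones(len(y)) if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        return weighted_r2(np.asarray(y, dtype=float), self.predict(X), w)

    def result(self) -> FittedModel:
        return FittedModel(
            columns=list(self.columns_),
            coef=self.coef_.copy(),
            se=self.se_.copy(),
            p_values=self.p_values_.copy(),
            weighted_r2=float(self.weighted_r2_),
            df_resid=int(self.df_resid_),
            n_obs=int(self.n_obs_),
            dropped_columns=list(self.dropped_columns_),
            selection_trace=list(self._trace),
            settings=dict(self._settings),
            n_candidates=int(self.n_candidates_),
        )


class StepwiseWLS(WeightedLeastSquares):
    """Forward-stepwise WLS with a p-value entry criterion.

    Starting from the forced block (columns whose name begins with
    ``forced_prefix``, by default the age-sex cells), each step enters the
    candidate with the smallest entry p-value if it is below ``entry_p``
    (ties broken by column name); after each entry, entered non-forced
    columns whose current p-value is at or above ``stay_p`` are removed,
    worst first. ``stay_p`` defaults to ``entry_p``.
    """

    def __init__(
        self,
        entry_p: float = 1e-4,
        stay_p: Optional[float] = None,
        allow_removal: bool = True,
        forced_prefix: str = f"{AGE_SEX_SYSTEM}:",
        drop_tol: float = DROP_TOL,
    ) -> None:
        super().__init__(drop_tol=drop_tol)
        self.entry_p = entry_p
        self.stay_p = stay_p
        self.allow_removal = allow_removal
        self.forced_prefix = forced_prefix

    def fit(
        self,
        X: ArrayLike,
        y: Optional[np.ndarray] = None,
        sample_weight: Optional[np.ndarray] = None,
        forced_columns: Optional[Sequence[str]] = None,
    ) -> "StepwiseWLS":
        if not 0.0 < self.entry_p <= 1.0:
            raise ValueError("entry_p must lie in (0, 1]")
        stay_p = self.entry_p if self.stay_p is None else self.stay_p
        Xs, yv, wv, names, _ = _unpack(X, y, sample_weight)
        n = Xs.shape[0]
        G, q, yty = _gram(Xs, yv, wv)
        gdiag = np.diag(G)

        if forced_columns is not None:
            forced_set = set(forced_columns)
            missing = forced_set - set(names)
            if missing:
                raise ValueError(f"forced columns not in X: {sorted(missing)[:5]}")
            forced_idx = [j for j, c in enumerate(names) if c in forced_set]
        else:
            forced_idx = [
                j for j, c in enumerate(names) if c.startswith(self.forced_prefix)
            ]
        forced_kept = _select_independent(G, forced_idx, self.drop_tol)
        dropped = [names[j] for j in forced_idx if j not in set(forced_kept)]
        candidates = [j for j in range(len(names)) if j not in set(forced_idx)]

        selected: list[int] = list(forced_kept)
        trace: list[dict] = []
        step = 0
        while candidates:
            entry = self._best_entry(G, q, yty, gdiag, selected, candidates, n, names)
            if entry is None:
                break
            j, p_enter = entry
            if not p_enter < self.entry_p:
                break
            step += 1
            selected.append(j)
            candidates.remove(j)
            trace.append(
                {"step": step, "action": "enter", "column": names[j],
                 "p_value": float(p_enter)}
            )
            if self.allow_removal:
                step = self._removal_sweep(
                    G, q, yty, selected, set(forced_kept), candidates,
                    n, names, stay_p, trace, step,
                )

        beta, se, p, rss, df = _solve_stats(G, q, yty, selected, n)
        self.feature_names_in_ = names
        self.columns_ = [names[j] for j in selected]
        self.dropped_columns_ = dropped
        self.coef_ = beta
        self.se_ = se
        self.p_values_ = p
        self.df_resid_ = df
        self.n_obs_ = n
        self.sigma2_ = rss / df if df > 0 else np.nan
        self.weighted_r2_ = _weighted_r2_from_rss(yv, wv, rss)
        self.n_candidates_ = len(names) - len(forced_idx)
        self._trace = trace
        self._settings = {
            "estimator": "stepwise_wls",
            "entry_p": self.entry_p,
            "stay_p": stay_p,
            "allow_removal": self.allow_removal,
        }
        self.forced_columns_ = [names[j] for j in forced_kept]
        return self

    def _best_entry(self, G, q, yty, gdiag, selected, candidates, n, names):
        """Smallest entry p-value among candidates via Schur complements."""
        k = len(selected)
        df = n - (k + 1)
        if df <= 0:
            return None
        cand = np.asarray(candidates, dtype=np.intp)
        Gs = G[np.ix_(selected, selected)]
        qs = q[selected]
        beta_s = np.linalg.solve(Gs, qs) if k else np.empty(0)
        rss = max(yty - float(qs @ beta_s), 0.0) if k else yty
        Gsc = G[np.ix_(selected, cand)] if k else np.empty((0, len(cand)))
        T1 = np.linalg.solve(Gs, Gsc) if k else Gsc
        s = gdiag[cand] - np.einsum("ij,ij->j", Gsc, T1)
        bnum = q[cand] - (beta_s @ Gsc if k else 0.0)
        valid = (gdiag[cand] > 0) & (s > self.drop_tol * gdiag[cand])
        if not valid.any():
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            rss_new = np.maximum(rss - bnum**2 / s, 0.0)
            sigma2 = rss_new / df
            t2 = np.where(sigma2 > 0, (bnum**2 / s) / sigma2, np.inf)
        p = 2.0 * stats.t.sf(np.sqrt(t2), df)
        p = np.where(valid, p, np.inf)
        best = min(
            (float(p[i]), names[cand[i]], int(cand[i])) for i in range(len(cand))
        )
        if not np.isfinite(best[0]):
            return None
        return best[2], best[0]

    def _removal_sweep(
        self, G, q, yty, selected, forced, candidates, n, names, stay_p,
        trace, step,
    ) -> int:
        while True:
            _, _, p, _, df = _solve_stats(G, q, yty, selected, n)
            if df <= 0:
                return step
            removable = [
                (float(p[i]), names[j], j)
                for i, j in enumerate(selected)
                if j not in forced and p[i] >= stay_p
            ]
            if not removable:
                return step
            worst = max(removable, key=lambda item: (item[0], item[1]))
            step += 1
            selected.remove(worst[2])
            candidates.append(worst[2])
            candidates.sort()
            trace.append(
                {"step": step, "action": "remove", "column": worst[1],
                 "p_value": worst[0]}
            )


# ---------------------------------------------------------------------------
# functional wrappers and flags
# ---------------------------------------------------------------------------

def wls_fit(
    X: ArrayLike,
    y: Optional[np.ndarray] = None,
    w: Optional[np.ndarray] = None,
) -> FittedModel:
    return WeightedLeastSquares().fit(X, y, sample_weight=w).result()


def stepwise_fit(
    X: ArrayLike,
    y: Optional[np.ndarray] = None,
    w: Optional[np.ndarray] = None,
    entry_p: float = 1e-4,
    forced_columns: Optional[Sequence[str]] = None,
    allow_removal: bool = True,
) -> FittedModel:
    est = StepwiseWLS(entry_p=entry_p, allow_removal=allow_removal)
    est.fit(X, y, sample_weight=w, forced_columns=forced_columns)
    return est.result()


def significance_flags(
    model: FittedModel,
    alpha: float = 0.05,
    m: Optional[int] = None,
    ceiling: float = 1e-4,
) -> dict[str, bool]:
    """Bonferroni-corrected significance per retained column.

    The threshold is min(alpha/m, ceiling) with ``m`` defaulting to the
    number of candidate columns considered, and the comparison is strict.
    """
    m = m if m is not None else (model.n_candidates or len(model.columns))
    if m <= 0:
        raise ValueError("Bonferroni family size m must be positive")
    threshold = min(alpha / m, ceiling)
    return {
        col: bool(p < threshold)
        for col, p in zip(model.columns, model.p_values)
    }


def predict(
    model: FittedModel,
    matrix: FeatureMatrix,
    sample_weight: Optional[np.ndarray] = None,
) -> PredictionSet:
    values = model.predict(matrix)
    w = sample_weight if sample_weight is not None else matrix.w
    w = np.ones(len(values)) if w is None else np.asarray(w, dtype=float)
    share = float(np.dot(w, values < 0) / w.sum())
    return PredictionSet(index=matrix.index, values=values, negative_share=share)
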