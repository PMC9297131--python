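"""Serfling-type harmonic regression with a LASSO-selected outlier filter.

The model for hourly RSV is

    y = intercept + trend (cubic orthogonal polynomials in elapsed days)
        + day-type harmonics (sin/cos n*omega*t, n = 1..4, weekday and
          weekend separately, plus a weekend level)
        + selected interval indicators (outlier/epidemic nuisance terms)
        + error,

fitted in two stages: (1) cross-validated LASSO over the nuisance indicator
ladder only — the intercept, trend, and harmonic block are never penalized,
since shrinking the coefficients of interest would bias the circular
summaries — then (2) ordinary least squares on the unpenalized block plus the
selected indicators.  Subtracting the fitted indicator contribution gives the
outlier-filtered series used for all downstream summaries and plots.

Partial penalization is solved exactly by profiling: for fixed nuisance
coefficients b the optimal unpenalized coefficients are the OLS fit of
(y - N b) on the unpenalized block U, so the joint problem reduces to a plain
LASSO of the U-residualized response on the U-residualized indicators.  That
reduced problem is solved with scikit-learn's LARS path on a Gram matrix
residualized in closed form, N'N - (U'N)'(U'U)^{-1}(U'N), which avoids ever
densifying the indicator block.  Cross-validation uses seeded shuffled K-fold
over observations (an interval indicator only predicts its own window, so
contiguous fold blocks can never credit it: the window would sit wholly inside
one held-out fold); the penalty is the sparsest value within one standard
error of the CV minimum ("1se", the default) or the CV minimum ("min").  Indicator columns are standardized to unit norm inside the
LASSO only (wide windows would otherwise be under-penalized); reported
coefficients are on the original 0/1 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lars_path_gram

from .basis import DesignMatrices, WIDTH_PRESETS
from .io import HourlySeries

__all__ = [
    "FittedModel",
    "DiurnalHarmonicRegression",
    "select_nuisance",
    "fit_ols",
    "filter_series",
    "fit_series",
]

_HARM_OFFSET = {"weekday": 0, "weekend": 8}
_FN_OFFSET = {"sin": 0, "cos": 1}


# ---------------------------------------------------------------------------
# Selection workspace: everything that depends on the design but not on y.
# Cached on the DesignMatrices so repeated fits on one timestamp grid (e.g.
# simulation studies, bootstrap pipelines) pay the Gram algebra once.
# ---------------------------------------------------------------------------

def _solve_psd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def _gram_pieces(U, N, rows=None):
    """(U'U, U'N, dense N'N) restricted to ``rows`` (None = all)."""
    if rows is not None:
        U = U[rows]
        N = N[rows]
    A = U.T @ U
    B = U.T @ N  # dense (u, p) via sparse matmul
    B = np.asarray(B)
    NtN = (N.T @ N).toarray()
    return A, B, NtN


def _residualized_gram(A, B, NtN, scratch=None):
    """Residualized, unit-norm-scaled Gram. Takes ownership of ``NtN``."""
    P = _solve_psd(A, B)
    if scratch is not None:
        C = np.matmul(B.T, P, out=scratch)
    else:
        C = B.T @ P
    np.subtract(NtN, C, out=NtN)
    Gs = NtN
    norms = np.sqrt(np.clip(np.diag(Gs), 0.0, None))
    valid = norms > 1e-8
    scale = np.where(valid, norms, 1.0)
    Gs /= scale[:, None]
    Gs /= scale[None, :]
    # invalid columns (numerically inside the unpenalized span) are frozen out
    Gs[~valid, :] = 0.0
    Gs[:, ~valid] = 0.0
    Gs[~valid, ~valid] = 1.0
    return Gs, scale, valid


def _full_workspace(design: DesignMatrices) -> dict:
    """Full-data Gram pieces (y-independent); cached on the design."""
    key = ("gram_full",)
    if key in design._workspace:
        return design._workspace[key]
    U = design.unpenalized
    N = design.nuisance.tocsr()
    A, B, NtN = _gram_pieces(U, N)
    Gs, scale, valid = _residualized_gram(A, B, NtN)  # consumes NtN
    ws = {"U": U, "N": N, "A": A, "B": B, "Gs": Gs, "scale": scale,
          "valid": valid}
    design._workspace[key] = ws
    return ws


def _fold_workspace(design: DesignMatrices, cv_folds: int, seed: int) -> list[dict]:
    """Per-fold training Grams for seeded shuffled K-fold CV; cached lazily."""
    key = ("gram_folds", cv_folds, seed)
    if key in design._workspace:
        return design._workspace[key]
    U = design.unpenalized
    N = design.nuisance.tocsr()
    n = design.n
    A, B, NtN = _gram_pieces(U, N)
    scratch = np.empty_like(NtN)
    order = np.random.default_rng(seed).permutation(n)
    folds = []
    for test_idx in np.array_split(order, cv_folds):
        test_idx = np.sort(test_idx)
        A_te, B_te, NtN_te = _gram_pieces(U, N, test_idx)
        A_tr, B_tr = A - A_te, B - B_te
        Gs_tr, scale_tr, valid_tr = _residualized_gram(A_tr, B_tr, NtN - NtN_te,
                                                       scratch)
        folds.append({
            "test_idx": test_idx,
            "U_te": U[test_idx],
            "N_te": N[test_idx],
            "A_tr": A_tr,
            "B_tr": B_tr,
            "Gs": Gs_tr,
            "scale": scale_tr,
            "valid": valid_tr,
            "n_tr": n - len(test_idx),
        })
    design._workspace[key] = folds
    return folds


def _lasso_path_coefs(xy_s, Gs, n_samples, alphas_grid, max_terms):
    """LASSO coefficients (standardized scale) on a fixed alpha grid.

    Runs the LARS-LASSO path from the Gram matrix and linearly interpolates
    the piecewise-linear path at the requested alphas (clamped to the last
    breakpoint if the path was truncated by ``max_terms``).
    Returns (active_rows, coefs[active_rows, n_alphas]).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        alphas, _, coefs = lars_path_gram(
            Xy=xy_s.copy(), Gram=Gs, n_samples=n_samples,
            method="lasso", max_iter=max_terms,
            alpha_min=float(alphas_grid.min()) * 0.5)
    rows = np.flatnonzero(np.any(coefs != 0.0, axis=1))
    if len(rows) == 0:
        return rows, np.zeros((0, len(alphas_grid)))
    xp = alphas[::-1]
    out = np.empty((len(rows), len(alphas_grid)))
    for i, r in enumerate(rows):
        out[i] = np.interp(alphas_grid, xp, coefs[r, ::-1])
    return rows, out


def select_nuisance(y: np.ndarray, design: DesignMatrices,
                    cv_folds: int = 10, seed: int = 0,
                    penalty_rule: str = "1se", n_alphas: int = 100,
                    max_terms: int = 60,
                    return_details: bool = False):
    """Cross-validated LASSO selection of outlier indicator columns.

    Returns the list of selected ``(width k, window m)`` columns (and the CV
    details when ``return_details``). Folds are a seeded random partition of
    the observations into ``cv_folds`` groups.
    """
    if penalty_rule not in ("1se", "min"):
        raise ValueError("penalty_rule must be '1se' or 'min'")
    y = np.asarray(y, dtype=float)
    n = design.n
    if len(y) != n:
        raise ValueError("y length does not match the design")
    n_unpen = design.unpenalized.shape[1]
    if n < n_unpen:
        raise ValueError(f"need at least {n_unpen} rows to fit the unpenalized block")
    ws = _full_workspace(design)
    details = {"cv_folds": cv_folds, "seed": seed, "penalty_rule": penalty_rule,
               "fold_scheme": "seeded shuffled K-fold"}

    Uty = ws["U"].T @ y
    Nty = ws["N"].T @ y

    xy_full = Nty - ws["B"].T @ _solve_psd(ws["A"], Uty)
    xy_s_full = np.where(ws["valid"], xy_full / ws["scale"], 0.0)
    alpha_max = float(np.max(np.abs(xy_s_full), initial=0.0)) / n
    y_scale = float(np.std(y)) + 1e-30
    if alpha_max <= 1e-10 * y_scale or design.nuisance.shape[1] == 0:
        details.update({"alphas": np.array([]), "chosen_alpha": 0.0,
                        "reason": "no residual signal in the nuisance block"})
        return ([], details) if return_details else []

    # correlation screen (strong-rule style): the LARS path is run on the
    # columns with the largest full-data residualized correlations; the cap is
    # far above the path length so the screen is effectively lossless for
    # localized outlier designs, while keeping the per-fold Gram small.
    n_screen = int(min(design.nuisance.shape[1], max(480, 8 * max_terms)))
    screen = np.sort(np.argsort(-np.abs(xy_s_full))[:n_screen])

    alphas_grid = np.geomspace(alpha_max, alpha_max * 1e-3, n_alphas)
    mse = np.empty((cv_folds, n_alphas))
    for f, fold in enumerate(_fold_workspace(design, cv_folds, seed)):
        te = fold["test_idx"]
        y_te = y[te]
        Uty_tr = Uty - fold["U_te"].T @ y_te
        Nty_tr = Nty - fold["N_te"].T @ y_te
        xy_tr = Nty_tr - fold["B_tr"].T @ _solve_psd(fold["A_tr"], Uty_tr)
        xy_s = np.where(fold["valid"], xy_tr / fold["scale"], 0.0)
        sub, coef_s = _lasso_path_coefs(xy_s[screen],
                                        fold["Gs"][np.ix_(screen, screen)],
                                        fold["n_tr"], alphas_grid, max_terms)
        rows = screen[sub]
        # back to the 0/1 scale for prediction
        coef = coef_s / fold["scale"][rows, None] if len(rows) else coef_s
        # profile the unpenalized block on the training rows for each alpha
        rhs = Uty_tr[:, None] - fold["B_tr"][:, rows] @ coef
        a = _solve_psd(fold["A_tr"], rhs)                      # (u, n_alphas)
        pred = fold["U_te"] @ a
        if len(rows):
            pred = pred + fold["N_te"][:, rows].toarray() @ coef
        mse[f] = np.mean((y_te[:, None] - pred) ** 2, axis=0)

    mean_mse = mse.mean(axis=0)
    se_mse = mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(mean_mse))
    if penalty_rule == "min":
        i_chosen = i_min
    else:
        ok = mean_mse <= mean_mse[i_min] + se_mse[i_min]
        i_chosen = int(np.argmax(ok))  # first (largest) alpha within one SE
    chosen_alpha = float(alphas_grid[i_chosen])

    sub, coef_s = _lasso_path_coefs(
        xy_s_full[screen], ws["Gs"][np.ix_(screen, screen)], n,
        np.array([chosen_alpha]), max_terms)
    rows = screen[sub]
    support = rows[np.abs(coef_s[:, 0]) > 1e-12] if len(rows) else rows
    selected = [design.nuisance_meta[j] for j in np.sort(support)]
    details.update({"alphas": alphas_grid, "mean_mse": mean_mse, "se_mse": se_mse,
                    "chosen_alpha": chosen_alpha, "alpha_min_cv": float(alphas_grid[i_min]),
                    "n_selected": len(selected)})
    return (selected, details) if return_details else selected


# ---------------------------------------------------------------------------
# OLS fit and the fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Coefficients, residuals, and the outlier-filtered series of one fit."""

    intercept: float
    trend_coeffs: np.ndarray                  # (3,)
    harmonic_coeffs: np.ndarray               # (16,), order as harmonic_names
    weekend_level: float
    nuisance_coeffs: dict[tuple[int, int], float]
    residuals: np.ndarray
    fitted: np.ndarray
    filtered_series: np.ndarray               # observed minus nuisance part
    selected_columns: list[tuple[int, int]]
    cv_details: dict
    design: DesignMatrices
    y: np.ndarray
    trend_level_mid: float                    # trend contribution at study midpoint

    def harmonic_coef(self, daytype: str, n: int, fn: str) -> float:
        """Coefficient of ``fn(n*omega*t)`` for the given day type."""
        idx = _HARM_OFFSET[daytype] + (n - 1) * 2 + _FN_OFFSET[fn]
        return float(self.harmonic_coeffs[idx])

    @property
    def nuisance_contribution(self) -> np.ndarray:
        return self.y - self.filtered_series

    def coefficient_table(self) -> pd.DataFrame:
        """Flat coefficient table (block, name, estimate) for serialization."""
        rows = [("intercept", "intercept", self.intercept)]
        for i, c in enumerate(self.trend_coeffs):
            rows.append(("trend", f"poly{i + 1}", float(c)))
        for name, c in zip(self.design.harmonic_names[:-1], self.harmonic_coeffs):
            rows.append(("harmonic", name, float(c)))
        rows.append(("harmonic", "weekend_level", self.weekend_level))
        for (k, m), c in sorted(self.nuisance_coeffs.items()):
            rows.append(("nuisance", f"k{k}_m{m}", float(c)))
        return pd.DataFrame(rows, columns=["block", "name", "estimate"])


def _dedupe_collinear(design: DesignMatrices,
                      selected: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop exactly duplicated indicator columns among the selection.

    Truncated final windows can coincide across widths; among duplicates the
    narrowest width, then the earliest window, is kept (the most local
    explanation of the outlier).
    """
    if len(selected) < 2:
        return list(selected)
    meta_index = {km: j for j, km in enumerate(design.nuisance_meta)}
    cols = design.nuisance[:, [meta_index[km] for km in selected]].toarray().T
    _, first, inverse = np.unique(cols, axis=0, return_index=True,
                                  return_inverse=True)
    keep = []
    for g in range(inverse.max() + 1):
        members = [selected[i] for i in np.flatnonzero(inverse == g)]
        best = min(members)  # (k, m) lexicographic: narrowest k, earliest m
        if len(members) > 1:
            warnings.warn(f"dropping duplicated indicator columns "
                          f"{sorted(set(members) - {best})} in favour of {best}")
        keep.append(best)
    return sorted(keep)


def fit_ols(y: np.ndarray, design: DesignMatrices,
            selected: Sequence[tuple[int, int]] | None = None,
            cv_details: dict | None = None) -> FittedModel:
    """Ordinary least squares on the unpenalized block + selected indicators."""
    y = np.asarray(y, dtype=float)
    if len(y) != design.n:
        raise ValueError("y length does not match the design")
    selected = _dedupe_collinear(design, list(selected or []))
    meta_index = {km: j for j, km in enumerate(design.nuisance_meta)}
    try:
        cols = [meta_index[km] for km in selected]
    except KeyError as exc:
        raise ValueError(f"selected column {exc.args[0]} not in the design") from None
    N_sel = design.nuisance[:, cols].toarray() if cols else np.empty((design.n, 0))
    X = np.column_stack([design.unpenalized, N_sel])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("collinear design after selection; minimum-norm OLS used")
    fitted = X @ beta
    n_u = design.unpenalized.shape[1]
    nuis = beta[n_u:]
    nuisance_contrib = N_sel @ nuis if cols else np.zeros(design.n)
    d = design.elapsed_days
    mid = 0.5 * (float(d.min()) + float(d.max()))
    trend_mid = float(design.trend_basis.transform(np.array([mid]))[0] @ beta[1:4])
    return FittedModel(
        intercept=float(beta[0]),
        trend_coeffs=beta[1:4].copy(),
        harmonic_coeffs=beta[4:20].copy(),
        weekend_level=float(beta[20]),
        nuisance_coeffs={km: float(b) for km, b in zip(selected, nuis)},
        residuals=y - fitted,
        fitted=fitted,
        filtered_series=y - nuisance_contrib,
        selected_columns=list(selected),
        cv_details=dict(cv_details or {}),
        design=design,
        y=y,
        trend_level_mid=trend_mid,
    )


def filter_series(model: FittedModel) -> np.ndarray:
    """Observed series minus the fitted nuisance (outlier) contribution."""
    return model.filtered_series.copy()


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class DiurnalHarmonicRegression(RegressorMixin, BaseEstimator):
    """Serfling harmonic regression of hourly RSV with LASSO outlier filtering.

    Parameters
    ----------
    widths : str or sequence of int, default "default"
        Nuisance indicator width ladder: a preset name (``default`` =
        {8,16,32,64,128,168}; ``sensitivity_a`` = {7,...,168};
        ``sensitivity_b`` = {9,...,168}) or explicit widths in hours.
    select : bool, default True
        Run the cross-validated LASSO outlier selection; with False the model
        is a plain trend + harmonics fit.
    cv_folds : int, default 10
        Cross-validation folds (seeded random partition) for the LASSO penalty.
    penalty_rule : {"1se", "min"}, default "1se"
        Penalty choice: sparsest within one SE of the CV minimum, or the
        CV minimum itself.
    max_terms : int, default 60
        Cap on the LARS path length (maximum indicators considered).
    n_alphas : int, default 100
        Penalty grid resolution for cross-validation.
    seed : int, default 0
        Seeds the cross-validation fold partition.

    Attributes
    ----------
    intercept_, trend_coeffs_, harmonic_coeffs_, weekend_level_,
    nuisance_coeffs_, selected_columns_, residuals_, filtered_series_,
    cv_details_, model_ (the full :class:`FittedModel`), design_.

    Examples
    --------
    >>> est = DiurnalHarmonicRegression(select=False)
    >>> est.fit(annotated_frame, y)             # doctest: +SKIP
    >>> est.filtered_series_                    # doctest: +SKIP
    """

    def __init__(self, widths: str | Sequence[int] = "default",
                 select: bool = True, cv_folds: int = 10,
                 penalty_rule: str = "1se", max_terms: int = 60,
                 n_alphas: int = 100, seed: int = 0):
        self.widths = widths
        self.select = select
        self.cv_folds = cv_folds
        self.penalty_rule = penalty_rule
        self.max_terms = max_terms
        self.n_alphas = n_alphas
        self.seed = seed

    # -- plumbing -----------------------------------------------------------
    @staticmethod
    def _coerce(X, y):
        if isinstance(X, HourlySeries):
            if not X.annotated:
                raise ValueError("series must be locally annotated (to_local_time)")
            frame = X.frame
            y = X.rsv if y is None else np.asarray(y, dtype=float)
            return frame, y
        if isinstance(X, pd.DataFrame):
            if y is None:
                if "rsv" not in X.columns:
                    raise ValueError("y not given and no 'rsv' column in X")
                y = X["rsv"].to_numpy(dtype=float)
            return X, np.asarray(y, dtype=float)
        raise TypeError("X must be an annotated HourlySeries or DataFrame")

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y=None, design: DesignMatrices | None = None):
        """Fit on an annotated series/frame (or a prebuilt design) and y."""
        if design is None:
            frame, y = self._coerce(X, y)
            design = DesignMatrices.from_annotations(frame, self.widths)
        else:
            y = np.asarray(X.rsv if isinstance(X, HourlySeries) else y
                           if y is not None else X, dtype=float)
        if self.select:
            selected, details = select_nuisance(
                y, design, cv_folds=self.cv_folds, seed=self.seed,
                penalty_rule=self.penalty_rule, n_alphas=self.n_alphas,
                max_terms=self.max_terms, return_details=True)
        else:
            selected, details = [], {"skipped": True}
        self.model_ = fit_ols(y, design, selected, cv_details=details)
        self.design_ = design
        self.intercept_ = self.model_.intercept
        self.trend_coeffs_ = self.model_.trend_coeffs
        self.harmonic_coeffs_ = self.model_.harmonic_coeffs
        self.weekend_level_ = self.model_.weekend_level
        self.nuisance_coeffs_ = self.model_.nuisance_coeffs
        self.selected_columns_ = self.model_.selected_columns
        self.residuals_ = self.model_.residuals
        self.filtered_series_ = self.model_.filtered_series
        self.cv_details_ = self.model_.cv_details
        self.n_features_in_ = design.unpenalized.shape[1] + design.nuisance.shape[1]
        return self

    def predict(self, X, include_nuisance: bool = False) -> np.ndarray:
        """Fitted trend + harmonic mean at new annotated rows.

        With ``include_nuisance`` the selected indicator contributions are
        added for rows whose elapsed hours fall inside a selected window.
        """
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        if isinstance(X, HourlySeries):
            X = X.frame
        from .basis import build_harmonic_basis

        m = self.model_
        days = X["elapsed_days"].to_numpy(dtype=float)
        trend = self.design_.trend_basis.transform(days)
        harm = build_harmonic_basis(X["hour_of_day"].to_numpy(),
                                    X["is_weekend"].to_numpy())
        out = (m.intercept + trend @ m.trend_coeffs
               + harm[:, :16] @ m.harmonic_coeffs + harm[:, 16] * m.weekend_level)
        if include_nuisance and m.nuisance_coeffs:
            x = X["elapsed_hours"].to_numpy(dtype=np.int64)
            for (k, mm), b in m.nuisance_coeffs.items():
                out = out + np.where((x >= k * mm) & (x < k * (mm + 1)), b, 0.0)
        return out


def fit_series(series: HourlySeries, **params) -> FittedModel:
    """One-call convenience: fit the full model to an annotated series."""
    est = DiurnalHarmonicRegression(**params)
    est.fit(series)
    return est.model_
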