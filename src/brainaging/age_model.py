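"""Stepwise age-associative regression on cell-type-specific genes.

Chronological age in years is regressed on gene expression by
forward-backward stepwise ordinary least squares. Cohort covariates (brain
bank source, cause of death) are dummy-coded and forced into the model;
candidate terms are gene main effects and, optionally, pairwise products of
already-selected genes. A term enters when its partial-F p-value is below
``entry_p`` and leaves when it rises above ``removal_p``; re-entry of a
just-removed term is forbidden for one step so the procedure terminates.

The regressor follows the scikit-learn estimator contract (``fit`` /
``predict``, ``get_params``/``set_params``, trailing-underscore fitted
attributes) so it composes with sklearn model selection; module-level
functions wrap it for pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

Term = tuple  # ("gene", g) or ("interaction", g1, g2)


def _term_name(term: Term) -> str:
    if term[0] == "gene":
        return term[1]
    return f"{term[1]}:{term[2]}"


def _term_column(term: Term, X: pd.DataFrame) -> np.ndarray:
    for g in term[1:]:
        if g not in X.columns:
            raise KeyError(f"gene {g!r} missing from expression matrix")
    if term[0] == "gene":
        return X[term[1]].to_numpy(dtype=float)
    return (X[term[1]] * X[term[2]]).to_numpy(dtype=float)


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


class StepwiseAgeRegressor(BaseEstimator, RegressorMixin):
    """Forward-backward stepwise OLS of age on gene expression.

    Parameters
    ----------
    candidate_genes
        Columns of X eligible for selection; None means all columns.
    entry_p, removal_p
        Partial-F p-value thresholds for adding and dropping a term;
        requires entry_p < removal_p (otherwise add/remove cycles are
        possible).
    allow_interactions
        When True, pairwise products of already-selected genes join the
        candidate pool.
    max_terms
        Upper bound on selected gene/interaction terms.
    criterion
        'pvalue' (partial-F thresholds, default) or 'aic' (a term is added /
        removed when it lowers the AIC).

    Attributes (after fit)
    ----------------------
    terms_ : list of selected term names, in selection order
    coef_ : pd.Series of coefficients (intercept, covariate dummies, terms)
    r2_, adj_r2_ : fit statistics of the final model
    covariate_r2_ : R^2 of the covariate-only model
    """

    def __init__(
        self,
        candidate_genes: Sequence[str] | None = None,
        entry_p: float = 0.05,
        removal_p: float = 0.10,
        allow_interactions: bool = True,
        max_terms: int = 20,
        criterion: str = "pvalue",
    ):
        self.candidate_genes = candidate_genes
        self.entry_p = entry_p
        self.removal_p = removal_p
        self.allow_interactions = allow_interactions
        self.max_terms = max_terms
        self.criterion = criterion

    # -- internal helpers ---------------------------------------------------

    def _forced_design(self, covariates: pd.DataFrame | None, n: int):
        """Intercept + dummy-coded covariates, with redundant columns dropped."""
        cols = [np.ones(n)]
        names = ["intercept"]
        if covariates is not None:
            dummies = pd.get_dummies(covariates.astype("category"), drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(str(name))
        design = np.column_stack(cols)
        rank = np.linalg.matrix_rank(design)
        while rank < design.shape[1]:
            # drop the last column whose removal keeps the rank
            for j in range(design.shape[1] - 1, 0, -1):
                reduced = np.delete(design, j, axis=1)
                if np.linalg.matrix_rank(reduced) == rank:
                    warnings.warn(
                        f"dropping collinear covariate column {names[j]!r}",
                        stacklevel=2,
                    )
                    design = reduced
                    del names[j]
                    break
            rank = np.linalg.matrix_rank(design)
        return design, names

    def _candidates(self, selected: list[Term], genes: list[str]) -> list[Term]:
        in_model = set(selected)
        pool: list[Term] = [("gene", g) for g in genes if ("gene", g) not in in_model]
        if self.allow_interactions:
            sel_genes = [t[1] for t in selected if t[0] == "gene"]
            for i, g1 in enumerate(sel_genes):
                for g2 in sel_genes[i + 1 :]:
                    term = ("interaction", *sorted((g1, g2)))
                    if term not in in_model:
                        pool.append(term)
        return pool

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, covariates: pd.DataFrame | None = None):
        """Select terms and estimate the final OLS model.

        X is a samples x genes DataFrame (arrays get positional column
        names); y is age in years.
        """
        if self.entry_p >= self.removal_p:
            raise ValueError("entry_p must be < removal_p")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if self.criterion not in ("pvalue", "aic"):
            raise ValueError("criterion must be 'pvalue' or 'aic'")
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n < 10:
            raise ValueError("need at least 10 samples")
        if X.shape[0] != n:
            raise ValueError("X and y must have the same number of samples")
        if covariates is not None and len(covariates) != n:
            raise ValueError("covariates must align with samples")

        genes = (
            [str(g) for g in self.candidate_genes]
            if self.candidate_genes is not None
            else list(X.columns)
        )
        missing = [g for g in genes if g not in X.columns]
        if missing:
            raise KeyError(f"candidate genes missing from matrix: {missing}")

        forced, forced_names = self._forced_design(covariates, n)
        tss = float(((y - y.mean()) ** 2).sum())
        rss_forced = _rss(forced, y)
        self.covariate_r2_ = 1 - rss_forced / tss if tss > 0 else 0.0

        selected: list[Term] = []
        columns: list[np.ndarray] = []
        rss_cur = rss_forced
        just_removed: Term | None = None

        def aic(rss: float, k: int) -> float:
            return n * np.log(max(rss, 1e-300) / n) + 2 * k

        for _ in range(4 * self.max_terms + 4):
            changed = False
            design_cur = np.column_stack([forced] + columns) if columns else forced
            p_cur = design_cur.shape[1]

            # forward step
            if len(selected) < self.max_terms:
                best_term, best_stat, best_rss, best_col = None, np.inf, None, None
                for term in self._candidates(selected, genes):
                    if term == just_removed:
                        continue
                    col = _term_column(term, X)
                    trial = np.column_stack([design_cur, col])
                    df2 = n - (p_cur + 1)
                    if df2 <= 0:
                        continue
                    rss_new = _rss(trial, y)
                    if self.criterion == "aic":
                        stat = aic(rss_new, p_cur + 1)
                    else:
                        if rss_new <= 0:
                            stat = 0.0
                        else:
                            F = (rss_cur - rss_new) / (rss_new / df2)
                            stat = float(stats.f.sf(max(F, 0.0), 1, df2))
                    if stat < best_stat:
                        best_term, best_stat, best_rss, best_col = term, stat, rss_new, col
                accept = (
                    best_term is not None
                    and (
                        best_stat < self.entry_p
                        if self.criterion == "pvalue"
                        else best_stat < aic(rss_cur, p_cur)
                    )
                )
                if accept:
                    selected.append(best_term)
                    columns.append(best_col)
                    rss_cur = best_rss
                    design_cur = np.column_stack([forced] + columns)
                    p_cur = design_cur.shape[1]
                    changed = True
            just_removed = None

            # backward step (covariates are forced and never removable)
            if selected:
                worst_term, worst_stat, worst_idx = None, -np.inf, None
                df2 = n - p_cur
                for idx, term in enumerate(selected):
                    reduced = np.column_stack(
                        [forced] + [c for j, c in enumerate(columns) if j != idx]
                    )
                    rss_without = _rss(reduced, y)
                    if self.criterion == "aic":
                        stat = aic(rss_cur, p_cur) - aic(rss_without, p_cur - 1)
                    else:
                        if df2 <= 0 or rss_cur <= 0:
                            stat = -np.inf
                        else:
                            F = (rss_without - rss_cur) / (rss_cur / df2)
                            stat = float(stats.f.sf(max(F, 0.0), 1, df2))
                    if stat > worst_stat:
                        worst_term, worst_stat, worst_idx = term, stat, idx
                remove = (
                    worst_stat > self.removal_p
                    if self.criterion == "pvalue"
                    else worst_stat > 0
                )
                if remove:
                    just_removed = worst_term
                    del selected[worst_idx]
                    del columns[worst_idx]
                    design_cur = np.column_stack([forced] + columns) if columns else forced
                    rss_cur = _rss(design_cur, y)
                    changed = True

            if not changed:
                break

        design = np.column_stack([forced] + columns) if columns else forced
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        names = forced_names + [_term_name(t) for t in selected]
        self.coef_ = pd.Series(coef, index=names)
        self.terms_ = [_term_name(t) for t in selected]
        self._selected_terms = list(selected)
        self._forced_names = forced_names
        self._covariate_levels = (
            {c: covariates[c].astype("category").cat.categories for c in covariates}
            if covariates is not None
            else None
        )
        rss_final = _rss(design, y)
        self.r2_ = 1 - rss_final / tss if tss > 0 else 0.0
        k = design.shape[1]
        self.adj_r2_ = (
            1 - (1 - self.r2_) * (n - 1) / (n - k) if n > k else self.r2_
        )
        self.n_features_in_ = X.shape[1]
        self._train_mean_age = float(y.mean())
        return self

    def _design_for(self, X: pd.DataFrame, covariates: pd.DataFrame | None) -> np.ndarray:
        n = X.shape[0]
        cols = {"intercept": np.ones(n)}
        if self._covariate_levels is not None:
            if covariates is None:
                raise ValueError("model was fit with covariates; pass them to predict")
            dummies = pd.get_dummies(
                pd.DataFrame(
                    {
                        c: pd.Categorical(covariates[c], categories=lv)
                        for c, lv in self._covariate_levels.items()
                    }
                ),
                drop_first=True,
            )
            for name in dummies.columns:
                cols[str(name)] = dummies[name].to_numpy(dtype=float)
        for term in self._selected_terms:
            cols[_term_name(term)] = _term_column(term, X)
        return np.column_stack([cols[name] for name in self.coef_.index])

    def predict(self, X, covariates: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted age in years per sample."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("regressor is not fitted")
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        return self._design_for(X, covariates) @ self.coef_.to_numpy()


@dataclass
class AgeModelSpec:
    """Specification of one stepwise fit: candidates, covariates, thresholds."""

    candidate_genes: Sequence[str] | None = None
    covariates: pd.DataFrame | None = None
    allow_interactions: bool = True
    entry_p: float = 0.05
    removal_p: float = 0.10
    max_terms: int = 20
    criterion: str = "pvalue"


@dataclass
class AgeModelFit:
    """A fitted age model: selected terms, fit statistics, predictions."""

    model: StepwiseAgeRegressor
    terms: pd.DataFrame
    r2: float
    adj_r2: float
    covariate_r2: float
    predicted: pd.Series

    @property
    def n_gene_terms(self) -> int:
        return len(self.model.terms_)


def fit_stepwise_age_model(
    expression: pd.DataFrame, ages: Sequence[float], spec: AgeModelSpec | None = None
) -> AgeModelFit:
    """Fit the stepwise age model on a gene x sample expression matrix."""
    spec = spec or AgeModelSpec()
    model = StepwiseAgeRegressor(
        candidate_genes=spec.candidate_genes,
        entry_p=spec.entry_p,
        removal_p=spec.removal_p,
        allow_interactions=spec.allow_interactions,
        max_terms=spec.max_terms,
        criterion=spec.criterion,
    )
    X = expression.T
    model.fit(X, ages, covariates=spec.covariates)
    predicted = pd.Series(
        model.predict(X, covariates=spec.covariates), index=expression.columns,
        name="predicted_age",
    )
    terms = pd.DataFrame(
        {"term": model.coef_.index, "coefficient": model.coef_.to_numpy()}
    )
    return AgeModelFit(
        model=model,
        terms=terms,
        r2=model.r2_,
        adj_r2=model.adj_r2_,
        covariate_r2=model.covariate_r2_,
        predicted=predicted,
    )


def predict_age(
    fit: AgeModelFit, expression: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> pd.Series:
    """Predicted ages (years) for new samples of a gene x sample matrix."""
    return pd.Series(
        fit.model.predict(expression.T, covariates=covariates),
        index=expression.columns,
        name="predicted_age",
    )


def compare_celltype_models(fits: Mapping[str, AgeModelFit]) -> pd.DataFrame:
    """Rank per-cell-type fits by R^2 (ties broken by fewer gene terms)."""
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    rows = [
        {"cell_type": t, "r2": f.r2, "n_gene_terms": f.n_gene_terms}
        for t, f in fits.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        ["r2", "n_gene_terms", "cell_type"], ascending=[False, True, True],
        kind="mergesort",
    )
    return out.reset_index(drop=True)
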