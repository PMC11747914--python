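"""Nuisance removal: scanner batch (parametric empirical-Bayes location/scale
harmonization), sex (linear residualization) and age (cross-validated
polynomial residualization).

The batch model is the classic empirical-Bayes feature harmonization: regional
values are standardized per region, per-batch location (gamma) and scale
(delta^2) estimates are shrunk toward batch-level priors — a normal prior for
locations, an inverse-gamma prior for scales, hyperparameters by method of
moments — via the usual fixed-point iteration, and the data are adjusted as
``(z - gamma*) / delta*`` before unstandardizing.  Sex and age are removed in
their own least-squares steps, each preserving the per-region grand mean so
the corrected tables stay in physical units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold


@dataclass
class BatchModel:
    """Fitted batch-harmonization parameters (per batch x region)."""

    batches: np.ndarray          # unique batch identifiers, fitting order
    gamma_star: np.ndarray       # (n_batches, n_regions) additive, standardized units
    delta_star: np.ndarray       # (n_batches, n_regions) multiplicative, > 0
    gamma_hat: np.ndarray        # raw per-batch location estimates
    delta_hat_sq: np.ndarray     # raw per-batch scale estimates
    alpha: np.ndarray            # per-region grand mean
    sigma: np.ndarray            # per-region pooled SD
    regions: list

    def to_dict(self) -> dict:
        return {
            "batches": self.batches.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "alpha": self.alpha.tolist(),
            "sigma": self.sigma.tolist(),
            "regions": list(self.regions),
        }


@dataclass
class AgeModel:
    """Per-region polynomial age model selected by k-fold cross-validation."""

    degrees: np.ndarray          # selected degree per region, in {1,2,3}
    coefficients: list           # per-region polyfit coefficients (highest power first)
    cv_errors: np.ndarray        # (n_regions, 3) mean CV MSE for degrees 1..3
    age_mean: float
    age_scale: float
    regions: list

    def to_dict(self) -> dict:
        return {
            "degrees": self.degrees.tolist(),
            "coefficients": [c.tolist() for c in self.coefficients],
            "cv_errors": self.cv_errors.tolist(),
            "age_mean": self.age_mean,
            "age_scale": self.age_scale,
            "regions": list(self.regions),
        }


def _aprior(gamma_hat_row: np.ndarray) -> tuple[float, float]:
    return float(np.mean(gamma_hat_row)), float(np.var(gamma_hat_row, ddof=1))


def _ig_priors(delta_sq_row: np.ndarray) -> tuple[float, float]:
    # method-of-moments inverse-gamma hyperparameters
    m = np.mean(delta_sq_row)
    v = np.var(delta_sq_row, ddof=1)
    if v <= 1e-12:
        return 2.0 + 1e6, (1e6 + 1.0) * m  # near-degenerate prior pinned at m
    lam = (2 * v + m**2) / v
    theta = (m * v + m**3) / v
    return float(lam), float(theta)


def combat_fit(table: pd.DataFrame, batch, *, tol: float = 1e-4, max_iter: int = 100) -> BatchModel | None:
    """Fit the empirical-Bayes batch model on a participants x regions table.

    Returns ``None`` (after a warning) when only one batch is present: with a
    single scanner there is nothing to harmonize and application is a no-op.
    """
    batch = np.asarray(batch)
    if batch.shape[0] != table.shape[0]:
        raise ValueError("batch assignment length must match table rows")
    values = table.to_numpy(dtype=float)
    batches, counts = np.unique(batch, return_counts=True)
    if batches.size == 1:
        warnings.warn("single batch: harmonization is a no-op", stacklevel=2)
        return None
    singletons = batches[counts < 3]
    if singletons.size:
        raise ValueError(f"batch {singletons[0]!r} has fewer than 3 participants")

    sds = values.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sds < 1e-12)
    if zero_var.size:
        raise ValueError(f"region {table.columns[zero_var[0]]!r} has zero variance")

    # standardize: grand mean weighted by batch size, pooled residual variance
    batch_means = np.stack([values[batch == b].mean(axis=0) for b in batches])
    weights = counts / counts.sum()
    alpha = weights @ batch_means
    resid = values - batch_means[np.searchsorted(batches, batch)]
    sigma = np.sqrt((resid**2).mean(axis=0))
    sigma = np.maximum(sigma, 1e-12)
    z = (values - alpha) / sigma

    gamma_hat = np.stack([z[batch == b].mean(axis=0) for b in batches])
    # ddof=0 to match the pooled-variance standardization: with no batch
    # effect, delta_hat is exactly 1
    delta_hat_sq = np.stack([z[batch == b].var(axis=0) for b in batches])

    gamma_star = np.empty_like(gamma_hat)
    delta_star_sq = np.empty_like(delta_hat_sq)
    for bi, b in enumerate(batches):
        n_b = counts[bi]
        g_bar, tau_sq = _aprior(gamma_hat[bi])
        lam, theta = _ig_priors(delta_hat_sq[bi])
        zb = z[batch == b]
        g = gamma_hat[bi].copy()
        d = delta_hat_sq[bi].copy()
        for _ in range(max_iter):
            g_new = (n_b * tau_sq * gamma_hat[bi] + d * g_bar) / (n_b * tau_sq + d)
            ssq = ((zb - g_new) ** 2).sum(axis=0)
            d_new = (theta + 0.5 * ssq) / (n_b / 2 + lam - 1)
            change = max(np.abs(g_new - g).max(), np.abs(d_new - d).max())
            g, d = g_new, d_new
            if change < tol:
                break
        gamma_star[bi] = g
        delta_star_sq[bi] = d

    return BatchModel(
        batches=batches,
        gamma_star=gamma_star,
        delta_star=np.sqrt(delta_star_sq),
        gamma_hat=gamma_hat,
        delta_hat_sq=delta_hat_sq,
        alpha=alpha,
        sigma=sigma,
        regions=list(table.columns),
    )


def combat_apply(table: pd.DataFrame, model: BatchModel | None, batch) -> pd.DataFrame:
    """Adjust a table with a fitted batch model; identity when model is None."""
    if model is None:
        return table.copy()
    if list(table.columns) != list(model.regions):
        raise ValueError("region set differs from the one the model was fitted on")
    batch = np.asarray(batch)
    idx = np.searchsorted(model.batches, batch)
    if not np.all(model.batches[idx] == batch):
        raise ValueError("batch labels not seen during fitting")
    z = (table.to_numpy(dtype=float) - model.alpha) / model.sigma
    z_adj = (z - model.gamma_star[idx]) / model.delta_star[idx]
    return pd.DataFrame(z_adj * model.sigma + model.alpha, index=table.index, columns=table.columns)


def residualize_sex(table: pd.DataFrame, sex) -> pd.DataFrame:
    """Remove a linear sex effect per region, keeping each region's grand mean."""
    sex = np.asarray(sex, dtype=float)
    if np.unique(sex).size < 2:
        raise ValueError("both sexes must be present to residualize sex")
    values = table.to_numpy(dtype=float)
    x = sex - sex.mean()
    slope = (x @ (values - values.mean(axis=0))) / (x @ x)
    resid = values - np.outer(x, slope)
    return pd.DataFrame(resid, index=table.index, columns=table.columns)


def fit_age_model(table: pd.DataFrame, age, n_folds: int = 5, seed: int = 0,
                  rel_tol: float = 0.01) -> AgeModel:
    """Select, per region, the best of linear/quadratic/cubic age trends by CV.

    Mean squared prediction error over shuffled k-folds; the lowest degree
    whose CV error is within ``rel_tol`` (relative) of the minimum is
    selected — CV errors of nested polynomials are near-tied whenever the
    higher-order terms are null, and parsimony breaks those ties.  Age is
    centred and scaled before fitting for conditioning only.
    """
    age = np.asarray(age, dtype=float)
    if np.unique(age).size < 4:
        raise ValueError("age must take at least 4 distinct values")
    if table.shape[0] < 3 * n_folds:
        raise ValueError("need at least 3*n_folds participants")
    values = table.to_numpy(dtype=float)
    mean, scale = float(age.mean()), float(age.std() + 1e-12)
    a = (age - mean) / scale

    degrees_grid = (1, 2, 3)
    cv_err = np.zeros((values.shape[1], len(degrees_grid)))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(a):
        for di, deg in enumerate(degrees_grid):
            # one vandermonde solve for all regions at once
            coef = np.polynomial.polynomial.polyfit(a[train], values[train], deg)
            pred = np.polynomial.polynomial.polyval(a[test], coef).T
            cv_err[:, di] += ((values[test] - pred) ** 2).mean(axis=0)
    cv_err /= n_folds

    near_tie = cv_err <= (cv_err.min(axis=1, keepdims=True) * (1.0 + rel_tol))
    selected = near_tie.argmax(axis=1)  # lowest degree within tolerance of the minimum
    coefficients = []
    for r in range(values.shape[1]):
        deg = degrees_grid[selected[r]]
        coefficients.append(np.polynomial.polynomial.polyfit(a, values[:, r], deg))
    return AgeModel(
        degrees=np.array([degrees_grid[s] for s in selected]),
        coefficients=coefficients,
        cv_errors=cv_err,
        age_mean=mean,
        age_scale=scale,
        regions=list(table.columns),
    )


def residualize_age(table: pd.DataFrame, model: AgeModel, age) -> pd.DataFrame:
    """Subtract each region's fitted polynomial trend, restoring the grand mean."""
    if list(table.columns) != list(model.regions):
        raise ValueError("region set differs from the one the model was fitted on")
    age = np.asarray(age, dtype=float)
    a = (age - model.age_mean) / model.age_scale
    values = table.to_numpy(dtype=float)
    out = np.empty_like(values)
    for r, coef in enumerate(model.coefficients):
        pred = np.polynomial.polynomial.polyval(a, coef)
        out[:, r] = values[:, r] - pred + values[:, r].mean()
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def harmonize_table(
    table: pd.DataFrame,
    batch,
    sex,
    age,
    *,
    n_folds: int = 5,
    seed: int = 0,
):
    """Full correction chain in pipeline order: batch, then sex, then age.

    Returns the corrected table together with the fitted batch and age models.
    """
    batch_model = combat_fit(table, batch) if np.unique(np.asarray(batch)).size > 1 else None
    if batch_model is None and np.unique(np.asarray(batch)).size == 1:
        warnings.warn("single batch: skipping batch harmonization", stacklevel=2)
    corrected = combat_apply(table, batch_model, batch)
    corrected = residualize_sex(corrected, sex)
    age_model = fit_age_model(corrected, age, n_folds=n_folds, seed=seed)
    corrected = residualize_age(corrected, age_model, age)
    return corrected, batch_model, age_model
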