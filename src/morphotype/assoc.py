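"""Single-participant structural-association graphs.

Structural covariance is a population construct: the correlation of a
morphometric measure between two regions across participants.  To obtain a
*per-participant* analogue, each region pair is regressed across the whole
cohort and every participant's influence on that pooled line is measured with
Cook's distance; a Gaussian kernel turns the (direction-averaged) distance
into an edge weight in (0, 1].  Each participant thus receives one complete
weighted graph over regions per structural measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

P_PARAMS = 2  # predictors in a simple regression: intercept + slope


@dataclass
class PairRegression:
    """Pooled OLS of region b on region a with per-participant diagnostics."""

    region_a: str
    region_b: str
    slope: float
    intercept: float
    residuals: np.ndarray    # e_i
    leverage: np.ndarray     # h_ii of the hat matrix of [1, x]
    s2: float                # residual variance, denominator n - 2


@dataclass
class KernelParams:
    """Gaussian bandwidth for mapping deviations to edge weights."""

    sigma: float
    rule: str = "median"


def fit_pair_regression(x, y, region_a: str = "a", region_b: str = "b") -> PairRegression:
    """OLS of y on x with leverages and residual variance (n - 2 denominator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 participants per pair regression")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx < 1e-12:
        raise ValueError(f"region {region_a!r} is constant; cannot regress pair ({region_a}, {region_b})")
    slope = (xc @ y) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    leverage = 1.0 / n + xc**2 / sxx
    s2 = (resid @ resid) / (n - P_PARAMS)
    return PairRegression(region_a, region_b, float(slope), float(intercept), resid, leverage, float(s2))


def cooks_distance(fit: PairRegression, i: int | None = None):
    """Cook's distance D = e^2 h / (p s^2 (1-h)^2), p = 2; all zero on a perfect fit."""
    h = fit.leverage
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("leverage of 1: degenerate design point")
    if fit.s2 < 1e-12:
        d = np.zeros_like(fit.residuals)
    else:
        d = fit.residuals**2 * h / (P_PARAMS * fit.s2 * (1.0 - h) ** 2)
    return d if i is None else float(d[i])


def pairwise_deviations(table: pd.DataFrame) -> np.ndarray:
    """Direction-averaged Cook's distances for every region pair, vectorized.

    Returns an (n_participants, R, R) array D with D[:, a, b] the mean of the
    Cook's distances from regressing b on a and a on b; the diagonal is 0.
    Perfect-fit pairs (residual variance ~ 0) contribute zero deviation for
    every participant, with a warning.
    """
    values = table.to_numpy(dtype=float)
    n, n_regions = values.shape
    if n < 4:
        raise ValueError("need at least 4 participants")
    xc = values - values.mean(axis=0)
    sxx = (xc**2).sum(axis=0)
    const = np.flatnonzero(sxx < 1e-12)
    if const.size:
        raise ValueError(f"region {table.columns[const[0]]!r} is constant")

    sxy = xc.T @ xc                                   # (R, R) cross products
    slope = sxy / sxx[:, None]                        # slope[a, b]: b ~ a
    # residuals e[i, a, b] = yc[i, b] - slope[a, b] * xc[i, a]
    resid = xc[:, None, :] - slope[None, :, :] * xc[:, :, None]
    h = 1.0 / n + xc**2 / sxx                         # (n, R) leverage wrt predictor a
    s2 = (resid**2).sum(axis=0) / (n - P_PARAMS)      # (R, R)
    degenerate = s2 < 1e-12
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        warnings.warn("perfect-fit region pair(s): deviations set to 0 (weight 1)", stacklevel=2)
    s2_safe = np.where(s2 < 1e-12, 1.0, s2)
    hh = h[:, :, None]
    d = resid**2 * hh / (P_PARAMS * s2_safe[None] * (1.0 - hh) ** 2)
    d[:, degenerate] = 0.0
    d_sym = 0.5 * (d + d.transpose(0, 2, 1))
    idx = np.arange(n_regions)
    d_sym[:, idx, idx] = 0.0
    return d_sym


def choose_sigma(deviations: np.ndarray, rule: str = "median", fixed: float | None = None) -> KernelParams:
    """Bandwidth for the deviation-to-similarity Gaussian kernel.

    Default rule: median of the strictly positive deviations pooled over all
    pairs and participants of the measure.  ``fixed`` overrides the data.
    """
    if rule == "fixed" or fixed is not None:
        if not fixed or fixed <= 0:
            raise ValueError("fixed sigma must be positive")
        return KernelParams(sigma=float(fixed), rule="fixed")
    if rule != "median":
        raise ValueError(f"unknown bandwidth rule {rule!r}")
    pos = deviations[deviations > 0]
    if pos.size == 0:
        warnings.warn("all deviations are zero; sigma set to 1", stacklevel=2)
        return KernelParams(sigma=1.0, rule="median")
    return KernelParams(sigma=float(np.median(pos)), rule="median")


def build_participant_graphs(table: pd.DataFrame, params: KernelParams | None = None):
    """One complete weighted graph per participant for one structural measure.

    Edge weight = exp(-D^2 / (2 sigma^2)) of the direction-averaged Cook's
    distance D; weights lie in (0, 1] with 1 meaning the participant sits on
    the pooled regression line of that pair.  Returns an
    (n_participants, R, R) stack of symmetric weight matrices (unit diagonal)
    and the kernel parameters used.
    """
    deviations = pairwise_deviations(table)
    if params is None:
        params = choose_sigma(deviations)
    weights = np.exp(-(deviations**2) / (2.0 * params.sigma**2))
    # extreme outliers underflow exp to 0; clamp so weights stay in (0, 1]
    weights = np.maximum(weights, 1e-12)
    idx = np.arange(weights.shape[1])
    weights[:, idx, idx] = 1.0
    return weights, params


def graphs_to_long(weights: np.ndarray, participant_ids, regions, measure: str) -> pd.DataFrame:
    """Serialize a graph stack as long-format rows (one per participant-edge)."""
    n, r, _ = weights.shape
    ia, ib = np.triu_indices(r, k=1)
    records = {
        "participant_id": np.repeat(list(participant_ids), ia.size),
        "measure": measure,
        "region_a": np.tile(np.asarray(regions)[ia], n),
        "region_b": np.tile(np.asarray(regions)[ib], n),
        "weight": weights[:, ia, ib].ravel(),
    }
    return pd.DataFrame(records)
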