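"""Household asset wealth index and weighted quintile assignment.

Mirrors the DHS/MICS construction: within each country the household
asset indicators (ownership of goods, dwelling characteristics, water and
sanitation) are standardised with household weights and the first
principal component is taken as the wealth score; households are then
ranked into weighted quintiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def build_wealth_index(indicators, weights=None) -> np.ndarray:
    """First principal component of the weighted, standardised asset matrix.

    Parameters
    ----------
    indicators : array-like of shape (n_households, n_indicators)
        Binary/ordinal asset codes.  At least one indicator must vary.
    weights : array-like of positive household weights, optional

    The component is oriented so higher scores go with owning more assets
    (positive correlation with the indicator row sum).
    """
    X = np.asarray(indicators, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 households")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("household weights must be positive")
    w = w / w.sum()

    mean = w @ X
    var = w @ (X - mean) ** 2
    scale = np.maximum(w @ X ** 2, 1.0)
    keep = var > 1e-12 * scale
    if not keep.any():
        raise ValueError("degenerate assets: no indicator has nonzero variance")
    Z = (X[:, keep] - mean[keep]) / np.sqrt(var[keep])

    # weighted correlation matrix of the kept indicators
    R = (Z * w[:, None]).T @ Z
    eigval, eigvec = np.linalg.eigh(R)
    v = eigvec[:, -1]
    score = Z @ v

    total = X.sum(axis=1)
    orient = np.cov(score, total, aweights=w)[0, 1]
    if orient < 0:
        score = -score
    return score


def assign_quintiles(scores, weights) -> np.ndarray:
    """Weighted quintile labels 1 (poorest) .. 5 (richest).

    A household's label is determined by the weighted empirical CDF at its
    score using the midpoint convention (cumulative weight below its score
    plus half the weight tied at its score), so a heavy household that
    straddles a boundary gets the quintile containing its CDF midpoint.
    Tied scores always receive the same label.  Scale-invariant in weights
    and invariant to increasing transforms of scores.
    """
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise ValueError("scores and weights must have the same length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if np.ptp(s) == 0:
        raise ValueError("all scores identical: no ordering to rank")

    total = w.sum()
    values, inverse = np.unique(s, return_inverse=True)
    group_w = np.bincount(inverse, weights=w, minlength=len(values))
    cum = np.cumsum(group_w)
    midpoints = (cum - group_w / 2.0) / total
    labels_by_group = np.clip(np.ceil(midpoints * 5.0), 1, 5).astype(int)
    return labels_by_group[inverse]
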