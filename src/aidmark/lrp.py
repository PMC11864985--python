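"""Layer-wise relevance propagation (generalized gamma rule) for the risk net.

The predicted risk of a patient is redistributed backwards through the
network, layer by layer, onto the input markers.  For a neuron k with
activation a_k and incoming weights w_jk (including the bias as a unit neuron
a_0 = 1), relevance flows to the layer below as

    R_j = sum_k  [a_j+ (w_jk + g*w_jk+) + a_j- (w_jk + g*w_jk-)]
               / [sum_{0,j} a_j+ (w_jk + g*w_jk+) + a_j- (w_jk + g*w_jk-)]
               * 1{a_k > 0} * R_k
        + sum_k  [a_j+ (w_jk + g*w_jk-) + a_j- (w_jk + g*w_jk+)]
               / [sum_{0,j} a_j+ (w_jk + g*w_jk-) + a_j- (w_jk + g*w_jk+)]
               * 1{a_k < 0} * R_k

with (.)+ = max(0,.), (.)- = min(0,.), and g >= 0 the gamma parameter
(default 0.01).  Neurons with a_k = 0 propagate nothing.  The bias share of
each denominator is accumulated per patient into ``bias_absorbed`` so that

    sum_markers RC + bias_absorbed = predicted risk

holds exactly (up to floating point).  No epsilon stabilizer is added to the
denominators; a zero denominator with nonzero incoming relevance is routed to
``bias_absorbed`` and logged.

The relevance collected at an input column is the column's share of the risk;
for feature-expanded markers, the final risk contribution (RC) of the marker
is the sum over its (x, 1-x) pair.  A missing input (0, 0) receives exactly
zero relevance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxnn import CoxNet

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.01


def _branch_weights(w: np.ndarray, gamma: float, sign_matched: bool) -> np.ndarray:
    return w + gamma * (np.maximum(w, 0.0) if sign_matched else np.minimum(w, 0.0))


def lrp_backward(net: CoxNet, X: np.ndarray, gamma: float = DEFAULT_GAMMA):
    """Propagate predicted risk back to the expanded input columns.

    Returns ``(relevance, bias_absorbed, risk)`` where ``relevance`` has one
    column per expanded input column.  Accepts a single row or a matrix; rows
    are independent (the output does not depend on evaluation order).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out, _, A1 = net.forward(X)
    n, d = X.shape
    bias_absorbed = np.zeros(n)

    # --- output layer -> hidden layer -------------------------------------
    # hidden activations are nonnegative (ReLU), so only the a_j+ terms carry;
    # the branch is chosen by the sign of the output activation a_k = risk.
    w2 = net.W2
    pos = out > 0
    Wsel = np.where(pos[:, None], _branch_weights(w2, gamma, True)[None, :],
                    _branch_weights(w2, gamma, False)[None, :])
    bsel = np.where(pos, _branch_weights(np.array([net.b2]), gamma, True)[0],
                    _branch_weights(np.array([net.b2]), gamma, False)[0])
    N1 = A1 * Wsel                      # (n, hidden)
    D1 = bsel + N1.sum(axis=1)          # (n,)
    zero_den = (D1 == 0) & (out != 0)
    if zero_den.any():
        logger.warning("LRP: zero denominator at output layer for %d patients; "
                       "relevance routed to bias_absorbed", int(zero_den.sum()))
        bias_absorbed[zero_den] += out[zero_den]
    ratio = np.divide(out, D1, out=np.zeros(n), where=(D1 != 0) & ~zero_den)
    R1 = N1 * ratio[:, None]
    bias_absorbed += np.where((D1 != 0) & ~zero_den, bsel * ratio, 0.0)

    # --- hidden layer -> input layer ---------------------------------------
    # a_k > 0 branch only (ReLU); a_k = 0 neurons carry R1 = 0 already.
    Xp, Xm = np.maximum(X, 0.0), np.minimum(X, 0.0)
    P1 = _branch_weights(net.W1, gamma, True)    # (d, hidden)
    P2 = _branch_weights(net.W1, gamma, False)
    bb1 = _branch_weights(net.b1, gamma, True)   # (hidden,)
    D0 = bb1 + Xp @ P1 + Xm @ P2                 # (n, hidden)
    active = (A1 > 0) & (R1 != 0)
    zero_den0 = active & (D0 == 0)
    if zero_den0.any():
        logger.warning("LRP: zero denominator at hidden layer for %d neuron slots; "
                       "relevance routed to bias_absorbed", int(zero_den0.sum()))
        bias_absorbed += np.where(zero_den0, R1, 0.0).sum(axis=1)
    c = np.divide(R1, D0, out=np.zeros_like(R1), where=active & (D0 != 0))
    relevance = Xp * (c @ P1.T) + Xm * (c @ P2.T)  # (n, d)
    bias_absorbed += c @ bb1
    return relevance, bias_absorbed, out


@dataclass
class RelevanceMatrix:
    """Per-patient, per-marker risk contributions (RC).

    Positive RC means the marker pushed the patient's predicted risk toward an
    adverse outcome; negative toward a favorable one.  ``bias_absorbed`` is
    the per-patient relevance taken up by bias terms, reported separately
    rather than redistributed, so ``rc.sum(axis=1) + bias_absorbed`` equals
    the predicted risk.
    """

    rc: pd.DataFrame
    bias_absorbed: pd.Series
    risk: pd.Series
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self):
        if not np.isfinite(self.rc.to_numpy()).all():
            raise ValueError("non-finite risk contributions")

    @property
    def markers(self) -> list[str]:
        return list(self.rc.columns)


def collapse_expanded(relevance: np.ndarray, colmap: list[tuple[str, str]]) -> pd.DataFrame:
    """Sum expanded-column relevances back to one RC per marker."""
    relevance = np.atleast_2d(relevance)
    if relevance.shape[1] != len(colmap):
        raise ValueError("relevance width does not match colmap")
    markers: list[str] = []
    for m, _ in colmap:
        if m not in markers:
            markers.append(m)
    out = np.zeros((relevance.shape[0], len(markers)))
    pos = {m: i for i, m in enumerate(markers)}
    for col, (m, _) in enumerate(colmap):
        out[:, pos[m]] += relevance[:, col]
    return pd.DataFrame(out, columns=markers)


def explain_cohort(net: CoxNet, X: np.ndarray, colmap: list[tuple[str, str]],
                   gamma: float = DEFAULT_GAMMA, index: pd.Index | None = None) -> RelevanceMatrix:
    """Row-wise LRP over a cohort, collapsed to per-marker risk contributions."""
    relevance, bias_absorbed, risk = lrp_backward(net, X, gamma=gamma)
    rc = collapse_expanded(relevance, colmap)
    if index is not None:
        rc.index = index
    return RelevanceMatrix(
        rc=rc,
        bias_absorbed=pd.Series(bias_absorbed, index=rc.index, name="bias_absorbed"),
        risk=pd.Series(risk, index=rc.index, name="risk"),
        gamma=gamma,
    )


@dataclass
class RiskGroups:
    """Quantile-based risk strata (1 = lowest risk .. k = highest)."""

    group: np.ndarray
    boundaries: np.ndarray
    k: int


def stratify_risk(risks, k: int = 5) -> RiskGroups:
    """Split patients into k near-equal risk groups ordered by predicted risk.

    Ties at a boundary are broken by stable patient order.
    """
    risks = np.asarray(risks, dtype=float)
    n = len(risks)
    if k < 1 or k > n:
        raise ValueError(f"cannot form {k} groups from {n} patients")
    order = np.argsort(risks, kind="stable")
    group = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, k), start=1):
        group[chunk] = g
    boundaries = np.quantile(risks, np.linspace(0, 1, k + 1))
    return RiskGroups(group=group, boundaries=boundaries, k=k)
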