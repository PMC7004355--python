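"""Monotone fusion of per-residue features into a catalytic-likelihood score.

Residue ranking combines several per-residue features — an electrostatic
titration-curve anomaly score, a sequence-conservation score, and a pocket
geometry score, each oriented so that larger means more functional-like —
into a single probability-like score that is *monotone* in every feature:
if residue A dominates residue B componentwise, A's score is never lower.

The estimator is least-squares isotonic regression over the componentwise
partial order. The exact projection onto the monotone cone is computed by
recursive block partitioning: each block is split by a maximum-weight
closure (solved as a min-cut / max-flow problem on the dominance DAG) until
no improving split exists; the fitted value of a final block is its mean.
In one dimension this reduces exactly to pool-adjacent-violators.

Prediction for a new feature vector is conservative: the maximum fitted
value over dominated training points, or 0 when none is dominated. Scores
are normalized by the maximum so the top residue scores 1.00, and residues
with a normalized score >= 0.01 (default cutoff) are predicted to be
functionally important.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MonotoneModel",
    "fit_monotone",
    "isotonic_fit",
    "score_and_normalize",
    "apply_cutoff",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 0.01


def _dominance_edges(X: np.ndarray) -> list[tuple[int, int]]:
    """Edges i -> j whenever x_i <= x_j componentwise (i != j).

    The transitive closure is harmless for the min-cut; no reduction is
    attempted.
    """
    n = len(X)
    edges = []
    for i in range(n):
        le = (X[i] <= X).all(axis=1) & ~(X[i] == X).all(axis=1)
        for j in np.nonzero(le)[0]:
            edges.append((i, int(j)))
    # equal feature vectors: tie them both ways so they share a block value
    for i in range(n):
        eq = (X[i] == X).all(axis=1)
        for j in np.nonzero(eq)[0]:
            if j != i:
                edges.append((i, int(j)))
    return edges


def _max_weight_upper_set(nodes: list[int], edges: list[tuple[int, int]], w: np.ndarray):
    """Maximum-weight subset U of ``nodes`` closed under dominance
    successors (i in U and i -> j implies j in U), by min-cut.

    Returns (U, weight of U).
    """
    node_set = set(nodes)
    pos = [i for i in nodes if w[i] > 0]
    neg = [i for i in nodes if w[i] < 0]
    if not pos:
        return [], 0.0
    if not neg:
        return list(nodes), float(w[list(nodes)].sum())
    G = nx.DiGraph()
    S, T = "src", "snk"
    big = float(np.abs(w[list(nodes)]).sum()) + 1.0
    for i in pos:
        G.add_edge(S, i, capacity=float(w[i]))
    for i in neg:
        G.add_edge(i, T, capacity=float(-w[i]))
    for i, j in edges:
        if i in node_set and j in node_set:
            G.add_edge(i, j, capacity=big)
    _, (s_side, _) = nx.minimum_cut(G, S, T)
    U = [i for i in nodes if i in s_side]
    return U, (float(w[U].sum()) if U else 0.0)


def isotonic_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact least-squares isotonic fit of y over the componentwise partial
    order of the rows of X. Returns fitted values (same length as y)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    edges = _dominance_edges(X)
    fitted = np.empty_like(y)

    def solve(block: list[int]):
        m = float(y[block].mean())
        if len(block) == 1:
            fitted[block[0]] = m
            return
        U, weight = _max_weight_upper_set(block, edges, y - m)
        if weight <= 1e-12 or not U or len(U) == len(block):
            for i in block:
                fitted[i] = m
            return
        L = [i for i in block if i not in set(U)]
        solve(L)
        solve(U)

    solve(list(range(len(y))))
    return fitted


@dataclass
class MonotoneModel:
    """Fitted monotone regression: training features + fitted values."""

    X: np.ndarray
    fitted: np.ndarray

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Max of fitted values over dominated training points; 0 if none.

        Monotone in the features by construction.
        """
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.X.shape[1]:
            raise ValueError("feature dimension mismatch")
        out = np.zeros(len(X_new))
        for k, x in enumerate(X_new):
            dominated = (self.X <= x).all(axis=1)
            if dominated.any():
                out[k] = self.fitted[dominated].max()
        return out


def fit_monotone(features: np.ndarray, labels: np.ndarray) -> MonotoneModel:
    """Fit the monotone (isotonic) model on training features and binary or
    graded labels."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 training items")
    if not np.isfinite(X).all():
        bad = np.nonzero(~np.isfinite(X).all(axis=1))[0]
        raise ValueError(f"non-finite features for items {bad.tolist()}")
    if not np.isfinite(y).all():
        raise ValueError("non-finite labels")
    return MonotoneModel(X=X.copy(), fitted=isotonic_fit(X, y))


def score_and_normalize(
    model: MonotoneModel,
    features: pd.DataFrame,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Score residues, normalize by the maximum raw score and rank.

    ``features`` needs a ``res_num`` column plus the feature columns. The
    top score normalizes to exactly 1.0; ranks are by descending normalized
    score with ties broken by ascending residue number.
    """
    df = features.copy()
    if feature_columns is None:
        feature_columns = [c for c in df.columns if c not in ("chain", "res_num", "res_name")]
    raw = model.predict(df[feature_columns].to_numpy(dtype=float))
    df["raw"] = raw
    top = raw.max()
    if top <= 0:
        warnings.warn("all raw scores are zero; normalization skipped")
        df["normalized"] = 0.0
    else:
        df["normalized"] = raw / top
    order = df.sort_values(["normalized", "res_num"], ascending=[False, True]).index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
    df["rank"] = ranks
    return df.sort_values("rank").reset_index(drop=True)


def apply_cutoff(scores: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Residues with normalized score >= cutoff, in rank order.

    Idempotent and order-preserving; an empty result is allowed.
    """
    kept = scores[scores["normalized"] >= cutoff]
    return kept.sort_values("rank").reset_index(drop=True)
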