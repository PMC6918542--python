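"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pmfmda.io import AssociationMatrix, DiseaseOntology
from pmfmda.model import Hyperparams


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)

def semantic_contribution_oracle(codes: set[str], delta: float) -> dict[str, float]:
    """Brute-force semantic contributions by enumerating all downward paths.

    For each node t of the prefix-closed DAG, walk every child chain within
    the DAG down to one of the disease's own codes and take the max of
    delta**path_length.
    """
    closure: set[str] = set()
    for c in codes:
        parts = c.split(".")
        for k in range(1, len(parts) + 1):
            closure.add(".".join(parts[:k]))

    def children(t):
        return [c for c in closure
                if c.rpartition(".")[0] == t and c != t]

    def best(t):
        if t in codes:
            return 1.0
        vals = [delta * best(c) for c in children(t)]
        return max(vals) if vals else 0.0

    return {t: best(t) for t in closure}


def auc_pair_count_oracle(scores, labels) -> float:
    """Exhaustive Mann-Whitney concordant-pair count, half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def average_precision_oracle(scores, labels) -> float:
    """Per-rank average precision with tied scores grouped at one threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        kept = scores >= thr
        tp = int(labels[kept].sum())
        precision = tp / int(kept.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def als_oracle(Y, U, V, lam_u, lam_v, iters=20000, tol=1e-14):
    """Closed-form alternating ridge regression for the lambda_1=lambda_2=0,
    all-ones-mask objective."""
    D = U.shape[0]
    prev = None
    for _ in range(iters):
        U = np.linalg.solve(V @ V.T + lam_u * np.eye(D), V @ Y.T)
        V = np.linalg.solve(U @ U.T + lam_v * np.eye(D), U @ Y)
        e = (0.5 * ((Y - U.T @ V) ** 2).sum()
             + 0.5 * lam_u * (U ** 2).sum() + 0.5 * lam_v * (V ** 2).sum())
        if prev is not None and abs(prev - e) / max(prev, 1e-300) < tol:
            break
        prev = e
    return U, V


def random_code_sets(rng, max_nodes=12, n_diseases=2):
    """Random prefix-closable tree-code sets with small alphabets, so the
    resulting DAGs stay under ``max_nodes`` nodes."""
    segments = ["A", "B", "C"]
    out = []
    for _ in range(n_diseases):
        codes = set()
        for _ in range(int(rng.integers(1, 4))):
            depth = int(rng.integers(1, 5))
            codes.add(".".join(rng.choice(segments) for _ in range(depth)))
        closure = set()
        for c in codes:
            parts = c.split(".")
            closure.update(".".join(parts[:k]) for k in range(1, len(parts) + 1))
        if len(closure) <= max_nodes:
            out.append(codes)
    return out or [{"A"}]


def random_instance(rng, n_max=10, m_max=10, d_max=4):
    """A random small model instance (Y, mask, U, V, S_m, S_d, hp)."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(2, m_max + 1))
    d = int(rng.integers(1, d_max + 1))
    Y = (rng.random((n, m)) < 0.3).astype(float)
    mask = np.ones((n, m)) if rng.random() < 0.5 else (rng.random((n, m)) < 0.8).astype(float)
    mask[Y == 1] = 1.0
    U = rng.uniform(0.05, 1.0, (d, n))
    V = rng.uniform(0.05, 1.0, (d, m))

    def sim(k):
        a = rng.uniform(size=(k, k))
        s = (a + a.T) / 2
        np.fill_diagonal(s, 1.0)
        return s

    hp = Hyperparams(latent_dim=d,
                     lambda_u=float(rng.uniform(0.01, 1.5)),
                     lambda_v=float(rng.uniform(0.01, 1.5)),
                     lambda_1=float(rng.uniform(0.0, 0.05)),
                     lambda_2=float(rng.uniform(0.0, 0.05)),
                     seed=int(rng.integers(2 ** 16)))
    return Y, mask, U, V, sim(n), sim(m), hp


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def chain_ontology() -> DiseaseOntology:
    """d1 and d2 are siblings under ancestor A; c is a deep chain leaf."""
    return DiseaseOntology({
        "d1": {"A.B"},
        "d2": {"A.C"},
        "c": {"A.B.C"},
    })


@pytest.fixture
def tiny_assoc() -> AssociationMatrix:
    values = np.array([
        [1, 1, 0],
        [0, 1, 0],
        [1, 0, 1],
        [0, 0, 1],
    ], dtype=float)
    return AssociationMatrix([f"m{i}" for i in range(4)],
                             [f"d{j}" for j in range(3)], values)
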