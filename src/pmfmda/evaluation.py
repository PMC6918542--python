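"""Cross-validation protocols and ranking metrics.

Three protocols probe different prediction regimes:

* **global LOOCV** — each known association is removed in turn, the model
  is refit on the rest, and the removed pair is ranked against all unknown
  pairs;
* **global k-fold CV** (k = 5 by default) — the known associations are
  shuffled and partitioned into k near-equal subsets, each held out once;
  a per-disease variant stratifies the partition within one disease's
  column;
* **CV_d (leave-disease-out)** — an entire disease column is deleted from
  training, emulating a novel disease with no known miRNAs; hit counts at
  ranking thresholds over the held-out column are reported alongside
  AUC/AUPR.

Similarities are recomputed from the training matrix of every fold so that
held-out associations never leak into the kernels or the functional
similarity.  AUC uses the rank-sum (Mann-Whitney) convention with ties
counted one half; AUPR uses the non-interpolated step rule (average
precision).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .io import AssociationMatrix
from .model import PMFMDA, Hyperparams
from .similarity import build_similarities


@dataclass
class FoldSplit:
    """One train/test split of the known associations."""

    protocol: str
    fold_id: int
    test_pairs: list[tuple[int, int]]
    train: AssociationMatrix
    seed: int | None = None


def _holdout(assoc: AssociationMatrix, pairs) -> AssociationMatrix:
    train = assoc.copy()
    for i, j in pairs:
        if assoc.values[i, j] != 1:
            raise ValueError(f"pair {(i, j)} is not a known association")
        train.values[i, j] = 0.0
    return train


def make_kfold_splits(assoc: AssociationMatrix, k: int = 5, seed: int = 0,
                      per_disease: str | None = None) -> list[FoldSplit]:
    """Shuffle the known associations and partition them into k folds.

    With ``per_disease`` set to a disease name, only that disease's column
    is partitioned (the single-disease k-fold scheme); all other
    associations always stay in training.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pairs = assoc.pairs()
    if per_disease is not None:
        j = assoc.disease_index(per_disease)
        pairs = [p for p in pairs if p[1] == j]
    if len(pairs) < k:
        raise ValueError(f"only {len(pairs)} associations for k={k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds = np.array_split(order, k)
    splits = []
    for fid, idx in enumerate(folds):
        test = [pairs[t] for t in idx]
        splits.append(FoldSplit("kfold", fid, test, _holdout(assoc, test), seed))
    return splits


def make_loocv_splits(assoc: AssociationMatrix) -> list[FoldSplit]:
    """One split per known association, held out in turn."""
    pairs = assoc.pairs()
    if not pairs:
        raise ValueError("no known associations")
    return [FoldSplit("loocv", fid, [p], _holdout(assoc, [p]))
            for fid, p in enumerate(pairs)]


def make_cvd_split(assoc: AssociationMatrix, disease: str) -> FoldSplit:
    """Delete an entire disease column from training (novel-disease test)."""
    j = assoc.disease_index(disease)
    test = [(int(i), j) for i in np.nonzero(assoc.values[:, j] == 1)[0]]
    if not test:
        raise ValueError(f"nothing to hold out: disease {disease!r} has no associations")
    return FoldSplit("cv_d", 0, test, _holdout(assoc, test))


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """ROC AUC (rank-sum with half credit for ties) plus the ROC points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    auc = float(_skm.roc_auc_score(labels, scores))
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr})


def pr_aupr(scores, labels) -> tuple[float, pd.DataFrame]:
    """Average precision (non-interpolated step rule) plus the PR points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined: no positive labels")
    aupr = float(_skm.average_precision_score(labels, scores))
    prec, rec, _ = _skm.precision_recall_curve(labels, scores)
    return aupr, pd.DataFrame({"recall": rec, "precision": prec})


def top_k_hits(scores: np.ndarray, positives: Sequence[int],
               ks: Sequence[int]) -> dict[int, int]:
    """Held-out positives among the top-k ranked candidates, for each k.

    ``scores`` are the candidate scores for one disease (training positives
    already excluded); ``positives`` indexes the held-out pairs within that
    candidate vector.  Ties break by index to keep the count deterministic.
    """
    if list(ks) != sorted(ks):
        raise ValueError("ks must be sorted ascending")
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    pos = set(int(p) for p in positives)
    counts = {}
    for k in ks:
        kk = min(k, len(order))
        counts[int(k)] = sum(1 for t in order[:kk] if int(t) in pos)
    return counts


@dataclass
class EvalReport:
    """Pooled and per-fold ranking performance for one protocol run."""

    protocol: str
    auc: float
    aupr: float
    roc_points: pd.DataFrame
    pr_points: pd.DataFrame
    per_fold: pd.DataFrame
    n_test_positives: int
    n_candidates: int
    top_k_counts: dict[int, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def fold_auc_mean(self) -> float:
        return float(self.per_fold["auc"].mean())

    @property
    def fold_auc_sd(self) -> float:
        return float(self.per_fold["auc"].std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    def summary(self) -> str:
        lines = [
            f"protocol          {self.protocol}",
            f"pooled AUC        {self.auc:.4f}",
            f"pooled AUPR       {self.aupr:.4f}",
            f"fold AUC          {self.fold_auc_mean:.4f} +/- {self.fold_auc_sd:.4f}"
            f" ({len(self.per_fold)} folds)",
            f"test positives    {self.n_test_positives}",
            f"candidates        {self.n_candidates}",
        ]
        if self.top_k_counts:
            hits = ", ".join(f"top-{k}: {c}" for k, c in self.top_k_counts.items())
            lines.append(f"ranking hits      {hits}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.plot(self.roc_points["fpr"], self.roc_points["tpr"],
                label=f"{self.protocol} (AUC={self.auc:.4f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax

    def plot_pr(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.step(self.pr_points["recall"], self.pr_points["precision"],
                where="post", label=f"{self.protocol} (AUPR={self.aupr:.4f})")
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
        ax.legend()
        return ax


SimilarityFn = Callable[[AssociationMatrix], tuple]


def _default_similarity_fn(ontology, delta, gamma_prime) -> SimilarityFn:
    def build(train: AssociationMatrix):
        return build_similarities(train, ontology, delta=delta,
                                  gamma_prime=gamma_prime)
    return build


def static_similarity_fn(s_m, s_d) -> SimilarityFn:
    """Precomputed similarities, reused across folds (the lax variant)."""
    return lambda train: (s_m, s_d)


def run_protocol(assoc: AssociationMatrix,
                 protocol: str = "kfold",
                 hyperparams: Hyperparams | None = None,
                 ontology=None,
                 similarity_fn: SimilarityFn | None = None,
                 k: int = 5,
                 diseases: Sequence[str] | None = None,
                 split_seed: int = 0,
                 ks: Sequence[int] = (20, 40, 60, 80, 100),
                 delta: float = 0.5,
                 gamma_prime: float = 1.0) -> EvalReport:
    """Run a full cross-validation protocol and score the held-out pairs.

    Per fold: similarities are rebuilt from the training matrix, the model
    is fit, and candidates are scored.  Pooled positives are the held-out
    pairs (scored by their own fold's model); pooled negatives are the
    pairs that are 0 in the *full* matrix, scored by every fold's model.
    Training 1-entries are never candidates.  For ``cv_d`` the candidate
    set is restricted to the held-out disease's column and per-k hit counts
    are reported.
    """
    hp = hyperparams or Hyperparams()
    simfn = similarity_fn or _default_similarity_fn(ontology, delta, gamma_prime)

    if protocol == "kfold":
        splits = make_kfold_splits(assoc, k=k, seed=split_seed)
    elif protocol == "loocv":
        splits = make_loocv_splits(assoc)
    elif protocol == "cv_d":
        names = list(diseases) if diseases else list(assoc.disease_names)
        splits = []
        for d in names:
            try:
                splits.append(make_cvd_split(assoc, d))
            except ValueError:
                continue
        for fid, sp in enumerate(splits):
            sp.fold_id = fid
        if not splits:
            raise ValueError("no disease with associations to hold out")
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    neg_mask = assoc.values == 0
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    fold_rows = []
    topk_total: dict[int, int] = {}
    n_pos = n_cand = 0

    for sp in splits:
        # leakage guard: held-out pairs must be absent from training
        for i, j in sp.test_pairs:
            assert sp.train.values[i, j] == 0.0, "test pair leaked into training"
        s_m, s_d = simfn(sp.train)
        res = PMFMDA(sp.train, s_m, s_d).fit(hp)
        scores = res.scores

        if protocol == "cv_d":
            j = sp.test_pairs[0][1]
            cand_rows = np.nonzero(sp.train.values[:, j] == 0)[0]
            cand_scores = scores[cand_rows, j]
            pos_rows = {i for i, _ in sp.test_pairs}
            labels = np.array([1 if i in pos_rows else 0 for i in cand_rows])
            pos_idx = np.nonzero(labels)[0]
            hits = top_k_hits(cand_scores, pos_idx, ks)
            for kk, c in hits.items():
                topk_total[kk] = topk_total.get(kk, 0) + c
        else:
            pos = np.array(sp.test_pairs)
            cand_scores = np.concatenate([scores[pos[:, 0], pos[:, 1]],
                                          scores[neg_mask]])
            labels = np.concatenate([np.ones(len(pos), dtype=int),
                                     np.zeros(int(neg_mask.sum()), dtype=int)])

        pooled_scores.append(cand_scores)
        pooled_labels.append(labels)
        n_pos += int(labels.sum())
        n_cand += len(labels)
        try:
            f_auc, _ = roc_auc(cand_scores, labels)
            f_aupr, _ = pr_aupr(cand_scores, labels)
        except ValueError:
            f_auc = f_aupr = np.nan
        fold_rows.append({"fold": sp.fold_id, "auc": f_auc, "aupr": f_aupr,
                          "n_test": len(sp.test_pairs),
                          "converged": res.converged, "n_iter": res.n_iter})

    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    auc, roc_pts = roc_auc(all_scores, all_labels)
    aupr, pr_pts = pr_aupr(all_scores, all_labels)
    return EvalReport(
        protocol=protocol, auc=auc, aupr=aupr,
        roc_points=roc_pts, pr_points=pr_pts,
        per_fold=pd.DataFrame(fold_rows),
        n_test_positives=n_pos, n_candidates=n_cand,
        top_k_counts=topk_total,
        config={"split_seed": split_seed, "model_seed": hp.seed, "k": k,
                "hyperparams": hp.__dict__.copy()},
    )


def grid_search(assoc: AssociationMatrix,
                grid: Sequence[tuple[float, float, float, float]] | dict,
                protocol: str = "kfold",
                hyperparams: Hyperparams | None = None,
                **protocol_kwargs) -> tuple[pd.DataFrame, dict]:
    """Evaluate the protocol over a grid of (lambda_U, lambda_V, lambda_1,
    lambda_2) quadruples and return the table plus the best-AUC row.

    ``grid`` may also be a dict of per-parameter value lists, expanded as a
    Cartesian product.
    """
    if isinstance(grid, dict):
        keys = ("lambda_u", "lambda_v", "lambda_1", "lambda_2")
        grid = list(itertools.product(*(grid[k] for k in keys)))
    if not grid:
        raise ValueError("empty grid")
    base = (hyperparams or Hyperparams()).__dict__.copy()
    rows = []
    for lu, lv, l1, l2 in grid:
        hp = Hyperparams(**{**base, "lambda_u": lu, "lambda_v": lv,
                            "lambda_1": l1, "lambda_2": l2})
        rep = run_protocol(assoc, protocol=protocol, hyperparams=hp,
                           **protocol_kwargs)
        rows.append({"lambda_u": lu, "lambda_v": lv, "lambda_1": l1,
                     "lambda_2": l2, "auc": rep.auc, "aupr": rep.aupr})
    table = pd.DataFrame(rows)
    best = table.loc[table["auc"].idxmax()].to_dict()
    return table, best
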