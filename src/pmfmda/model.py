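"""Similarity-regularized probabilistic matrix factorization.

The model treats the binary miRNA-disease association matrix
Y (n x m) as noisy observations of an inner product of nonnegative latent
factors, U (D x n) for miRNAs and V (D x m) for diseases, with zero-mean
Gaussian priors on the factors.  MAP estimation reduces to the regularized
squared loss

    E = 1/2 * sum_ij I_ij (Y_ij - U_i^T V_j)^2
        + lambda_U/2 ||U||_F^2 + lambda_V/2 ||V||_F^2
        + lambda_1/2 ||U^T U - S_m||_F^2 + lambda_2/2 ||V^T V - S_d||_F^2

where I is the observation indicator, and the last two terms pull the
factor Gram matrices toward the integrated miRNA (S_m) and disease (S_d)
similarity matrices.  E is minimized by alternating multiplicative updates
derived from the KKT complementary-slackness conditions, which preserve
nonnegativity of U and V.  Predicted association scores are Y' = U^T V;
within a disease's column, larger scores mean stronger predicted
association.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AssociationMatrix
from .similarity import SimilarityMatrix


@dataclass
class Hyperparams:
    """Tuning knobs of the factorization.

    ``lambda_u``/``lambda_v`` are the Frobenius (prior-precision ratio)
    regularizers; ``lambda_1``/``lambda_2`` weight the similarity terms.
    Defaults follow the tuned values lambda_U = lambda_V = 1 and
    lambda_1 = lambda_2 = 0.005.  ``ordering`` selects Gauss-Seidel
    (V's update sees the fresh U) or Jacobi alternation.
    """

    latent_dim: int = 50
    lambda_u: float = 1.0
    lambda_v: float = 1.0
    lambda_1: float = 0.005
    lambda_2: float = 0.005
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0
    epsilon: float = 1e-10
    ordering: str = "gauss-seidel"

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if min(self.lambda_u, self.lambda_v, self.lambda_1, self.lambda_2) < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.tol <= 0 or self.epsilon <= 0:
            raise ValueError("tol and epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.ordering not in ("gauss-seidel", "jacobi"):
            raise ValueError("ordering must be 'gauss-seidel' or 'jacobi'")


def _check_shapes(Y, mask, U, V, S_m, S_d) -> None:
    n, m = Y.shape
    d = U.shape[0]
    if mask.shape != (n, m):
        raise ValueError("mask shape mismatch")
    if U.shape != (d, n) or V.shape != (d, m):
        raise ValueError(f"factor shapes {U.shape}, {V.shape} do not match Y {Y.shape}")
    if S_m.shape != (n, n) or S_d.shape != (m, m):
        raise ValueError("similarity matrix shape mismatch")


def objective(Y, mask, U, V, S_m, S_d, hp: Hyperparams) -> float:
    """The regularized squared-loss objective E (see module docstring)."""
    _check_shapes(Y, mask, U, V, S_m, S_d)
    resid = mask * (Y - U.T @ V)
    val = 0.5 * float((resid ** 2).sum())
    val += 0.5 * hp.lambda_u * float((U ** 2).sum())
    val += 0.5 * hp.lambda_v * float((V ** 2).sum())
    val += 0.5 * hp.lambda_1 * float(((U.T @ U - S_m) ** 2).sum())
    val += 0.5 * hp.lambda_2 * float(((V.T @ V - S_d) ** 2).sum())
    return val


def gradients(Y, mask, U, V, S_m, S_d, hp: Hyperparams):
    """Analytic partials dE/dU and dE/dV of :func:`objective`.

    The masked data term is the gradient of the elementwise-masked loss:
    with R = I o (U^T V - Y), dE/dU = V R^T and dE/dV = U R.  The
    similarity terms assume S_m, S_d symmetric.
    """
    _check_shapes(Y, mask, U, V, S_m, S_d)
    R = mask * (U.T @ V - Y)
    gU = V @ R.T + hp.lambda_u * U + 2.0 * hp.lambda_1 * (U @ (U.T @ U) - U @ S_m)
    gV = U @ R + hp.lambda_v * V + 2.0 * hp.lambda_2 * (V @ (V.T @ V) - V @ S_d)
    return gU, gV


def kkt_residual(U, V, Y, mask, S_m, S_d, hp: Hyperparams) -> float:
    """Max complementary-slackness product |x * dE/dx| over all entries.

    Zero at an exact KKT point of the nonnegativity-constrained problem;
    a small value certifies approximate stationarity.
    """
    gU, gV = gradients(Y, mask, U, V, S_m, S_d, hp)
    return max(float(np.abs(U * gU).max(initial=0.0)),
               float(np.abs(V * gV).max(initial=0.0)))


def _multiplicative_step(F, num, den, eps):
    """F * num / (den + eps), leaving entries with both parts < eps unchanged."""
    frozen = (num < eps) & (den < eps)
    with np.errstate(invalid="ignore"):
        out = F * num / (den + eps)
    out[frozen] = F[frozen]
    return out


def update_factors(U, V, Y, mask, S_m, S_d, hp: Hyperparams):
    """One sweep of the multiplicative KKT updates; returns (U_new, V_new).

    Each factor entry is rescaled by the ratio of the negative to the
    positive part of its partial derivative, so a zero gradient leaves the
    entry fixed and nonnegativity is preserved.  The data term splits as
    numerator V (I o Y)^T and denominator V (I o U^T V)^T (mask-aware; with
    an all-ones mask these are the plain matrix products).  Under
    Gauss-Seidel ordering the V update uses the fresh U.
    """
    _check_shapes(Y, mask, U, V, S_m, S_d)
    if (U < 0).any() or (V < 0).any():
        raise ValueError("multiplicative update requires nonnegative factors")
    eps = hp.epsilon

    def step_u(U, V):
        num = V @ (mask * Y).T + 2.0 * hp.lambda_1 * (U @ S_m)
        den = V @ (mask * (U.T @ V)).T + hp.lambda_u * U \
            + 2.0 * hp.lambda_1 * (U @ (U.T @ U))
        return _multiplicative_step(U, num, den, eps)

    def step_v(U, V):
        num = U @ (mask * Y) + 2.0 * hp.lambda_2 * (V @ S_d)
        den = U @ (mask * (U.T @ V)) + hp.lambda_v * V \
            + 2.0 * hp.lambda_2 * (V @ (V.T @ V))
        return _multiplicative_step(V, num, den, eps)

    U_new = step_u(U, V)
    V_new = step_v(U_new if hp.ordering == "gauss-seidel" else U, V)
    return U_new, V_new


def _as_array(x):
    return x.values if isinstance(x, (SimilarityMatrix, AssociationMatrix)) else np.asarray(x, dtype=float)


class PMFMDA:
    """Similarity-regularized probabilistic matrix factorization model.

    Parameters
    ----------
    assoc
        Binary association matrix (an :class:`~pmfmda.io.AssociationMatrix`
        or a plain n x m array).  Rows are miRNAs, columns diseases.
    mirna_similarity, disease_similarity
        Integrated similarity matrices S_m (n x n) and S_d (m x m); plain
        arrays are accepted and symmetrized.
    mask
        Observation indicator; defaults to the association matrix's own
        mask (all-ones for plain arrays).

    Examples
    --------
    >>> model = PMFMDA(assoc, s_m, s_d)
    >>> res = model.fit(latent_dim=50, seed=0)
    >>> scores = res.predict()          # DataFrame, miRNAs x diseases
    """

    def __init__(self, assoc, mirna_similarity, disease_similarity,
                 mask=None) -> None:
        if isinstance(assoc, AssociationMatrix):
            self.mirna_names = list(assoc.mirna_names)
            self.disease_names = list(assoc.disease_names)
            self.Y = assoc.values.astype(float)
            self.mask = assoc.mask.astype(float) if mask is None else np.asarray(mask, float)
        else:
            self.Y = np.asarray(assoc, dtype=float)
            n, m = self.Y.shape
            self.mirna_names = [f"mirna_{i}" for i in range(n)]
            self.disease_names = [f"disease_{j}" for j in range(m)]
            self.mask = np.ones_like(self.Y) if mask is None else np.asarray(mask, float)
        # guard against asymmetric user-supplied similarity files
        sm = _as_array(mirna_similarity)
        sd = _as_array(disease_similarity)
        self.S_m = (sm + sm.T) / 2.0
        self.S_d = (sd + sd.T) / 2.0
        _check_shapes(self.Y, self.mask,
                      np.empty((1, self.Y.shape[0])), np.empty((1, self.Y.shape[1])),
                      self.S_m, self.S_d)

    @classmethod
    def from_associations(cls, assoc: AssociationMatrix, ontology=None,
                          delta: float = 0.5, gamma_prime: float = 1.0,
                          ) -> "PMFMDA":
        """Build the model from Y alone, constructing S_m and S_d from it."""
        from .similarity import build_similarities

        s_m, s_d = build_similarities(assoc, ontology, delta=delta,
                                      gamma_prime=gamma_prime)
        return cls(assoc, s_m, s_d)

    def initialize_factors(self, hp: Hyperparams):
        """Seeded strictly-positive uniform(0,1) starting factors."""
        rng = np.random.default_rng(hp.seed)
        n, m = self.Y.shape
        U0 = rng.uniform(size=(hp.latent_dim, n))
        V0 = rng.uniform(size=(hp.latent_dim, m))
        return U0, V0

    def fit(self, hyperparams: Hyperparams | None = None,
            start: tuple | None = None, **kwargs) -> "PMFMDAResults":
        """Alternate multiplicative updates until the objective stabilizes.

        Stops when the relative objective change drops below ``tol`` or
        after ``max_iter`` sweeps.  Keyword arguments override individual
        :class:`Hyperparams` fields.
        """
        hp = hyperparams if hyperparams is not None else Hyperparams(**kwargs)
        if hyperparams is not None and kwargs:
            hp = Hyperparams(**{**asdict(hp), **kwargs})
        U, V = self.initialize_factors(hp) if start is None else (
            np.asarray(start[0], float).copy(), np.asarray(start[1], float).copy())

        trace = [objective(self.Y, self.mask, U, V, self.S_m, self.S_d, hp)]
        converged = False
        for it in range(1, hp.max_iter + 1):
            U, V = update_factors(U, V, self.Y, self.mask, self.S_m, self.S_d, hp)
            e = objective(self.Y, self.mask, U, V, self.S_m, self.S_d, hp)
            if not np.isfinite(e):
                raise FloatingPointError(f"divergence at iteration {it}")
            trace.append(e)
            if abs(trace[-2] - e) / max(trace[-2], hp.epsilon) < hp.tol:
                converged = True
                break
        return PMFMDAResults(model=self, U=U, V=V, hyperparams=hp,
                             objective_trace=np.array(trace),
                             converged=converged, n_iter=len(trace) - 1)


@dataclass
class PMFMDAResults:
    """Fitted factors plus convergence diagnostics."""

    model: PMFMDA
    U: np.ndarray
    V: np.ndarray
    hyperparams: Hyperparams
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    _scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def scores(self) -> np.ndarray:
        """Predicted association score matrix Y' = U^T V (n x m)."""
        if self._scores is None:
            self._scores = self.U.T @ self.V
        return self._scores

    def predict(self) -> pd.DataFrame:
        """Y' with name indices: rows miRNAs, columns diseases."""
        return pd.DataFrame(self.scores, index=self.model.mirna_names,
                            columns=self.model.disease_names)

    def kkt_residual(self) -> float:
        return kkt_residual(self.U, self.V, self.model.Y, self.model.mask,
                            self.model.S_m, self.model.S_d, self.hyperparams)

    def rank_candidates(self, per_disease: bool = True,
                        include_known: bool = False,
                        top: int | None = None) -> pd.DataFrame:
        """Ranked unknown pairs by descending score (see io.rank_predictions)."""
        from .io import rank_predictions

        assoc = AssociationMatrix(self.model.mirna_names, self.model.disease_names,
                                  self.model.Y, self.model.mask)
        return rank_predictions(self.predict(), assoc, per_disease=per_disease,
                                include_known=include_known, top=top)

    def summary(self) -> str:
        hp = self.hyperparams
        n, m = self.model.Y.shape
        lines = [
            "Similarity-regularized PMF results",
            "=" * 44,
            f"{'miRNAs x diseases':<28}{n} x {m}",
            f"{'known associations':<28}{int(self.model.Y.sum())}",
            f"{'latent dimension':<28}{hp.latent_dim}",
            f"{'lambda_U, lambda_V':<28}{hp.lambda_u:g}, {hp.lambda_v:g}",
            f"{'lambda_1, lambda_2':<28}{hp.lambda_1:g}, {hp.lambda_2:g}",
            f"{'iterations':<28}{self.n_iter}",
            f"{'converged':<28}{self.converged}",
            f"{'initial objective':<28}{self.objective_trace[0]:.6g}",
            f"{'final objective':<28}{self.objective:.6g}",
            f"{'KKT residual':<28}{self.kkt_residual():.3g}",
            f"{'seed':<28}{hp.seed}",
        ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Persist factors, trace and parameters as labeled delimited text."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.U, columns=self.model.mirna_names).to_csv(
            d / "U.tsv", sep="\t", float_format="%.17g", index_label="dim")
        pd.DataFrame(self.V, columns=self.model.disease_names).to_csv(
            d / "V.tsv", sep="\t", float_format="%.17g", index_label="dim")
        np.savetxt(d / "objective_trace.tsv", self.objective_trace, fmt="%.17g")
        meta = {**asdict(self.hyperparams), "converged": self.converged,
                "n_iter": self.n_iter}
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory, model: PMFMDA | None = None) -> "PMFMDAResults":
        d = Path(directory)
        U_df = pd.read_csv(d / "U.tsv", sep="\t", index_col=0)
        V_df = pd.read_csv(d / "V.tsv", sep="\t", index_col=0)
        meta = json.loads((d / "metadata.json").read_text())
        converged = meta.pop("converged")
        n_iter = meta.pop("n_iter")
        hp = Hyperparams(**meta)
        U, V = U_df.to_numpy(), V_df.to_numpy()
        if model is None:
            n, m = U.shape[1], V.shape[1]
            model = PMFMDA(np.zeros((n, m)), np.eye(n), np.eye(m))
            model.mirna_names = list(U_df.columns)
            model.disease_names = list(V_df.columns)
        trace = np.loadtxt(d / "objective_trace.tsv", ndmin=1)
        return cls(model=model, U=U, V=V, hyperparams=hp,
                   objective_trace=trace, converged=converged, n_iter=n_iter)
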