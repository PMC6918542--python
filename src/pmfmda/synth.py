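"""Synthetic ontologies and planted low-rank association matrices.

Everything downstream (similarity construction, factorization, the CV
protocols) is exercisable without any external database: this module
generates a rooted disease vocabulary tree with dotted tree codes, and
binary association matrices planted from a nonnegative low-rank model —
the same generative story the factorization assumes (sparse nonnegative
factors, observations thresholded from their inner products), so hidden
associations are recoverable and ground-truth similarities are available
as oracles.

Generation is a pure function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AssociationMatrix, DiseaseOntology
from .similarity import SimilarityMatrix

#: sparsity of the known-association matrix in HMDD V2.0
#: (5,430 pairs over 495 x 383)
HMDD_DENSITY = 5430 / (495 * 383)


@dataclass(frozen=True)
class SynthSpec:
    """Shape, sparsity and noise of a synthetic instance."""

    n_mirnas: int = 100
    n_diseases: int = 80
    latent_dim: int = 5
    density: float = HMDD_DENSITY
    tree_depth: int = 3
    branching: int = 3
    noise_flip_rate: float = 0.0
    hide_fraction: float = 0.0
    uncovered_fraction: float = 0.1
    factor_sparsity: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_diseases, self.latent_dim) < 1:
            raise ValueError("dimensions must be positive")
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if self.density * self.n_mirnas * self.n_diseases < 1:
            raise ValueError("density too low to place a single association")
        if not 0 <= self.hide_fraction < 1 or not 0 <= self.noise_flip_rate < 1:
            raise ValueError("hide_fraction and noise_flip_rate must be in [0, 1)")


@dataclass
class PlantedInstance:
    """A planted association matrix with its generating ground truth."""

    assoc: AssociationMatrix
    hidden: list[tuple[int, int]]
    U_true: np.ndarray
    V_true: np.ndarray
    S_m_true: SimilarityMatrix = field(repr=False, default=None)  # type: ignore
    S_d_true: SimilarityMatrix = field(repr=False, default=None)  # type: ignore


def _tree_codes(depth: int, branching: int) -> list[str]:
    """All codes of a rooted tree: C1..Cb at level 1, dotted children below."""
    levels = [[f"C{i + 1:02d}" for i in range(branching)]]
    for _ in range(depth - 1):
        levels.append([f"{p}.{i + 1:03d}" for p in levels[-1]
                       for i in range(branching)])
    return [c for lvl in levels for c in lvl]


def generate_ontology(spec: SynthSpec) -> DiseaseOntology:
    """A disease vocabulary for diseases named ``disease_0000`` ...

    Diseases are assigned 1-2 tree codes each, cycling over the deepest
    codes first so that siblings exist; ``uncovered_fraction`` of diseases
    are omitted entirely to exercise the kernel fallback.
    """
    if spec.tree_depth < 1 or spec.branching < 1:
        raise ValueError("tree_depth and branching must be >= 1")
    rng = np.random.default_rng(spec.seed + 1)
    codes = _tree_codes(spec.tree_depth, spec.branching)
    deepest_first = sorted(codes, key=lambda c: c.count("."), reverse=True)
    n_uncovered = int(round(spec.uncovered_fraction * spec.n_diseases))
    uncovered = set(rng.choice(spec.n_diseases, size=n_uncovered,
                               replace=False)) if n_uncovered else set()
    onto = DiseaseOntology()
    for j in range(spec.n_diseases):
        if j in uncovered:
            continue
        primary = deepest_first[j % len(deepest_first)]
        assigned = {primary}
        if rng.random() < 0.3:  # occasional second tree number
            assigned.add(codes[int(rng.integers(len(codes)))])
        onto.add(f"disease_{j:04d}", assigned)
    return onto


def _normalized_gram(F: np.ndarray, names: list[str]) -> SimilarityMatrix:
    """Gram matrix of factor columns rescaled to unit diagonal."""
    g = F.T @ F
    d = np.sqrt(np.diag(g))
    vals = g / np.outer(d, d)
    return SimilarityMatrix(names, np.clip(vals, 0.0, 1.0))


def _sparse_nonneg_factors(rng, dim: int, n: int, sparsity: float) -> np.ndarray:
    """|N(0,1)| entries with a fraction zeroed; every column kept alive."""
    F = np.abs(rng.standard_normal((dim, n)))
    F[rng.random((dim, n)) < sparsity] = 0.0
    for col in range(n):
        if not F[:, col].any():
            F[int(rng.integers(dim)), col] = np.abs(rng.standard_normal())
    return F


def generate_planted_associations(spec: SynthSpec) -> PlantedInstance:
    """Plant Y from sparse nonnegative factors and optionally hide positives.

    The top ``density * n * m`` entries of U*^T V* become the 1-entries of
    Y; ``noise_flip_rate`` of entries are then flipped, and
    ``hide_fraction`` of the surviving 1s are zeroed and recorded as the
    recovery ground truth.  Ground-truth similarities are the unit-diagonal
    normalized Gram matrices of the planted factors.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, dim = spec.n_mirnas, spec.n_diseases, spec.latent_dim
    U = _sparse_nonneg_factors(rng, dim, n, spec.factor_sparsity)
    V = _sparse_nonneg_factors(rng, dim, m, spec.factor_sparsity)
    scores = U.T @ V

    k = int(round(spec.density * n * m))
    if k >= n * m:
        raise ValueError("density too high: no negative entries would remain")
    # stable top-k: break score ties by flat index so generation is pure
    flat_order = np.lexsort((np.arange(n * m), -scores.ravel()))
    Y = np.zeros(n * m)
    Y[flat_order[:k]] = 1.0
    Y = Y.reshape(n, m)

    if spec.noise_flip_rate > 0:
        n_flip = int(round(spec.noise_flip_rate * n * m))
        flips = rng.choice(n * m, size=n_flip, replace=False)
        Y.ravel()[flips] = 1.0 - Y.ravel()[flips]

    ones = np.argwhere(Y == 1)
    hidden: list[tuple[int, int]] = []
    if spec.hide_fraction > 0 and len(ones):
        n_hide = int(round(spec.hide_fraction * len(ones)))
        sel = rng.choice(len(ones), size=n_hide, replace=False)
        for i, j in ones[sel]:
            Y[i, j] = 0.0
            hidden.append((int(i), int(j)))

    mirna_names = [f"mirna_{i:04d}" for i in range(n)]
    disease_names = [f"disease_{j:04d}" for j in range(m)]
    assoc = AssociationMatrix(mirna_names, disease_names, Y)
    return PlantedInstance(
        assoc=assoc, hidden=hidden, U_true=U, V_true=V,
        S_m_true=_normalized_gram(U, mirna_names),
        S_d_true=_normalized_gram(V, disease_names),
    )


def hmdd_scale_fixture(seed: int = 20191211) -> tuple[AssociationMatrix, DiseaseOntology]:
    """A deterministic instance at the reference-dataset scale.

    495 miRNAs x 383 diseases with exactly 5,430 known associations, plus
    a matching ontology; intended for smoke and performance testing of the
    full pipeline, not for accuracy claims.
    """
    spec = SynthSpec(n_mirnas=495, n_diseases=383, latent_dim=20,
                     density=HMDD_DENSITY, tree_depth=4, branching=5,
                     uncovered_fraction=0.08, seed=seed)
    inst = generate_planted_associations(spec)
    onto = generate_ontology(replace(spec, n_diseases=383))
    return inst.assoc, onto
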