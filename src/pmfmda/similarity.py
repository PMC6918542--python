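"""Disease and miRNA similarity constructions.

Four building blocks feed the factorization model:

* **semantic similarity** between diseases, from their ancestor DAGs in a
  hierarchical disease vocabulary (MeSH-style tree numbers).  Each ancestor
  term receives a contribution that decays by a factor ``delta`` per edge
  away from the disease; two diseases are similar when heavily-weighted
  ancestors overlap.
* **functional similarity** between miRNAs: two miRNAs are similar when the
  disease sets they associate with are similar, via a best-match average
  over the disease similarity matrix.
* **Gaussian interaction profile (GIP) kernels** for both axes: an RBF
  kernel between binary interaction profiles (rows/columns of Y) with the
  bandwidth calibrated so that gamma = gamma' / (mean squared profile norm).
* **integration**: semantic (diseases) or functional (miRNAs) similarity
  where it is defined, GIP kernel as the fallback for entities the
  vocabulary or the training associations do not cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import AssociationMatrix, DiseaseOntology, parent_code

#: per-edge semantic decay factor
DEFAULT_DELTA = 0.5
#: GIP kernel bandwidth numerator gamma'
DEFAULT_GAMMA_PRIME = 1.0

_CLAMP_ATOL = 1e-12

SOURCE_PRIMARY = 1  # semantic / functional
SOURCE_KERNEL = 0


@dataclass
class SimilarityMatrix:
    """Symmetric, unit-diagonal square similarity matrix in [0, 1]."""

    names: list[str]
    values: np.ndarray
    source_tags: np.ndarray | None = None  # per-pair provenance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        lo, hi = self.values.min(initial=0.0), self.values.max(initial=1.0)
        if lo < -_CLAMP_ATOL or hi > 1 + _CLAMP_ATOL:
            raise ValueError(f"similarity values outside [0,1]: [{lo}, {hi}]")
        np.clip(self.values, 0.0, 1.0, out=self.values)
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 1.0)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.index(a), self.index(b)])


@dataclass
class SemanticProfile:
    """Per-ancestor semantic contributions D_d(t) of one disease's DAG."""

    disease: str
    contributions: dict[str, float] = field(default_factory=dict)

    @property
    def semantic_value(self) -> float:
        """DV(d) = sum of contributions over the disease's DAG; >= 1."""
        return float(sum(self.contributions.values()))


def semantic_contribution(ontology: DiseaseOntology, disease: str,
                          delta: float = DEFAULT_DELTA) -> SemanticProfile:
    """Semantic contribution of every ancestor term to ``disease``.

    The disease's own node(s) contribute 1; each other ancestor t
    contributes max over its children t' (within the disease's DAG) of
    delta * D_d(t'), evaluated by reverse-topological (deepest-first)
    traversal.
    """
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    if disease not in ontology:
        raise KeyError(f"no DAG for disease {disease!r}")
    own = ontology.codes(disease)
    nodes = ontology.ancestor_codes(disease)

    children: dict[str, list[str]] = {t: [] for t in nodes}
    for t in nodes:
        p = parent_code(t)
        if p is not None and p in nodes:
            children[p].append(t)

    contrib: dict[str, float] = {}
    for t in sorted(nodes, key=lambda c: c.count("."), reverse=True):
        if t in own:
            contrib[t] = 1.0
        else:
            contrib[t] = max(delta * contrib[c] for c in children[t])
    return SemanticProfile(disease=disease, contributions=contrib)


def disease_semantic_similarity(p_i: SemanticProfile,
                                p_j: SemanticProfile) -> float:
    """Shared-ancestor similarity of two semantic profiles, in [0, 1]."""
    shared = p_i.contributions.keys() & p_j.contributions.keys()
    if not shared:
        return 0.0
    num = sum(p_i.contributions[t] + p_j.contributions[t] for t in shared)
    return num / (p_i.semantic_value + p_j.semantic_value)


def semantic_similarity_matrix(ontology: DiseaseOntology,
                               disease_names: list[str],
                               delta: float = DEFAULT_DELTA,
                               ) -> tuple[SimilarityMatrix, np.ndarray]:
    """Pairwise semantic similarity plus a per-disease coverage flag.

    Diseases absent from the ontology are uncovered: their entries are left
    at 0 and must be filled by the GIP kernel fallback downstream.
    """
    if not disease_names:
        raise ValueError("disease_names is empty")
    m = len(disease_names)
    coverage = np.array([d in ontology for d in disease_names])
    profiles = {i: semantic_contribution(ontology, disease_names[i], delta)
                for i in np.nonzero(coverage)[0]}
    values = np.zeros((m, m))
    covered = sorted(profiles)
    for a, i in enumerate(covered):
        values[i, i] = 1.0
        for j in covered[a + 1:]:
            s = disease_semantic_similarity(profiles[i], profiles[j])
            values[i, j] = values[j, i] = s
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(disease_names), values), coverage


def mirna_functional_similarity(dt_i: set[str], dt_j: set[str],
                                dsim: SimilarityMatrix) -> float:
    """Best-match-average similarity between two miRNAs' disease sets."""
    if not dt_i or not dt_j:
        raise ValueError("miRNA has no associated diseases")
    idx = {name: k for k, name in enumerate(dsim.names)}
    ii = [idx[d] for d in dt_i]
    jj = [idx[d] for d in dt_j]
    block = dsim.values[np.ix_(ii, jj)]
    total = block.max(axis=1).sum() + block.max(axis=0).sum()
    return float(total / (len(ii) + len(jj)))


def functional_similarity_matrix(assoc: AssociationMatrix,
                                 dsim: SimilarityMatrix,
                                 disease_coverage: np.ndarray | None = None,
                                 ) -> tuple[SimilarityMatrix, np.ndarray]:
    """Pairwise functional similarity over miRNAs with coverage flags.

    A miRNA is covered when its training-set disease list is nonempty and
    all its diseases carry semantic similarity; uncovered miRNAs fall back
    to the GIP kernel downstream.
    """
    if list(dsim.names) != list(assoc.disease_names):
        raise ValueError("disease similarity names do not match association matrix")
    n = assoc.n_mirnas
    if disease_coverage is None:
        disease_coverage = np.ones(assoc.n_diseases, dtype=bool)
    sets: list[set[str]] = []
    coverage = np.zeros(n, dtype=bool)
    for i in range(n):
        jj = np.nonzero(assoc.values[i] == 1)[0]
        sets.append({assoc.disease_names[j] for j in jj})
        coverage[i] = len(jj) > 0 and bool(disease_coverage[jj].all())
    values = np.zeros((n, n))
    covered = np.nonzero(coverage)[0]
    for a, i in enumerate(covered):
        values[i, i] = 1.0
        for j in covered[a + 1:]:
            s = mirna_functional_similarity(sets[i], sets[j], dsim)
            values[i, j] = values[j, i] = s
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(assoc.mirna_names), values), coverage


def gaussian_kernel(profiles: np.ndarray, names: list[str],
                    gamma_prime: float = DEFAULT_GAMMA_PRIME) -> SimilarityMatrix:
    """GIP kernel over interaction profiles (one profile per row).

    The bandwidth is gamma'/(mean squared Euclidean profile norm), so
    duplicating every profile leaves the kernel unchanged.
    """
    profiles = np.asarray(profiles, dtype=float)
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    mean_sq = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("kernel bandwidth undefined: all profiles are zero")
    gamma = gamma_prime / mean_sq
    if len(profiles) == 1:
        values = np.ones((1, 1))
    else:
        sq = squareform(pdist(profiles, metric="sqeuclidean"))
        values = np.exp(-gamma * sq)
    return SimilarityMatrix(list(names), values)


def integrate_similarities(primary: SimilarityMatrix,
                           kernel: SimilarityMatrix,
                           coverage: np.ndarray) -> SimilarityMatrix:
    """Primary similarity where both entities are covered, kernel elsewhere."""
    if list(primary.names) != list(kernel.names):
        raise ValueError("name ordering differs between primary and kernel")
    coverage = np.asarray(coverage, dtype=bool)
    pair_covered = np.outer(coverage, coverage)
    values = np.where(pair_covered, primary.values, kernel.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(primary.names), values,
                            source_tags=pair_covered.astype(int))


def build_similarities(assoc: AssociationMatrix,
                       ontology: DiseaseOntology | None = None,
                       delta: float = DEFAULT_DELTA,
                       gamma_prime: float = DEFAULT_GAMMA_PRIME,
                       ) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated miRNA (S_m) and disease (S_d) similarity from Y.

    Disease semantic similarity (when an ontology is given) and miRNA
    functional similarity are used where defined; the GIP kernels of Y's
    columns/rows fill the rest.  Kernels and functional similarity are
    functions of ``assoc`` only, so passing a cross-validation training
    matrix keeps held-out associations out of the similarities.
    """
    m = assoc.n_diseases
    if ontology is not None and any(d in ontology for d in assoc.disease_names):
        sem, cov_d = semantic_similarity_matrix(ontology, assoc.disease_names, delta)
    else:
        sem = SimilarityMatrix(list(assoc.disease_names), np.eye(m))
        cov_d = np.zeros(m, dtype=bool)
    kd = gaussian_kernel(assoc.values.T, assoc.disease_names, gamma_prime)
    s_d = integrate_similarities(sem, kd, cov_d)

    func, cov_m = functional_similarity_matrix(assoc, s_d, cov_d)
    km = gaussian_kernel(assoc.values, assoc.mirna_names, gamma_prime)
    s_m = integrate_similarities(func, km, cov_m)
    return s_m, s_d
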