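"""Delimited-text formats and the indexed containers built from them.

The package works from three flat inputs: a two-column list of known
miRNA-disease association pairs, a table mapping disease names to
hierarchical tree codes (MeSH-style dotted tree numbers), and optional
precomputed square similarity matrices.  Everything here is plain TSV/CSV
so that fixtures and real exports interchange freely.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CODE_SEGMENT = re.compile(r"^[A-Za-z0-9]+$")

# header tokens recognised when auto-detecting a header row
_HEADER_TOKENS = {
    "mirna", "mirna_name", "mir", "microrna",
    "disease", "disease_name", "tree_number", "tree_code", "mesh",
    "score", "rank",
}


def _normalize(name: str) -> str:
    """Exact matching after whitespace trimming and case-folding."""
    return name.strip().casefold()


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix Y with name indices.

    ``values`` holds the known associations (1 = experimentally validated
    pair); ``mask`` is the observation indicator I used by the factorization
    loss.  By default every entry is observed (unknown pairs are treated as
    observed zeros, which is what ranking all unknown pairs requires); pass
    ``mask_unknown=True`` to builders for true missing-data semantics where
    only the 1-entries are observed.
    """

    mirna_names: list[str]
    disease_names: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones_like(self.values)
        self.mask = np.asarray(self.mask, dtype=float)
        n, m = self.values.shape
        if n != len(self.mirna_names) or m != len(self.disease_names):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.mirna_names)} miRNAs x {len(self.disease_names)} diseases"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape differs from values shape")
        if len(set(self.mirna_names)) != n or len(set(self.disease_names)) != m:
            raise ValueError("entity names must be unique within each axis")
        for arr, what in ((self.values, "values"), (self.mask, "mask")):
            uniq = np.unique(arr)
            if not np.isin(uniq, (0.0, 1.0)).all():
                raise ValueError(f"{what} entries must be 0 or 1")
        if ((self.values == 1) & (self.mask == 0)).any():
            raise ValueError("every known association must be observed (mask 1)")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_names)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) of the known associations."""
        return [tuple(ij) for ij in np.argwhere(self.values == 1)]

    def mirna_index(self, name: str) -> int:
        return self.mirna_names.index(name)

    def disease_index(self, name: str) -> int:
        return self.disease_names.index(name)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.mirna_names), list(self.disease_names),
            self.values.copy(), self.mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_names,
                            columns=self.disease_names)


class DiseaseOntology:
    """Disease name -> dotted tree codes, with per-disease ancestor DAGs.

    A disease's DAG is the union, over its tree codes, of all prefix
    chains: code "A.B.C" contributes nodes A.B.C, A.B and A.  Nodes are
    keyed by the opaque (case-sensitive) code string, so two diseases
    sharing a prefix share the corresponding ancestor nodes.
    """

    def __init__(self, terms: dict[str, set[str]] | None = None) -> None:
        self._codes: dict[str, frozenset[str]] = {}
        self._display: dict[str, str] = {}
        if terms:
            for name, codes in terms.items():
                self.add(name, codes)

    def add(self, name: str, codes) -> None:
        key = _normalize(name)
        if isinstance(codes, str):
            codes = {codes}
        merged = set(self._codes.get(key, ())) | {c.strip() for c in codes}
        for code in merged:
            validate_tree_code(code)
        self._codes[key] = frozenset(merged)
        self._display.setdefault(key, name.strip())

    def __contains__(self, name: str) -> bool:
        return _normalize(name) in self._codes

    def __len__(self) -> int:
        return len(self._codes)

    @property
    def disease_names(self) -> list[str]:
        return [self._display[k] for k in self._codes]

    def codes(self, name: str) -> frozenset[str]:
        key = _normalize(name)
        if key not in self._codes:
            raise KeyError(f"no DAG for disease {name!r}")
        return self._codes[key]

    def ancestor_codes(self, name: str) -> set[str]:
        """T_d: the disease's own codes plus every proper prefix."""
        closure: set[str] = set()
        for code in self.codes(name):
            parts = code.split(".")
            for k in range(1, len(parts) + 1):
                closure.add(".".join(parts[:k]))
        return closure

    def dag(self, name: str):
        """The disease's ancestor DAG as a DiGraph, edges child -> parent."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.ancestor_codes(name))
        for node in list(g.nodes):
            parent = parent_code(node)
            if parent is not None:
                g.add_edge(node, parent)
        return g


def parent_code(code: str) -> str | None:
    head, _, _ = code.rpartition(".")
    return head or None


def validate_tree_code(code: str, line: int | None = None) -> None:
    where = f" (line {line})" if line is not None else ""
    if not code:
        raise ValueError(f"empty tree code{where}")
    for seg in code.split("."):
        if not _CODE_SEGMENT.match(seg):
            raise ValueError(f"malformed tree code {code!r}{where}")


def _sniff_delimiter(sample: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def _read_rows(path, delimiter: str | None) -> tuple[list[list[str]], list[int]]:
    with open(path, newline="") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines()]
    sep = _sniff_delimiter("\n".join(lines[:20]), delimiter)
    rows, linenos = [], []
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        rows.append(next(csv.reader([ln], delimiter=sep)))
        linenos.append(lineno)
    return rows, linenos


def _looks_like_header(row: list[str]) -> bool:
    return all(_normalize(cell) in _HEADER_TOKENS for cell in row if cell.strip())


def read_association_pairs(path, delimiter: str | None = None,
                           sort_names: bool = False,
                           mask_unknown: bool = False) -> AssociationMatrix:
    """Read a two-column (miRNA, disease) pair list into a binary matrix.

    Row/column order is first-appearance order unless ``sort_names``.
    Duplicate pairs collapse to a single 1 (logged).  With ``mask_unknown``
    the observation mask equals the support of Y instead of all-ones.
    """
    rows, linenos = _read_rows(path, delimiter)
    if rows and _looks_like_header(rows[0]):
        rows, linenos = rows[1:], linenos[1:]
    if not rows:
        raise ValueError(f"no associations in {path}")

    pairs: list[tuple[str, str]] = []
    for row, lineno in zip(rows, linenos):
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise ValueError(f"{path}: line {lineno} has fewer than 2 fields")
        pairs.append((row[0].strip(), row[1].strip()))

    mirnas: dict[str, int] = {}
    diseases: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for m, d in pairs:
        if (m, d) in seen:
            logger.warning("duplicate association (%s, %s) collapsed", m, d)
        seen.add((m, d))
        mirnas.setdefault(m, len(mirnas))
        diseases.setdefault(d, len(diseases))

    mirna_names = sorted(mirnas) if sort_names else list(mirnas)
    disease_names = sorted(diseases) if sort_names else list(diseases)
    mi = {name: i for i, name in enumerate(mirna_names)}
    di = {name: j for j, name in enumerate(disease_names)}
    values = np.zeros((len(mirna_names), len(disease_names)))
    for m, d in seen:
        values[mi[m], di[d]] = 1.0
    mask = values.copy() if mask_unknown else np.ones_like(values)
    return AssociationMatrix(mirna_names, disease_names, values, mask)


def write_association_pairs(assoc: AssociationMatrix, path,
                            delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        for i, j in assoc.pairs():
            w.writerow([assoc.mirna_names[i], assoc.disease_names[j]])


def read_disease_tree(path, delimiter: str | None = None) -> DiseaseOntology:
    """Read (disease_name, tree_number) rows into a :class:`DiseaseOntology`.

    A disease occupying several rows accumulates all its tree numbers.
    """
    rows, linenos = _read_rows(path, delimiter)
    if rows and _looks_like_header(rows[0]):
        rows, linenos = rows[1:], linenos[1:]
    onto = DiseaseOntology()
    for row, lineno in zip(rows, linenos):
        if len(row) < 2 or not row[0].strip():
            raise ValueError(f"{path}: line {lineno} has fewer than 2 fields")
        code = row[1].strip()
        validate_tree_code(code, line=lineno)
        onto.add(row[0], {code})
    return onto


def write_disease_tree(onto: DiseaseOntology, path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        for name in onto.disease_names:
            for code in sorted(onto.codes(name)):
                w.writerow([name, code])


def read_similarity_matrix(path, delimiter: str = "\t"):
    """Labeled square similarity matrix (first row and column are names)."""
    from .similarity import SimilarityMatrix

    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return SimilarityMatrix(names=[str(x) for x in df.index],
                            values=df.to_numpy(dtype=float))


def write_similarity_matrix(sim, path, delimiter: str = "\t") -> None:
    pd.DataFrame(sim.values, index=sim.names, columns=sim.names).to_csv(
        path, sep=delimiter, float_format="%.17g")


def rank_predictions(scores: pd.DataFrame, assoc: AssociationMatrix,
                     per_disease: bool = False,
                     include_known: bool = False,
                     top: int | None = None) -> pd.DataFrame:
    """Rank candidate pairs by descending score.

    Candidates are the unknown pairs (value 0 in ``assoc``) unless
    ``include_known``.  Ties break by miRNA name ascending, then disease
    name, so ranking is deterministic.  Ranks are 1-based and contiguous,
    per disease when ``per_disease`` else globally.
    """
    records = []
    vals = scores.to_numpy()
    for i, m in enumerate(assoc.mirna_names):
        for j, d in enumerate(assoc.disease_names):
            if not include_known and assoc.values[i, j] == 1:
                continue
            records.append((m, d, vals[i, j]))
    df = pd.DataFrame(records, columns=["mirna", "disease", "score"])
    if df.empty:
        raise ValueError("no candidate pairs to rank")
    df = df.sort_values(["score", "mirna", "disease"],
                        ascending=[False, True, True], kind="mergesort")
    if per_disease:
        df["rank"] = df.groupby("disease", sort=False).cumcount() + 1
        if top is not None:
            df = df[df["rank"] <= top]
        df = df.sort_values(["disease", "rank"], kind="mergesort")
    else:
        df["rank"] = np.arange(1, len(df) + 1)
        if top is not None:
            df = df.head(top)
    return df.reset_index(drop=True)


def write_ranked_predictions(preds: pd.DataFrame, path,
                             delimiter: str = "\t") -> None:
    """Serialize ranked predictions with header (mirna, disease, score, rank)."""
    if preds.empty:
        raise ValueError("no predictions to write")
    preds.to_csv(path, sep=delimiter, index=False,
                 columns=["mirna", "disease", "score", "rank"],
                 float_format="%.8g")


def read_ranked_predictions(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter)
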