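"""Input/output and network assembly.

Reads tab-separated edge lists, FASTA sequence files, expression matrices,
square similarity-kernel matrices and disease-term DAG edge files, and builds
the three indexed 0/1 adjacency matrices the predictor consumes:

* ``A`` — circRNA x disease associations,
* ``Y`` — circRNA x miRNA interactions,
* ``O`` — disease x miRNA interactions.

Identifiers are opaque, case-sensitive strings.  Registries are sorted
lexicographically at construction so every matrix is reproducible
byte-for-byte from the same input files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    EmptyNetworkError,
    ParseError,
    RegistryError,
    ShapeError,
)

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8

ENTITY_KINDS = ("circRNA", "disease", "miRNA")


@dataclass(frozen=True)
class EntityRegistry:
    """Stable, sorted index over one entity set (circRNAs, diseases or miRNAs)."""

    kind: str
    ids: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_ids(cls, kind: str, ids: Iterable[str]) -> "EntityRegistry":
        ordered = tuple(sorted(set(ids)))
        return cls(kind=kind, ids=ordered, index={s: i for i, s in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.index

    def position(self, entity_id: str) -> int:
        try:
            return self.index[entity_id]
        except KeyError:
            raise RegistryError(
                f"unknown {self.kind} identifier: {entity_id!r}"
            ) from None


@dataclass(frozen=True)
class SimilarityKernel:
    """A square nonnegative similarity matrix with identifier labels."""

    matrix: np.ndarray
    ids: tuple[str, ...]
    name: str = "kernel"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError(f"kernel {self.name!r} is not square: {m.shape}")
        if m.shape[0] != len(self.ids):
            raise ShapeError(
                f"kernel {self.name!r}: {m.shape[0]} rows but {len(self.ids)} ids"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class BipartiteNetwork:
    """The three 0/1 association matrices with aligned registries.

    The miRNA axis of ``Y`` and ``O`` is one shared registry — the union of
    the miRNA identifiers seen in the circRNA-miRNA and disease-miRNA files.
    """

    A: np.ndarray  # nc x nd
    Y: np.ndarray  # nc x nm
    O: np.ndarray  # nd x nm
    circ: EntityRegistry
    disease: EntityRegistry
    mirna: EntityRegistry

    def __post_init__(self) -> None:
        nc, nd, nm = len(self.circ), len(self.disease), len(self.mirna)
        for name, mat, shape in (
            ("A", self.A, (nc, nd)),
            ("Y", self.Y, (nc, nm)),
            ("O", self.O, (nd, nm)),
        ):
            if mat.shape != shape:
                raise ShapeError(f"{name} has shape {mat.shape}, expected {shape}")
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"{name} must be a 0/1 matrix")

    @property
    def positive_pairs(self) -> list[tuple[str, str]]:
        """Known (circRNA, disease) associations, in registry order."""
        ii, jj = np.nonzero(self.A)
        return [(self.circ.ids[i], self.disease.ids[j]) for i, j in zip(ii, jj)]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued circRNA expression profiles (rows: circRNAs, cols: conditions)."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    condition_labels: tuple[str, ...]

    def row(self, circ_id: str) -> np.ndarray | None:
        try:
            return self.values[self.row_ids.index(circ_id)]
        except ValueError:
            return None


@dataclass(frozen=True)
class DiseaseDAG:
    """Directed acyclic parent->child term hierarchy plus disease->term mapping."""

    graph: nx.DiGraph  # edge parent -> child
    term_of: Mapping[str, str]  # disease id -> term id

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("disease term graph contains a cycle")
        missing = {t for t in self.term_of.values() if t not in self.graph}
        if missing:
            raise ValueError(f"mapped terms absent from DAG: {sorted(missing)}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)


# ---------------------------------------------------------------------------
# readers


def load_edge_list(path: str | Path, kind_a: str, kind_b: str) -> list[tuple[str, str]]:
    """Read a two-column TSV of (id_a, id_b) pairs.

    Lines starting with ``#`` and blank lines are skipped.  Duplicated pairs
    are dropped; the order of first appearance is preserved.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}: {line!r}"
                )
            pair = (fields[0], fields[1])
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if not pairs:
        raise EmptyNetworkError(f"{path}: no {kind_a}-{kind_b} edges found")
    return pairs


def build_network(
    cd_pairs: Sequence[tuple[str, str]],
    cm_pairs: Sequence[tuple[str, str]],
    dm_pairs: Sequence[tuple[str, str]],
) -> BipartiteNetwork:
    """Assemble A, Y, O from the three association pair lists.

    The circRNA registry is the union of circRNA ids in ``cd_pairs`` and
    ``cm_pairs``; the disease registry the union over ``cd_pairs`` and
    ``dm_pairs``; the miRNA registry the union over ``cm_pairs`` and
    ``dm_pairs``.  Entities seen in only one file keep an all-zero row/column
    in the matrices they do not appear in (this is logged, not an error).
    """
    circ = EntityRegistry.from_ids(
        "circRNA", [c for c, _ in cd_pairs] + [c for c, _ in cm_pairs]
    )
    disease = EntityRegistry.from_ids(
        "disease", [d for _, d in cd_pairs] + [d for d, _ in dm_pairs]
    )
    mirna = EntityRegistry.from_ids(
        "miRNA", [m for _, m in cm_pairs] + [m for _, m in dm_pairs]
    )

    only_dm = {d for d, _ in dm_pairs} - {d for _, d in cd_pairs}
    if only_dm:
        logger.info(
            "%d diseases appear only in disease-miRNA edges (zero column in A): %s",
            len(only_dm),
            sorted(only_dm),
        )

    A = np.zeros((len(circ), len(disease)), dtype=np.int8)
    for c, d in cd_pairs:
        A[circ.position(c), disease.position(d)] = 1
    Y = np.zeros((len(circ), len(mirna)), dtype=np.int8)
    for c, m in cm_pairs:
        Y[circ.position(c), mirna.position(m)] = 1
    O = np.zeros((len(disease), len(mirna)), dtype=np.int8)
    for d, m in dm_pairs:
        O[disease.position(d), mirna.position(m)] = 1
    return BipartiteNetwork(A=A, Y=Y, O=O, circ=circ, disease=disease, mirna=mirna)


def read_kernel_matrix(path: str | Path, name: str | None = None) -> SimilarityKernel:
    """Read a labeled square TSV similarity matrix.

    Asymmetry up to 1e-8 is silently tolerated; beyond that the matrix is
    symmetrized to (K + K^T)/2 with a warning.  Negative entries are refused.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ShapeError(f"{path}: kernel matrix is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise ShapeError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative similarity {values[i, j]} at ({df.index[i]}, {df.columns[j]})"
        )
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > SYMMETRY_TOL:
        warnings.warn(
            f"{path}: kernel asymmetric (max |K-K^T| = {asym:.3g}); symmetrizing",
            stacklevel=2,
        )
    values = (values + values.T) / 2.0  # exact no-op for symmetric input
    return SimilarityKernel(
        matrix=values, ids=tuple(str(s) for s in df.index), name=name or path.stem
    )


def write_kernel_matrix(kernel: SimilarityKernel, path: str | Path) -> None:
    """Write a kernel as a labeled TSV, full float precision (round-trip safe)."""
    df = pd.DataFrame(kernel.matrix, index=list(kernel.ids), columns=list(kernel.ids))
    df.to_csv(Path(path), sep="\t", float_format="%.17g")


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence dict."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise EmptyNetworkError(f"{path}: no FASTA records")
    return records


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column ids, first row condition labels).

    Rows containing missing values are rejected outright: a profile with holes
    would silently corrupt every Pearson similarity it enters.
    """
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    if df.isna().any(axis=None):
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: rows with missing expression values: {bad}")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        row_ids=tuple(str(s) for s in df.index),
        condition_labels=tuple(str(c) for c in df.columns),
    )


def read_disease_dag(
    edges_path: str | Path, mapping_path: str | Path | None = None
) -> DiseaseDAG:
    """Read a parent->child term edge TSV and an optional disease->term TSV.

    Without a mapping file every disease id is taken to be its own term.
    """
    edge_pairs = load_edge_list(edges_path, "term", "term")
    graph = nx.DiGraph()
    graph.add_edges_from(edge_pairs)
    if mapping_path is not None:
        term_of = dict(load_edge_list(mapping_path, "disease", "term"))
    else:
        term_of = {t: t for t in graph.nodes}
    return DiseaseDAG(graph=graph, term_of=term_of)
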