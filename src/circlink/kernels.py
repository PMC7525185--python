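"""Similarity kernels for circRNAs and diseases.

Four circRNA kernels are computable from raw inputs:

* ``SC_Seq`` — global affine-gap sequence alignment similarity,
* ``SC_RG``  — regulatory similarity from shared miRNA partner sets,
* ``SC_EP``  — Pearson expression-profile similarity,
* ``SC_GIP`` — Gaussian interaction-profile kernel over miRNA interactions.

On the disease side two kernels are computable here — DAG-based semantic
similarity (``SD_Dss``) and the GIP kernel over disease-miRNA interactions
(``SD_GIP``) — and any number of precomputed kernels (symptom co-occurrence,
Lin, PSB, Resnik, SemFunSim exports) are consumed as labeled TSV matrices.

All kernels are symmetric with entries in [0, 1]; GIP and semantic kernels
have unit diagonal by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import AbstractSet, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (
    BandwidthUndefinedError,
    ConfigurationError,
    RegistryError,
    UnknownTermError,
    ZeroVarianceError,
)
from .io_net import BipartiteNetwork, DiseaseDAG, ExpressionMatrix, SimilarityKernel

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global alignment parameters (EDNAFULL semantics).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  ``N``
    scores 0 against every symbol, itself included — the EDNAFULL ambiguity
    rows are collapsed to neutral.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 16.0
    gap_extend: float = 4.0

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend > 0:
            raise ConfigurationError("require gap_open >= gap_extend > 0")

    def score(self, a: str, b: str) -> float:
        """Substitution score for one column."""
        if a == "N" or b == "N":
            return 0.0
        return self.match if a == b else self.mismatch


@dataclass(frozen=True)
class SemanticDecay:
    """Per-generation decay of a term's semantic contribution to a descendant."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ConfigurationError(f"delta must lie in (0,1), got {self.delta}")


@dataclass(frozen=True)
class GipBandwidth:
    """The bandwidth gamma = n / sum_i ||profile_i||^2 of a GIP kernel."""

    gamma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise BandwidthUndefinedError(f"invalid GIP bandwidth {self.gamma}")


# ---------------------------------------------------------------------------
# circRNA kernels


def regulatory_similarity(
    m_i: AbstractSet[str], m_j: AbstractSet[str], form: str = "ochiai"
) -> float:
    """Overlap similarity between two miRNA partner sets.

    ``form="ochiai"`` (default): |intersection| / sqrt(|M_i| * |M_j|), which is
    1 for identical sets.  ``form="product"`` divides by the plain product of
    the set sizes instead.  Empty sets score 0 against anything.
    """
    if not m_i or not m_j:
        return 0.0
    shared = len(m_i & m_j)
    if form == "ochiai":
        return shared / float(np.sqrt(len(m_i) * len(m_j)))
    if form == "product":
        return shared / float(len(m_i) * len(m_j))
    raise ConfigurationError(f"unknown regulatory similarity form {form!r}")


def expression_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two expression profiles, clipped below at 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("profiles must be equal-length 1-d vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("constant expression profile: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(r, 0.0)


def gip_bandwidth(profiles: np.ndarray) -> GipBandwidth:
    """gamma = n / sum_i ||profile_i||^2 over the whole profile matrix."""
    profiles = np.asarray(profiles, dtype=float)
    total = float(np.square(profiles).sum())
    if total == 0.0:
        raise BandwidthUndefinedError(
            "all interaction profiles are zero; GIP bandwidth undefined"
        )
    return GipBandwidth(gamma=profiles.shape[0] / total)


def gip_kernel(
    profiles: np.ndarray, ids: Sequence[str], name: str = "GIP"
) -> SimilarityKernel:
    """Gaussian interaction-profile kernel K[i,j] = exp(-gamma ||p_i - p_j||^2).

    The bandwidth is set from the mean squared profile norm over all rows;
    rows that are all zero are kept and scored by the same formula.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need a 2-d profile matrix with at least 2 rows")
    gamma = gip_bandwidth(profiles).gamma
    sq = np.square(profiles).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return SimilarityKernel(matrix=K, ids=tuple(ids), name=name)


# ---------------------------------------------------------------------------
# disease semantic similarity


def _ancestor_closure(dag: DiseaseDAG, term: str) -> set[str]:
    import networkx as nx

    return {term} | nx.ancestors(dag.graph, term)


def semantic_value(
    dag: DiseaseDAG, term: str, decay: SemanticDecay = SemanticDecay()
) -> tuple[dict[str, float], float]:
    """Semantic contributions D_d(t) over the ancestor closure of ``term``.

    D_d(d) = 1; for an ancestor t, D_d(t) = max over children c of t inside
    the closure of delta * D_d(c).  Returns (contributions, their sum DV(d)).
    """
    if term not in dag.graph:
        raise UnknownTermError(f"term {term!r} not in disease DAG")
    closure = _ancestor_closure(dag, term)
    contrib: dict[str, float] = {term: 1.0}
    # walk ancestors upward; a term's value depends only on closure children
    pending = [t for t in closure if t != term]
    while pending:
        progressed = False
        for t in list(pending):
            children = [c for c in dag.graph.successors(t) if c in closure]
            if all(c in contrib for c in children):
                contrib[t] = decay.delta * max(contrib[c] for c in children)
                pending.remove(t)
                progressed = True
        if not progressed:  # pragma: no cover - DAG invariant prevents this
            raise RuntimeError("cycle detected while scoring semantic values")
    return contrib, float(sum(contrib.values()))


def semantic_similarity(
    dag: DiseaseDAG, term_i: str, term_j: str, decay: SemanticDecay = SemanticDecay()
) -> float:
    """Shared-ancestor semantic similarity between two disease terms."""
    ci, vi = semantic_value(dag, term_i, decay)
    cj, vj = semantic_value(dag, term_j, decay)
    shared = ci.keys() & cj.keys()
    if not shared:
        return 0.0
    return sum(ci[t] + cj[t] for t in shared) / (vi + vj)


def semantic_kernel(
    dag: DiseaseDAG,
    disease_ids: Sequence[str],
    decay: SemanticDecay = SemanticDecay(),
    name: str = "SD_Dss",
) -> SimilarityKernel:
    """Pairwise semantic similarity over a disease registry.

    Diseases without a term mapping get zero rows (coverage is logged).
    """
    n = len(disease_ids)
    K = np.zeros((n, n))
    mapped = [(i, dag.term_of[d]) for i, d in enumerate(disease_ids) if d in dag.term_of]
    missing = n - len(mapped)
    if missing:
        logger.warning("%d/%d diseases lack a DAG term; zero semantic rows", missing, n)
    values = {i: semantic_value(dag, t, decay) for i, t in mapped}
    for a, (i, _) in enumerate(mapped):
        ci, vi = values[i]
        K[i, i] = 1.0
        for j, _ in mapped[a + 1 :]:
            cj, vj = values[j]
            shared = ci.keys() & cj.keys()
            if shared:
                K[i, j] = K[j, i] = sum(ci[t] + cj[t] for t in shared) / (vi + vj)
    return SimilarityKernel(matrix=K, ids=tuple(disease_ids), name=name)


# ---------------------------------------------------------------------------
# sequence similarity


@lru_cache(maxsize=None)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(DNA_ALPHABET, dims=2)
    for a in DNA_ALPHABET:
        for b in DNA_ALPHABET:
            matrix[a, b] = params.score(a, b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def sequence_similarity(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Fraction of positively scoring columns in the optimal global alignment.

    The alignment is the Gotoh three-state affine-gap optimum under
    match +5 / mismatch -4 with the configured gap costs; the returned value
    is the "similar columns / alignment length" percentage as a fraction,
    so identical sequences score exactly 1.
    """
    for label, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{label} is empty")
        bad = set(seq) - set(DNA_ALPHABET)
        if bad:
            raise ValueError(f"{label} contains non-IUPAC characters: {sorted(bad)}")
    alignment = _aligner(params).align(seq_a, seq_b)[0]
    cols_a, cols_b = alignment[0], alignment[1]
    length = len(cols_a)
    positive = sum(
        1
        for a, b in zip(cols_a, cols_b)
        if a != "-" and b != "-" and params.score(a, b) > 0
    )
    return positive / length


def alignment_score(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Optimal global affine-gap alignment score (for cross-checks)."""
    return float(_aligner(params).score(seq_a, seq_b))


def sequence_kernel(
    sequences: Mapping[str, str],
    circ_ids: Sequence[str],
    params: AlignmentParams = AlignmentParams(),
    name: str = "SC_Seq",
) -> SimilarityKernel:
    """Pairwise sequence similarity; circRNAs without a sequence get zero rows."""
    n = len(circ_ids)
    K = np.zeros((n, n))
    have = [i for i, c in enumerate(circ_ids) if c in sequences]
    if len(have) < n:
        logger.warning("%d/%d circRNAs lack sequences; zero rows", n - len(have), n)
    for a, i in enumerate(have):
        K[i, i] = 1.0
        for j in have[a + 1 :]:
            K[i, j] = K[j, i] = sequence_similarity(
                sequences[circ_ids[i]], sequences[circ_ids[j]], params
            )
    return SimilarityKernel(matrix=K, ids=tuple(circ_ids), name=name)


# ---------------------------------------------------------------------------
# full-registry kernels and stack assembly


def regulatory_kernel(
    network: BipartiteNetwork, form: str = "ochiai", name: str = "SC_RG"
) -> SimilarityKernel:
    """Regulatory similarity over all circRNA pairs from their miRNA partner sets."""
    sets = [set(np.nonzero(row)[0]) for row in np.asarray(network.Y)]
    n = len(sets)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = regulatory_similarity(sets[i], sets[j], form=form)
    return SimilarityKernel(matrix=K, ids=network.circ.ids, name=name)


def expression_kernel(
    expression: ExpressionMatrix,
    circ_ids: Sequence[str],
    name: str = "SC_EP",
) -> SimilarityKernel:
    """Pairwise clipped-Pearson expression similarity over a circRNA registry.

    circRNAs absent from the expression matrix (or with constant profiles)
    contribute zero rows; coverage is logged.
    """
    n = len(circ_ids)
    K = np.zeros((n, n))
    rows: dict[int, np.ndarray] = {}
    for i, c in enumerate(circ_ids):
        v = expression.row(c)
        if v is not None and np.ptp(v) > 0:
            rows[i] = v
    if len(rows) < n:
        logger.warning(
            "expression profiles cover %d/%d circRNAs; rest get zero rows",
            len(rows),
            n,
        )
    have = sorted(rows)
    for a, i in enumerate(have):
        K[i, i] = 1.0
        for j in have[a + 1 :]:
            K[i, j] = K[j, i] = expression_similarity(rows[i], rows[j])
    return SimilarityKernel(matrix=K, ids=tuple(circ_ids), name=name)


def assemble_kernel_stacks(
    network: BipartiteNetwork,
    expression: ExpressionMatrix | None = None,
    sequences: Mapping[str, str] | None = None,
    dag: DiseaseDAG | None = None,
    precomputed: Sequence[SimilarityKernel] = (),
    alignment_params: AlignmentParams = AlignmentParams(),
    decay: SemanticDecay = SemanticDecay(),
    regulatory_form: str = "ochiai",
) -> tuple[list[SimilarityKernel], list[SimilarityKernel]]:
    """Build the circRNA and disease kernel stacks for fusion.

    The circRNA side is [SC_Seq, SC_RG, SC_EP, SC_GIP] (absent inputs are
    dropped with a warning); the disease side is [SD_Dss, SD_GIP] followed by
    the precomputed kernels in the given order.  Fewer than two kernels on
    either side is a configuration error — cross-diffusion needs a partner.
    """
    circ_ids, disease_ids = network.circ.ids, network.disease.ids

    circ_kernels: list[SimilarityKernel] = []
    if sequences is not None:
        circ_kernels.append(sequence_kernel(sequences, circ_ids, alignment_params))
    else:
        logger.warning("no sequences supplied; dropping SC_Seq")
    circ_kernels.append(regulatory_kernel(network, form=regulatory_form))
    if expression is not None:
        circ_kernels.append(expression_kernel(expression, circ_ids))
    else:
        logger.warning("no expression matrix supplied; dropping SC_EP")
    circ_kernels.append(gip_kernel(network.Y, circ_ids, name="SC_GIP"))

    disease_kernels: list[SimilarityKernel] = []
    if dag is not None:
        disease_kernels.append(semantic_kernel(dag, disease_ids, decay))
    else:
        logger.warning("no disease DAG supplied; dropping SD_Dss")
    disease_kernels.append(gip_kernel(network.O, disease_ids, name="SD_GIP"))
    for k in precomputed:
        if k.ids != tuple(disease_ids):
            raise RegistryError(
                f"precomputed kernel {k.name!r} ids do not match the disease registry"
            )
        disease_kernels.append(k)

    for side, stack in (("circRNA", circ_kernels), ("disease", disease_kernels)):
        if len(stack) < 2:
            raise ConfigurationError(
                f"need at least 2 {side} kernels for fusion, have {len(stack)}"
            )
    return circ_kernels, disease_kernels
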