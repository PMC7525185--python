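"""Self-contained synthetic studies with planted association structure.

The generator emulates the structure of curated circRNA-disease resources
(sparse 0/1 bipartite association matrices, expression profiles, circRNA
sequences, a small disease term hierarchy and a handful of precomputed
disease similarity matrices) using a planted-block model: circRNAs,
diseases and miRNAs are partitioned into communities; associations are
dense within a community and sparse across; expression rows are noisy block
centroids; sequences are mutated block consensi; the disease DAG groups
same-block diseases under shared parents.  The planted blocks give every
kernel, the fusion stage and the end-to-end classifier a known signal to
recover, with no external downloads.

All outputs are reproducible bit-for-bit from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_net import (
    BipartiteNetwork,
    DiseaseDAG,
    EntityRegistry,
    ExpressionMatrix,
    SimilarityKernel,
    write_kernel_matrix,
)

# free generator knobs held fixed across studies (see docs/methods.md)
N_CONDITIONS = 90       # expression profile width, as in exosomal profiles
SEQ_LENGTH = 240        # synthetic circRNA length
MUTATION_RATE = 0.1     # per-base divergence from the block consensus
N_PRECOMPUTED = 5       # synthetic stand-ins for external disease kernels
EXPRESSION_NOISE_SD = 0.5
BETWEEN_BLOCK_BASELINE = 0.2


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of one planted-block synthetic dataset."""

    nc: int = 40
    nd: int = 15
    nm: int = 60
    n_blocks: int = 3
    within_block_assoc_prob: float = 0.6
    background_assoc_prob: float = 0.02
    kernel_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_assoc_prob < self.within_block_assoc_prob <= 1.0:
            raise ConfigurationError(
                "require 0 <= background < within_block probability <= 1"
            )
        if min(self.nc, self.nd, self.nm) < self.n_blocks or self.n_blocks < 1:
            raise ConfigurationError(
                "every entity set must be at least as large as n_blocks"
            )
        if self.kernel_noise_sd < 0:
            raise ConfigurationError("kernel_noise_sd must be nonnegative")


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated study: network, raw kernel inputs and block assignments."""

    spec: SyntheticSpec
    network: BipartiteNetwork
    expression: ExpressionMatrix
    sequences: dict[str, str]
    dag: DiseaseDAG
    precomputed: list[SimilarityKernel]
    circ_blocks: np.ndarray
    disease_blocks: np.ndarray
    mirna_blocks: np.ndarray


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal blocks over 0..n-1 (matches registry order)."""
    return np.concatenate(
        [np.full(len(part), b) for b, part in enumerate(np.array_split(np.arange(n), n_blocks))]
    )


def _planted_adjacency(
    rows: np.ndarray, cols: np.ndarray, within: float, background: float,
    rng: np.random.Generator,
) -> np.ndarray:
    prob = np.where(rows[:, None] == cols[None, :], within, background)
    return (rng.random(prob.shape) < prob).astype(np.int8)


def _ensure_nonzero_rows(M: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                         rng: np.random.Generator) -> None:
    """Give every all-zero row one within-block link (keeps kernels well posed)."""
    for i in np.nonzero(M.sum(axis=1) == 0)[0]:
        mates = np.nonzero(cols == rows[i])[0]
        M[i, rng.choice(mates)] = 1


def generate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """Generate one complete synthetic study from a spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    width = max(2, len(str(max(spec.nc, spec.nd, spec.nm) - 1)))
    circ_ids = [f"circ-{i:0{width}d}" for i in range(spec.nc)]
    disease_ids = [f"dis-{j:0{width}d}" for j in range(spec.nd)]
    mirna_ids = [f"mir-{m:0{width}d}" for m in range(spec.nm)]

    cb = _block_assignment(spec.nc, spec.n_blocks)
    db = _block_assignment(spec.nd, spec.n_blocks)
    mb = _block_assignment(spec.nm, spec.n_blocks)

    within, background = spec.within_block_assoc_prob, spec.background_assoc_prob
    A = _planted_adjacency(cb, db, within, background, rng)
    Y = _planted_adjacency(cb, mb, within, background, rng)
    O = _planted_adjacency(db, mb, within, background, rng)
    _ensure_nonzero_rows(Y, cb, mb, rng)
    _ensure_nonzero_rows(O, db, mb, rng)

    network = BipartiteNetwork(
        A=A, Y=Y, O=O,
        circ=EntityRegistry.from_ids("circRNA", circ_ids),
        disease=EntityRegistry.from_ids("disease", disease_ids),
        mirna=EntityRegistry.from_ids("miRNA", mirna_ids),
    )

    # expression: block centroid + Gaussian noise
    centroids = rng.normal(size=(spec.n_blocks, N_CONDITIONS))
    values = centroids[cb] + EXPRESSION_NOISE_SD * rng.normal(
        size=(spec.nc, N_CONDITIONS)
    )
    expression = ExpressionMatrix(
        values=values,
        row_ids=tuple(circ_ids),
        condition_labels=tuple(f"cond-{k:02d}" for k in range(N_CONDITIONS)),
    )

    # sequences: per-block consensus with point mutations
    alphabet = np.array(list("ACGT"))
    consensus = rng.integers(0, 4, size=(spec.n_blocks, SEQ_LENGTH))
    sequences: dict[str, str] = {}
    for i, c in enumerate(circ_ids):
        bases = consensus[cb[i]].copy()
        mutate = rng.random(SEQ_LENGTH) < MUTATION_RATE
        bases[mutate] = (bases[mutate] + rng.integers(1, 4, size=int(mutate.sum()))) % 4
        sequences[c] = "".join(alphabet[bases])

    # DAG: root -> block parents -> one term per disease
    graph = nx.DiGraph()
    term_of = {}
    for b in range(spec.n_blocks):
        graph.add_edge("T:root", f"T:block-{b}")
    for j, d in enumerate(disease_ids):
        graph.add_edge(f"T:block-{db[j]}", f"T:{d}")
        term_of[d] = f"T:{d}"
    dag = DiseaseDAG(graph=graph, term_of=term_of)

    # synthetic stand-ins for externally precomputed disease similarities:
    # block structure plus symmetric Gaussian noise, clipped to [0, 1]
    base = np.where(db[:, None] == db[None, :], 1.0, BETWEEN_BLOCK_BASELINE)
    precomputed = []
    for k in range(N_PRECOMPUTED):
        noise = rng.normal(scale=spec.kernel_noise_sd, size=(spec.nd, spec.nd))
        K = np.clip(base + (noise + noise.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(K, 1.0)
        precomputed.append(
            SimilarityKernel(matrix=K, ids=tuple(disease_ids), name=f"SD_Syn{k + 1}")
        )

    return SyntheticStudy(
        spec=spec, network=network, expression=expression, sequences=sequences,
        dag=dag, precomputed=precomputed,
        circ_blocks=cb, disease_blocks=db, mirna_blocks=mb,
    )


def generate_random_kernels(n: int, K: int, seed: int) -> list[SimilarityKernel]:
    """K random valid similarity kernels: symmetric, [0,1], unit diagonal."""
    if n < 2 or K < 2:
        raise ConfigurationError("need n >= 2 and K >= 2")
    rng = np.random.default_rng(seed)
    ids = tuple(f"e{i:03d}" for i in range(n))
    kernels = []
    for k in range(K):
        raw = rng.random((n, n))
        S = (raw + raw.T) / 2.0
        np.fill_diagonal(S, 1.0)
        kernels.append(SimilarityKernel(matrix=S, ids=ids, name=f"rand{k}"))
    return kernels


# ---------------------------------------------------------------------------
# serialization of a study to the on-disk formats the pipeline consumes


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write every input file of a study (TSV edge lists, FASTA, matrices)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = study.network
    paths: dict[str, Path] = {}

    def edges(name: str, M: np.ndarray, rows, cols) -> None:
        p = out / f"{name}.tsv"
        with p.open("w") as fh:
            fh.write(f"# {name} edges\n")
            for i, j in zip(*np.nonzero(M)):
                fh.write(f"{rows[i]}\t{cols[j]}\n")
        paths[name] = p

    edges("circ_disease", net.A, net.circ.ids, net.disease.ids)
    edges("circ_mirna", net.Y, net.circ.ids, net.mirna.ids)
    edges("disease_mirna", net.O, net.disease.ids, net.mirna.ids)

    fasta = out / "sequences.fasta"
    with fasta.open("w") as fh:
        for cid, seq in study.sequences.items():
            fh.write(f">{cid}\n{seq}\n")
    paths["sequences"] = fasta

    expr = out / "expression.tsv"
    pd.DataFrame(
        study.expression.values,
        index=list(study.expression.row_ids),
        columns=list(study.expression.condition_labels),
    ).to_csv(expr, sep="\t", float_format="%.17g")
    paths["expression"] = expr

    dag_edges = out / "dag_edges.tsv"
    with dag_edges.open("w") as fh:
        fh.write("# parent\tchild\n")
        for parent, child in study.dag.graph.edges:
            fh.write(f"{parent}\t{child}\n")
    paths["dag_edges"] = dag_edges
    dag_map = out / "dag_mapping.tsv"
    with dag_map.open("w") as fh:
        fh.write("# disease\tterm\n")
        for d, t in study.dag.term_of.items():
            fh.write(f"{d}\t{t}\n")
    paths["dag_mapping"] = dag_map

    for kernel in study.precomputed:
        p = out / f"{kernel.name}.tsv"
        write_kernel_matrix(kernel, p)
        paths[kernel.name] = p
    return paths
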