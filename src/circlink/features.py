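"""Per-pair feature matrices for the convolutional classifier.

Each (circRNA c_i, disease d_j) pair becomes a 2 x (nc + nd + np) matrix of
three side-by-side blocks:

* block 1 (2 x nc): row 1 the fused circRNA similarities Sc*[i, .],
  row 2 the association column A[., j] — which circRNAs d_j is known to
  associate with;
* block 2 (2 x nd): row 1 the association row A[i, .], row 2 the fused
  disease similarities Sd*[j, .];
* block 3 (2 x np): the pair's miRNA interaction profiles Y[i, .] and
  O[j, .] compressed to np principal-component scores by a projector fitted
  once on the row-stack of Y and O.

The cell A[i, j] appears verbatim in blocks 1 and 2; with ``mask_label``
(the default for training features) it is zeroed so the classifier cannot
read the pair's own label off its input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .errors import ConfigurationError, ShapeError
from .io_net import BipartiteNetwork

Label = Literal[0, 1, "unknown"]

DEFAULT_COMPONENTS = 50


@dataclass(frozen=True)
class MirnaProjector:
    """PCA projector from miRNA interaction profiles to np scores."""

    components: np.ndarray  # nm x np, orthonormal columns
    mean: np.ndarray  # nm
    n_components: int

    def project(self, profile: np.ndarray) -> np.ndarray:
        profile = np.asarray(profile, dtype=float)
        if profile.shape[-1] != self.mean.shape[0]:
            raise ShapeError(
                f"profile length {profile.shape[-1]} != {self.mean.shape[0]} miRNAs"
            )
        return (profile - self.mean) @ self.components


@dataclass(frozen=True)
class PairFeature:
    """The 2 x (nc + nd + np) feature matrix of one circRNA-disease pair."""

    X: np.ndarray
    circ_id: str
    disease_id: str
    label: Label

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != 2:
            raise ShapeError(f"pair feature must be 2 x W, got {self.X.shape}")
        if not np.isfinite(self.X).all():
            raise ValueError("pair feature contains non-finite entries")


def fit_mirna_projector(
    Y: np.ndarray, O: np.ndarray, n_components: int = DEFAULT_COMPONENTS
) -> MirnaProjector:
    """Fit PCA on the (nc + nd) x nm row-stack of Y and O (mean-centered).

    The stack carries no circRNA-disease labels, so one fit is shared by all
    pairs and all cross-validation folds.
    """
    stack = np.vstack([np.asarray(Y, float), np.asarray(O, float)])
    n_rows, nm = stack.shape
    if n_components > min(n_rows, nm):
        raise ConfigurationError(
            f"np={n_components} exceeds min(nc+nd, nm)={min(n_rows, nm)}"
        )
    rank = np.linalg.matrix_rank(stack - stack.mean(axis=0))
    if rank < n_components:
        raise ConfigurationError(
            f"profile stack has rank {rank} < np={n_components}; use a smaller np"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(stack)
    return MirnaProjector(
        components=pca.components_.T.copy(),
        mean=pca.mean_.copy(),
        n_components=n_components,
    )


def build_pair_feature(
    circ_id: str,
    disease_id: str,
    Sc: np.ndarray,
    Sd: np.ndarray,
    network: BipartiteNetwork,
    projector: MirnaProjector,
    label: Label = "unknown",
    mask_label: bool = True,
) -> PairFeature:
    """Assemble the 2 x (nc + nd + np) feature matrix for one pair."""
    i = network.circ.position(circ_id)
    j = network.disease.position(disease_id)
    A = np.asarray(network.A, dtype=float)
    a_col = A[:, j].copy()
    a_row = A[i, :].copy()
    if mask_label:
        a_col[i] = 0.0
        a_row[j] = 0.0
    block1 = np.vstack([Sc[i, :], a_col])
    block2 = np.vstack([a_row, Sd[j, :]])
    block3 = np.vstack(
        [projector.project(network.Y[i, :]), projector.project(network.O[j, :])]
    )
    return PairFeature(
        X=np.hstack([block1, block2, block3]),
        circ_id=circ_id,
        disease_id=disease_id,
        label=label,
    )


def build_dataset(
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[Label],
    Sc: np.ndarray,
    Sd: np.ndarray,
    network: BipartiteNetwork,
    projector: MirnaProjector,
    mask_label: bool = True,
) -> list[PairFeature]:
    """One PairFeature per (circ, disease) pair, in the given order."""
    if len(pairs) != len(labels):
        raise ConfigurationError("pairs and labels differ in length")
    if len(set(pairs)) != len(pairs):
        dupes = [p for p in set(pairs) if list(pairs).count(p) > 1]
        raise ConfigurationError(f"duplicate pairs in dataset: {dupes[:5]}")
    return [
        build_pair_feature(
            c, d, Sc, Sd, network, projector, label=lab, mask_label=mask_label
        )
        for (c, d), lab in zip(pairs, labels)
    ]


def stack_features(dataset: Sequence[PairFeature]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into (X: n x 2 x W, y: n) arrays; unknown labels -> -1."""
    X = np.stack([pf.X for pf in dataset])
    y = np.array([-1 if pf.label == "unknown" else int(pf.label) for pf in dataset])
    return X, y


def save_features(dataset: Sequence[PairFeature], path: str | Path) -> None:
    """Persist features as an .npz container plus a JSON sidecar of pair ids."""
    path = Path(path)
    X, y = stack_features(dataset)
    np.savez_compressed(path, X=X, y=y)
    sidecar = {
        "pairs": [[pf.circ_id, pf.disease_id] for pf in dataset],
        "labels": [pf.label for pf in dataset],
        "width": int(X.shape[2]),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_features(path: str | Path) -> list[PairFeature]:
    """Inverse of :func:`save_features`."""
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz) as data:
        X = data["X"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return [
        PairFeature(X=X[k], circ_id=c, disease_id=d, label=lab)
        for k, ((c, d), lab) in enumerate(zip(meta["pairs"], meta["labels"]))
    ]
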