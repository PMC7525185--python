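"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a library result from first principles by a route
the implementation does not share: exhaustive enumeration for alignments,
plain-Python arithmetic for metrics, cell-by-cell loops for feature
assembly, pair counting for AUC.
"""

from __future__ import annotations

import math

import numpy as np


def enumerate_global_alignments(
    a: str, b: str, match=5.0, mismatch=-4.0, gap_open=16.0, gap_extend=4.0
) -> tuple[float, set[float]]:
    """Enumerate EVERY global alignment of a and b with affine gap costs.

    A gap of length L costs gap_open + (L-1)*gap_extend; a gap in one
    sequence immediately following a gap in the other opens a new gap.
    N scores 0 against everything.  Returns the optimal score and the set
    of (positive columns / alignment length) fractions over all optimal
    alignments.
    """

    def sub(x: str, y: str) -> float:
        if x == "N" or y == "N":
            return 0.0
        return match if x == y else mismatch

    results: list[tuple[float, int, int]] = []

    def rec(i: int, j: int, prev: str, score: float, pos: int, length: int) -> None:
        if i == len(a) and j == len(b):
            results.append((score, pos, length))
            return
        if i < len(a) and j < len(b):
            s = sub(a[i], b[j])
            rec(i + 1, j + 1, "M", score + s, pos + (s > 0), length + 1)
        if i < len(a):
            cost = gap_extend if prev == "D" else gap_open
            rec(i + 1, j, "D", score - cost, pos, length + 1)
        if j < len(b):
            cost = gap_extend if prev == "I" else gap_open
            rec(i, j + 1, "I", score - cost, pos, length + 1)

    rec(0, 0, "", 0.0, 0, 0)
    best = max(score for score, _, _ in results)
    sims = {p / n for score, p, n in results if math.isclose(score, best)}
    return best, sims


def brute_force_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Plain-Python evaluation of the confusion-table metric formulas."""
    out: dict[str, float] = {}
    out["Pre"] = tp / (tp + fp) if tp + fp else float("nan")
    out["Sen"] = tp / (tp + fn) if tp + fn else float("nan")
    out["Acc"] = (tp + tn) / (tp + tn + fp + fn)
    if math.isnan(out["Pre"]) or math.isnan(out["Sen"]) or out["Pre"] + out["Sen"] == 0:
        out["F1"] = float("nan")
    else:
        out["F1"] = 2 * out["Sen"] * out["Pre"] / (out["Sen"] + out["Pre"])
    den = math.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    out["MCC"] = (tp * tn - fp * fn) / den if den else float("nan")
    return out


def pair_counting_auc(scores, labels) -> float:
    """AUC by direct enumeration of positive/negative pairs (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_pair_feature(
    i: int, j: int, Sc, Sd, A, Y, O, projector, mask_label: bool
) -> np.ndarray:
    """Cell-by-cell assembly of the 2 x (nc+nd+np) pair feature matrix."""
    nc, nd = A.shape
    n_p = projector.n_components
    X = np.zeros((2, nc + nd + n_p))
    for k in range(nc):
        X[0, k] = Sc[i, k]
        X[1, k] = 0.0 if (mask_label and k == i) else A[k, j]
    for k in range(nd):
        X[0, nc + k] = 0.0 if (mask_label and k == j) else A[i, k]
        X[1, nc + k] = Sd[j, k]
    y_scores = (np.asarray(Y[i, :], float) - projector.mean) @ projector.components
    o_scores = (np.asarray(O[j, :], float) - projector.mean) @ projector.components
    for k in range(n_p):
        X[0, nc + nd + k] = y_scores[k]
        X[1, nc + nd + k] = o_scores[k]
    return X


def brute_force_mutual_neighbor_weights(S: np.ndarray, k: int) -> np.ndarray:
    """Enumerate all (i, j) and score mutual/one-sided/absent neighborhood."""
    n = S.shape[0]
    hoods = []
    for i in range(n):
        others = sorted(range(n), key=lambda j: (-S[i, j], j))
        others = [j for j in others if j != i][:k]
        hoods.append({i, *others})
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            in_i, in_j = j in hoods[i], i in hoods[j]
            w[i, j] = 1.0 if (in_i and in_j) else 0.0 if not (in_i or in_j) else 0.5
    return w
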