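"""Coordination-shell neighbor graphs, mean pair distances and difference maps.

The neighbor graph is built once on the reference ("wild-type") condition:
a residue pair (i, j) belongs to the graph iff its time-averaged Cα–Cα
distance is within the second coordination shell, whose radius encloses
twice the volume of the first shell (r₂ = r₁·2^{1/3}; with the conventional
first-shell cutoff of 7.2 Å this gives ≈ 9.1 Å).  The graph is frozen and
reused for the perturbed condition so the difference map ΔR̄ᵢⱼ =
R̄ᵢⱼ,mut − R̄ᵢⱼ,ref is defined on a fixed pair set.  The per-residue profile
ΔR̄ᵢ averages a residue's incident ΔR̄ᵢⱼ over its Nₙ shell neighbors and
measures local expansion (>0) or contraction (<0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pca_states import FrameWeights
from .trajectory_io import Trajectory

__all__ = [
    "FIRST_SHELL_RADIUS",
    "DEFAULT_POS_THRESHOLD",
    "DEFAULT_NEG_THRESHOLD",
    "NeighborGraph",
    "MeanDistanceMatrix",
    "DeltaDistanceMatrix",
    "DeltaResidueProfile",
    "second_shell_radius",
    "build_neighbor_graph",
    "mean_distances",
    "delta_matrix",
    "significant_pairs",
    "delta_residue_profile",
]

#: Conventional first-coordination-shell Cα–Cα cutoff (Å), the maximum
#: separation of two contacting residues in elastic-network practice.
FIRST_SHELL_RADIUS = 7.2

#: Default significance thresholds (Å) on ΔR̄ij for "moves apart" / "moves closer".
DEFAULT_POS_THRESHOLD = 2.50
DEFAULT_NEG_THRESHOLD = -1.40


@dataclass
class NeighborGraph:
    shell_radius: float
    pairs: frozenset[tuple[int, int]]  # (i, j) with i < j, 1-based serials
    built_from: str = ""

    def neighbors_of(self, i: int) -> list[int]:
        out = [b for a, b in self.pairs if a == i] + [a for a, b in self.pairs if b == i]
        return sorted(out)


@dataclass
class MeanDistanceMatrix:
    values: dict[tuple[int, int], float]
    graph: NeighborGraph
    condition_tag: str = ""

    def __getitem__(self, pair: tuple[int, int]) -> float:
        i, j = sorted(pair)
        return self.values[(i, j)]


@dataclass
class DeltaDistanceMatrix:
    values: dict[tuple[int, int], float]
    graph: NeighborGraph
    pos_threshold: float = DEFAULT_POS_THRESHOLD
    neg_threshold: float = DEFAULT_NEG_THRESHOLD

    def __getitem__(self, pair: tuple[int, int]) -> float:
        i, j = sorted(pair)
        return self.values[(i, j)]

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, j, v) for (i, j), v in sorted(self.values.items())]
        return pd.DataFrame(rows, columns=["res_i", "res_j", "delta_mean_distance"])


@dataclass
class DeltaResidueProfile:
    """Per-residue mean of incident ΔR̄ij; NaN where a residue has no neighbors."""

    residues: np.ndarray
    values: np.ndarray
    neighbor_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "n_neighbors": self.neighbor_counts,
                "delta_mean": self.values,
            }
        )


def second_shell_radius(r1: float) -> float:
    """Radius of the sphere with twice the volume of the first shell.

    >>> round(second_shell_radius(7.2), 1)
    9.1
    """
    if r1 <= 0:
        raise ValueError("shell radius must be positive")
    return r1 * 2.0 ** (1.0 / 3.0)


def _pair_distance_means(
    traj: Trajectory, weights: FrameWeights | None, chunk: int = 200
) -> np.ndarray:
    """(N, N) matrix of weighted time-averaged Cα–Cα distances.

    Frames are processed in chunks to keep memory flat at paper scale.
    """
    if weights is None:
        weights = FrameWeights.uniform(traj.n_frames)
    coords = traj.coords[weights.frame_indices]
    w = weights.weights
    n = traj.n_residues
    acc = np.zeros((n, n))
    for start in range(0, len(w), chunk):
        c = coords[start : start + chunk]
        diff = c[:, :, None, :] - c[:, None, :, :]
        dists = np.linalg.norm(diff, axis=3)  # (chunk, N, N)
        acc += np.einsum("m,mij->ij", w[start : start + chunk], dists)
    denom = w.sum() if weights.convention == "normalized" else len(w)
    return acc / denom


def build_neighbor_graph(
    ref: Trajectory,
    radius: float | None = None,
    weights: FrameWeights | None = None,
) -> NeighborGraph:
    """Second-shell neighbor graph on the reference condition.

    A pair enters the graph iff its (weighted) time-averaged reference
    distance is ≤ ``radius`` (default the second-shell radius derived from
    the 7.2 Å first shell).  Thresholding the *time-averaged* distance makes
    the pair set deterministic and independent of frame order.
    """
    if radius is None:
        radius = second_shell_radius(FIRST_SHELL_RADIUS)
    if radius <= 0:
        raise ValueError("radius must be positive")
    mean_d = _pair_distance_means(ref, weights)
    serials = [lab[0] for lab in ref.residue_labels]
    pairs = set()
    n = ref.n_residues
    for a in range(n):
        for b in range(a + 1, n):
            if mean_d[a, b] <= radius:
                pairs.add((serials[a], serials[b]))
    return NeighborGraph(
        shell_radius=float(radius), pairs=frozenset(pairs), built_from=ref.condition_tag
    )


def mean_distances(
    traj: Trajectory,
    graph: NeighborGraph,
    weights: FrameWeights | None = None,
) -> MeanDistanceMatrix:
    """Weighted time-averaged Cα–Cα distance for every graph pair."""
    if traj.n_frames == 0:
        raise ValueError("empty frame set")
    serial_to_col = {lab[0]: k for k, lab in enumerate(traj.residue_labels)}
    missing = {i for p in graph.pairs for i in p} - set(serial_to_col)
    if missing:
        raise ValueError(f"graph residues missing from trajectory: {sorted(missing)}")
    if weights is None:
        weights = FrameWeights.uniform(traj.n_frames)
    values = {}
    coords = traj.coords
    for i, j in sorted(graph.pairs):
        d = np.linalg.norm(
            coords[:, serial_to_col[i], :] - coords[:, serial_to_col[j], :], axis=1
        )
        values[(i, j)] = float(weights.mean(d))
    return MeanDistanceMatrix(values=values, graph=graph, condition_tag=traj.condition_tag)


def delta_matrix(wt: MeanDistanceMatrix, mut: MeanDistanceMatrix) -> DeltaDistanceMatrix:
    """ΔR̄ij = R̄ij,mut − R̄ij,wt on the shared frozen pair set.

    Positive entries mean the pair moves apart in the perturbed condition,
    negative entries that it moves closer.
    """
    if wt.graph.pairs != mut.graph.pairs:
        raise ValueError("mean-distance matrices built on different neighbor graphs")
    values = {p: mut.values[p] - wt.values[p] for p in wt.values}
    return DeltaDistanceMatrix(values=values, graph=wt.graph)


def significant_pairs(
    delta: DeltaDistanceMatrix,
    pos_thresh: float = DEFAULT_POS_THRESHOLD,
    neg_thresh: float = DEFAULT_NEG_THRESHOLD,
) -> list[tuple[int, int, float, str]]:
    """Pairs whose ΔR̄ij exceeds the apart/closer significance thresholds.

    Returns ``(i, j, delta, tag)`` tuples with tag ``"apart"`` for
    ΔR̄ij > pos_thresh and ``"closer"`` for ΔR̄ij < neg_thresh.
    """
    if not (pos_thresh > 0 > neg_thresh):
        raise ValueError("need pos_thresh > 0 > neg_thresh")
    out = []
    for (i, j), v in sorted(delta.values.items()):
        if v > pos_thresh:
            out.append((i, j, v, "apart"))
        elif v < neg_thresh:
            out.append((i, j, v, "closer"))
    return out


def delta_residue_profile(
    delta: DeltaDistanceMatrix, graph: NeighborGraph | None = None
) -> DeltaResidueProfile:
    """Per-residue local volume change ΔR̄i = Σⱼ ΔR̄ij / Nₙ."""
    graph = graph or delta.graph
    if graph.pairs != delta.graph.pairs:
        raise ValueError("graph inconsistent with delta matrix")
    residues = sorted({r for p in graph.pairs for r in p})
    sums = {r: 0.0 for r in residues}
    counts = {r: 0 for r in residues}
    for (i, j), v in delta.values.items():
        sums[i] += v
        counts[i] += 1
        sums[j] += v
        counts[j] += 1
    vals = np.array([sums[r] / counts[r] if counts[r] else np.nan for r in residues])
    return DeltaResidueProfile(
        residues=np.array(residues),
        values=vals,
        neighbor_counts=np.array([counts[r] for r in residues]),
    )
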