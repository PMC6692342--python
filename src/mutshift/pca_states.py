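"""Magnitude-matrix PCA and conformational-state partitioning.

The analysis reduces each residue's mean-centered position vector to its
Euclidean norm, collects the norms in an N×M magnitude matrix, forms the
N×N second-moment matrix C = (1/M)·A·Aᵀ from it (the magnitude rows are
deliberately *not* re-centered, so C is a second-moment rather than a true
covariance matrix), and diagonalizes C.  Frames are then projected onto the
top two modes and partitioned into conformational states as connected
high-density regions of the (PCA1, PCA2) plane; the most densely populated
state and its occupancy probability drive the state-weighted averages used
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .trajectory_io import Trajectory

__all__ = [
    "MagnitudeMatrix",
    "PCAModel",
    "ProjectionSeries",
    "StatePartition",
    "FrameWeights",
    "magnitude_matrix",
    "fit_pca",
    "project",
    "partition_states",
    "state_weighted_frames",
]


@dataclass
class MagnitudeMatrix:
    """N×M matrix of ‖mean-centered residue position‖ in Å."""

    values: np.ndarray
    condition_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("magnitude matrix must be 2-D (N × M)")
        if (self.values < 0).any():
            raise ValueError("magnitudes must be non-negative")


@dataclass
class PCAModel:
    covariance: np.ndarray
    eigenvectors: np.ndarray  # columns, orthonormal, sorted by eigenvalue desc
    eigenvalues: np.ndarray


@dataclass
class ProjectionSeries:
    mode_index: int  # 1-based
    values: np.ndarray


@dataclass
class StatePartition:
    """Frame-to-state assignment on the (PCA1, PCA2) plane.

    State labels are 1-based, ordered by descending occupancy probability
    (ties broken by lexicographic order of the state centroid, then by the
    provisional label), so the dominant state is always label 1.
    """

    state_labels: np.ndarray
    state_probabilities: dict[int, float]
    dominant_state: int
    state_centroids: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_probabilities)


@dataclass
class FrameWeights:
    """Frames selected for downstream averages, each with a weight.

    ``convention`` controls how the weights enter a time average:

    - ``"normalized"`` (default): weighted mean, Σwₖxₖ/Σwₖ.  With the
      constant per-frame weight produced by dominant-state selection this
      equals the plain mean over the selected frames.
    - ``"probability-scaled"``: Σwₖxₖ/K over the K selected frames, i.e.
      the selected-frame mean multiplied by the state probability.
    """

    frame_indices: np.ndarray
    weights: np.ndarray
    convention: str = "normalized"

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.frame_indices.shape != self.weights.shape:
            raise ValueError("frame_indices and weights must have equal length")
        if self.convention not in ("normalized", "probability-scaled"):
            raise ValueError(f"unknown weighting convention {self.convention!r}")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def mean(self, values: np.ndarray, axis: int = 0) -> np.ndarray:
        """Weighted time average of per-frame values (frame axis first)."""
        v = np.asarray(values)[self.frame_indices]
        w = self.weights
        shape = [1] * v.ndim
        shape[axis] = len(w)
        wb = w.reshape(shape)
        if self.convention == "normalized":
            return (v * wb).sum(axis=axis) / w.sum()
        return (v * wb).sum(axis=axis) / len(w)

    @classmethod
    def uniform(cls, n_frames: int) -> "FrameWeights":
        return cls(np.arange(n_frames), np.ones(n_frames))


def magnitude_matrix(traj: Trajectory) -> MagnitudeMatrix:
    """Magnitudes of mean-centered residue positions, shape (N, M).

    Entry (i, m) is ‖r_i(t_m) − ⟨r_i⟩‖ with ⟨r_i⟩ the temporal mean over
    all M frames.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    centered = traj.coords - traj.coords.mean(axis=0, keepdims=True)
    mags = np.linalg.norm(centered, axis=2).T  # (N, M)
    return MagnitudeMatrix(mags, condition_tag=traj.condition_tag)


def fit_pca(mag: MagnitudeMatrix) -> PCAModel:
    """Second-moment matrix C = (1/M)·A·Aᵀ and its eigendecomposition.

    The magnitude rows are used exactly as given (no row re-centering).
    Eigenpairs are sorted by descending eigenvalue; each eigenvector's sign
    is fixed so its largest-magnitude component is positive.
    """
    a = mag.values
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite entries in magnitude matrix")
    n, m = a.shape
    if m < 2:
        raise ValueError("need at least 2 frames for PCA")
    cov = (a @ a.T) / m
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for i in range(n):
        k = np.argmax(np.abs(evecs[:, i]))
        if evecs[k, i] < 0:
            evecs[:, i] = -evecs[:, i]
    return PCAModel(covariance=cov, eigenvectors=evecs, eigenvalues=evals)


def project(mag: MagnitudeMatrix, model: PCAModel, mode: int) -> ProjectionSeries:
    """Project each frame's magnitude column onto the given PCA mode (1-based)."""
    n = mag.values.shape[0]
    if not 1 <= mode <= n:
        raise ValueError(f"mode must be in 1..{n}")
    v = model.eigenvectors[:, mode - 1]
    return ProjectionSeries(mode_index=mode, values=v @ mag.values)


def partition_states(
    pc1: ProjectionSeries,
    pc2: ProjectionSeries,
    bins: int | None = None,
    density_floor: float = 0.10,
) -> StatePartition:
    """Partition frames into connected high-density states of the PCA plane.

    A 2-D histogram is built on (PCA1, PCA2) — by default √M bins per axis
    (clipped to 8..64), a rule that neither over-resolves sparse samples nor
    merges well-separated modes; pass ``bins`` to override.  The histogram is
    smoothed with a 1-bin Gaussian kernel to give a stable density estimate;
    bins with smoothed density above ``density_floor``·max form state cores,
    and states are the 4-connected components of the core bins.  Frames
    falling outside every core are assigned to the nearest core bin
    (Euclidean distance between bin centers), so every frame is labeled.
    Deterministic and invariant to frame order.
    """
    x = np.asarray(pc1.values, dtype=float)
    y = np.asarray(pc2.values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("projection series lengths differ")
    m = len(x)

    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return StatePartition(
            state_labels=np.ones(m, dtype=int),
            state_probabilities={1: 1.0},
            dominant_state=1,
            state_centroids={1: (float(x[0]), float(y[0]))},
        )

    if bins is None:
        bins = int(np.clip(np.ceil(np.sqrt(m)), 8, 64))
    xe = np.linspace(x.min(), x.max(), bins + 1) if np.ptp(x) > 0 else np.array([x[0] - 0.5, x[0] + 0.5])
    ye = np.linspace(y.min(), y.max(), bins + 1) if np.ptp(y) > 0 else np.array([y[0] - 0.5, y[0] + 0.5])
    counts, xe, ye = np.histogram2d(x, y, bins=[xe, ye])
    density = ndimage.gaussian_filter(counts, sigma=1.0, mode="constant")

    core = density > density_floor * density.max()
    comp, n_comp = ndimage.label(core, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])

    # map every frame to its bin
    ix = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, counts.shape[0] - 1)
    iy = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, counts.shape[1] - 1)
    labels = comp[ix, iy]

    if (labels == 0).any():
        xc = 0.5 * (xe[:-1] + xe[1:])
        yc = 0.5 * (ye[:-1] + ye[1:])
        core_idx = np.argwhere(comp > 0)
        tree = cKDTree(np.column_stack([xc[core_idx[:, 0]], yc[core_idx[:, 1]]]))
        out = labels == 0
        _, nearest = tree.query(np.column_stack([x[out], y[out]]))
        labels[out] = comp[core_idx[nearest, 0], core_idx[nearest, 1]]

    # relabel: descending probability, ties by centroid lexicographic order
    stats = []
    for lab in range(1, n_comp + 1):
        mask = labels == lab
        cnt = int(mask.sum())
        cx = float(x[mask].mean()) if cnt else np.inf
        cy = float(y[mask].mean()) if cnt else np.inf
        stats.append((-cnt, cx, cy, lab))
    stats.sort()
    remap = {old: new + 1 for new, (_, _, _, old) in enumerate(stats)}
    new_labels = np.array([remap[lab] for lab in labels], dtype=int)

    probs: dict[int, float] = {}
    centroids: dict[int, tuple[float, float]] = {}
    for negcnt, cx, cy, old in stats:
        lab = remap[old]
        probs[lab] = -negcnt / m
        centroids[lab] = (cx, cy)
    probs = {k: v for k, v in probs.items() if v > 0}
    centroids = {k: centroids[k] for k in probs}
    dominant = min(k for k in probs if probs[k] == max(probs.values()))
    return StatePartition(
        state_labels=new_labels,
        state_probabilities=probs,
        dominant_state=dominant,
        state_centroids=centroids,
    )


def state_weighted_frames(
    part: StatePartition, traj: Trajectory, convention: str = "normalized"
) -> FrameWeights:
    """Dominant-state frames, each weighted by the dominant-state probability."""
    if len(part.state_labels) != traj.n_frames:
        raise ValueError("partition does not cover the trajectory")
    idx = np.flatnonzero(part.state_labels == part.dominant_state)
    assert idx.size > 0, "dominant state cannot be empty"
    p = part.state_probabilities[part.dominant_state]
    return FrameWeights(idx, np.full(idx.size, p), convention=convention)
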