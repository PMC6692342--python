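"""Per-residue RMSF and pairwise fluctuation cross-correlation maps.

RMSF_i = sqrt(⟨‖r_i(t) − ⟨r_i⟩‖²⟩) measures a residue's average excursion
about its temporal mean after rigid-body motion is removed.  The dynamic
cross-correlation C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨‖Δr_i‖²⟩⟨‖Δr_j‖²⟩) of the 3-D
fluctuation vectors lies in [−1, 1]: +1 for perfectly coupled motion, −1
for perfectly anti-coupled, 0 for uncoupled.  Difference maps between
conditions expose correlations lost or newly formed upon mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pca_states import FrameWeights
from .trajectory_io import Trajectory

__all__ = [
    "RMSFProfile",
    "CorrelationMap",
    "CorrelationDifference",
    "rmsf",
    "correlation_map",
    "difference_map",
    "DEFAULT_CATEGORY_THRESHOLD",
]

DEFAULT_CATEGORY_THRESHOLD = 0.4

CATEGORY_CODES = {
    "unchanged": 0,
    "gained-positive": 1,
    "gained-negative": 2,
    "lost": 3,
}


@dataclass
class RMSFProfile:
    values: np.ndarray  # per-residue, Å
    condition_tag: str = ""
    effective_n: float = 0.0  # Kish effective sample size of the weights


@dataclass
class CorrelationMap:
    values: np.ndarray  # (N, N), zeros where undefined
    defined: np.ndarray  # (N, N) bool; False where a residue had zero fluctuation
    condition_tag: str = ""
    effective_n: float = 0.0


@dataclass
class CorrelationDifference:
    delta: np.ndarray  # b − a
    categories: np.ndarray  # (N, N) int codes, see CATEGORY_CODES
    threshold: float

    def category_name(self, i: int, j: int) -> str:
        inv = {v: k for k, v in CATEGORY_CODES.items()}
        return inv[int(self.categories[i, j])]


def _weights_or_uniform(traj: Trajectory, weights: FrameWeights | None):
    if weights is None:
        weights = FrameWeights.uniform(traj.n_frames)
    coords = traj.coords[weights.frame_indices]
    w = weights.weights / weights.weights.sum()
    ess = 1.0 / float((w**2).sum())
    return coords, w, ess


def rmsf(traj: Trajectory, weights: FrameWeights | None = None) -> RMSFProfile:
    """Root-mean-square fluctuation of each residue about its weighted mean.

    Requires an aligned trajectory; RMSF is meaningless while rigid-body
    motion is still present.
    """
    if not traj.aligned:
        raise ValueError("trajectory must be superposed to its first frame first")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    coords, w, ess = _weights_or_uniform(traj, weights)
    mean = np.einsum("m,mnd->nd", w, coords)
    dev = coords - mean
    msf = np.einsum("m,mnd,mnd->n", w, dev, dev)
    return RMSFProfile(values=np.sqrt(msf), condition_tag=traj.condition_tag, effective_n=ess)


def correlation_map(
    traj: Trajectory,
    weights: FrameWeights | None = None,
    convention: str = "vector",
) -> CorrelationMap:
    """Dynamic cross-correlation of residue fluctuations.

    ``convention="vector"`` (standard) correlates the 3-D fluctuation
    vectors; ``"magnitude"`` correlates the scalar fluctuation magnitudes
    (Pearson correlation of ‖Δr_i(t)‖ series), exposed for sensitivity
    checks.  Residues with zero fluctuation give undefined rows/columns,
    flagged in ``defined`` with the value stored as 0.
    """
    if not traj.aligned:
        raise ValueError("trajectory must be superposed to its first frame first")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    coords, w, ess = _weights_or_uniform(traj, weights)
    mean = np.einsum("m,mnd->nd", w, coords)
    dev = coords - mean
    if convention == "vector":
        cross = np.einsum("m,mnd,mkd->nk", w, dev, dev)
    elif convention == "magnitude":
        mags = np.linalg.norm(dev, axis=2)  # (M, N)
        mags = mags - np.einsum("m,mn->n", w, mags)
        cross = np.einsum("m,mn,mk->nk", w, mags, mags)
    else:
        raise ValueError(f"unknown correlation convention {convention!r}")
    var = np.diag(cross).copy()
    mobile = var > 1e-12  # fluctuations below 1e-6 Å count as static
    denom = np.sqrt(np.outer(var, var), where=np.outer(mobile, mobile), out=np.ones_like(cross))
    values = np.where(np.outer(mobile, mobile), cross / denom, 0.0)
    np.clip(values, -1.0, 1.0, out=values)
    defined = np.outer(mobile, mobile)
    return CorrelationMap(
        values=values, defined=defined, condition_tag=traj.condition_tag, effective_n=ess
    )


def difference_map(
    a: CorrelationMap | RMSFProfile,
    b: "CorrelationMap | RMSFProfile",
    threshold: float = DEFAULT_CATEGORY_THRESHOLD,
):
    """Elementwise b − a between two conditions.

    For RMSF profiles the result is a plain per-residue delta array.  For
    correlation maps the result also carries a categorical map: a pair is
    ``gained-positive``/``gained-negative`` when its correlation magnitude
    rises from below ``threshold`` in *a* to at/above it in *b* (sign from
    *b*; a sign flip at large magnitude counts as gained with the new
    sign), ``lost`` when it falls from at/above to below, else
    ``unchanged``.
    """
    if isinstance(a, RMSFProfile) and isinstance(b, RMSFProfile):
        if a.values.shape != b.values.shape:
            raise ValueError("profile length mismatch")
        return b.values - a.values
    if not (isinstance(a, CorrelationMap) and isinstance(b, CorrelationMap)):
        raise TypeError("inputs must both be CorrelationMap or both RMSFProfile")
    if a.values.shape != b.values.shape:
        raise ValueError("map shape mismatch")
    delta = b.values - a.values
    big_a = np.abs(a.values) >= threshold
    big_b = np.abs(b.values) >= threshold
    same_sign = np.sign(a.values) == np.sign(b.values)
    cats = np.zeros(a.values.shape, dtype=int)
    gained = big_b & (~big_a | ~same_sign)
    cats[gained & (b.values > 0)] = CATEGORY_CODES["gained-positive"]
    cats[gained & (b.values < 0)] = CATEGORY_CODES["gained-negative"]
    cats[big_a & ~big_b] = CATEGORY_CODES["lost"]
    cats[~(a.defined & b.defined)] = CATEGORY_CODES["unchanged"]
    np.fill_diagonal(cats, CATEGORY_CODES["unchanged"])
    return CorrelationDifference(delta=delta, categories=cats, threshold=threshold)
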