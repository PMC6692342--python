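"""Synthetic Cα trajectory pairs with planted, recoverable structure.

The generator emulates the data regime the analysis pipeline targets —
paired "wild-type" / "mutant" Cα trajectories of a single-domain protein,
~10 ps frame spacing — with every analysis readout planted as ground truth:

* a self-avoiding backbone chain (mean Cα–Cα step 3.8 Å) shared by both
  conditions, plus iid per-coordinate Gaussian noise;
* one *multi-state pair*: a short terminal segment whose distance to an
  anchor residue switches between planted means (default 8.3 / 16.0 Å)
  under a two-state Markov chain with uneven stationary occupancies
  (default 0.8 / 0.2); in the mutant the minor state collapses, leaving a
  predominant conformation;
* five *shifted pairs*: residues displaced in the mutant mean structure so
  exactly those pairs' time-averaged distances grow by a planted amount
  (default +3 Å) while every other second-shell pair stays inside the
  significance thresholds;
* a mutant-only *factor field*: a zero-momentum displacement pattern with
  opposite loadings on a source block and three target blocks, giving
  anti-correlated fluctuations (gained-negative correlations) exactly
  between source and target residues;
* optional pseudo-side-chain atoms carrying a salt bridge coupled to the
  Markov state and an always-present hydrogen bond, so interaction
  detection is testable without real structures;
* rigid-body drift applied last, so frame superposition is exercised.

The planted quantities are returned in a :class:`GroundTruth` record keyed
like the pipeline outputs.  Generation is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory_io import AtomRecord, Trajectory

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_pair",
    "ground_truth_report",
    "write_ground_truth",
    "read_ground_truth",
    "factor_model_correlation",
    "markov_stationary",
]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic wild-type/mutant pair.

    Defaults are the desk-scale fixture: 50 residues, 2000 frames at 10 ps.
    ``paper_scale`` switches to 165 residues × 10000 frames.
    """

    n_residues: int = 50
    n_frames: int = 2000
    frame_dt: float = 10.0  # ps
    seed: int = 0
    bond_length: float = 3.8  # Å, mean Cα–Cα step
    noise_sigma: float = 0.3  # Å, per coordinate per frame

    # multi-state (Markov) pair: terminal segment vs an anchor residue
    state_means: tuple[float, ...] = (8.3, 16.0)
    state_sigmas: tuple[float, ...] = (0.5, 0.5)
    transition: tuple[tuple[float, ...], ...] = ((0.98, 0.02), (0.08, 0.92))
    segment_length: int = 3
    anchor_offset: int = 8  # chain separation between anchor and segment end
    mut_state_collapse: bool = True  # mutant stays in state 1

    # planted mean-distance shifts (mutant only)
    n_shift_pairs: int = 5
    shift: float = 3.0  # Å

    # mutant-only anti-correlated factor field
    factor_sigma: float = 1.5  # Å, factor amplitude std
    source_loading: float = 2.0
    target_loading: float = -2.0 / 3.0  # balances momentum: 4·2 = 12·(2/3)
    block_size: int = 4
    n_target_blocks: int = 3

    rigid_drift: bool = True
    drift_rot_deg: float = 0.5  # per-frame rotation random-walk step
    drift_trans: float = 0.05  # Å per-frame translation random-walk step

    pseudo_sidechains: bool = True
    salt_bridge_bound: float = 2.9  # Å O–N when the coupled state is occupied
    salt_bridge_unbound: float = 6.0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if any(s <= 0 for s in self.state_sigmas) and self.noise_sigma > 0:
            raise ValueError("state sigmas must be positive")
        if self.n_residues < 20:
            raise ValueError("need at least 20 residues for the planted layout")
        reach = self.bond_length * self.anchor_offset
        if max(self.state_means) > reach:
            raise ValueError(
                f"planted state mean {max(self.state_means)} Å exceeds the chain "
                f"reach {reach:.1f} Å between anchor and segment"
            )

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "SyntheticConfig":
        return cls(n_residues=165, n_frames=10000, seed=seed)

    def segment_indices(self) -> list[int]:
        return list(range(self.n_residues - self.segment_length, self.n_residues))

    @property
    def anchor_index(self) -> int:
        return self.n_residues - 1 - self.anchor_offset


@dataclass
class GroundTruth:
    """Planted quantities, keyed like the pipeline outputs (1-based serials)."""

    seed: int
    n_residues: int
    n_frames: int
    multistate_pair: tuple[int, int]
    state_means: list[float]
    state_sigmas: list[float]
    stationary_probs: list[float]
    wt_state_probs: list[float]  # empirical fractions of the realized path
    mut_state_probs: list[float]
    wt_peaks: list[float]
    mut_peaks: list[float]
    shift_pairs: list[tuple[int, int, float]]  # (i, j, implied ΔR̄ij)
    significant_pairs: list[tuple[int, int]]
    gained_negative_pairs: list[tuple[int, int]]
    planted_correlations: dict[str, float]  # "i-j" -> analytic C_ij (mutant)
    salt_bridge: dict | None = None
    hbond: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["multistate_pair"] = tuple(d["multistate_pair"])
        d["shift_pairs"] = [tuple(p) for p in d["shift_pairs"]]
        d["significant_pairs"] = [tuple(p) for p in d["significant_pairs"]]
        d["gained_negative_pairs"] = [tuple(p) for p in d["gained_negative_pairs"]]
        return cls(**d)


def ground_truth_report(gt: GroundTruth) -> dict:
    """JSON-ready dict of all planted quantities."""
    return gt.to_dict()


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth_report(gt), fh, indent=2)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


def markov_stationary(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    t = np.asarray(transition, dtype=float)
    evals, evecs = np.linalg.eig(t.T)
    k = np.argmin(np.abs(evals - 1.0))
    p = np.real(evecs[:, k])
    return p / p.sum()


def factor_model_correlation(
    phi_i: np.ndarray, phi_j: np.ndarray, sigma_s: float, noise_sigma: float
) -> float:
    """Analytic cross-correlation of two residues under a one-factor model.

    With fluctuations Δr_i = s(t)·Φ_i + ε_i, s ~ N(0, σ_s²) and iid
    per-coordinate noise of std ``noise_sigma``:

        C_ij = (Φ_i·Φ_j) σ_s² / √[(|Φ_i|²σ_s² + 3σ_ε²)(|Φ_j|²σ_s² + 3σ_ε²)]
    """
    s2 = sigma_s**2
    e2 = 3.0 * noise_sigma**2
    num = float(np.dot(phi_i, phi_j)) * s2
    den = np.sqrt((np.dot(phi_i, phi_i) * s2 + e2) * (np.dot(phi_j, phi_j) * s2 + e2))
    return num / den


# ---------------------------------------------------------------------------
# backbone and planting helpers
# ---------------------------------------------------------------------------


def _self_avoiding_chain(n: int, step: float, rng: np.random.Generator) -> np.ndarray:
    """Persistent self-avoiding walk; non-adjacent residues kept ≥ 4 Å apart."""
    for _attempt in range(50):
        pos = [np.zeros(3)]
        direction = _random_unit(rng)
        ok = True
        for _i in range(1, n):
            placed = False
            for _try in range(300):
                cand_dir = direction * 1.2 + _random_unit(rng)
                cand_dir /= np.linalg.norm(cand_dir)
                cand = pos[-1] + step * cand_dir
                prev = np.asarray(pos[:-1])
                if len(prev) == 0 or np.linalg.norm(prev - cand, axis=1).min() >= 4.0:
                    pos.append(cand)
                    direction = cand_dir
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pos)
    raise RuntimeError("failed to grow a self-avoiding chain")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _markov_path(
    transition: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    p = markov_stationary(transition)
    k = len(p)
    path = np.empty(n, dtype=int)
    path[0] = rng.choice(k, p=p)
    for m in range(1, n):
        path[m] = rng.choice(k, p=transition[path[m - 1]])
    return path


def _segment_state_positions(
    backbone: np.ndarray, cfg: SyntheticConfig, u_seg: np.ndarray
) -> list[np.ndarray]:
    """Segment mean positions in each planted state (translation planting)."""
    seg = cfg.segment_indices()
    anchor = backbone[cfg.anchor_index]
    j0 = backbone[seg[-1]]
    out = []
    for d in cfg.state_means:
        delta = anchor + d * u_seg - j0
        out.append(backbone[seg] + delta)
    return out


def _implied_mean_structure(
    backbone: np.ndarray,
    cfg: SyntheticConfig,
    u_seg: np.ndarray,
    state_probs: np.ndarray,
    moved: dict[int, np.ndarray],
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Noise-free structure with moved residues; segment handled per state."""
    base = backbone.copy()
    for j, p in moved.items():
        base[j] = p
    seg_states = _segment_state_positions(backbone, cfg, u_seg)
    return base, seg_states


def _implied_pair_means(
    base: np.ndarray,
    seg_states: list[np.ndarray],
    seg_idx: list[int],
    state_probs: np.ndarray,
) -> np.ndarray:
    """All-pairs state-mixture mean distances of the noise-free structure."""
    n = len(base)
    struct = base.copy()
    dmats = []
    for s, seg_pos in enumerate(seg_states):
        struct[seg_idx] = seg_pos
        diff = struct[:, None, :] - struct[None, :, :]
        dmats.append(np.linalg.norm(diff, axis=2))
    out = np.zeros((n, n))
    for p, dm in zip(state_probs, dmats):
        out += p * dm
    return out


def _choose_shift_pairs(
    backbone: np.ndarray,
    cfg: SyntheticConfig,
    blocked: set[int],
    u_seg: np.ndarray,
    rng: np.random.Generator,
) -> dict[tuple[int, int], dict[int, np.ndarray]]:
    """Pick pairs (i, j) and mutant displacements so that exactly the
    planted pairs cross the significance thresholds.

    The pair partner is i = j±2 (a natural second-shell pair at ~5–7.5 Å).
    j is moved so d(i, j) grows by ``cfg.shift``; its chain neighbors j±1
    are dragged along at 40% of the displacement (a harmonic-restraint-like
    relaxation) so their own pair distances stay controlled.  A candidate
    direction is accepted only if every other second-shell distance of the
    moved trio changes within (−1.2, 2.3) Å — inside the (−1.40, 2.50)
    defaults — with ≥ 3.4 Å clearance, ≥ 10 Å from the swinging segment
    and from previously planted zones.  Returns per-pair displacement maps.
    """
    n = cfg.n_residues
    seg_pts = np.vstack(
        [backbone[cfg.segment_indices()]]
        + _segment_state_positions(backbone, cfg, u_seg)
    )
    dist0 = np.linalg.norm(backbone[:, None, :] - backbone[None, :, :], axis=2)

    candidates = []
    for j in range(n):
        if j in blocked or (j - 1) in blocked or (j + 1) in blocked:
            continue
        for i in (j - 2, j + 2):
            if 0 <= i < n and i not in blocked and 4.2 <= dist0[i, j] <= 7.8:
                candidates.append((i, j))
    rng.shuffle(candidates)

    chosen: dict[tuple[int, int], dict[int, np.ndarray]] = {}
    used: set[int] = set()
    zone_pts: list[np.ndarray] = []
    for i, j in candidates:
        if len(chosen) == cfg.n_shift_pairs:
            break
        if any(abs(j - k) < 6 for k in used):
            continue
        u0 = (backbone[j] - backbone[i]) / dist0[i, j]
        target_d = dist0[i, j] + cfg.shift
        for trial in range(400):
            if trial == 0:
                u = u0
            else:
                u = u0 + rng.normal(size=3)
                u /= np.linalg.norm(u)
            p_new = backbone[i] + target_d * u
            delta = p_new - backbone[j]
            moves = {j: delta}
            for jj in (j - 1, j + 1):
                if 0 <= jj < n and jj not in blocked:
                    moves[jj] = 0.4 * delta
            ok = True
            for a, da in moves.items():
                pa = backbone[a] + da
                for k in range(n):
                    if k == a:
                        continue
                    dk = moves.get(k)
                    pk = backbone[k] if dk is None else backbone[k] + dk
                    new = np.linalg.norm(pa - pk)
                    if new < 3.4:
                        ok = False
                        break
                    if (a, k) in ((j, i), (i, j)):
                        continue
                    old = dist0[a, k]
                    if old <= 10.0 and not (-1.2 < new - old < 2.3):
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            pts = np.vstack(
                [[backbone[a] + da for a, da in moves.items()]]
                + [[backbone[a] for a in moves]]
            )
            if np.linalg.norm(seg_pts[:, None, :] - pts[None, :, :], axis=2).min() < 10.0:
                continue
            if zone_pts and np.linalg.norm(
                np.asarray(zone_pts)[:, None, :] - pts[None, :, :], axis=2
            ).min() < 10.0:
                continue
            chosen[(i, j)] = moves
            used.update((i, j))
            zone_pts.extend(pts)
            break
    if len(chosen) < cfg.n_shift_pairs:
        raise RuntimeError("could not place the requested shift pairs")
    return chosen


def _choose_factor_blocks(
    backbone: np.ndarray,
    cfg: SyntheticConfig,
    moved: dict[tuple[int, int], "np.ndarray"],
    rng: np.random.Generator,
) -> tuple[list[int], list[list[int]]]:
    """Contiguous source and target blocks, spatially clear of the planted
    shift pairs and of the swinging segment (0-based indices)."""
    n = cfg.n_residues
    shift_res = {k for p in moved for k in p}
    moved_res = {a for mv in moved.values() for a in mv}
    seg_block = set(cfg.segment_indices()) | {cfg.anchor_index}
    excluded = shift_res | moved_res | seg_block
    bs = cfg.block_size
    runs = []
    for start in range(0, n - bs + 1):
        block = list(range(start, start + bs))
        if any(k in excluded for k in block):
            continue
        runs.append(block)
    chosen: list[list[int]] = []
    order = list(range(len(runs)))
    rng.shuffle(order)
    for idx in order:
        block = runs[idx]
        if any(set(block) & set(c) for c in chosen):
            continue
        chosen.append(block)
        if len(chosen) == 1 + cfg.n_target_blocks:
            break
    if len(chosen) < 1 + cfg.n_target_blocks:
        raise RuntimeError("could not place the factor blocks")
    return chosen[0], chosen[1:]


def _factor_field(
    backbone: np.ndarray,
    cfg: SyntheticConfig,
    source: list[int],
    targets: list[list[int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-rigid-body displacement field Φ (N×3) realizing the blocks.

    The loadings are momentum-balanced (Σaᵢ = 0) and the common direction û
    is taken parallel to Σaᵢrᵢ, which makes the net torque (Σaᵢrᵢ)×û vanish:
    the field is orthogonal to all six rigid-body modes by construction, so
    frame superposition leaves the planted motion intact and no loading
    leaks onto unplanted residues.  The six modes are still projected out
    numerically as a safety net.
    """
    n = cfg.n_residues
    loads = np.zeros(n)
    loads[source] = cfg.source_loading
    for block in targets:
        loads[block] = cfg.target_loading
    loads -= loads.mean()  # exact momentum balance
    center = backbone - backbone.mean(axis=0)
    w = loads @ center
    u = w / np.linalg.norm(w) if np.linalg.norm(w) > 1e-9 else _random_unit(rng)
    phi = loads[:, None] * u[None, :]

    modes = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = 1.0
        modes.append(t.ravel())
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        modes.append(np.cross(np.broadcast_to(axis, (n, 3)), center).ravel())
    flat = phi.ravel().astype(float)
    basis = np.linalg.qr(np.asarray(modes).T)[0]
    flat -= basis @ (basis.T @ flat)
    return flat.reshape(n, 3)


def _apply_drift(
    coords: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list]:
    """Cumulative rigid-body rotation+translation random walk, frame 0 fixed."""
    m = coords.shape[0]
    out = coords.copy()
    transforms = [(Rotation.identity(), np.zeros(3))]
    rot = Rotation.identity()
    trans = np.zeros(3)
    pivot = coords[0].mean(axis=0)
    for k in range(1, m):
        step = Rotation.from_rotvec(
            np.radians(cfg.drift_rot_deg) * rng.normal(size=3)
        )
        rot = step * rot
        trans = trans + cfg.drift_trans * rng.normal(size=3)
        out[k] = rot.apply(coords[k] - pivot) + pivot + trans
        transforms.append((rot, trans))
    return out, transforms


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def generate_pair(
    config: SyntheticConfig,
) -> tuple[Trajectory, Trajectory, GroundTruth]:
    """Generate the wild-type and mutant trajectories plus their ground truth."""
    cfg = config
    for sub in range(20):
        try:
            return _generate_once(cfg, sub)
        except RuntimeError:
            continue
    raise RuntimeError("synthetic geometry search failed for this configuration")


def _generate_once(cfg: SyntheticConfig, sub: int):
    ss = np.random.SeedSequence([cfg.seed, sub])
    (
        r_backbone,
        r_pairs,
        r_factor,
        r_wt,
        r_mut,
        r_path_wt,
        r_path_mut,
        r_drift_wt,
        r_drift_mut,
    ) = [np.random.default_rng(s) for s in ss.spawn(9)]

    n, m = cfg.n_residues, cfg.n_frames
    backbone = _self_avoiding_chain(n, cfg.bond_length, r_backbone)
    transition = np.asarray(cfg.transition, dtype=float)
    stationary = markov_stationary(transition)

    seg_idx = cfg.segment_indices()
    anchor = cfg.anchor_index

    # segment swing direction: away from the chain body, collision-checked
    body = np.array([k for k in range(n) if k not in seg_idx])
    u_seg = None
    outward = backbone[seg_idx[-1]] - backbone[body].mean(axis=0)
    outward /= np.linalg.norm(outward)
    for trial in range(200):
        cand = outward if trial == 0 else _random_unit(r_backbone)
        states = _segment_state_positions(backbone, cfg, cand)
        clear = min(
            np.linalg.norm(backbone[body][:, None, :] - sp[None, :, :], axis=2).min()
            for sp in states
        )
        if clear >= 3.8:
            u_seg = cand
            break
    if u_seg is None:
        raise RuntimeError("no collision-free segment swing direction")

    moved = _choose_shift_pairs(
        backbone, cfg, set(seg_idx) | {anchor}, u_seg, r_pairs
    )
    source, targets = _choose_factor_blocks(backbone, cfg, moved, r_factor)
    phi = _factor_field(backbone, cfg, source, targets, r_factor)

    # ---- self-check: construction-implied significant set is exactly planted
    displacements = {
        a: backbone[a] + da for mv in moved.values() for a, da in mv.items()
    }
    base_mut, seg_states = _implied_mean_structure(
        backbone, cfg, u_seg, stationary, displacements
    )
    wt_probs = stationary
    mut_probs = np.array([1.0, 0.0]) if cfg.mut_state_collapse else stationary
    d_wt = _implied_pair_means(backbone, seg_states, seg_idx, wt_probs)
    d_mut = _implied_pair_means(base_mut, seg_states, seg_idx, mut_probs)
    shell = 7.2 * 2.0 ** (1.0 / 3.0)
    planted = {tuple(sorted((i, j))) for (i, j) in moved}
    # mutant-only factor fluctuations inflate mean distances (convexity);
    # perpendicular variance is 2/3 of the relative factor displacement
    rel = phi[:, None, :] - phi[None, :, :]
    var_perp = (2.0 / 3.0) * (rel**2).sum(axis=2) * cfg.factor_sigma**2
    for a in range(n):
        for b in range(a + 1, n):
            if d_wt[a, b] > shell:
                continue
            d_mut_eff = np.sqrt(d_mut[a, b] ** 2 + var_perp[a, b])
            delta = d_mut_eff - d_wt[a, b]
            if (a, b) in planted:
                if delta < 2.6:
                    raise RuntimeError("planted shift eroded by geometry")
            elif not (-1.25 < delta < 2.35):
                raise RuntimeError("unplanted pair crosses the thresholds")

    # ---- assemble frames -------------------------------------------------
    path_wt = _markov_path(transition, m, r_path_wt)
    if cfg.mut_state_collapse:
        path_mut = np.zeros(m, dtype=int)
    else:
        path_mut = _markov_path(transition, m, r_path_mut)

    def build(base, path, noise_rng, with_factor):
        coords = np.broadcast_to(base, (m, n, 3)).copy()
        coords += noise_rng.normal(scale=cfg.noise_sigma, size=(m, n, 3))
        if with_factor:
            s = noise_rng.normal(scale=cfg.factor_sigma, size=m)
            coords += s[:, None, None] * phi[None, :, :]
        # pin the segment: rigid translation so |r_segend - r_anchor| = d_m
        d = np.array(
            [
                cfg.state_means[p] + cfg.state_sigmas[p] * noise_rng.normal()
                for p in path
            ]
        )
        target = coords[:, anchor, :] + d[:, None] * u_seg
        delta = target - coords[:, seg_idx[-1], :]
        coords[:, seg_idx, :] += delta[:, None, :]
        return coords

    coords_wt = build(backbone, path_wt, r_wt, with_factor=False)
    coords_mut = build(base_mut, path_mut, r_mut, with_factor=True)

    serial = lambda k: k + 1  # noqa: E731  1-based residue serials

    # ---- pseudo-side-chain atoms ----------------------------------------
    labels = [(k + 1, "GLY") for k in range(n)]
    salt_truth = hbond_truth = None
    details = {"WT": [], "MUT": []}
    if cfg.pseudo_sidechains:
        shift_residues = {k for p in moved for k in p} | set(displacements)
        block_residues = set(source).union(*targets)
        quiet = [
            k
            for k in range(n)
            if k not in block_residues
            and k not in seg_idx
            and k not in shift_residues
            and k != anchor
        ]
        acid, base_res, donor_res, acc_res = quiet[0], quiet[1], quiet[2], quiet[3]
        labels[acid] = (acid + 1, "GLU")
        labels[base_res] = (base_res + 1, "LYS")

        def sidechains(coords, path):
            v = coords[:, base_res, :] - coords[:, acid, :]
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            oe1 = coords[:, acid, :] + 1.0 * v
            on = np.where(
                np.asarray(path)[:, None] == 0,
                cfg.salt_bridge_bound,
                cfg.salt_bridge_unbound,
            )
            nz = oe1 + on * v
            w = coords[:, acc_res, :] - coords[:, donor_res, :]
            w /= np.linalg.norm(w, axis=1, keepdims=True)
            o_acc = coords[:, acc_res, :] + 1.0 * w
            n_don = o_acc - 2.9 * w
            h_don = n_don + 1.0 * w  # collinear N–H···O
            return [
                AtomRecord(acid + 1, "GLU", "OE1", "O", oe1),
                AtomRecord(base_res + 1, "LYS", "NZ", "N", nz),
                AtomRecord(donor_res + 1, "GLY", "N", "N", n_don),
                AtomRecord(donor_res + 1, "GLY", "H", "H", h_don),
                AtomRecord(acc_res + 1, "GLY", "O", "O", o_acc),
            ]

        details["WT"] = sidechains(coords_wt, path_wt)
        details["MUT"] = sidechains(coords_mut, path_mut)
        salt_truth = {
            "acid_residue": acid + 1,
            "base_residue": base_res + 1,
            "coupled_state": 1,
            "occupancy_wt": float((path_wt == 0).mean()),
            "occupancy_mut": float((path_mut == 0).mean()),
        }
        hbond_truth = {
            "donor_residue": donor_res + 1,
            "acceptor_residue": acc_res + 1,
            "occupancy": 1.0,
        }

    # ---- rigid drift (last, so alignment is exercised) -------------------
    def drift(coords, detail, rng):
        if not cfg.rigid_drift:
            return coords, detail
        out, transforms = _apply_drift(coords, cfg, rng)
        new_detail = []
        pivot = coords[0].mean(axis=0)
        for rec in detail:
            c = rec.coords.copy()
            for k in range(1, m):
                rot, trans = transforms[k]
                c[k] = rot.apply(rec.coords[k] - pivot) + pivot + trans
            new_detail.append(AtomRecord(rec.residue_index, rec.residue_name, rec.atom_name, rec.element, c))
        return out, new_detail

    coords_wt, det_wt = drift(coords_wt, details["WT"], r_drift_wt)
    coords_mut, det_mut = drift(coords_mut, details["MUT"], r_drift_mut)

    times = np.arange(m) * cfg.frame_dt
    wt = Trajectory(coords_wt, labels, times, condition_tag="WT", atom_detail=det_wt)
    mut = Trajectory(coords_mut, labels, times, condition_tag="MUT", atom_detail=det_mut)

    # ---- ground truth ----------------------------------------------------
    planted_corr = {}
    for si in source:
        for block in targets:
            for tj in block:
                c = factor_model_correlation(
                    phi[si], phi[tj], cfg.factor_sigma, cfg.noise_sigma
                )
                planted_corr[f"{serial(si)}-{serial(tj)}"] = c
    gained_negative = sorted(
        tuple(sorted((serial(si), serial(tj))))
        for si in source
        for block in targets
        for tj in block
    )
    shift_truth = sorted(
        (serial(min(i, j)), serial(max(i, j)), float(d_mut[min(i, j), max(i, j)] - d_wt[min(i, j), max(i, j)]))
        for (i, j) in moved
    )
    gt = GroundTruth(
        seed=cfg.seed,
        n_residues=n,
        n_frames=m,
        multistate_pair=(serial(anchor), serial(seg_idx[-1])),
        state_means=list(cfg.state_means),
        state_sigmas=list(cfg.state_sigmas),
        stationary_probs=[float(p) for p in stationary],
        wt_state_probs=[float((path_wt == s).mean()) for s in range(len(stationary))],
        mut_state_probs=[float((path_mut == s).mean()) for s in range(len(stationary))],
        wt_peaks=list(cfg.state_means),
        mut_peaks=[cfg.state_means[0]] if cfg.mut_state_collapse else list(cfg.state_means),
        shift_pairs=shift_truth,
        significant_pairs=[(i, j) for i, j, _ in shift_truth],
        gained_negative_pairs=gained_negative,
        planted_correlations=planted_corr,
        salt_bridge=salt_truth,
        hbond=hbond_truth,
    )
    return wt, mut, gt
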