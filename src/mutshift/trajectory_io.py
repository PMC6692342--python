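"""Trajectory containers, readers/writers and rigid-body superposition.

A :class:`Trajectory` holds one condition's Cα coordinate time series as an
``(M, N, 3)`` array in Å, together with 1-based residue labels and frame
times in ps.  Topologies are read from PDB; coordinates from DCD/XTC (via
MDAnalysis) or from a plain whitespace/comma table with columns
``frame resid x y z [time_ps]`` so that test fixtures need no binary files.

Rigid-body motion is removed by least-squares (Kabsch) superposition of every
frame onto the first frame of the same trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "AtomRecord",
    "read_trajectory",
    "read_plain_table",
    "write_plain_table",
    "superpose_to_first_frame",
    "slice_equilibrated",
]


@dataclass
class AtomRecord:
    """A non-Cα atom tracked across frames, for interaction detection.

    ``coords`` has shape (M, 3).  Atom names follow PDB conventions
    (e.g. ``OD1`` on Asp, ``NZ`` on Lys, ``H`` for a polar hydrogen).
    """

    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray


@dataclass
class Trajectory:
    """Cα coordinate time series for one condition.

    Parameters
    ----------
    coords
        Array of shape (M, N, 3), Å.
    residue_labels
        Length-N list of ``(serial_index, residue_name)``, 1-based.
    frame_times
        Length-M array of times in ps.
    condition_tag
        Free-text condition label, e.g. ``"WT-GTP"``.
    aligned
        True once rigid-body motion has been removed.
    atom_detail
        Optional side-chain/backbone atom records for interaction detection.
    """

    coords: np.ndarray
    residue_labels: list[tuple[int, str]]
    frame_times: np.ndarray
    condition_tag: str = ""
    aligned: bool = False
    atom_detail: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (M, N, 3)")
        m, n, _ = self.coords.shape
        if m < 1:
            raise ValueError("trajectory needs at least one frame")
        if n < 2:
            raise ValueError("trajectory needs at least two residues")
        if len(self.residue_labels) != n:
            raise ValueError("residue_labels length must equal N")
        if self.frame_times.shape != (m,):
            raise ValueError("frame_times length must equal M")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def residue_position(self, serial: int) -> np.ndarray:
        """(M, 3) coordinates of the residue with 1-based serial index."""
        idx = [lab[0] for lab in self.residue_labels].index(serial)
        return self.coords[:, idx, :]


def _read_table_array(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if not parts[0].lstrip("+-").replace(".", "", 1).isdigit():
                continue  # header line
            rows.append([float(p) for p in parts])
    if not rows:
        raise ValueError(f"no coordinate rows found in {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"ragged rows in {path}")
    return np.asarray(rows, dtype=float)


def read_plain_table(
    path: str | Path,
    residue_labels: Sequence[tuple[int, str]] | None = None,
    frame_dt: float = 10.0,
    condition_tag: str = "",
) -> Trajectory:
    """Read the plain-table coordinate dialect.

    Columns are ``frame resid x y z`` with an optional sixth ``time_ps``
    column; whitespace- or comma-delimited; ``#`` comments and a header
    line are ignored.  Residue labels default to ``(serial, "GLY")`` when
    no topology is supplied.
    """
    arr = _read_table_array(Path(path))
    if arr.shape[1] not in (5, 6):
        raise ValueError("plain table needs 5 or 6 columns: frame resid x y z [time]")
    frames = arr[:, 0].astype(int)
    resids = arr[:, 1].astype(int)
    frame_ids = np.unique(frames)
    serials = np.unique(resids)
    m, n = len(frame_ids), len(serials)
    if len(arr) != m * n:
        raise ValueError("every frame must contain exactly one row per residue")
    order = np.lexsort((resids, frames))
    arr = arr[order]
    coords = arr[:, 2:5].reshape(m, n, 3)
    if arr.shape[1] == 6:
        times = arr[:, 5].reshape(m, n)[:, 0]
    else:
        times = frame_ids.astype(float) * frame_dt
    if residue_labels is None:
        residue_labels = [(int(s), "GLY") for s in serials]
    else:
        residue_labels = list(residue_labels)
        if len(residue_labels) != n:
            raise ValueError("topology residue count does not match table")
    return Trajectory(coords, residue_labels, times, condition_tag=condition_tag)


def write_plain_table(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the plain-table dialect (6 columns, %.4f Å)."""
    with open(path, "w") as fh:
        fh.write("frame\tresid\tx\ty\tz\ttime_ps\n")
        for m in range(traj.n_frames):
            t = traj.frame_times[m]
            for k, (serial, _name) in enumerate(traj.residue_labels):
                x, y, z = traj.coords[m, k]
                fh.write(f"{m}\t{serial}\t{x:.4f}\t{y:.4f}\t{z:.4f}\t{t:g}\n")


def write_pdb(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame as a Cα-only PDB (topology for round trips)."""
    with open(path, "w") as fh:
        for k, (serial, name) in enumerate(traj.residue_labels):
            x, y, z = traj.coords[frame, k]
            fh.write(
                f"ATOM  {k + 1:>5d}  CA  {name:>3s} A{serial:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n"
            )
        fh.write("END\n")


_SIDECHAIN_NO = {"N", "O"}  # elements kept for interaction detection


def read_trajectory(
    topology_path: str | Path,
    coords_path: str | Path | None = None,
    atom_selection: str = "calpha",
    frame_dt: float = 10.0,
    condition_tag: str = "",
    with_atom_detail: bool = False,
) -> Trajectory:
    """Read topology + coordinates into a Cα :class:`Trajectory`.

    ``topology_path`` must be a PDB.  ``coords_path`` may be a DCD/XTC file,
    a plain table (``.tsv``/``.csv``/``.dat``/``.txt``), or ``None`` to take
    frames from the PDB itself (multi-MODEL).  ``atom_selection`` currently
    supports ``"calpha"``; residue order follows the topology.
    """
    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    if atom_selection != "calpha":
        raise ValueError(f"unsupported atom selection: {atom_selection!r}")

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path))
    ca = u.select_atoms("name CA")
    if ca.n_atoms < 2:
        raise ValueError("selection resolves to fewer than 2 atoms")
    labels = [(int(r.resid), str(r.resname)) for r in ca.residues]

    if coords_path is not None and Path(coords_path).suffix.lower() in (
        ".tsv",
        ".csv",
        ".dat",
        ".txt",
        ".tab",
    ):
        return read_plain_table(
            coords_path, residue_labels=labels, frame_dt=frame_dt, condition_tag=condition_tag
        )

    if coords_path is not None:
        coords_path = Path(coords_path)
        if not coords_path.exists():
            raise FileNotFoundError(coords_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology_path), str(coords_path))
        ca = u.select_atoms("name CA")

    frames = []
    times = []
    detail_sel = None
    detail_frames: list[list[np.ndarray]] = []
    if with_atom_detail:
        detail_sel = u.select_atoms("not name CA")
    for ts in u.trajectory:
        frames.append(ca.positions.copy())
        t = float(ts.time) if np.isfinite(ts.time) and ts.time > 0 else ts.frame * frame_dt
        times.append(t)
        if detail_sel is not None and detail_sel.n_atoms:
            detail_frames.append(detail_sel.positions.copy())
    coords = np.asarray(frames, dtype=float)
    if coords.shape[1] != len(labels):
        raise ValueError("atom count mismatch between topology and frames")

    atom_detail: list[AtomRecord] = []
    if detail_sel is not None and detail_sel.n_atoms:
        stack = np.asarray(detail_frames)
        for k, atom in enumerate(detail_sel.atoms):
            elem = (atom.name[:1] if not atom.element else atom.element).upper()
            if elem in _SIDECHAIN_NO or elem == "H":
                atom_detail.append(
                    AtomRecord(
                        residue_index=int(atom.resid),
                        residue_name=str(atom.resname),
                        atom_name=str(atom.name),
                        element=elem,
                        coords=stack[:, k, :],
                    )
                )

    return Trajectory(
        coords,
        labels,
        np.asarray(times, dtype=float),
        condition_tag=condition_tag,
        atom_detail=atom_detail,
    )


def _kabsch_transform(ref: np.ndarray, mobile: np.ndarray):
    """Rotation + translation minimizing RMSD(mobile → ref)."""
    ref_c = ref.mean(axis=0)
    mob_c = mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mobile - mob_c)
    return rot, ref_c, mob_c


def superpose_to_first_frame(traj: Trajectory) -> Trajectory:
    """Remove rigid-body motion by superposing every frame onto frame 1.

    Uses the closed-form least-squares rigid fit on Cα atoms; frame 1 is
    returned unchanged.  Side-chain atom records, when present, are carried
    through the same per-frame transform so interaction geometry is
    preserved relative to the backbone.
    """
    ref = traj.coords[0]
    centered = ref - ref.mean(axis=0)
    # degenerate reference: all points collinear (or coincident)
    sv = np.linalg.svd(centered, compute_uv=False)
    if traj.n_residues >= 3 and sv[1] < 1e-8:
        raise ValueError("degenerate (collinear/coincident) reference frame")

    new_coords = np.empty_like(traj.coords)
    new_coords[0] = ref
    transforms = [None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on near-planar sets
        for m in range(1, traj.n_frames):
            rot, ref_c, mob_c = _kabsch_transform(ref, traj.coords[m])
            new_coords[m] = rot.apply(traj.coords[m] - mob_c) + ref_c
            transforms.append((rot, ref_c, mob_c))

    detail = []
    for rec in traj.atom_detail:
        new = rec.coords.copy()
        for m in range(1, traj.n_frames):
            rot, ref_c, mob_c = transforms[m]
            new[m] = rot.apply(rec.coords[m] - mob_c) + ref_c
        detail.append(replace(rec, coords=new))

    return replace(traj, coords=new_coords, aligned=True, atom_detail=detail)


def slice_equilibrated(traj: Trajectory, discard_initial: float) -> Trajectory:
    """Drop the pre-equilibration frames with time < ``discard_initial`` ps."""
    if discard_initial <= 0:
        return traj
    keep = traj.frame_times >= discard_initial
    if not keep.any():
        raise ValueError("discarding the initial segment would leave zero frames")
    detail = [replace(r, coords=r.coords[keep]) for r in traj.atom_detail]
    return replace(
        traj,
        coords=traj.coords[keep],
        frame_times=traj.frame_times[keep],
        atom_detail=detail,
    )
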