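"""Geometric salt-bridge and hydrogen-bond detection over a trajectory.

A salt bridge is called in a frame when any acidic side-chain oxygen
(Asp OD1/OD2, Glu OE1/OE2) lies within a cutoff (default 3.2 Å) of a basic
side-chain nitrogen (Lys NZ, Arg NE/NH1/NH2; His ND1/NE2 only when
explicitly enabled).  A hydrogen bond requires donor–acceptor heavy-atom
distance ≤ 3.5 Å and a donor–H–acceptor angle ≥ 150° by default; when no
hydrogen positions are available, a distance-only mode is used with a
warning.  Each detected interaction carries its per-frame presence series
and occupancy, optionally conditioned on conformational states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pca_states import StatePartition
from .trajectory_io import AtomRecord, Trajectory

__all__ = [
    "InteractionRecord",
    "detect_salt_bridges",
    "detect_hbonds",
    "interaction_timeline",
    "DEFAULT_SALT_BRIDGE_CUTOFF",
    "DEFAULT_HBOND_DISTANCE",
    "DEFAULT_HBOND_ANGLE",
]

DEFAULT_SALT_BRIDGE_CUTOFF = 3.2  # Å, O–N
DEFAULT_HBOND_DISTANCE = 3.5  # Å, donor–acceptor heavy atoms
DEFAULT_HBOND_ANGLE = 150.0  # degrees, donor–H–acceptor

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_ATOMS = ("ND1", "NE2")


@dataclass
class InteractionRecord:
    kind: str  # "salt-bridge" | "h-bond"
    residue_i: int
    residue_j: int
    atoms: tuple[str, str]
    presence: np.ndarray  # bool per frame
    occupancy: float = field(init=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.occupancy = float(self.presence.mean())


def _atoms_by_residue(
    detail: list[AtomRecord], wanted: dict[str, tuple[str, ...]]
) -> dict[int, list[AtomRecord]]:
    out: dict[int, list[AtomRecord]] = {}
    for rec in detail:
        names = wanted.get(rec.residue_name)
        if names and rec.atom_name in names:
            out.setdefault(rec.residue_index, []).append(rec)
    return out


def detect_salt_bridges(
    traj: Trajectory,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    include_histidine: bool = False,
) -> list[InteractionRecord]:
    """Salt bridges between acidic O and basic N side-chain atoms.

    Returns one record per (acidic residue, basic residue) pair with
    nonzero occupancy, using the closest O–N atom pair for the atom tag.
    Residues whose expected side-chain atoms are missing are skipped with
    a warning.
    """
    basic = dict(BASIC_ATOMS)
    if include_histidine:
        basic["HIS"] = HIS_ATOMS
    acid_atoms = _atoms_by_residue(traj.atom_detail, ACIDIC_ATOMS)
    base_atoms = _atoms_by_residue(traj.atom_detail, basic)

    expected_acid = {r[0] for r in traj.residue_labels if r[1] in ACIDIC_ATOMS}
    expected_base = {r[0] for r in traj.residue_labels if r[1] in basic}
    for missing in sorted((expected_acid - set(acid_atoms)) | (expected_base - set(base_atoms))):
        warnings.warn(f"residue {missing}: side-chain atoms missing, skipped")

    records = []
    for ra, a_atoms in sorted(acid_atoms.items()):
        for rb, b_atoms in sorted(base_atoms.items()):
            if ra == rb:
                continue
            best = None
            presence = None
            min_mean = np.inf
            for ao in a_atoms:
                for bn in b_atoms:
                    d = np.linalg.norm(ao.coords - bn.coords, axis=1)
                    hit = d <= cutoff
                    presence = hit if presence is None else (presence | hit)
                    if d.mean() < min_mean:
                        min_mean = d.mean()
                        best = (ao.atom_name, bn.atom_name)
            if presence is not None and presence.any():
                records.append(
                    InteractionRecord(
                        kind="salt-bridge",
                        residue_i=ra,
                        residue_j=rb,
                        atoms=best,
                        presence=presence,
                    )
                )
    return records


@dataclass
class HBondSite:
    """Donor or acceptor specification for H-bond detection."""

    residue_index: int
    heavy_atom: str
    hydrogen: str | None = None  # donors only


def _find_atom(traj: Trajectory, resid: int, name: str) -> AtomRecord | None:
    for rec in traj.atom_detail:
        if rec.residue_index == resid and rec.atom_name == name:
            return rec
    return None


def detect_hbonds(
    traj: Trajectory,
    donors: list[HBondSite],
    acceptors: list[HBondSite],
    d_cutoff: float = DEFAULT_HBOND_DISTANCE,
    angle_cutoff: float = DEFAULT_HBOND_ANGLE,
) -> list[InteractionRecord]:
    """Hydrogen bonds between explicit donor and acceptor sites.

    Present in a frame iff donor–acceptor distance ≤ ``d_cutoff`` and the
    donor–H–acceptor angle ≥ ``angle_cutoff``.  Donors without a hydrogen
    record fall back to the distance-only criterion with a warning.
    """
    records = []
    for don in donors:
        d_atom = _find_atom(traj, don.residue_index, don.heavy_atom)
        if d_atom is None:
            warnings.warn(f"donor {don.residue_index}:{don.heavy_atom} missing, skipped")
            continue
        h_atom = _find_atom(traj, don.residue_index, don.hydrogen) if don.hydrogen else None
        if don.hydrogen and h_atom is None:
            warnings.warn(
                f"hydrogen {don.residue_index}:{don.hydrogen} missing; distance-only mode"
            )
        for acc in acceptors:
            if acc.residue_index == don.residue_index:
                continue
            a_atom = _find_atom(traj, acc.residue_index, acc.heavy_atom)
            if a_atom is None:
                warnings.warn(f"acceptor {acc.residue_index}:{acc.heavy_atom} missing, skipped")
                continue
            da = np.linalg.norm(d_atom.coords - a_atom.coords, axis=1)
            present = da <= d_cutoff
            if h_atom is not None:
                hd = d_atom.coords - h_atom.coords
                ha = a_atom.coords - h_atom.coords
                cosang = np.einsum("md,md->m", hd, ha) / (
                    np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1)
                )
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                present = present & (angle >= angle_cutoff)
            if present.any():
                records.append(
                    InteractionRecord(
                        kind="h-bond",
                        residue_i=don.residue_index,
                        residue_j=acc.residue_index,
                        atoms=(don.heavy_atom, acc.heavy_atom),
                        presence=present,
                    )
                )
    return records


def interaction_timeline(
    records: list[InteractionRecord],
    states: StatePartition | None = None,
) -> list[dict]:
    """Per-record occupancy, overall and conditioned on each PCA state.

    Conditioning on states exposes bond-state/conformation coupling: a bond
    present only while the trajectory occupies one conformational state
    shows conditional occupancy 1 there and 0 elsewhere.
    """
    out = []
    for rec in records:
        row = {
            "kind": rec.kind,
            "residue_i": rec.residue_i,
            "residue_j": rec.residue_j,
            "atoms": rec.atoms,
            "occupancy": rec.occupancy,
        }
        if states is not None:
            if len(states.state_labels) != len(rec.presence):
                raise ValueError("state partition frame count mismatch")
            per_state = {}
            for lab in sorted(states.state_probabilities):
                mask = states.state_labels == lab
                per_state[lab] = float(rec.presence[mask].mean()) if mask.any() else 0.0
            row["occupancy_by_state"] = per_state
        out.append(row)
    return out
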