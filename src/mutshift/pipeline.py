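"""End-to-end wild-type vs mutant comparison.

``run_comparison`` chains the full analysis: align → discard equilibration →
magnitude-matrix PCA and state partition → second-shell neighbor graph on
the reference → mean/delta distances → significant pairs → distance
distributions and population shifts for those pairs → RMSF, correlation and
difference maps → salt-bridge/H-bond occupancies conditioned on PCA states.
All artifacts are written as TSV/JSON with a run manifest; every stage is a
pure function of (inputs, config), so reruns reproduce tables exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .trajectory_io import Trajectory, superpose_to_first_frame, slice_equilibrated
from .pca_states import (
    FrameWeights,
    magnitude_matrix,
    fit_pca,
    project,
    partition_states,
    state_weighted_frames,
)
from .pair_geometry import (
    DEFAULT_NEG_THRESHOLD,
    DEFAULT_POS_THRESHOLD,
    FIRST_SHELL_RADIUS,
    build_neighbor_graph,
    delta_matrix,
    delta_residue_profile,
    mean_distances,
    second_shell_radius,
    significant_pairs,
)
from .distributions import distance_distribution, population_shift
from .dynamics import correlation_map, difference_map, rmsf
from .interactions import detect_salt_bridges, interaction_timeline

log = logging.getLogger("mutshift")

#: K-Ras-style functional region annotation (residue serial ranges), shipped
#: as an optional labeling aid; the engine itself is protein-agnostic.
KRAS_REGIONS = {
    "P-loop": (10, 17),
    "Switch-I": (25, 40),
    "Switch-II": (60, 74),
    "alpha3": (92, 103),
}


@dataclass
class ComparisonConfig:
    """All tunable constants of the comparison, with field-standard defaults."""

    discard_initial: float = 0.0  # ps dropped from the start of each run
    first_shell_radius: float = FIRST_SHELL_RADIUS  # Å
    pos_threshold: float = DEFAULT_POS_THRESHOLD  # Å, "moves apart"
    neg_threshold: float = DEFAULT_NEG_THRESHOLD  # Å, "moves closer"
    state_density_floor: float = 0.10  # fraction of max 2-D histogram count
    state_weight_distances: bool = True  # dominant-state weighting of R̄ij
    state_weight_graph: bool = False  # ... of the neighbor-graph build
    weight_convention: str = "normalized"  # or "probability-scaled"
    bin_width: float | None = None  # Å; None = Freedman–Diaconis
    peak_prominence: float = 0.05
    correlation_category_threshold: float = 0.4
    salt_bridge_cutoff: float = 3.2  # Å
    out_dir: str | None = None
    seed: int = 0

    @property
    def shell_radius(self) -> float:
        return second_shell_radius(self.first_shell_radius)


@dataclass
class ComparisonResult:
    config: ComparisonConfig
    graph: object
    delta: object
    significant: list
    profile: object
    partitions: dict
    distributions: dict
    shifts: dict
    rmsf_profiles: dict
    rmsf_delta: np.ndarray
    correlations: dict
    correlation_difference: object
    interactions: dict
    manifest: dict = field(default_factory=dict)


def _config_hash(cfg: ComparisonConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_comparison(
    wt: Trajectory,
    mut: Trajectory,
    config: ComparisonConfig | None = None,
) -> ComparisonResult:
    """Run the full comparison of a perturbed condition against a reference."""
    cfg = config or ComparisonConfig()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    log.info("stage align: superposing both conditions onto their first frames")
    wt = superpose_to_first_frame(slice_equilibrated(wt, cfg.discard_initial))
    mut = superpose_to_first_frame(slice_equilibrated(mut, cfg.discard_initial))

    log.info("stage pca: magnitude-matrix PCA and state partition")
    partitions, weights = {}, {}
    for tag, traj in (("WT", wt), ("MUT", mut)):
        mag = magnitude_matrix(traj)
        model = fit_pca(mag)
        pc1 = project(mag, model, 1)
        pc2 = project(mag, model, 2)
        part = partition_states(pc1, pc2, density_floor=cfg.state_density_floor)
        partitions[tag] = part
        weights[tag] = state_weighted_frames(part, traj, convention=cfg.weight_convention)
        if out:
            pd.DataFrame(
                {
                    "frame": np.arange(traj.n_frames),
                    "time_ps": traj.frame_times,
                    "PCA_1": pc1.values,
                    "PCA_2": pc2.values,
                    "state": part.state_labels,
                }
            ).to_csv(out / f"projection_{tag}.tsv", sep="\t", index=False)

    log.info("stage graph: second-shell neighbor graph on the reference (r=%.2f Å)", cfg.shell_radius)
    graph = build_neighbor_graph(
        wt,
        radius=cfg.shell_radius,
        weights=weights["WT"] if cfg.state_weight_graph else None,
    )

    log.info("stage distances: mean and delta distances on %d pairs", len(graph.pairs))
    w_wt = weights["WT"] if cfg.state_weight_distances else None
    w_mut = weights["MUT"] if cfg.state_weight_distances else None
    mean_wt = mean_distances(wt, graph, weights=w_wt)
    mean_mut = mean_distances(mut, graph, weights=w_mut)
    delta = delta_matrix(mean_wt, mean_mut)
    sig = significant_pairs(delta, cfg.pos_threshold, cfg.neg_threshold)
    profile = delta_residue_profile(delta, graph)

    log.info("stage distributions: W(Rij) for %d significant pairs", len(sig))
    dists, shifts = {}, {}
    for i, j, _v, _tag in sig:
        d_wt = distance_distribution(
            wt, (i, j), bin_width=cfg.bin_width, min_prominence=cfg.peak_prominence
        )
        d_mut = distance_distribution(
            mut, (i, j), bin_width=cfg.bin_width, min_prominence=cfg.peak_prominence
        )
        dists[(i, j)] = {"WT": d_wt, "MUT": d_mut}
        shifts[(i, j)] = population_shift(d_wt, d_mut)

    log.info("stage dynamics: RMSF and correlation maps")
    rmsf_profiles = {"WT": rmsf(wt), "MUT": rmsf(mut)}
    rmsf_delta = difference_map(rmsf_profiles["WT"], rmsf_profiles["MUT"])
    correlations = {"WT": correlation_map(wt), "MUT": correlation_map(mut)}
    corr_diff = difference_map(
        correlations["WT"], correlations["MUT"], threshold=cfg.correlation_category_threshold
    )

    log.info("stage interactions: salt bridges with state-conditioned occupancy")
    inter = {}
    for tag, traj in (("WT", wt), ("MUT", mut)):
        recs = detect_salt_bridges(traj, cutoff=cfg.salt_bridge_cutoff)
        inter[tag] = interaction_timeline(recs, partitions[tag])

    manifest = {
        "tool": "mutshift",
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "config": asdict(cfg),
        "seed": cfg.seed,
        "conditions": {"WT": wt.condition_tag, "MUT": mut.condition_tag},
        "n_residues": wt.n_residues,
        "n_frames": {"WT": wt.n_frames, "MUT": mut.n_frames},
    }

    result = ComparisonResult(
        config=cfg,
        graph=graph,
        delta=delta,
        significant=sig,
        profile=profile,
        partitions=partitions,
        distributions=dists,
        shifts=shifts,
        rmsf_profiles=rmsf_profiles,
        rmsf_delta=rmsf_delta,
        correlations=correlations,
        correlation_difference=corr_diff,
        interactions=inter,
        manifest=manifest,
    )
    if out:
        _write_bundle(result, out, mean_wt, mean_mut)
    return result


def _write_bundle(res: ComparisonResult, out: Path, mean_wt, mean_mut) -> None:
    rows = []
    flags = {(i, j): tag for i, j, _v, tag in res.significant}
    for (i, j), dv in sorted(res.delta.values.items()):
        rows.append(
            (i, j, mean_wt.values[(i, j)], mean_mut.values[(i, j)], dv, flags.get((i, j), ""))
        )
    pd.DataFrame(
        rows, columns=["res_i", "res_j", "mean_wt", "mean_mut", "delta", "flag"]
    ).to_csv(out / "delta_map.tsv", sep="\t", index=False)
    res.profile.to_frame().to_csv(out / "delta_profile.tsv", sep="\t", index=False)

    pd.DataFrame(
        {
            "residue": res.profile.residues
            if len(res.profile.residues) == len(res.rmsf_profiles["WT"].values)
            else np.arange(1, len(res.rmsf_profiles["WT"].values) + 1),
            "rmsf_wt": res.rmsf_profiles["WT"].values,
            "rmsf_mut": res.rmsf_profiles["MUT"].values,
            "delta": res.rmsf_delta,
        }
    ).to_csv(out / "rmsf.tsv", sep="\t", index=False)

    np.savetxt(out / "correlation_WT.tsv", res.correlations["WT"].values, delimiter="\t", fmt="%.6f")
    np.savetxt(out / "correlation_MUT.tsv", res.correlations["MUT"].values, delimiter="\t", fmt="%.6f")
    np.savetxt(
        out / "correlation_categories.tsv",
        res.correlation_difference.categories,
        delimiter="\t",
        fmt="%d",
    )

    state_summary = {
        tag: {
            "probabilities": part.state_probabilities,
            "dominant": part.dominant_state,
        }
        for tag, part in res.partitions.items()
    }
    with open(out / "states.json", "w") as fh:
        json.dump(state_summary, fh, indent=2, default=float)

    shift_report = {
        f"{i}-{j}": {
            "peak_count_change": s.peak_count_change,
            "matched_peaks": s.matched_peaks,
            "total_variation": s.total_variation,
            "label": s.label,
        }
        for (i, j), s in res.shifts.items()
    }
    with open(out / "population_shifts.json", "w") as fh:
        json.dump(shift_report, fh, indent=2, default=float)
    with open(out / "interactions.json", "w") as fh:
        json.dump(res.interactions, fh, indent=2, default=str)
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, default=float)


def report(res: ComparisonResult, regions: dict | None = None) -> str:
    """Human-readable markdown summary of a comparison result."""
    lines = ["# Comparison summary", ""]
    apart = [(i, j, v) for i, j, v, t in res.significant if t == "apart"]
    closer = [(i, j, v) for i, j, v, t in res.significant if t == "closer"]
    if not res.significant:
        lines.append("No significant pair-distance changes at the configured thresholds.")
    else:
        lines.append(f"## Significant pairs ({len(res.significant)})")
        for i, j, v in sorted(apart, key=lambda r: -r[2]):
            lines.append(f"- {i}–{j}: ΔR̄ = +{v:.2f} Å (apart){_annotate(i, j, regions)}")
        for i, j, v in sorted(closer, key=lambda r: r[2]):
            lines.append(f"- {i}–{j}: ΔR̄ = {v:.2f} Å (closer){_annotate(i, j, regions)}")
    lines.append("")

    prof = res.profile
    if len(prof.values) and np.isfinite(prof.values).any():
        hi = int(np.nanargmax(prof.values))
        lo = int(np.nanargmin(prof.values))
        lines.append("## Local volume change extremes")
        lines.append(
            f"- largest expansion: residue {prof.residues[hi]} (ΔR̄ᵢ = {prof.values[hi]:+.2f} Å)"
        )
        lines.append(
            f"- largest contraction: residue {prof.residues[lo]} (ΔR̄ᵢ = {prof.values[lo]:+.2f} Å)"
        )
        lines.append("")

    lines.append("## Conformational states")
    for tag, part in res.partitions.items():
        probs = ", ".join(f"{k}: {p:.3f}" for k, p in sorted(part.state_probabilities.items()))
        lines.append(f"- {tag}: {part.n_states} state(s) ({probs}); dominant = {part.dominant_state}")
    for (i, j), s in res.shifts.items():
        lines.append(
            f"- pair {i}–{j}: {s.label} (Δpeaks = {s.peak_count_change:+d}, "
            f"TV = {s.total_variation:.3f})"
        )
    lines.append("")

    cats = res.correlation_difference.categories
    n_gn = int((np.triu(cats, 1) == 2).sum())
    n_gp = int((np.triu(cats, 1) == 1).sum())
    n_lost = int((np.triu(cats, 1) == 3).sum())
    lines.append("## Correlated motions")
    lines.append(
        f"- gained-negative: {n_gn} pairs; gained-positive: {n_gp}; lost: {n_lost} "
        f"(|C| threshold {res.correlation_difference.threshold})"
    )
    lines.append("")

    lines.append("## Interactions")
    for tag, recs in res.interactions.items():
        if not recs:
            lines.append(f"- {tag}: none detected")
        for r in recs:
            by_state = r.get("occupancy_by_state", {})
            cond = ", ".join(f"state {k}: {v:.2f}" for k, v in by_state.items())
            lines.append(
                f"- {tag}: {r['kind']} {r['residue_i']}–{r['residue_j']} "
                f"occupancy {r['occupancy']:.2f}" + (f" ({cond})" if cond else "")
            )
    return "\n".join(lines) + "\n"


def _annotate(i: int, j: int, regions: dict | None) -> str:
    if not regions:
        return ""
    names = []
    for r in (i, j):
        for name, (lo, hi) in regions.items():
            if lo <= r <= hi:
                names.append(f"{r}∈{name}")
    return f"  [{', '.join(names)}]" if names else ""
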