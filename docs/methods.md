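# Methods

This note documents the models, conventions and numerical choices behind
`mutshift`, in the order the pipeline applies them, together with what the
synthetic benchmark does and does not establish about real data.

## Trajectory handling

Trajectories are Cα-only: an (M, N, 3) array in Å with 1-based residue
serials and frame times in ps.  Topology comes from PDB; coordinates from
DCD/XTC (via MDAnalysis) or from a plain whitespace/comma table
(`frame resid x y z [time_ps]`) provided so that test fixtures and small
exchanges need no binary formats.

Rigid-body motion is removed by superposing every frame onto the **first
frame of the same trajectory**, using the closed-form least-squares
(Kabsch) fit on Cα atoms.  Each condition is aligned to its own first
frame, not to a shared reference; all downstream quantities are internal
(distances, fluctuations about the mean), so the choice of reference frame
cancels.  The equilibration cut (`slice_equilibrated`) drops frames before
a configurable time; with 1 µs runs sampled every 10 ps, the convention is
to discard the first 100 ns and analyze the remaining 900 ns.

Degenerate reference frames (collinear Cα sets, detected by a vanishing
second singular value) are rejected rather than fitted.

## Coordination shells and the difference map

The first coordination shell uses the elastic-network contact convention
r₁ = 7.2 Å; the second shell is defined by volume doubling,
r₂ = r₁·2^(1/3) = 9.07 ≈ 9.1 Å.  Pair membership is decided on the
**time-averaged** reference distance, not any single frame — this makes the
pair set deterministic and frame-order independent — and the graph is
frozen and reused for the perturbed condition so ΔR̄ᵢⱼ is defined on a fixed
support.  The significance thresholds (+2.50 / −1.40 Å) are configuration
defaults, not constants.  ΔR̄ᵢ averages a residue's incident ΔR̄ᵢⱼ over its
Nₙ shell neighbors and is undefined (NaN) for residues with no neighbors.

## Magnitude-matrix PCA and state weighting

The PCA operates on the N×M matrix of *norms* of mean-centered positions.
Two consequences are intentional and documented rather than "fixed":

* the norm discards direction, so the analysis sees scalar fluctuation
  amplitudes per residue;
* the rows of the norm matrix have nonzero means and are **not**
  re-centered, so C = (1/M)·A·Aᵀ is a second-moment matrix.  Its top
  eigenvector mainly encodes the mean amplitude profile; multi-state
  structure appears in the leading modes as amplitude switching.  The
  projection second moment equals the eigenvalue exactly
  (⟨PCAᵢ²⟩ = Λᵢ), which the tests assert.

Eigenvector signs are fixed by making each vector's largest-magnitude
component positive.

States are connected high-density regions of the (PCA₁, PCA₂) plane: a 2-D
histogram with √M bins per axis (clipped to 8..64) is smoothed with a 1-bin
Gaussian kernel; bins above 10% of the maximum smoothed density form cores;
states are 4-connected components of cores; frames outside every core join
the nearest core bin, so the partition covers all frames.  A square-root
bin rule is used here instead of Freedman–Diaconis because the IQR-based FD
width degenerates on well-separated multimodal projections (one giant bin
merges the modes) and over-resolves sparse samples; the 1-D distance
histograms below keep FD, where it behaves well.  Labels are ordered by
descending occupancy (ties: lexicographic centroid, then provisional
label), so the dominant state is always label 1.

State weighting follows the convention that dominant-state frames carry
weight equal to the dominant-state probability.  Two interpretations are
implemented because the sentence defining the weighting is ambiguous in its
source: `"normalized"` (default) uses the weighted mean, which for a
constant weight equals the plain dominant-state mean; `"probability-scaled"`
multiplies the dominant-state mean by the state probability.  The pipeline
default applies state weighting to mean distances but not to the
neighbor-graph build.

## Distance distributions, peaks, occupancies

W(Rᵢⱼ) is a weighted, density-normalized histogram (Freedman–Diaconis bin
widths by default; a fixed width, e.g. 0.25 Å, can be forced for
cross-condition comparability), smoothed with a 1-bin Gaussian kernel and
re-normalized.  Peaks are local maxima of the smoothed curve above a
prominence floor (default 5% of the maximum), with the position refined by
a three-point parabolic fit around the peak bin — this recovers mode
positions well below one bin width for approximately symmetric modes.
Mode occupancies assign each frame to its nearest peak (1-D Voronoi).
Boundary occupancies (`state_occupancy`) require an explicit boundary; the
package never infers one silently.

Population shifts re-bin both conditions onto common edges (union range,
the finer of the two widths) and report the peak-count change, a greedy
nearest-position peak matching (tolerance 1.0 Å), and the total-variation
distance ½Σ|p−q| ∈ [0, 1].  A peak-count drop is labeled "state collapse".

## RMSF and cross-correlations

RMSF_i = √⟨‖rᵢ(t) − ⟨rᵢ⟩‖²⟩ on aligned Cα coordinates, with weighted means
throughout and the Kish effective sample size reported alongside.  The
cross-correlation uses 3-D fluctuation vectors (the standard dynamic
cross-correlation convention); a scalar-magnitude variant is exposed as an
option for sensitivity checks.  Residues whose fluctuation variance is
below 1e-12 Å² are flagged undefined (value stored as 0) instead of
propagating NaN.  Categorical difference maps use |C| ≥ 0.4: a pair is
*gained* when its magnitude rises past the threshold from the reference to
the perturbed condition (sign taken from the new value; a sign flip at
large magnitude counts as gained with the new sign), *lost* in the reverse
case.

## Interactions

Salt bridges: any acidic side-chain O (Asp OD1/OD2, Glu OE1/OE2) within
3.2 Å of a basic side-chain N (Lys NZ, Arg NE/NH1/NH2) — the convention of
the widely used VMD plugin.  Histidine counts as basic only behind an
explicit flag.  Hydrogen bonds: donor–acceptor ≤ 3.5 Å and donor–H–acceptor
≥ 150°, community-standard values chosen here because the motivating
analyses do not state theirs; with no hydrogen positions the detector falls
back to distance-only with a warning.  Occupancies are reported overall and
conditioned on PCA states, which exposes bond/conformation coupling.

## Synthetic benchmark

The generator builds a persistent self-avoiding chain (step 3.8 Å,
non-adjacent clearance ≥ 4 Å) shared by both conditions and adds iid
per-coordinate Gaussian noise (σ = 0.3 Å).  Planted features:

* **Multi-state pair** — the three terminal residues translate rigidly so
  the distance from the chain end to an anchor residue (8 positions
  upstream) follows a two-state Markov chain: means 8.3 / 16.0 Å,
  within-state σ = 0.5 Å, transition matrix ((0.98, 0.02), (0.08, 0.92))
  with stationary occupancies (0.8, 0.2) and dwell times of ~50 / ~12.5
  frames.  In the mutant the chain stays in state 1 (state collapse).
* **Shifted pairs** — five pairs (i, i±2) at protruding positions; the
  moving residue is displaced so d(i, j) grows by exactly 3 Å, its chain
  neighbors are dragged at 40% (a harmonic-restraint-like relaxation), and
  the direction is search-selected so every *other* second-shell distance
  changes within (−1.2, +2.3) Å.  A construction-time self-check recomputes
  all implied mean-distance changes (including the state-mixture means of
  the swinging segment and the convexity bias of the mutant-only factor
  fluctuations) and rejects geometries where any unplanted pair would cross
  the significance thresholds; the generator retries deterministically
  derived sub-seeds until the planted set is provably exact.
* **Anti-correlated blocks** — a one-factor displacement field
  Δrᵢ = s(t)·Φᵢ with s ~ N(0, 1.5²), loadings +2 on a 4-residue source
  block and −2/3 on three 4-residue target blocks (momentum-balanced), and
  the common direction chosen parallel to Σaᵢrᵢ so the field carries no net
  torque: it is orthogonal to all six rigid-body modes by construction and
  superposition cannot smear it onto unplanted residues.  The analytic
  correlation C = ΦᵢΦⱼσ_s²/√((Φᵢ²σ_s²+3σ_ε²)(Φⱼ²σ_s²+3σ_ε²)) ≈ −0.87 for
  source–target pairs is stored in the ground truth.
* **Interactions** — pseudo-side-chain atoms give one salt bridge whose
  O–N distance is 2.9 Å in state 1 and 6.0 Å in state 2 (occupancy equals
  the state-1 fraction, exactly), and one always-present collinear H-bond.
* **Rigid drift** — a cumulative rotation (0.5°/frame) and translation
  (0.05 Å/frame) random walk applied last, so the alignment stage is
  genuinely exercised.

Desk-scale defaults are 50 residues × 2000 frames at 10 ps (a paper-scale
profile, 165 × 10000, sits behind `SyntheticConfig.paper_scale()`).  The
generator is deterministic given the seed (`numpy` SeedSequence spawning).

**What the benchmark does not show.**  The synthetic ensemble has no
force-field physics: no solvent, no secondary structure, no thermodynamic
consistency, Gaussian rather than heavy-tailed fluctuations, and planted
features that are cleanly separable by design.  Passing the recovery suite
demonstrates that the estimators measure what they claim to measure at
realistic sampling depth and noise — not that real mutation effects of this
size would be equally unambiguous, where slower convergence, anharmonicity
and overlapping signals apply.

## Numerical choices and degenerate inputs

* Superposition uses `scipy.spatial.transform.Rotation.align_vectors`;
  degenerate (collinear) references raise.
* Eigendecomposition uses `numpy.linalg.eigh` on the symmetrized matrix;
  eigenvalues are reported as computed (tiny negatives are tolerated to
  −1e-10 by the contract, not clipped).
* All-identical projection points form a single state of probability 1.
* A constant-distance distribution is a single bin with one peak at its
  center.
* Distributions require ≥ 30 frames (configurable floor).
* Tie-breaks are deterministic everywhere: dominant state by lowest label,
  peak matching greedily in source order.

## Known limitations

* Cα-only; no side-chain distance options outside the interaction module.
* Replicate simulations are analyzed separately; pooling is an explicit
  opt-in, since the right choice depends on whether replicates equilibrate
  to the same basin.
* State partitioning is histogram-based by design (no mixture-model fits);
  very overlapping states will merge.
* The H-bond detector does not infer hydrogen positions; protonate inputs
  upstream or accept distance-only calls.
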