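# mutshift

Quantify how a point mutation shifts a protein's **local conformational
states and dynamics** from paired molecular-dynamics trajectories.

Given two Cα coordinate time series — a reference condition ("wild type")
and a perturbed condition ("mutant") — the package measures, residue pair by
residue pair, where the protein expands or contracts, which pairs hop
between discrete conformational states, how state populations shift, and
which correlated motions are gained or lost.  It was designed for
KRas-G12D-style comparisons (165 residues, microsecond trajectories sampled
every 10 ps) but is protein-agnostic.

## The analysis

**Coordination-shell difference maps.**  Residue pairs are enumerated
within the *second coordination shell* of the reference ensemble: pairs
whose time-averaged Cα–Cα distance R̄ᵢⱼ is below r₂ = r₁·2^⅓ ≈ 9.1 Å, the
radius enclosing twice the volume of the conventional r₁ ≈ 7.2 Å contact
shell.  On this frozen pair set the mutation difference map is

    ΔR̄ᵢⱼ = R̄ᵢⱼ(mut) − R̄ᵢⱼ(ref)

(positive: the pair moves apart; negative: closer).  Pairs with
ΔR̄ᵢⱼ > 2.50 Å or < −1.40 Å are flagged significant, and the per-residue
profile ΔR̄ᵢ = Σⱼ ΔR̄ᵢⱼ / Nₙ summarizes local volume change.

**Magnitude-matrix PCA states.**  Each residue's mean-centered position is
reduced to its norm ‖r̄ᵢ(t)‖; the N×M matrix A of norms gives the
second-moment matrix C = (1/M)·A·Aᵀ (the rows are deliberately *not*
re-centered), whose top two eigenvectors define a projection plane.  Frames
are partitioned into conformational states as connected high-density
regions of that plane; the most populated state and its occupancy weight
the downstream averages.

**Distance distributions W(Rᵢⱼ).**  For significant pairs the distribution
of instantaneous distances is estimated, its peaks mark local states, and
occupancies, peak matches and the total-variation distance quantify the
population shift between conditions (e.g. a bimodal 8.3/16 Å pair
collapsing to one predominant conformation).

**Dynamics.**  Per-residue RMSF and the dynamic cross-correlation map
Cᵢⱼ = ⟨Δrᵢ·Δrⱼ⟩ / √(⟨‖Δrᵢ‖²⟩⟨‖Δrⱼ‖²⟩) ∈ [−1, 1], with categorical
difference maps (gained-positive / gained-negative / lost at |C| ≥ 0.4).

**Interactions.**  Geometric salt-bridge (acidic O – basic N ≤ 3.2 Å) and
hydrogen-bond (D–A ≤ 3.5 Å, D–H–A ≥ 150°) occupancies, conditioned on the
PCA states to expose bond/conformation coupling.

Because raw MD trajectories of the motivating study are not publicly
deposited, the package ships a first-class synthetic-data generator
(`mutshift.synthetic_data`) that plants all of the above — multi-state pair
distances with Markov switching, mean-distance shifts, anti-correlated
fluctuation blocks, state-coupled salt bridges, rigid-body drift — with a
machine-readable ground truth, so the entire pipeline is verifiable end to
end.

## Worked example

```sh
mutshift simulate --seed 0 --out demo/sim
mutshift analyze \
    --wt-topology demo/sim/wt.pdb  --wt-coords demo/sim/wt_coords.tsv \
    --mut-topology demo/sim/mut.pdb --mut-coords demo/sim/mut_coords.tsv \
    --out demo/run
```

prints (abridged):

```
## Significant pairs (5)
- 25–27: ΔR̄ = +3.01 Å (apart)
- 33–35: ΔR̄ = +2.99 Å (apart)
- 11–13: ΔR̄ = +2.99 Å (apart)
- 17–19: ΔR̄ = +2.99 Å (apart)
- 1–3:  ΔR̄ = +2.98 Å (apart)

## Conformational states
- WT: 2 state(s) (1: 0.775, 2: 0.225); dominant = 1
- MUT: 1 state(s) (1: 1.000); dominant = 1

## Correlated motions
- gained-negative: 48 pairs; gained-positive: 73; lost: 36 (|C| threshold 0.4)
```

The five pairs flagged "apart" are exactly the five +3 Å shifts the
generator planted (`demo/sim/ground_truth.json`); the wild-type state split
0.775/0.225 is the realized occupancy of the planted two-state Markov chain
(stationary 0.8/0.2), which collapses to a single predominant conformation
in the mutant; and the 48 gained-negative pairs are exactly the planted
anti-correlated source×target block pairs.  `demo/run/` holds the full
artifact bundle (delta map, ΔR̄ᵢ profile, projections, RMSF, correlation
matrices, population shifts, manifest).

The same analysis is available as a library:

```python
from mutshift import SyntheticConfig, generate_pair, run_comparison
wt, mut, truth = generate_pair(SyntheticConfig(seed=0))
result = run_comparison(wt, mut)
```

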