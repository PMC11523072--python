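# Methods

## Scope and model

`macronoe` implements the analysis used to judge conformational
ensembles of macrocycles (rings of 12 or more atoms) against NMR NOE
upper distance bounds, plus the REST2 enhanced-sampling machinery such
ensembles are typically produced with. The package operates on three
ingredients: a molecular graph (connectivity only), a conformer
ensemble (ordered coordinate frames in nm), and a table of NOE upper
bounds between hydrogen groups. No molecular dynamics engine is
involved; ensembles come from files or from the synthetic generator,
and the replica-exchange component is a torsional Monte Carlo toy built
to exercise the ladder/scaling machinery.

## NOE back-calculation

NOE cross-peak intensity decays as r⁻⁶, so the ensemble average that an
upper bound constrains is

d_avg = ⟨ d_ab⁻⁶ ⟩^(−1/6),

where the mean runs **jointly** over the frames of the analysis window
and over all hydrogen pairs (a ∈ group A, b ∈ group B). Design choices
made here, where conventions differ between labs:

* **Normalization, not summation**, over equivalent pairs (no
  pseudo-atom multiplicity correction). Summing instead of averaging
  would shift methyl-group distances by a constant factor 3^(1/6);
  averaging is the standard pseudo-atom practice.
* Because a single joint mean is taken, time-averaging and
  pair-averaging commute; the order is immaterial.
* The violation is clamped at zero, max(0, d_avg − d_ref); the signed
  excess is recoverable as d_avg − d_ref from the per-restraint table.
* The quality score counts violations **strictly greater than**
  0.05 nm. The threshold is configurable; strictness matters only for
  exactly-boundary synthetic cases.
* The "analyze the trailing part of the trajectory" convention is
  generalized to a window fraction in (0, 1] (default 1.0): the last
  ⌈w·n⌉ frames enter the averages.

Heavy-atom restraint notation is expanded to the bonded hydrogens via
the molecular graph; every hydrogen must have exactly one bonded heavy
atom (validated at graph construction). Restraints are classified
macrocyclic / extracyclic / mixed by whether both, neither, or one of
the two heavy anchors belongs to the macrocycle.

Ring membership uses the smallest set of smallest rings (networkx
minimum cycle basis) with a ≥ 12 threshold. For fused or bridged
systems there is no unique notion of "the macrocyclic portion"; the
SSSR rule is this package's deterministic choice.

## Split-error estimate

The window is divided into n_segments (default 5) contiguous equal
blocks, remainder frames dropped from the end; d_avg is recomputed per
block and the **population** standard deviation over blocks is the
per-restraint error bar. The scalar convergence summary is the root
mean square of those standard deviations over restraints. Segment
errors are order-dependent by construction (they measure drift);
the full-window average is not.

## Prochiral assignment

The two hydrogens of a prochiral CH₂ cannot be distinguished from the
NMR data alone, so they are assigned to best match the restraints:
for each prochiral center the two candidate assignments are enumerated
and the total clamped violation over the affected restraints is
minimized. Centers that share a restraint are enumerated jointly
(capped at 12 centers per sharing set; realistic tables are far below
this); independent centers separate exactly. Ties break toward the
lower-index hydrogen, which makes the operation deterministic and
idempotent. Whether the original analysis optimized per restraint or
per center jointly is not documented anywhere we know of; joint
per-center minimization is the stronger reading and never increases the
total violation relative to any fixed assignment.

## Graph alignment

Restraint assignments made on one atom ordering are transferred to
another force field's topology by graph isomorphism (VF2, element- and
bond-preserving; bond orders ignored — distances do not need them).
Among automorphic alternatives (methyl rotations, prochiral swaps) the
lexicographically smallest image tuple is chosen, so mappings are
reproducible run to run. Enumeration is capped at 20 000 isomorphisms;
beyond that the first match is kept (not reached for molecule-sized
graphs with typical symmetry groups).

## Clustering

Pairwise heavy-atom RMSD after Kabsch superposition (proper rotations
only; the SVD determinant sign is corrected to exclude reflections) is
the metric; average-linkage agglomerative clustering (scipy's
Lance–Williams implementation, cross-checked in the tests against a
naive all-pairs recomputation) produces a fixed number of clusters
(default 5). A centroid is ill-defined in an RMSD metric space, so the
representative is the **medoid**: the member with the lowest mean RMSD
to its own cluster, ties to the lowest frame index. Populations are
exact rationals (counts over frames). RMSD matrices above 2000 frames
require an explicit opt-in; no frame sieving is implemented.

## REST2 ladders and topology scaling

λ ladders between 1 and the final scaling f (defaults n = 12,
f = 0.125, quadratic — typical production settings):

* exponential: λ_i = f^(i/i_max);
* quadratic: √λ linear in the replica index from 1 to √f, i.e.
  λ_i = (1 − (1 − √f)·i/i_max)². The associated step parameter
  τ = (1 − √f)/i_max is reported as metadata. The quadratic scheme is
  fixed by its endpoints and the √λ-linearity; this is the
  parameterization consistent with "quadratic in replica index" and the
  stated bounds.

Effective solute temperature: T_eff = T₀/λ (2400 K at λ = 0.125,
T₀ = 300 K).

Topology scaling follows common partial-tempering practice on a
GROMACS-style topology subset ([defaults], [atomtypes], [moleculetype],
[atoms], [bonds], [pairs], [angles], [dihedrals], [system],
[molecules]; unknown directives preserved verbatim; no preprocessor):

* solute atom charges × √λ; solute LJ ε × λ via duplicated atom types
  suffixed `_s` (so solvent–solvent terms are untouched without editing
  pair lists). Under geometric-mean combination this yields
  intra-solute nonbonded × λ and solute–solvent × √λ.
* solute dihedral force constants (proper type 9 and improper type 4)
  × λ; 1-4 pair interactions inherit the atom-parameter scaling.
* bonds never scale (constrained in production MD); angle force
  constants scale only with the opt-in flag (the gREST-style variant
  used for strained rings).
* geometry parameters (equilibrium lengths and angles, phases,
  multiplicities) never change.
* scaling is a semigroup: λ₁ then λ₂ equals λ₁λ₂ (re-scaling an
  already-tempered type multiplies its ε in place).

The energy contract — U_dihedral,solute(scaled) = λ·U(1), intra-solute
electrostatics × λ, solute–solvent × √λ, solvent untouched — is
verified numerically by a small topology energy evaluator (harmonic
bonds/angles, periodic dihedrals, Coulomb + LJ with nrexcl-style
exclusions and explicit 1-4 pairs) rather than trusted from the
algebra.

## Toy replica-exchange sampler

The toy solute is a torsional model: periodic dihedral terms
k(1 + cos(mφ − φ₀)), optional harmonic bond angles, and nonbonded
(Coulomb + LJ) terms evaluated on the 1-4 distance of an ideal 4-atom
chain whose closed-form geometry couples a torsion and (optionally) an
angle variable. All terms are tagged solute; with angle tempering
enabled the model's energy is exactly linear in λ.

Sampling is single-variable Metropolis with Gaussian proposals
(σ = 0.3 rad default) at kT = 2.49435 kJ/mol (300 K); torsions are
wrapped onto (−π, π]. Exchanges are attempted every 100 steps on
alternating even/odd neighbor pairs with the standard Hamiltonian
criterion Δ = β[(U_i(x_j) + U_j(x_i)) − (U_i(x_i) + U_j(x_j))],
acceptance min(1, e^−Δ). Exchange records carry the full
configuration→slot permutation after every attempt, validated for
consistency when statistics are computed; demultiplexed walker
trajectories are recorded alongside the per-slot series.

Barrier crossings are counted as sign changes of the unwrapped torsion
minus the barrier location. Two factory models matter for the
qualitative findings:

* a 3-torsion double-well solute for the ladder-uniformity comparison
  (k = 10 kJ/mol per torsion, barriers ≈ 8 kT);
* a **gated** model for the angle-tempering comparison: a double well
  at ±π/2 whose both saddles (φ = 0 and π) are blocked by LJ repulsion
  on the chain 1-4 distance. The repulsion only relaxes when the stiff
  chain angle (k = 600 kJ/mol/rad², θ₀ = 1.6 rad) opens by ≈ 0.3 rad,
  which costs ≈ 9 kT unscaled — so the flip stays frozen at every
  replica unless the angle term itself is tempered. Crossing counts for
  this comparison are measured on the demultiplexed walkers: per-slot
  series register exchange swaps between walkers stuck in different
  wells as spurious crossings and would mask the effect.

## Synthetic data generator

The generator emulates the statistical structure of the real validation
setting with fully known ground truth:

* a schematic macrocycle: a planar regular ring of carbons (bond
  0.15 nm) with prochiral CH₂ centers, methyl groups (3-H equivalence
  groups) and an exocyclic carbon tail; geometry is idealized, not
  chemically minimized — the pipeline consumes distances only.
* a small number of conformational **states**: template coordinate sets
  differing by an out-of-plane tail fold, mixed with chosen fractions.
  Defaults are two states at (0.973, 0.027) — one strongly dominant
  conformer, the regime typical of converged macrocycle ensembles — and
  isotropic Gaussian jitter of σ = 0.01 nm within each state, an order
  of magnitude below the inter-template separation so that state
  recovery is well-posed (tight sub-states rather than broad thermal
  basins).
* NOE bounds derived **from the ensemble itself**: d_ref = d_avg +
  margin, so a nonnegative margin yields zero violations by
  construction and a margin of −v plants a violation of exactly v.
  Restraint targets are sampled from hydrogen equivalence-group pairs
  at least 3 bonds apart.

What passing on these data does *not* show: correctness on broad,
anharmonic conformational basins, real NOE tables with inconsistent or
calibration-limited bounds, spin diffusion, or solvent effects — the
generator has exact group structure, Gaussian noise, and
self-consistent bounds by design.

## Comparison statistics

Violation-fraction tables (rows = compound×solvent simulations,
columns = force fields) are compared with a Friedman omnibus test on
the complete rows (listwise deletion mirrors dropping a compound a
force field could not parametrize) followed by pairwise two-sided
Wilcoxon signed-rank tests with pairwise deletion, zeros dropped
(Wilcoxon convention). Ties receive average ranks; the Friedman
chi-square includes the standard tie correction. For ≤ 25 nonzero
differences the Wilcoxon null is computed **exactly** by dynamic
programming over doubled ranks — equivalent to enumerating all 2ⁿ sign
patterns and valid under ties, which scipy's exact method does not
accept — and the tie-corrected normal approximation is used above.
P-values are reported raw (matching common reporting practice); Holm
adjustment is available but off by default. A pair with all differences
zero reports p = 1 with a degenerate-pair warning.

## Numerical and testing notes

* Coordinates are nm internally; PDB I/O converts from/to Å (MDAnalysis
  readers/writers; ~1e-4 nm round-trip precision from the PDB format's
  3 decimals).
* Kabsch RMSD is computed with a double-precision SVD; identical
  structures give 0 to ≈ 1e-12, and reflections are excluded.
* Sampler validity checks thin trajectories (stride 50) before applying
  multinomial/KS error models, so that the i.i.d. assumption those
  models make approximately holds; the two-state reference populations
  come from quadrature of the Boltzmann weight on a 20 001-point grid.
* Problem sizes in the tests and acceptance script: 100-frame synthetic
  ensembles, 20 000–50 000-step Monte Carlo runs, 5 seeds per
  qualitative comparison, 1000 random ensembles for the r⁻⁶ oracle
  sweep — sizes at which every stochastic check separates cleanly from
  its alternative.
* Exchange-rate spread (max − min over neighbor pairs) is an order
  statistic with substantial seed-to-seed noise; the ladder-uniformity
  comparison is therefore reported both per seed and as means over
  seeds, and the acceptance script uses 50 000-step runs to keep the
  per-pair rate estimates tight.

## Known limitations

* No relaxation-matrix NOE back-calculation, spin diffusion or
  order-parameter corrections; r⁻⁶ averaging only.
* The GROMACS topology subset has no preprocessor (#include, #define)
  and no dihedral-type lookup tables; parameters must be inline.
* No frame weights in ensembles (v1) and no sieving in clustering.
* The toy sampler has no Cartesian degrees of freedom, solvent
  particles or forces; it exists to exercise ladders, scaling and
  exchange bookkeeping, not to simulate molecules.
* Literature-specific bound discards/renormalizations are not
  reproduced; a generic exclusion filter substitutes.
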