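# macronoe

Validation of macrocycle conformational ensembles against NMR NOE upper
distance bounds, together with the REST2 (replica exchange with solute
tempering) machinery used to generate such ensembles: λ-ladder
construction, Hamiltonian topology scaling, exchange diagnostics, and a
desk-scale torsional replica-exchange sampler.

## Who this is for

Molecular-modelling practitioners who simulate macrocyclic compounds
(rings of ≥ 12 atoms, a chemical space where conformational sampling is
hard and force-field quality is uneven) and want to ask: *does my
ensemble satisfy the experimentally observed NOE contacts?* — and, when
several force fields or protocols are compared, *are the differences
statistically meaningful?*

## The core quantities

For a restraint between hydrogen groups *A* and *B* with literature
upper bound *d*<sup>ref</sup>, the ensemble-averaged distance uses r⁻⁶
weighting (NOE intensity falls off as r⁻⁶):

    d_avg = ⟨ d_ab⁻⁶ ⟩^(−1/6)

with the mean running jointly over the analysis-window frames and all
equivalent hydrogen pairs (a ∈ A, b ∈ B). The violation is the clamped
excess max(0, d_avg − d<sup>ref</sup>), and a simulation's quality
score is the **fraction of restraints with violation > 0.05 nm**.
Error bars come from splitting the trajectory into five equal segments
and taking the standard deviation of the per-segment averages.

On the sampling side, REST2 scales the solute's dihedral and
intramolecular nonbonded terms by λ (solute–solvent by √λ), emulating a
solute temperature T₀/λ. Replica ladders follow either

    exponential:  λ_i = f^(i / i_max)
    quadratic:    √λ_i linear in i from 1 to √f

with *f* the final scaling (default 0.125, i.e. 2400 K effective at
T₀ = 300 K). Bond-angle scaling (a gREST variant) can be included for
strained rings.

## Worked example

```python
import macronoe as mn

# synthetic two-state macrocycle ensemble with known ground truth
spec = mn.SynthSpec(seed=11)
graph, _ = mn.make_toy_macrocycle(spec)
ensemble, labels = mn.sample_ensemble(spec, 100)

# derive NOE bounds from the ensemble, planting 0.10 nm violations on 4 of 10
pairs = mn.make_restraint_pairs(graph, 10, seed=1)
table = mn.derive_bounds(ensemble, pairs, [-0.10] * 4 + [0.05] * 6, graph=graph)

result = mn.NOEValidation(ensemble, graph, table).fit()
print(result.summary())
```

prints (abridged):

```
NOE upper-bound validation
==============================================================
restraints: 10   frames: 100   window: 1
violation threshold: 0.05 nm (strict)
fraction of violations: 0.400
  macrocyclic  0.600
  mixed        0.200
rms split error: 0.0033 nm (5 segments)
--------------------------------------------------------------
 id  d_avg_nm  d_ref_nm  violation_nm  split_std_nm      region  bond_separation
 r1    0.8393    0.7393        0.1000        0.0024 macrocyclic                6
 r2    0.6588    0.5588        0.1000        0.0021 macrocyclic                4
 r3    0.8130    0.7130        0.1000        0.0026 macrocyclic                5
 r4    0.7352    0.6352        0.1000        0.0025       mixed                5
 r5    0.8105    0.8605        0.0000        0.0038       mixed                6
 ...
```

The fraction of violations is exactly the planted 0.4: the four
restraints whose bounds were tightened by 0.10 nm violate by 0.10 nm,
the rest are satisfied. A REST2 ladder for production use:

```python
sched = mn.quadratic_lambdas(n=12, f=0.125)
print([round(l, 3) for l in sched])
# [1.0, 0.886, 0.779, 0.678, 0.585, 0.499, 0.419, 0.346, 0.281, 0.222, 0.17, 0.125]
print(mn.effective_temperature(sched[11]))  # 2400.0 K
```

A command-line interface mirrors the library
(`macronoe validate|cluster|rest2-ladder|rest2-scale|toy-rest2|synth|compare|graph-info|restraints-check`).

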