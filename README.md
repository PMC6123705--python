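# enoe

Exact-NOE (eNOE) extraction and ensemble validation for small RNA.

Conventional NOESY analysis turns cross-peak intensities into loose upper
distance bounds; most of the r⁻⁶ distance information in the
cross-relaxation rate is thrown away. The *exact NOE* protocol keeps it: a
buildup series over several mixing times is corrected for spin diffusion
with a full relaxation-matrix simulation, diagonal decays and cross-peak
buildups are fitted for the auto- and cross-relaxation rates ρ and σ, and σ
is inverted into an effective distance with tight, class-dependent bounds.
Those restraints, in turn, let conformer ensembles be validated
quantitatively — by r⁻⁶-averaged distances, restraint target functions,
jack-knife cross-validation, order parameters S², bundle RMSDs and torsion
angles. The reference use case is a 14-mer UUCG-tetraloop RNA measured at
900 MHz with τc = 2.23 ns, but nothing is specific to that molecule.

This package is aimed at NMR spectroscopists and method developers who want
the numerical core of that protocol — magnetization-transfer simulation,
correction, fitting, restraint generation, ensemble metrics — as a tested
Python library with a thin command-line layer, plus a synthetic-data module
that generates NOESY buildups from known geometry so every stage can be
verified against ground truth.

## The model

Magnetization deviations of a proton network obey the Solomon equations
dΔM/dt = −R ΔM, with auto-relaxation rates ρᵢ on the diagonal of R and
cross-relaxation rates σᵢⱼ off the diagonal. For rigid isotropic tumbling,

    σᵢⱼ   = K r⁻⁶ [6 J(2ω₀) − J(0)]
    ρᵢⱼ   = K r⁻⁶ [J(0) + 3 J(ω₀) + 6 J(2ω₀)]
    J(ω)  = τc / (1 + (ω τc)²),     K = (1/10) ((μ₀/4π) ħ γ_H²)²

NOESY intensities over a mixing time τ_m are entries of A(τ_m) = exp(−R τ_m).
The full-matrix spin-diffusion correction multiplies each measured intensity
by the ratio of the simulated isolated-pair intensity to the simulated
full-matrix intensity from a reference structure (conformer-averaged for an
ensemble). Diagonals are fitted to ΔM(0)·exp(−ρτ), corrected cross peaks to
the two-spin closed form with ρᵢ, ρⱼ, ΔM(0) frozen and σ free, and σ is
inverted through σ ~ r⁻⁶. Bounds follow the restraint class: bidirectional
(both cross peaks fitted) — upper = lower = r; unidirectional — ±10%;
generic-normalized (gn, overlapped diagonal replaced by group-maximum ΔM(0)
and ρ) — upper limit 1.1 r only.

## Worked example

```python
from enoe import ExperimentConditions, NOESYBuildupModel
from enoe.synthetic import make_helix_spin_system, simulate_noesy

cond = ExperimentConditions(tau_c=2.23e-9, larmor_frequency=900.0)
spins, truth = make_helix_spin_system(4, seed=1, displacement=0.3)
buildups = simulate_noesy(spins, cond, (0.04, 0.08, 0.12, 0.16))

result = NOESYBuildupModel(buildups, spins, cond).fit()
print(result.summary())

pair = result.restraints[0].pair
print(f"{pair[0]}-{pair[1]}: fitted {result.restraints[0].r_eff:.3f} A, "
      f"true {truth.distance(*pair):.3f} A")
```

prints (abridged):

```
eNOE buildup fit results
============================================================
conditions:       tau_c = 2.23 ns, 900 MHz
fit range:        40-160 ms
corrected:        True
diagonal decays:  20 fitted (0 fallback rho = 2.9 1/s)
cross fits:       190 (0 rejected/flagged)
restraints:       190 bidirectional (190 total)
...
G1.H1'-G1.H2': fitted 1.755 A, true 1.755 A
```

i.e. on noiseless synthetic data the full pipeline recovers every distance
essentially exactly; with the 40–160 ms fit range the maximum error for
pairs up to 5 Å stays below 10⁻⁴ Å, comfortably inside the 0.1 Å accuracy
the method claims for real data.

The same steps are available from the shell:

```sh
enoe simulate --residues 4 --seed 1 --out peaks.tsv --truth truth.tsv
enoe fit --structure ref.pdb --peaks peaks.tsv --tauc 2.23 --upl x.upl --lol x.lol
enoe validate --structure bundle.pdb --upl x.upl --lol x.lol
enoe advisor --tauc 2.74        # maximal useful NOESY mixing time
```

## Layout

| module | contents |
| --- | --- |
| `enoe.spin_system_io` | PDB ensembles, atom-name normalization, buildup tables, CYANA-style `.upl`/`.lol` files |
| `enoe.relaxation` | dipolar rates, full relaxation matrix, NOESY propagation, two-spin closed form |
| `enoe.spin_diffusion` | correction factors and their application |
| `enoe.fitting` | diagonal/cross fits, normalization selection, quality flags, gn parameters |
| `enoe.restraints` | σ→r conversion, restraint classes, distance comparison, target function, jack-knife, peak pruning |
| `enoe.ensemble_metrics` | order parameters S², bundle RMSD, nucleic-acid torsions |
| `enoe.synthetic` | helix fixture, NOESY simulator, τc and mixing-time helpers |
| `enoe.model` | `NOESYBuildupModel` / `NOESYBuildupResults` facade |
| `enoe.cli` | the `enoe` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
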