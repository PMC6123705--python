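# Methods

This note documents the model, the numerical choices and the limitations of
the `enoe` package: what is computed, under which assumptions, with which
defaults, and what the synthetic-data tests do and do not establish about
real spectra.

## Relaxation model

The package treats a molecule's protons as a homonuclear dipolar network
under rigid isotropic tumbling. Magnetization deviations follow the Solomon
equations dΔM/dt = −R ΔM with

- σᵢⱼ = K rᵢⱼ⁻⁶ [6 J(2ω₀) − J(0)] (cross relaxation),
- pairwise auto contribution ρᵢⱼ = K rᵢⱼ⁻⁶ [J(0) + 3 J(ω₀) + 6 J(2ω₀)],
- diagonal Rᵢᵢ = Σ_j ρᵢⱼ + ρ_ext,
- J(ω) = τc / (1 + (ωτc)²), K = (1/10)((μ₀/4π) ħ γ_H²)² with
  γ_H = 2.6752218744×10⁸ rad s⁻¹ T⁻¹.

The constant convention matters only internally: distance extraction
inverts exactly the same expressions, so any self-consistent convention
yields identical distances (verified by the σ↔r round-trip test, identity
to 10⁻¹⁰ over 1.8–6 Å).

NOESY transfer over a mixing time is A(τ_m) = exp(−R τ_m), evaluated by a
dense symmetric eigendecomposition (all mixing times from one
factorization). The closed-form two-spin solution is kept as a separate
code path and doubles as the fitting model; agreement with the matrix
exponential is tested to a relative 10⁻⁹.

Assumptions: isotropic rigid tumbling (rotational anisotropy of small RNA
hairpins contributes errors on the order of 2% and is not modelled);
no cross-correlated relaxation, no heteronuclear pathways, no chemical
exchange inside the matrix. Solvent-exchange leakage can be emulated
through the additive per-proton rate `rho_external` (default 0; no
literature value is asserted for it).

## Spin-diffusion correction

For each analysed pair the correction factor at each mixing time is
⟨two-spin intensity⟩ / ⟨full-matrix intensity⟩, both simulated from a
reference structure with uniform initial magnetization, conformer averaging
done on intensities *before* the ratio (the ratio of averages is what
corrects the conformer-averaged observable). Factors → 1 as τ_m → 0 and are
exactly 1 when no third spin exists.

The pipeline applies corrections to **both cross peaks and diagonals** by
default. Correcting the diagonals (ratio of the pure monoexponential
exp(−ρᵢτ) to the simulated full-matrix diagonal) restores exactly the
monoexponential behavior the decay fit assumes; with it, the noiseless
end-to-end pipeline recovers σ to a relative 10⁻⁴ and distances to ~10⁻⁵ Å.
With cross-only correction (available via `correct_diagonals=False` on
`apply_corrections` and `fit`), the monoexponential fit of the intrinsically
multi-exponential diagonals leaves a residual bias that reaches ~0.14 Å for
the worst methylene pairs of the 20-proton fixture — above the 0.1 Å
accuracy the protocol targets. The full correction is therefore the
package's default protocol; the switch exists for comparison studies.

A single correction pass is performed; an iterated
correct → recalculate-structure → re-correct loop is out of scope because
the package does not recompute structures.

## Fitting

- Diagonals: least squares of ΔM(0)·exp(−ρτ) in log-parameters (positivity
  is structural), seeded by a log-linear regression. If fewer than 3 points
  lie in the fit range, the decay is non-positive or non-decaying, or
  r² < 0.9, the fit falls back to ρ = 2.9 s⁻¹ (a typical proton
  auto-relaxation rate at these conditions, configurable via
  `ExperimentConditions.rho_fallback`) with ΔM(0) back-extrapolated from
  the earliest point.
- Cross peaks: σ is the only free parameter of the two-spin closed form,
  with ρᵢ, ρⱼ, ΔM(0) frozen from the diagonal fits; both directions are
  fitted independently when both cross peaks exist, and their σ's averaged
  before distance conversion. Standard errors come from the Gauss–Newton
  Jacobian.
- Fit range: 40–160 ms by default. The empirical rule
  τ_max ≈ 4×10⁻¹⁰ s²/τc (2.5×10⁻¹⁰ for proteins) gives 179 ms at
  τc = 2.23 ns, which snaps down to the 160 ms grid point. Longer ranges
  amplify both spin-diffusion corrections and the multi-exponential bias of
  geminal-coupled diagonals; the package reproduces the direction of that
  bias (ΔM(0) and ρ fitted over 40–320 ms are smaller than over 40–160 ms)
  but not specific percentages, which depend on unpublished simulation
  parameters.
- Quality control: visual fit inspection is replaced by explicit thresholds
  (diagonal r² ≥ 0.9, σ relative standard error ≤ 20%, ≥ 3 points),
  configurable via `FitThresholds`. Fits are flagged, never deleted; flags
  name the failed criterion and are monotone under threshold tightening.
- Normalization selection: origin spin preferred; destination used when
  only its diagonal is clean; rejected when neither passes.

## Restraints and validation

Distance bounds by class: bidirectional — upper = lower = r (no tolerance);
unidirectional — ±10%; gn — upper 1.1 r, no lower bound. gn (generic
normalized) fits replace an overlapped diagonal's ΔM(0) and ρ by the maxima
of its atom group (amino / methylene / other; hydroxyls are a separate
class but grouped with "other" unless configured). The group-maximum ΔM(0)
deflates σ, pushing the distance up; the group-maximum ρ inflates it
slightly in the other direction. The +10% tolerance absorbs that
counter-term: in noiseless simulations with class-heterogeneous ΔM(0) the
gn *upper limit* (1.1 r) bounds the true distance for every overlapped
proton, while the raw gn distance alone can undershoot by a few percent
when within-group ρ values are inhomogeneous (e.g. chain-terminal
residues). This is the reason gn restraints are upper limits with
tolerance rather than exact distances.

The target function is the unweighted Σ (violation)² in Å², with effective
distances computed either per conformer or r⁻⁶-averaged over states
(multi-state ensembles must satisfy restraints on average, not
individually). Violations below 10⁻⁹ Å are treated as numerical zeros;
violations ≥ 0.2 Å are highlighted separately. Jack-knife cross-validation
partitions the restraints into k seeded folds (each restraint held out
exactly once) and sums the held-out partial TFs; the package evaluates
supplied ensembles, it does not recompute structures, so TF values are
comparative, not reproductions of any structure-calculation engine's
internal weighting.

Peak pruning emulates the growing spectral overlap of larger RNAs: a
fraction f of cross peaks and 2f of diagonals are deleted uniformly at
random (diagonal overlap grows faster because only one resonance must
coincide), and each surviving cross peak is reclassified by its surviving
diagonals (2 → bidirectional, 1 → unidirectional, 0 → gn). Stratification
by residue is not modelled.

## Ensemble metrics

- S² = ½(3 Σ_{αβ} ⟨μ_α μ_β⟩² − 1) with equal conformer weights; 1 for one
  conformer, 0.25 for two orthogonal states, → 0 for isotropic sampling.
- Bundle RMSD: mean RMSD-to-mean after optimal (Kabsch) superposition onto
  the iteratively refined mean coordinates, over a residue/atom subset.
  Published bundle statistics do not always state their superposition
  convention; deviations from printed values of a few hundredths of an Å
  can stem from that choice alone.
- Torsions: IUPAC α…ζ, χ (O4'–C1'–N9–C4 purines / N1–C2 pyrimidines),
  ν1, ν2, and η2 defined as C1'–C2'–O2'–HO2' (skipped when the hydroxyl
  proton is absent, as it usually is outside stabilized loops). Circular
  mean/std across conformers.

## Synthetic data

`make_helix_spin_system` builds a deterministic parametric helix (32°
twist, 2.7 Å rise, five protons per residue) whose proton lattice mimics
the A-form situation that matters for the method: a geminal methylene pair
at 1.78 Å dominating its diagonal relaxation, nearest non-geminal contacts
at ~1.8–2.4 Å, and pair distances spanning 1.8–6 Å with a minimum of
1.7 Å. Conformer jitter is applied rigidly per residue (covalent geometry
preserved) and redrawn if it would violate the minimum distance. ΔM(0)
heterogeneity (class-dependent base levels with downward per-spin scatter)
is available to exercise gn normalization. The simulator emits
conformer-averaged full-matrix intensities for all diagonals and both
directions of every cross pair; additive Gaussian noise is scaled to the
largest first-mixing-time diagonal, the way signal-to-noise is quoted in
NOESY practice.

What the fixture does *not* emulate: real chemical-shift overlap (overlap
is modelled abstractly by deleting peaks), internal dynamics beyond rigid
per-residue displacement, exchange broadening, baseline and lineshape
artifacts, and spectrometer noise correlations. Passing tests on synthetic
data therefore establish the correctness of the numerics — simulation,
correction, fitting, inversion — not the experimental robustness of peak
extraction, which is upstream of this package.

Default study conditions throughout: τc = 2.23 ns (H₂O; 2.74 ns for D₂O via
the 23% Stokes–Einstein viscosity scaling), 900 MHz, eight mixing times
40–320 ms with fits restricted to 40–160 ms.

## Problem sizes

The test suite and the acceptance script run on 10–30-proton systems
(20 protons for the headline recovery experiment, 97 evaluated pairs ≤ 5 Å)
and Monte-Carlo loops of 100 seeds for noise-robustness checks — sizes at
which the dense eigendecomposition is effectively free. For systems beyond
a few hundred protons the relaxation matrix accepts a distance cutoff
(default none; suggested 8 Å), which zeroes long-range σ entries while
keeping every pair's diagonal contribution.

## Known limitations

- No structure calculation: restraint files are produced and ensembles are
  evaluated, but simulated annealing / torsion-angle dynamics belongs to
  dedicated engines.
- Exchangeable-proton leakage is a knob, not a calibrated model.
- The three-spin approximation for partially deuterated molecules is not
  implemented (full-matrix only).
- mmCIF input and non-standard residues are out of scope; the atom-name
  dialect table covers the four ribonucleotides and fails loudly otherwise.
- Comparisons against deposited reference ensembles require the user to
  supply the coordinate files; none are bundled.
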