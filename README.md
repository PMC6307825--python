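# rnpmd

Validation and free-energy analysis of protein–RNA molecular-dynamics
ensembles against NMR data.

MD simulations of protein–RNA complexes — an RRM domain bound to a
pre-miRNA terminal loop being the motivating system — produce multi-model
coordinate ensembles that must be scored against the primary NMR
observables and characterised at the binding interface before any
conclusion about an engineered complex can be trusted.  `rnpmd` provides
that analysis tier as a tested Python library plus a thin CLI:

* **NOE back-calculation and violation statistics.**  For an upper-bound
  restraint the ensemble-effective distance is the r⁻⁶ average
  ⟨r⟩ = ((1/N_f) Σ_f r⁻⁶)^(−1/6); a restraint is violated when
  ⟨r⟩ > r_NOE.  Reports give per-category satisfied fractions, counts of
  violations above 0.05 nm and 0.3 nm, and the mean violation.
* **MD-adapted structure ensemble.**  The 10% of frames with fewest NOE
  violations are retained, k-means-clustered (k = 20 by default) on
  superposed coordinates, and each cluster's medoid frame is exported —
  the conformers that best reconcile the force field with the NMR data.
* **Interface contacts.**  Hydrogen bonds (donor–acceptor ≤ 0.35 nm and
  D–H–A ≥ 135°) and aromatic stacking (ring-centre distance < 0.5 nm,
  plane angle < 30°) with per-trajectory occupancy tables.
* **Backbone plasticity and entropy.**  Per-residue circular dispersion of
  ω = φ + ψ with F/t/T fluctuation/transition tags (minority-region
  occupancy ≥ 30% ⇒ T), and first-order dihedral-histogram conformational
  entropy S = −R Σ p ln p with TΔS differences between states.
* **Collective variables.**  DRID (per-anchor moments of inverse Cα/P
  distances, score (1/3N) Σᵢ‖v_n(·,i) − v₀(·,i)‖), the smoothed fraction
  of native contacts Q = (1/N) Σ 1/(1 + exp[β(r_ij − λr⁰_ij)]) with
  β = 50 nm⁻¹, λ = 1.8, and 2-D Gaussian-KDE sampling-density maps.
* **REST2 planning.**  Geometric λ ladders λ_i = λ_min^(i/(n−1)) and
  partial-scaling regions (mutated nucleotides + flanking phosphates +
  protein residues within 0.5 nm).
* **Non-equilibrium free energies.**  The Crooks-theorem maximum-likelihood
  (Bennett) ΔG from bidirectional work values with bootstrap errors, a
  Gaussian-intersection cross-check, and the binding thermodynamic cycle
  ΔΔG = ΔG_complex − ΔG_free.

A first-class synthetic-data module generates every input with planted
ground truth (exact occupancies, known violation status, Gaussian work
pairs satisfying the Crooks relation, labelled conformer mixtures), so the
whole pipeline is testable without trajectories.

## Worked example

Generate fixtures and run the free-energy cycle:

```sh
rnpmd simulate-fixtures --out demo_fix --seed 7 --n-frames 100
rnpmd ddg --work-complex demo_fix/work_complex.tsv \
          --work-free demo_fix/work_free.tsv --out demo_ddg --n-boot 500
```

prints

```
dG_complex = -1.988 +/- 0.037 kcal/mol
dG_free    = -0.824 +/- 0.039 kcal/mol
ddG        = -1.164 +/- 0.054 kcal/mol
```

The fixtures plant ΔG = −2.0 kcal/mol for the mutation in the complex and
−0.8 kcal/mol in the free protein, so the true ΔΔG is −1.2 kcal/mol: the
maximum-likelihood estimator recovers both legs within its bootstrap error,
and the negative sign means the mutation favours binding.  The NOE report
on the same fixtures,

```sh
rnpmd noe --pdb demo_fix/complex.pdb --noe-table demo_fix/noe.tsv --out demo_noe
```

prints a satisfied fraction of 0.8 (8 of the 10 planted restraints are
satisfied by construction) and a mean violation of 0.05 nm, the planted
margin.  `rnpmd run-all --out run --seed 7` chains every stage and writes a
manifest (input hashes, seeds, parameters); reruns with the same seed are
byte-identical.

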