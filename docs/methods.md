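# Methods

This note documents the models and procedures implemented in `rnpmd`, the
parameter choices that matter, what the synthetic fixtures emulate, and the
numerical decisions a maintainer would want written down.

## NOE ensemble averaging and violation scoring

NOE cross-relaxation rates fall off as r⁻⁶, so an ensemble of N_f frames
is compared to an upper-bound restraint through the generalized mean
⟨r⟩ = ((1/N_f) Σ_f r_f⁻⁶)^(−1/6), which is dominated by the shortest
distances the ensemble visits.  For restraints between atom *groups*
(methyl or aromatic pseudo-atoms) the per-frame distance is itself the
r⁻⁶ sum over all cross pairs, r_eff = (Σ_{a,b} r_ab⁻⁶)^(−1/6) — the
convention consistent with NOE physics when equivalent protons contribute
to one cross peak.  A minimum-distance alternative is available via
`group_mode="min"` for comparison with more permissive conventions.

A restraint is violated when ⟨r⟩ exceeds the bound; an optional tolerance
(default 0, i.e. strict) can absorb integration noise.  The mean violation
is emitted both over violated restraints and over all restraints, always
as a non-negative magnitude ⟨r⟩ − r_NOE; both denominators are printed
with explicit labels because the literature is inconsistent about which
one "average violation" refers to.

**MD-adapted ensemble.**  Frames are ranked by per-frame violation count,
ties broken by total violation magnitude and then by frame index (so the
selection is reproducible); the best 10% are retained, k-means-clustered
on whole-complex superposed coordinates (k = 20 by default, seeded
k-means++ with 10 restarts), and each cluster's medoid — the member with
least cumulative pairwise superposed RMSD — is exported, ordered by
cluster population.

## Interface contacts

Hydrogen bonds use the heavy-atom criterion: donor–acceptor distance
≤ 0.35 nm *and* donor–H–acceptor angle ≥ 135°.  Hydrogens must be present;
there is deliberately no heavy-atom-only fallback, because a silent
fallback changes occupancies irreproducibly.  Stacking uses ring-centre
distance < 0.5 nm and inter-plane angle < 30°, with the plane normal from
an SVD best-fit and the angle folded into [0°, 90°] (ring normals have
arbitrary sign).  Ring centres are unweighted centroids by default — ring
atoms (C/N) have near-identical masses — with a mass-weighted variant
behind a flag.

Occupancy is reported per trajectory (100 · present/total frames, never
pooled across trajectories), while distance/angle mean ± sd pool the
present frames of all trajectories, matching how interface tables are
conventionally printed.  Candidate interactions must be declared
explicitly; there is no automatic donor/acceptor perception, since curated
interaction lists are the norm for this analysis.

## Backbone plasticity (PAD) and conformational entropy

The per-residue plasticity descriptor is the circular standard deviation
of ω = φ + ψ: with R̄ the mean resultant length of e^{iω}, dispersion
= sqrt(−2 ln R̄) converted to degrees.  The original angular-dispersion
method does not publish a closed formula, so the dispersion measure is
documented here as "PAD-like" and is pluggable.

Transition tagging assigns each frame to a Ramachandran region (broad α,
β and left-handed-α rectangles plus an "other" catch-all; boundaries are
configurable JSON because no standard prints them).  All non-modal
occupancy is pooled as "minority": below a 1% noise floor the residue is a
pure fluctuator (F); at ≥ 30% minority it shows long transitions (T);
in between, short transitions (t).  Pooling over all minority regions
(rather than per-region thresholds) was a design choice; it makes the tag
monotone in total excursion time.

Conformational entropy is the first-order dihedral-histogram estimate
S = −R Σ_bins p ln p per torsion (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹), summed
over a residue's φ, ψ, χ_n as independent terms, with 10° right-closed
bins on (−180°, 180°] so results are deterministic.  No
mutual-information corrections are applied: the estimate is meant for
qualitative state-to-state comparisons (TΔS), not absolute entropies.
TΔS uncertainties come from a block bootstrap (contiguous 10% blocks,
seeded) to respect time correlation.

## Collective variables

**DRID.**  Anchors are the Cα and P atoms.  For each anchor the inverse
distances to all other anchors give three features: mean μ, sqrt of the
second central moment ν, and the *signed* cube root of the third central
moment ξ (so skew direction survives).  The score between a frame and a
reference is (1/(3N)) Σ_i ‖v_n(·,i) − v₀(·,i)‖ with a per-anchor Euclidean
norm — implemented exactly in this form, with the 1/(3N) prefactor outside
the per-anchor norms.

**Fraction of native contacts.**  Q = (1/N) Σ 1/(1 + exp[β(r_ij −
λ·r⁰_ij)]) over heavy-atom pairs closer than 0.45 nm in the reference
frame.  β defaults to 50 nm⁻¹ (5 Å⁻¹), the standard smoothing constant for
this functional form; λ = 1.8.  β is configurable for sensitivity checks,
including deliberately unphysical values.

**Sampling maps.**  A joint 2-D Gaussian KDE (Scott bandwidth) over
(Q, DRID) points, evaluated on a regular grid padded by 3 sd and
renormalised so the grid integral is 1 within 10⁻³.  A zero-variance CV
raises an error suggesting jitter rather than returning a degenerate map.

## Clustering

k-means runs on flattened coordinates after superposing every frame onto
the first frame (Kabsch with determinant correction) on the chosen
selection — the standard practical approximation to RMSD-metric
clustering, since true pairwise RMSD is not a vector-space metric.
Initialisation is seeded k-means++ with 10 restarts, ≤ 500 iterations,
tolerance 10⁻⁸ nm²; the best inertia is kept, so results are deterministic
given a seed.  Cluster representatives are exact medoids under pairwise
superposed RMSD, ties broken by lowest frame index.  The interface
selection takes all atoms of the named nucleotides plus every whole
protein residue with a heavy atom within 0.45 nm of a nucleotide heavy
atom in the reference frame (residue-level membership, matching how
interface shells are described in practice).  The reference for
superposition is the first frame; an iterative mean-structure reference
was considered and rejected as an unnecessary source of path dependence.

## REST2 planning

λ ladders are geometric, λ_i = λ_min^(i/(n−1)), giving a constant ratio
between neighbours; endpoints are set exactly to 1 and λ_min.  The
partial-scaling region contains the mutated nucleotides, their flanking
phosphate groups — both the residue's own 5′ phosphate and the next
residue's phosphate on the 3′ side, configurable, since "flanking" is
ambiguous — and every whole protein residue with a heavy atom within
0.5 nm of the nucleotides' heavy atoms.  The three interaction classes
(λ-scaled solute–solute, λ^1/2 solute–environment, unscaled
environment–environment) are emitted descriptively; writing
engine-specific scaled topologies is out of scope.  Effective temperatures
T/λ are reported as a convenience.

## Crooks maximum-likelihood free energies

Given forward works W_F (A→B) and reverse works W_R (B→A) at temperature
T, the Crooks fluctuation theorem P_F(W)/P_R(−W) = e^{β(W−ΔG)} leads to
the Bennett self-consistent maximum-likelihood equation with the
ln(n_F/n_R) sample-size offset.  The residual is monotone in ΔG; the root
is bracketed on [min(−W_R), max(W_F)] padded by 10 kT (the discrete MLE
root can sit slightly outside the raw sample range when sample sizes are
unbalanced) and solved by Brent's method to machine precision.  When the
forward and mirrored-reverse work histograms share less than 1% of their
mass the estimator raises an error carrying the overlap diagnostic instead
of returning a number that the data cannot support.

Uncertainties are a seeded bootstrap (default 1000 resamples) over work
values, or over replicate groups when the work table tags replicates; the
bootstrap root-finds are vectorised (bisection over all resamples at
once).  A Gaussian-intersection estimator — the crossing point of normal
fits to P_F(W) and P_R(−W), reducing to the midpoint of the means at equal
variance — serves as an independent cross-check, not as the primary
estimator.  The thermodynamic cycle combines two legs as ΔΔG =
ΔG_complex − ΔG_free with errors in quadrature; negative ΔΔG means the
mutation favours binding.

In the reversible (σ→0) limit the MLE coincides with the Jarzynski
exponential average and returns the planted ΔG exactly; this is asserted
in the tests.

## Synthetic fixtures: what they emulate and what they do not

The generators produce minimal geometric abstractions — dummy residues
with field-standard atom names (N/H/CA, P/OP1/C1′, hexagonal rings), not
chemically valid molecules — because every analysis stage consumes
geometry only.  Occupancies and minority fractions are planted by frame
counting (exactly round(f·n) frames), so truth assertions are exact rather
than statistical.  Work samples are Gaussian pairs whose means are fixed
by the fluctuation theorem: μ_F = ΔG + σ²/2kT, μ_R = −ΔG + σ²/2kT.
Conformer mixtures are internal deformations of a common scaffold
(rigid-body differences would vanish under superposition), rescaled until
every pairwise superposed RMSD clears the requested separation, and are
refused when separation ≤ 4·noise.

Passing tests on these fixtures demonstrates that the estimators and
criteria are implemented correctly; they do not demonstrate force-field
accuracy, convergence of real trajectories, solvent effects, or the
validity of any specific experimental restraint set.  Real-ensemble
characteristics deliberately not emulated include anisotropic and
correlated atomic fluctuations, realistic Ramachandran densities outside
the planted modes, non-Gaussian work distributions, and pseudo-atom
bookkeeping in deposited restraint files (the NOE table format supports
atom groups; equivalence conventions are left to the caller).

## Problem sizes and defaults

Default analysis conditions mirror the study conventions: H-bond cuts
0.35 nm/135°, stacking 0.5 nm/30°, interface shell 0.45 nm,
partial-scaling shell 0.5 nm, NOE retention 10% with k = 20, transition
threshold 30%, T = 298 K, energies in kcal/mol, lengths in nm (PDB I/O
converts from/to Å), residues 1-based, atom indices 0-based.  The bundled
fixtures use 100-frame ensembles, 500-frame dihedral series and
2000/2000-sample work sets — sizes at which every planted truth is
recovered and the closed-form checks are sharp — and all generators are
deterministic given a seed.

## Known limitations

* PDB numeric precision bounds round-trip fidelity at 10⁻³ nm.
* First-order entropy ignores correlations between torsions; TΔS values
  are comparative only.
* k-means on superposed coordinates is an approximation to RMSD-metric
  clustering and, like any k-means, requires k as an input.
* The NOE engine assumes a single global topology; pooled multi-ensemble
  reports concatenate frames (the r⁻⁶ average of a union is computed on
  the union, never by averaging per-ensemble reports).
* No periodic-boundary handling anywhere: inputs must be whole-molecule,
  imaged ensembles, as deposited NMR/MD-adapted PDB files are.
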