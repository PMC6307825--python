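"""Synthetic fixtures with planted ground truth.

Every generator here builds a minimal geometric abstraction of a
protein–RNA system — dummy residues with field-standard atom names, not
chemically valid molecules — so that each analysis stage can be tested
against exactly known answers:

* a two-chain complex with hydrogen bonds planted at chosen per-frame
  occupancies and stacking pairs at exact (distance, plane-angle) geometry,
* per-residue (φ, ψ) series with pure fluctuations or two-state switching
  at an exact minority fraction,
* bidirectional work samples from the Gaussian pair that satisfies the
  Crooks fluctuation theorem for a planted ΔG,
* cluster-structured conformer mixtures with recorded labels,
* NOE restraint tables whose satisfaction status is known by construction.

All generators are deterministic given a seed; truths are exact, not
statistical, wherever construction permits (occupancies and minority
fractions are planted by frame counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import HBondSpec, StackSpec
from .free_energy import GAS_CONSTANT_KCAL, WorkSet
from .geometry import DihedralSeries, kabsch_superpose
from .io import AtomRecord, Ensemble, Frame, Selection
from .noe import NOERestraint, backcalc_noe

__all__ = [
    "SyntheticTruth",
    "PlannedHBond",
    "PlannedStack",
    "InteractionPlan",
    "DihedralPlan",
    "make_complex_ensemble",
    "make_dihedral_fixture",
    "make_work_samples",
    "make_cluster_mixture",
    "make_noe_fixture",
]

# Ramachandran mode centres used by the dihedral generator
ALPHA_MODE = (-63.0, -43.0)
BETA_MODE = (-120.0, 135.0)

RING_RADIUS = 0.139  # nm, aromatic C–C bond geometry


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic fixture."""

    planted_hbond_occupancies: dict[str, float] = field(default_factory=dict)
    planted_stack_geometries: dict[str, tuple[float, float]] = field(default_factory=dict)
    planted_transition_fractions: dict[int, float] = field(default_factory=dict)
    planted_delta_g: float | None = None
    planted_cluster_assignment: np.ndarray | None = None
    planted_noe_violations: list[bool] = field(default_factory=list)
    hbond_specs: list[HBondSpec] = field(default_factory=list)
    stack_specs: list[StackSpec] = field(default_factory=list)
    hbond_present_frames: dict[str, np.ndarray] = field(default_factory=dict)
    cluster_conformers: np.ndarray | None = None


@dataclass
class PlannedHBond:
    label: str
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class PlannedStack:
    label: str
    distance: float  # nm between ring centres
    angle: float  # degrees between ring planes


@dataclass
class InteractionPlan:
    hbonds: list[PlannedHBond] = field(default_factory=list)
    stacks: list[PlannedStack] = field(default_factory=list)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _hexagon(center: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    ang = np.radians(np.arange(6) * 60.0)
    return center + RING_RADIUS * (
        np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2
    )


def make_complex_ensemble(
    n_frames: int,
    plan: InteractionPlan,
    seed: int = 0,
    present_distance: float = 0.29,
    broken_distance: float = 0.50,
) -> tuple[Ensemble, SyntheticTruth]:
    """Toy two-chain complex with planted H-bonds and stacking pairs.

    Each planted H-bond is satisfied (donor–acceptor 0.29 nm, D–H–A 180°)
    in exactly ``round(occupancy · n_frames)`` frames, chosen by a seeded
    draw, and broken (0.50 nm) in the rest.  Stacking pairs are built at
    the exact planted (distance, plane angle) in every frame.  Every frame
    is given an independent rigid-body pose so that frame coordinates
    differ while all internal geometry is exact.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    topology: list[AtomRecord] = []
    base_coords: list[np.ndarray] = []
    acceptor_moves: list[tuple[int, np.ndarray, np.ndarray]] = []  # (atom, present, broken)
    truth = SyntheticTruth()

    def add_atom(name, element, resi, resname, chain, pos):
        topology.append(
            AtomRecord(
                atom_index=len(topology),
                atom_name=name,
                element=element,
                residue_index=resi,
                residue_name=resname,
                chain_id=chain,
            )
        )
        base_coords.append(np.asarray(pos, dtype=float))
        return len(topology) - 1

    # --- planted hydrogen bonds, one isolated block each -------------------
    for b, hb in enumerate(plan.hbonds):
        y = 3.0 * b
        n_pos = np.array([0.0, y, 0.0])
        prot_resi = b + 1
        rna_resi = 28 + b
        add_atom("CA", "C", prot_resi, "ALA", "A", n_pos + [-0.15, 0.0, 0.05])
        add_atom("C", "C", prot_resi, "ALA", "A", n_pos + [-0.25, 0.1, 0.0])
        add_atom("O", "O", prot_resi, "ALA", "A", n_pos + [-0.30, 0.2, 0.0])
        add_atom("N", "N", prot_resi, "ALA", "A", n_pos)
        add_atom("H", "H", prot_resi, "ALA", "A", n_pos + [0.10, 0.0, 0.0])
        present = n_pos + [present_distance, 0.0, 0.0]
        broken = n_pos + [broken_distance, 0.0, 0.0]
        acc = add_atom("N3", "N", rna_resi, "U", "R", present)
        add_atom("C1'", "C", rna_resi, "U", "R", present + np.array([0.15, 0.1, 0.0]))
        add_atom("P", "P", rna_resi, "U", "R", present + np.array([0.3, -0.2, 0.1]))
        add_atom("OP1", "O", rna_resi, "U", "R", present + np.array([0.4, -0.3, 0.1]))
        acceptor_moves.append((acc, present, broken))
        truth.hbond_specs.append(
            HBondSpec(
                donor=("A", prot_resi, "N"),
                hydrogen=("A", prot_resi, "H"),
                acceptor=("R", rna_resi, "N3"),
                label=hb.label,
            )
        )

    # --- planted stacking pairs --------------------------------------------
    stack_ring_indices: list[tuple[list[int], list[int]]] = []
    for s, st in enumerate(plan.stacks):
        y = 3.0 * (len(plan.hbonds) + s)
        center_a = np.array([6.0, y, 0.0])
        prot_resi = 100 + s
        rna_resi = 60 + s
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
        ring_a_pts = _hexagon(center_a, e1, e2)
        names_a = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        idx_a = [
            add_atom(nm, "C", prot_resi, "PHE", "A", p)
            for nm, p in zip(names_a, ring_a_pts)
        ]
        theta = np.radians(st.angle)
        center_b = center_a + np.array([0.0, 0.0, st.distance])
        f1 = np.array([1.0, 0.0, 0.0])
        f2 = np.array([0.0, np.cos(theta), np.sin(theta)])
        ring_b_pts = _hexagon(center_b, f1, f2)
        names_b = ["N1", "C2", "N3", "C4", "C5", "C6"]
        elements_b = ["N", "C", "N", "C", "C", "C"]
        idx_b = [
            add_atom(nm, el, rna_resi, "A", "R", p)
            for nm, el, p in zip(names_b, elements_b, ring_b_pts)
        ]
        stack_ring_indices.append((idx_a, idx_b))
        truth.planted_stack_geometries[st.label] = (st.distance, st.angle)

    base = np.array(base_coords)

    # choose the present frames for each H-bond
    for hb, (acc, present, broken) in zip(plan.hbonds, acceptor_moves):
        k = int(round(hb.occupancy * n_frames))
        frames_present = np.sort(rng.permutation(n_frames)[:k])
        truth.hbond_present_frames[hb.label] = frames_present
        truth.planted_hbond_occupancies[hb.label] = k / n_frames

    frames = []
    for f in range(n_frames):
        coords = base.copy()
        for hb, (acc, present, broken) in zip(plan.hbonds, acceptor_moves):
            if f not in truth.hbond_present_frames[hb.label]:
                coords[acc] = broken
        R = _random_rotation(rng)
        t = rng.normal(scale=0.5, size=3)
        frames.append(Frame(coordinates=coords @ R.T + t, frame_index=f))

    ens = Ensemble(topology=topology, frames=frames, label=f"synthetic-complex-seed{seed}")
    for (idx_a, idx_b), st in zip(stack_ring_indices, plan.stacks):
        truth.stack_specs.append(
            StackSpec(
                ring_a=Selection(atom_indices=idx_a, expression=f"ring_a[{st.label}]"),
                ring_b=Selection(atom_indices=idx_b, expression=f"ring_b[{st.label}]"),
                label=st.label,
            )
        )
    return ens, truth


@dataclass
class DihedralPlan:
    """Per-residue plan for the dihedral generator."""

    mode: str = "fluctuation"  # or "two_state"
    sigma: float = 5.0  # wrapped-normal width, degrees
    minority_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fluctuation", "two_state"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "two_state" and not (0.0 < self.minority_fraction < 1.0):
            raise ValueError("minority fraction must lie in (0, 1)")


def _wrap(a: np.ndarray) -> np.ndarray:
    out = np.mod(a + 180.0, 360.0) - 180.0
    out[out == -180.0] = 180.0
    return out


def make_dihedral_fixture(
    n_frames: int,
    plan: dict[int, DihedralPlan],
    seed: int = 0,
    chain_id: str = "A",
) -> tuple[dict[int, tuple[DihedralSeries, DihedralSeries]], SyntheticTruth]:
    """Per-residue (φ, ψ) series with planted dynamics.

    ``fluctuation`` residues sample a wrapped normal around the α-helical
    mode; ``two_state`` residues spend exactly
    ``round(minority_fraction · n_frames)`` frames at the β mode (seeded
    placement) and the rest at α, with the same wrapped-normal jitter.
    """
    rng = np.random.default_rng(seed)
    series: dict[int, tuple[DihedralSeries, DihedralSeries]] = {}
    truth = SyntheticTruth()
    for resi, p in sorted(plan.items()):
        in_minority = np.zeros(n_frames, dtype=bool)
        if p.mode == "two_state":
            k = int(round(p.minority_fraction * n_frames))
            in_minority[rng.permutation(n_frames)[:k]] = True
            truth.planted_transition_fractions[resi] = k / n_frames
        else:
            truth.planted_transition_fractions[resi] = 0.0
        phi0 = np.where(in_minority, BETA_MODE[0], ALPHA_MODE[0])
        psi0 = np.where(in_minority, BETA_MODE[1], ALPHA_MODE[1])
        phi = _wrap(phi0 + rng.normal(scale=p.sigma, size=n_frames))
        psi = _wrap(psi0 + rng.normal(scale=p.sigma, size=n_frames))
        series[resi] = (
            DihedralSeries(chain_id=chain_id, residue_index=resi, angle_name="phi", values=phi),
            DihedralSeries(chain_id=chain_id, residue_index=resi, angle_name="psi", values=psi),
        )
    return series, truth


def make_work_samples(
    delta_g: float,
    sigma: float,
    n_f: int,
    n_r: int,
    temperature_k: float = 298.0,
    seed: int = 0,
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[WorkSet, SyntheticTruth]:
    """Gaussian bidirectional work samples obeying the Crooks relation.

    For a Gaussian work distribution of variance σ² the fluctuation theorem
    fixes the means: μ_F = ΔG + σ²/(2kT) and μ_R = −ΔG + σ²/(2kT) (the
    dissipated work σ²/(2kT) is the same in both directions).  σ = 0 gives
    the reversible limit where every forward work equals ΔG exactly.
    Units: kcal/mol.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_f < 2 or n_r < 2:
        raise ValueError("need at least 2 samples per direction")
    rng = np.random.default_rng(seed)
    kt = GAS_CONSTANT_KCAL * temperature_k
    dissipated = sigma**2 / (2.0 * kt)
    if sigma == 0.0:
        wf = np.full(n_f, delta_g)
        wr = np.full(n_r, -delta_g)
    else:
        wf = rng.normal(loc=delta_g + dissipated, scale=sigma, size=n_f)
        wr = rng.normal(loc=-delta_g + dissipated, scale=sigma, size=n_r)
    ws = WorkSet(
        forward=wf,
        reverse=wr,
        temperature_k=temperature_k,
        label_a=label_a,
        label_b=label_b,
    )
    truth = SyntheticTruth(planted_delta_g=delta_g)
    return ws, truth


def make_cluster_mixture(
    k: int,
    n_frames: int,
    separation: float,
    noise: float,
    seed: int = 0,
    n_residues: int = 8,
) -> tuple[Ensemble, SyntheticTruth]:
    """Frames drawn around *k* rigid conformers with recorded labels.

    Conformers are built as internal deformations of a common scaffold
    (rigid-body differences would vanish under superposition) and rescaled
    so that every pairwise superposed RMSD is at least ``separation``.
    Frames add isotropic Gaussian noise of width ``noise`` per coordinate.
    Raises when ``separation ≤ 4·noise`` (clusters unidentifiable).
    """
    if k < 1 or n_frames < k:
        raise ValueError("need n_frames >= k >= 1")
    if k > 1 and separation <= 4.0 * noise:
        raise ValueError("separation <= 4*noise: clusters are unidentifiable")
    rng = np.random.default_rng(seed)

    topology = []
    names = ["N", "CA", "C"]
    elements = ["N", "C", "C"]
    for resi in range(1, n_residues + 1):
        for nm, el in zip(names, elements):
            topology.append(
                AtomRecord(
                    atom_index=len(topology),
                    atom_name=nm,
                    element=el,
                    residue_index=resi,
                    residue_name="GLY",
                    chain_id="A",
                )
            )
    n_atoms = len(topology)
    scaffold = rng.normal(scale=0.8, size=(n_atoms, 3))

    conformers = [scaffold]
    if k > 1:
        offsets = []
        for _ in range(k - 1):
            d = rng.normal(size=(n_atoms, 3))
            d /= np.sqrt(np.mean(np.sum(d**2, axis=1)))  # unit RMS amplitude
            offsets.append(d)
        amp = separation
        for _ in range(4):  # rescale until all pairwise RMSDs clear the bar
            conformers = [scaffold] + [scaffold + amp * d for d in offsets]
            min_rmsd = np.inf
            whole = Selection(atom_indices=list(range(n_atoms)), expression="all")
            for a in range(k):
                for b in range(a + 1, k):
                    r = kabsch_superpose(
                        Frame(coordinates=conformers[a]),
                        Frame(coordinates=conformers[b]),
                        whole,
                    ).rmsd
                    min_rmsd = min(min_rmsd, r)
            if min_rmsd >= separation:
                break
            amp *= 1.5 * separation / max(min_rmsd, 1e-9)

    labels = np.array([i % k for i in range(n_frames)])
    rng.shuffle(labels)
    frames = []
    for f in range(n_frames):
        coords = conformers[labels[f]] + rng.normal(scale=noise, size=(n_atoms, 3))
        frames.append(Frame(coordinates=coords, frame_index=f))
    ens = Ensemble(topology=topology, frames=frames, label=f"synthetic-mixture-k{k}")
    truth = SyntheticTruth(
        planted_cluster_assignment=labels,
        cluster_conformers=np.stack(conformers),
    )
    return ens, truth


def make_noe_fixture(
    ens: Ensemble,
    n_satisfied: int,
    n_violated: int,
    margin: float,
    seed: int = 0,
) -> tuple[list[NOERestraint], SyntheticTruth]:
    """NOE restraints whose satisfaction status is planted by construction.

    For seeded random atom pairs the ensemble-effective distance ⟨r⟩ is
    back-calculated, then the bound is set to ⟨r⟩ + margin (satisfied) or
    ⟨r⟩ − margin (violated, by exactly ``margin``).
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if ens.n_frames < 1:
        raise ValueError("ensemble has no frames")
    rng = np.random.default_rng(seed)
    n_total = n_satisfied + n_violated
    chains = {r.chain_id for r in ens.topology}

    def category(a1: AtomRecord, a2: AtomRecord) -> str:
        if a1.chain_id != a2.chain_id:
            return "intermolecular"
        return "intra_rna" if a1.chain_id == "R" else "intra_protein"

    restraints: list[NOERestraint] = []
    truth_flags: list[bool] = []
    attempts = 0
    while len(restraints) < n_total and attempts < 100 * n_total:
        attempts += 1
        i, j = rng.choice(ens.n_atoms, size=2, replace=False)
        a1, a2 = ens.topology[int(i)], ens.topology[int(j)]
        if (a1.chain_id, a1.residue_index, a1.atom_name) == (
            a2.chain_id,
            a2.residue_index,
            a2.atom_name,
        ):
            continue
        want_violated = len(restraints) >= n_satisfied
        probe = NOERestraint(
            group1=((a1.chain_id, a1.residue_index, a1.atom_name),),
            group2=((a2.chain_id, a2.residue_index, a2.atom_name),),
            r_noe=1.0,
            category=category(a1, a2),
        )
        r_avg = backcalc_noe(ens, probe)
        bound = r_avg - margin if want_violated else r_avg + margin
        if bound <= 0:
            continue
        restraints.append(
            NOERestraint(
                group1=probe.group1,
                group2=probe.group2,
                r_noe=bound,
                category=probe.category,
            )
        )
        truth_flags.append(want_violated)
    if len(restraints) < n_total:
        raise RuntimeError("could not construct the requested restraints")
    truth = SyntheticTruth(planted_noe_violations=truth_flags)
    return restraints, truth
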