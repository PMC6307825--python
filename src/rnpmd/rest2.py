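"""Planning utilities for replica exchange with solute tempering (REST2).

In REST2 the solute–solute potential terms of replica *i* are scaled by a
factor λ_i, solute–solvent terms by λ_i^1/2 and solvent–solvent terms are
left unscaled, so only the solute is effectively heated (T_eff = T/λ).
Two planning tasks are covered:

* a geometric λ ladder between the reference replica (λ = 1) and a chosen
  λ_min, λ_i = λ_min^(i/(n−1)),
* selection of the partial-scaling (PS) region: the mutated nucleotides,
  their flanking phosphate groups and every protein residue with a heavy
  atom within a cutoff of the nucleotides' heavy atoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import Ensemble, Selection

__all__ = [
    "LambdaLadder",
    "ScalingRegion",
    "geometric_ladder",
    "partial_scaling_region",
]

PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O1P", "O2P"}


@dataclass
class LambdaLadder:
    """Strictly decreasing λ values, λ₀ = 1 down to λ_min."""

    lambdas: np.ndarray
    lambda_min: float

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)

    @property
    def n_replicas(self) -> int:
        return len(self.lambdas)

    def effective_temperatures(self, temperature_k: float = 298.0) -> np.ndarray:
        """T_eff = T/λ per replica (informational)."""
        return temperature_k / self.lambdas

    def to_json(self) -> dict:
        return {
            "lambdas": self.lambdas.tolist(),
            "n_replicas": self.n_replicas,
            "lambda_min": self.lambda_min,
        }


def geometric_ladder(n: int, lambda_min: float) -> LambdaLadder:
    """Geometric λ ladder: λ_i = λ_min^(i/(n−1)), i = 0..n−1.

    The ratio λ_{i+1}/λ_i is constant, endpoints are exactly 1 and
    ``lambda_min``.
    """
    if n < 2:
        raise ValueError("need at least 2 replicas")
    if not (0.0 < lambda_min < 1.0):
        raise ValueError("lambda_min must lie in (0, 1)")
    i = np.arange(n)
    lambdas = lambda_min ** (i / (n - 1))
    lambdas[0] = 1.0
    lambdas[-1] = lambda_min
    return LambdaLadder(lambdas=lambdas, lambda_min=lambda_min)


@dataclass
class ScalingRegion:
    """Atom classes of a partial-scaling REST2 setup."""

    scaled: Selection  # solute region scaled by λ
    scaled_residues: list[tuple[str, int, str]] = field(default_factory=list)
    cutoff: float = 0.5
    interaction_classes: dict = field(
        default_factory=lambda: {
            "lambda": "scaled-region – scaled-region",
            "sqrt_lambda": "scaled-region – environment",
            "unscaled": "environment – environment",
        }
    )

    def report(self) -> str:
        lines = [
            f"Partial-scaling region ({len(self.scaled)} atoms, cutoff {self.cutoff} nm)",
            "residues:",
        ]
        for chain, resi, name in self.scaled_residues:
            lines.append(f"  {chain} {resi} {name}")
        lines.append("interaction scaling: " + json.dumps(self.interaction_classes))
        return "\n".join(lines)


def partial_scaling_region(
    ens: Ensemble,
    rna_chain: str,
    mutated_nucleotides: list[int],
    cutoff: float = 0.5,
    flanking: str = "both",
    reference_frame: int = 0,
) -> ScalingRegion:
    """Atoms to temper in a partial-scaling REST2 run.

    The region is the mutated nucleotides, their flanking phosphate groups
    (5′ side = the nucleotide's own phosphate, 3′ side = the next residue's;
    ``flanking`` ∈ {"both", "5prime", "3prime", "none"}) and every whole
    protein residue having at least one heavy atom within ``cutoff`` of a
    heavy atom of those nucleotides in the reference frame.
    """
    if flanking not in ("both", "5prime", "3prime", "none"):
        raise ValueError(f"unknown flanking mode {flanking!r}")
    nucleotides = set(mutated_nucleotides)
    coords = ens.frames[reference_frame].coordinates

    nuc_idx = [
        r.atom_index
        for r in ens.topology
        if r.chain_id == rna_chain and r.residue_index in nucleotides
    ]
    if not nuc_idx:
        raise ValueError("mutated nucleotides not found in topology")
    nuc_heavy = [i for i in nuc_idx if ens.topology[i].element.upper() != "H"]

    phosphate_idx = []
    phos_residues = set()
    if flanking in ("both", "5prime"):
        phos_residues |= nucleotides
    if flanking in ("both", "3prime"):
        phos_residues |= {r + 1 for r in nucleotides}
    for r in ens.topology:
        if (
            r.chain_id == rna_chain
            and r.residue_index in phos_residues
            and r.atom_name in PHOSPHATE_ATOMS
        ):
            phosphate_idx.append(r.atom_index)

    shell: set[tuple[str, int]] = set()
    for r in ens.topology:
        if r.chain_id == rna_chain or r.element.upper() == "H":
            continue
        d = np.linalg.norm(coords[nuc_heavy] - coords[r.atom_index], axis=1)
        if d.min() <= cutoff:
            shell.add((r.chain_id, r.residue_index))
    if not shell:
        import warnings

        warnings.warn("no protein residues within the cutoff of the nucleotides")

    indices = set(nuc_idx) | set(phosphate_idx)
    residue_list: list[tuple[str, int, str]] = []
    seen_res: set[tuple[str, int]] = set()
    for r in ens.topology:
        if (r.chain_id, r.residue_index) in shell:
            indices.add(r.atom_index)
        if r.atom_index in indices and (r.chain_id, r.residue_index) not in seen_res:
            seen_res.add((r.chain_id, r.residue_index))
            residue_list.append((r.chain_id, r.residue_index, r.residue_name))

    sel = Selection(
        atom_indices=sorted(indices),
        expression=f"partial-scaling(nucleotides {sorted(nucleotides)}, cutoff {cutoff} nm)",
    )
    return ScalingRegion(scaled=sel, scaled_residues=residue_list, cutoff=cutoff)
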