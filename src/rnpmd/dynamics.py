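"""Backbone plasticity (PAD-style angular dispersion with F/t/T tags) and
dihedral-histogram conformational entropy.

The per-residue plasticity descriptor is the circular standard deviation of
ω = φ + ψ (the sum of the Ramachandran angles).  Residues are additionally
tagged by how they move between Ramachandran regions:

* ``F`` — fluctuations only: all non-modal regions below a noise floor,
* ``T`` — long transitions: minority regions occupy ≥ 30% of the frames,
* ``t`` — short transitions: minority occupancy between the noise floor
  and 30%.

Conformational entropy is the first-order dihedral-histogram estimate
S = −R Σ_bins p ln p per torsion, summed over a residue's torsions; it is a
qualitative comparator, not an absolute entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DihedralSeries

__all__ = [
    "GAS_CONSTANT_KCAL",
    "RamachandranRegionMap",
    "DEFAULT_REGIONS",
    "PADResult",
    "pad_dispersion",
    "tag_transitions",
    "dihedral_entropy",
    "entropy_difference",
]

#: gas constant, kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.9872e-3


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Fold angles into (−180, 180]."""
    out = np.mod(np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0
    out[out == -180.0] = 180.0
    return out


@dataclass
class RamachandranRegionMap:
    """Named axis-aligned rectangles on the (φ, ψ) torus plus an implicit
    ``other`` catch-all.  Rectangles are checked in order; intervals are
    half-open (lo, hi]."""

    regions: list[tuple[str, tuple[float, float], tuple[float, float]]]

    def assign(self, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
        phi = _wrap_deg(phi)
        psi = _wrap_deg(psi)
        labels = np.full(len(phi), "other", dtype=object)
        unassigned = np.ones(len(phi), dtype=bool)
        for name, (plo, phi_hi), (slo, shi) in self.regions:
            hit = (
                unassigned
                & (phi > plo)
                & (phi <= phi_hi)
                & (psi > slo)
                & (psi <= shi)
            )
            labels[hit] = name
            unassigned &= ~hit
        return labels

    @classmethod
    def from_json(cls, obj: list) -> "RamachandranRegionMap":
        return cls(
            regions=[
                (str(name), (float(p[0]), float(p[1])), (float(s[0]), float(s[1])))
                for name, p, s in obj
            ]
        )


#: broad α / β / left-handed-α rectangles; everything else is "other"
DEFAULT_REGIONS = RamachandranRegionMap(
    regions=[
        ("alpha", (-160.0, -20.0), (-120.0, 50.0)),
        ("beta", (-180.0, -20.0), (50.0, 180.0)),
        ("beta", (-180.0, -20.0), (-180.0, -120.0)),
        ("Lalpha", (20.0, 160.0), (-50.0, 120.0)),
    ]
)


@dataclass
class PADResult:
    chain_id: str
    residue_index: int
    dispersion_deg: float
    tag: str  # F, t, T
    minority_fraction: float
    region_occupancy: dict[str, float] = field(default_factory=dict)


def pad_dispersion(series_phi: DihedralSeries, series_psi: DihedralSeries) -> float:
    """Circular standard deviation (degrees) of ω = φ + ψ.

    Uses the circular-variance definition sqrt(−2 ln R̄) where R̄ is the
    mean resultant length of the unit vectors e^{iω}.
    """
    if len(series_phi) != len(series_psi):
        raise ValueError("phi and psi series have different lengths")
    if len(series_phi) < 2:
        raise ValueError("need at least 2 frames")
    omega = np.radians(_wrap_deg(series_phi.values + series_psi.values))
    rbar = float(np.abs(np.mean(np.exp(1j * omega))))
    if rbar <= 0.0:
        rbar = np.finfo(float).tiny
    return float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(rbar)))))


def tag_transitions(
    series_phi: DihedralSeries,
    series_psi: DihedralSeries,
    regions: RamachandranRegionMap = DEFAULT_REGIONS,
    minority_threshold: float = 0.30,
    noise_floor: float = 0.01,
) -> PADResult:
    """Classify a residue as fluctuating (F) or transitioning (t/T).

    Each frame is assigned a Ramachandran region; the modal region is the
    most occupied one and all other occupancy is pooled as "minority".
    Minority occupancy ≥ ``minority_threshold`` gives T, occupancy above
    ``noise_floor`` but below the threshold gives t, otherwise F.
    """
    if not regions.regions:
        raise ValueError("empty region map")
    labels = regions.assign(series_phi.values, series_psi.values)
    names, counts = np.unique(labels, return_counts=True)
    occ = {str(n): c / len(labels) for n, c in zip(names, counts)}
    modal = max(occ, key=lambda n: occ[n])
    minority = 1.0 - occ[modal]
    if all(v <= noise_floor for n, v in occ.items() if n != modal):
        tag = "F"
    elif minority >= minority_threshold:
        tag = "T"
    else:
        tag = "t"
    return PADResult(
        chain_id=series_phi.chain_id,
        residue_index=series_phi.residue_index,
        dispersion_deg=pad_dispersion(series_phi, series_psi),
        tag=tag,
        minority_fraction=minority,
        region_occupancy=occ,
    )


def _histogram_probs(values: np.ndarray, bin_width: float) -> np.ndarray:
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    n_bins = int(round(n_bins))
    v = _wrap_deg(values)
    # right-closed bins on (-180, 180]: shift so bin k covers (-180 + k*w, -180 + (k+1)*w]
    idx = np.ceil((v + 180.0) / bin_width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts / counts.sum()


def dihedral_entropy(
    series_set: list[DihedralSeries], bin_width: float = 10.0
) -> float:
    """First-order histogram entropy of one residue, kcal mol⁻¹ K⁻¹.

    S = −R Σ_bins p ln p per torsion, summed over the given (φ, ψ, χ_n)
    series as independent terms; empty bins contribute zero.
    """
    if not series_set:
        raise ValueError("need at least one angle series")
    s = 0.0
    for series in series_set:
        p = _histogram_probs(series.values, bin_width)
        nz = p[p > 0]
        s += -GAS_CONSTANT_KCAL * float(np.sum(nz * np.log(nz)))
    return s


def entropy_difference(
    state_a: list[DihedralSeries],
    state_b: list[DihedralSeries],
    temperature_k: float = 298.0,
    bin_width: float = 10.0,
    n_boot: int = 200,
    n_blocks: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """TΔS = T·(S_a − S_b) in kcal/mol with a block-bootstrap uncertainty.

    Both states must carry the same torsion inventory for the residue.
    Blocks are contiguous 1/``n_blocks`` stretches of frames, resampled
    with replacement to respect time correlation.
    """
    inv_a = [(s.chain_id, s.residue_index, s.angle_name) for s in state_a]
    inv_b = [(s.chain_id, s.residue_index, s.angle_name) for s in state_b]
    if inv_a != inv_b:
        raise ValueError("angle inventories of the two states differ")

    tds = temperature_k * (
        dihedral_entropy(state_a, bin_width) - dihedral_entropy(state_b, bin_width)
    )

    rng = np.random.default_rng(seed)

    def _boot_entropy(series_list: list[DihedralSeries]) -> float:
        out = 0.0
        for s in series_list:
            n = len(s.values)
            edges = np.linspace(0, n, n_blocks + 1).astype(int)
            blocks = [s.values[edges[i] : edges[i + 1]] for i in range(n_blocks)]
            pick = rng.integers(0, n_blocks, size=n_blocks)
            resampled = np.concatenate([blocks[j] for j in pick])
            p = _histogram_probs(resampled, bin_width)
            nz = p[p > 0]
            out += -GAS_CONSTANT_KCAL * float(np.sum(nz * np.log(nz)))
        return out

    reps = np.array(
        [
            temperature_k * (_boot_entropy(state_a) - _boot_entropy(state_b))
            for _ in range(n_boot)
        ]
    )
    return float(tds), float(reps.std(ddof=1))
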