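"""NOE back-calculation and restraint-violation analysis.

The effective ensemble distance for an NOE restraint is the r⁻⁶ average

    ⟨r⟩ = ( (1/N_f) Σ_frames r⁻⁶ )^(−1/6)

reflecting the distance dependence of NOE cross-relaxation.  For restraints
between atom groups (pseudo-atoms such as methyl protons) the per-frame
distance is itself the r⁻⁶-summed effective distance over all cross pairs,
r_eff = (Σ_{a∈g1, b∈g2} r_ab⁻⁶)^(−1/6); a minimum-distance alternative is
available via ``group_mode="min"``.

The module also selects an "MD-adapted structure ensemble": the fraction of
frames that best satisfy the NOE bounds, clustered, with one representative
(medoid) frame per cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Ensemble, Frame, Selection

__all__ = [
    "NOERestraint",
    "NOEReport",
    "parse_atom_group",
    "format_atom_group",
    "backcalc_noe",
    "violation_report",
    "per_frame_violation_count",
    "select_md_adapted_ensemble",
]

AtomGroup = tuple[tuple[str, int, str], ...]  # ((chain, residue, atom_name), ...)


def parse_atom_group(text: str) -> AtomGroup:
    """Parse ``chain:resi:name`` specs joined by ``+`` into an atom group."""
    members = []
    for part in text.split("+"):
        fields = part.split(":")
        if len(fields) != 3:
            raise ValueError(f"bad atom spec {part!r}; expected chain:resi:name")
        chain, resi, name = fields
        members.append((chain, int(resi), name))
    return tuple(members)


def format_atom_group(group: AtomGroup) -> str:
    return "+".join(f"{c}:{r}:{n}" for c, r, n in group)


@dataclass
class NOERestraint:
    """An upper-bound distance restraint between two atom groups."""

    group1: AtomGroup
    group2: AtomGroup
    r_noe: float  # upper bound, nm
    category: str = "intermolecular"

    def __post_init__(self) -> None:
        if self.r_noe <= 0:
            raise ValueError("NOE upper bound must be positive")
        if not self.group1 or not self.group2:
            raise ValueError("restraint groups must be non-empty")
        if set(self.group1) & set(self.group2):
            raise ValueError("restraint groups must be disjoint")

    def resolve(self, topology) -> tuple[np.ndarray, np.ndarray]:
        """Resolve both groups to 0-based atom indices of *topology*."""
        lookup = {
            (r.chain_id, r.residue_index, r.atom_name): r.atom_index
            for r in topology
        }
        try:
            i1 = np.array([lookup[m] for m in self.group1], dtype=int)
            i2 = np.array([lookup[m] for m in self.group2], dtype=int)
        except KeyError as exc:
            raise KeyError(f"restraint atom {exc.args[0]} not in topology") from None
        return i1, i2


def _per_frame_r6_sum(coords: np.ndarray, i1: np.ndarray, i2: np.ndarray) -> np.ndarray:
    """Σ_{a,b} r_ab⁻⁶ per frame; coords shape (n_frames, n_atoms, 3)."""
    diff = coords[:, i1, None, :] - coords[:, None, i2, :]
    r2 = np.sum(diff * diff, axis=-1)
    return np.sum(r2 ** -3.0, axis=(1, 2))


def _per_frame_effective(coords, i1, i2, group_mode: str) -> np.ndarray:
    if group_mode == "r6":
        return _per_frame_r6_sum(coords, i1, i2) ** (-1.0 / 6.0)
    if group_mode == "min":
        diff = coords[:, i1, None, :] - coords[:, None, i2, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        return r.min(axis=(1, 2))
    raise ValueError(f"unknown group_mode {group_mode!r}")


def backcalc_noe(
    ens: Ensemble, restraint: NOERestraint, group_mode: str = "r6"
) -> float:
    """Ensemble-effective NOE distance ⟨r⟩ (nm) for one restraint."""
    i1, i2 = restraint.resolve(ens.topology)
    r_eff = _per_frame_effective(ens.coordinate_array(), i1, i2, group_mode)
    return float(np.mean(r_eff ** -6.0) ** (-1.0 / 6.0))


@dataclass
class NOEReport:
    """Per-restraint violation table plus the headline summary numbers."""

    table: pd.DataFrame  # one row per restraint
    satisfied_fraction: dict[str, float]  # per category + "all"
    n_violations_gt_005: int
    n_violations_gt_03: int
    mean_violation_over_violated: float
    mean_violation_over_all: float
    tolerance: float = 0.0

    def to_tsv(self, path: str) -> str:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")
        return path

    def summary(self) -> dict:
        return {
            "satisfied_fraction": self.satisfied_fraction,
            "n_violations_gt_0.05nm": self.n_violations_gt_005,
            "n_violations_gt_0.3nm": self.n_violations_gt_03,
            "mean_violation_over_violated_nm": self.mean_violation_over_violated,
            "mean_violation_over_all_nm": self.mean_violation_over_all,
            "tolerance_nm": self.tolerance,
        }

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        return path


def violation_report(
    ens: Ensemble,
    restraints: list[NOERestraint],
    tolerance: float = 0.0,
    group_mode: str = "r6",
) -> NOEReport:
    """Score all restraints against the ensemble.

    A restraint is violated iff ⟨r⟩ exceeds its upper bound (plus the
    optional tolerance).  The average violation is emitted both over the
    violated restraints and over all restraints; both are magnitudes
    (⟨r⟩ − r_NOE ≥ 0 on violated restraints).
    """
    if not restraints:
        raise ValueError("restraint list is empty")
    rows = []
    for r in restraints:
        r_avg = backcalc_noe(ens, r, group_mode=group_mode)
        violated = r_avg > r.r_noe + tolerance
        mag = (r_avg - r.r_noe) if violated else 0.0
        rows.append(
            {
                "group1": format_atom_group(r.group1),
                "group2": format_atom_group(r.group2),
                "category": r.category,
                "r_noe_nm": r.r_noe,
                "r_avg_nm": r_avg,
                "violated": violated,
                "violation_nm": mag,
            }
        )
    table = pd.DataFrame(rows)
    sat = {"all": float((~table["violated"]).mean())}
    for cat, sub in table.groupby("category"):
        sat[str(cat)] = float((~sub["violated"]).mean())
    viol = table.loc[table["violated"], "violation_nm"]
    return NOEReport(
        table=table,
        satisfied_fraction=sat,
        n_violations_gt_005=int((table["violation_nm"] > 0.05).sum()),
        n_violations_gt_03=int((table["violation_nm"] > 0.3).sum()),
        mean_violation_over_violated=float(viol.mean()) if len(viol) else 0.0,
        mean_violation_over_all=float(table["violation_nm"].sum() / len(table)),
        tolerance=tolerance,
    )


def per_frame_violation_count(
    topology,
    frame: Frame,
    restraints: list[NOERestraint],
    tolerance: float = 0.0,
    group_mode: str = "r6",
) -> int:
    """Number of restraints whose single-frame effective distance exceeds
    the bound (the N_f = 1 reduction of the ensemble average)."""
    coords = frame.coordinates[None]
    count = 0
    for r in restraints:
        i1, i2 = r.resolve(topology)
        r_eff = float(_per_frame_effective(coords, i1, i2, group_mode)[0])
        if r_eff > r.r_noe + tolerance:
            count += 1
    return count


@dataclass
class MDAdaptedEnsemble:
    """Representative frames best agreeing with the NOE data."""

    ensemble: Ensemble  # centroid frames, ordered by cluster population
    retained_frame_indices: list[int]
    centroid_frame_indices: list[int]  # indices into the original ensemble
    cluster_populations: list[float]
    labels: np.ndarray = field(repr=False)  # per retained frame


def select_md_adapted_ensemble(
    ens: Ensemble,
    restraints: list[NOERestraint],
    frame_fraction: float = 0.10,
    k: int = 20,
    seed: int = 0,
    group_mode: str = "r6",
) -> MDAdaptedEnsemble:
    """Build the MD-adapted structure ensemble.

    Retains the best ``frame_fraction`` of frames by per-frame NOE violation
    count (ties broken by total violation magnitude, then frame order),
    clusters them by k-means on whole-complex superposed coordinates and
    returns the per-cluster medoid frames ordered by cluster population.
    """
    from .cluster import centroid_frame, kmeans_conformers

    n_keep = max(1, int(round(frame_fraction * ens.n_frames)))
    if k > n_keep:
        raise ValueError(f"k={k} exceeds the {n_keep} retained frames")

    coords = ens.coordinate_array()
    keys = []
    for f, frame in enumerate(ens.frames):
        count = 0
        total_mag = 0.0
        for r in restraints:
            i1, i2 = r.resolve(ens.topology)
            r_eff = float(_per_frame_effective(coords[f : f + 1], i1, i2, group_mode)[0])
            if r_eff > r.r_noe:
                count += 1
                total_mag += r_eff - r.r_noe
        keys.append((count, total_mag, f))
    keys.sort()
    retained = [f for _, _, f in keys[:n_keep]]
    retained.sort()  # keep chronological order inside the retained set

    sub = Ensemble(
        topology=ens.topology,
        frames=[
            Frame(coordinates=ens.frames[f].coordinates.copy(), frame_index=i)
            for i, f in enumerate(retained)
        ],
        label=f"{ens.label}|noe-best-{frame_fraction:g}",
    )
    whole = Selection(atom_indices=list(range(ens.n_atoms)), expression="all")
    result = kmeans_conformers(sub, whole, k=k, seed=seed)

    order = np.argsort(result.populations)[::-1]
    centroid_orig = []
    populations = []
    cent_frames = []
    for rank, c in enumerate(order):
        local = result.centroid_frame_indices[c]
        centroid_orig.append(retained[local])
        populations.append(float(result.populations[c]))
        cent_frames.append(
            Frame(coordinates=sub.frames[local].coordinates.copy(), frame_index=rank)
        )
    out = Ensemble(
        topology=ens.topology,
        frames=cent_frames,
        label=f"{ens.label}|md-adapted-k{k}",
    )
    return MDAdaptedEnsemble(
        ensemble=out,
        retained_frame_indices=retained,
        centroid_frame_indices=centroid_orig,
        cluster_populations=populations,
        labels=result.labels,
    )
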