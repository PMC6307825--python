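"""Hydrogen-bond and aromatic-stacking occupancy analysis.

Criteria: an H-bond is present when the donor–acceptor heavy-atom distance
is ≤ 0.35 nm and the donor–H–acceptor angle at the intervening hydrogen is
≥ 135°.  A stacking interaction is present when the ring centres are closer
than 0.5 nm and the angle between the two ring planes is below 30°.

Occupancy is reported per trajectory (percentage of frames in which the
interaction is observed); distance/angle statistics are pooled over the
present frames of all trajectories, as interface tables are conventionally
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import angle as _angle
from .geometry import distance as _distance
from .geometry import plane_angle, ring_plane_normal
from .io import Ensemble, Frame, Selection

__all__ = [
    "HBondSpec",
    "StackSpec",
    "OccupancyTable",
    "hbond_present",
    "stack_present",
    "hbond_geometry",
    "stack_geometry",
    "occupancy_table",
]

AtomSpec = tuple[str, int, str]  # (chain, residue, atom_name)


def _resolve(topology, spec: AtomSpec) -> int:
    for r in topology:
        if (r.chain_id, r.residue_index, r.atom_name) == spec:
            return r.atom_index
    raise KeyError(f"atom {spec} not found in topology")


@dataclass
class HBondSpec:
    """A candidate hydrogen bond: donor heavy atom, its hydrogen, acceptor."""

    donor: AtomSpec
    hydrogen: AtomSpec
    acceptor: AtomSpec
    label: str = ""

    def __post_init__(self) -> None:
        if len({self.donor, self.hydrogen, self.acceptor}) != 3:
            raise ValueError("donor, hydrogen and acceptor must be distinct atoms")
        if self.donor[:2] != self.hydrogen[:2]:
            raise ValueError("hydrogen must belong to the donor residue")

    def resolve(self, topology) -> tuple[int, int, int]:
        return (
            _resolve(topology, self.donor),
            _resolve(topology, self.hydrogen),
            _resolve(topology, self.acceptor),
        )


@dataclass
class StackSpec:
    """A candidate stacking pair of two aromatic rings."""

    ring_a: Selection
    ring_b: Selection
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.ring_a) < 5 or len(self.ring_b) < 5:
            raise ValueError("each ring needs at least 5 atoms")


def hbond_geometry(
    topology, frame: Frame, spec: HBondSpec
) -> tuple[float, float]:
    """(heavy–heavy distance nm, donor–H–acceptor angle degrees)."""
    d, h, a = spec.resolve(topology)
    if not np.any(np.isfinite(frame.coordinates[h])):
        raise ValueError(f"hydrogen {spec.hydrogen} has no coordinates")
    return _distance(frame, d, a), _angle(frame, d, h, a)


def hbond_present(
    topology,
    frame: Frame,
    spec: HBondSpec,
    d_cut: float = 0.35,
    a_cut: float = 135.0,
) -> bool:
    """H-bond criterion: d(donor, acceptor) ≤ d_cut and ∠D–H–A ≥ a_cut."""
    d, ang = hbond_geometry(topology, frame, spec)
    return d <= d_cut and ang >= a_cut


def _ring_center(frame: Frame, ring: Selection, topology, mass_weighted: bool):
    pts = frame.coordinates[ring.as_array()]
    if not mass_weighted:
        return pts.mean(axis=0)
    masses = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}
    w = np.array(
        [masses.get(topology[i].element.upper(), 12.0) for i in ring.atom_indices]
    )
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def stack_geometry(
    topology,
    frame: Frame,
    spec: StackSpec,
    mass_weighted: bool = False,
) -> tuple[float, float]:
    """(ring-centre distance nm, folded inter-plane angle degrees)."""
    ca = _ring_center(frame, spec.ring_a, topology, mass_weighted)
    cb = _ring_center(frame, spec.ring_b, topology, mass_weighted)
    na = ring_plane_normal(frame, spec.ring_a)
    nb = ring_plane_normal(frame, spec.ring_b)
    return float(np.linalg.norm(ca - cb)), plane_angle(na, nb)


def stack_present(
    topology,
    frame: Frame,
    spec: StackSpec,
    d_cut: float = 0.5,
    theta_cut: float = 30.0,
    mass_weighted: bool = False,
) -> bool:
    """Stacking criterion: centre distance < d_cut and plane angle < theta_cut."""
    d, theta = stack_geometry(topology, frame, spec, mass_weighted)
    return d < d_cut and theta < theta_cut


@dataclass
class OccupancyTable:
    """Interface-interaction table: geometry statistics and per-trajectory
    occupancies (percent)."""

    table: pd.DataFrame
    trajectory_labels: list[str]

    def to_tsv(self, path: str) -> str:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")
        return path


def occupancy_table(
    ensembles: list[Ensemble],
    hbonds: list[HBondSpec] | None = None,
    stacks: list[StackSpec] | None = None,
    d_cut_hb: float = 0.35,
    a_cut_hb: float = 135.0,
    d_cut_stack: float = 0.5,
    theta_cut_stack: float = 30.0,
    mass_weighted: bool = False,
) -> OccupancyTable:
    """Per-trajectory occupancies plus pooled present-frame geometry stats.

    Occupancy is never pooled across trajectories: each ensemble gets its
    own column, 100 · (present frames) / (total frames).  Distance/angle
    mean ± sd are computed over the union of present frames.
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    hbonds = hbonds or []
    stacks = stacks or []
    topology = ensembles[0].topology
    labels = [e.label or f"traj{i+1}" for i, e in enumerate(ensembles)]

    rows = []
    specs = [("hbond", s) for s in hbonds] + [("stack", s) for s in stacks]
    for kind, spec in specs:
        dists: list[float] = []
        angs: list[float] = []
        occs = []
        for ens in ensembles:
            present = 0
            for frame in ens.frames:
                if kind == "hbond":
                    d, a = hbond_geometry(ens.topology, frame, spec)
                    ok = d <= d_cut_hb and a >= a_cut_hb
                else:
                    d, a = stack_geometry(ens.topology, frame, spec, mass_weighted)
                    ok = d < d_cut_stack and a < theta_cut_stack
                if ok:
                    present += 1
                    dists.append(d)
                    angs.append(a)
            occs.append(100.0 * present / ens.n_frames)
        row = {
            "label": spec.label or kind,
            "type": kind,
            "mean_distance_nm": float(np.mean(dists)) if dists else np.nan,
            "sd_distance_nm": float(np.std(dists, ddof=0)) if dists else np.nan,
            "mean_angle_deg": float(np.mean(angs)) if angs else np.nan,
            "sd_angle_deg": float(np.std(angs, ddof=0)) if angs else np.nan,
        }
        for lab, occ in zip(labels, occs):
            row[f"occupancy_{lab}_pct"] = occ
        rows.append(row)
    return OccupancyTable(table=pd.DataFrame(rows), trajectory_labels=labels)
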