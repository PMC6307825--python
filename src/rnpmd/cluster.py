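"""Conformational clustering of ensembles.

Frames are superposed onto the first frame on the chosen selection and
clustered by k-means in flattened coordinate space — the standard practical
approximation to RMSD-metric clustering (true pairwise RMSD is not a
vector-space metric).  Cluster representatives are medoids: the member with
the lowest cumulative pairwise superposed RMSD to all other members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose, superposed_rmsd
from .io import Ensemble, Frame, Selection

__all__ = [
    "ClusterResult",
    "interface_selection",
    "kmeans_conformers",
    "centroid_frame",
]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-frame cluster label in [0, k)
    populations: np.ndarray  # per-cluster fraction, sums to 1
    centroid_frame_indices: list[int]  # medoid frame per cluster
    inertia: float

    @property
    def k(self) -> int:
        return len(self.populations)

    def split_by_source(self, sources: np.ndarray) -> dict:
        """Per-source cluster populations for a concatenated ensemble
        (parsing a combined clustering back into individual runs)."""
        out = {}
        for src in np.unique(sources):
            sub = self.labels[sources == src]
            out[src] = np.array(
                [np.mean(sub == c) for c in range(self.k)]
            )
        return out


def interface_selection(
    ens: Ensemble,
    rna_chain: str,
    rna_residues: range | list[int],
    cutoff: float = 0.45,
    reference_frame: int = 0,
) -> Selection:
    """Interface atoms: all atoms of the named nucleotides plus all atoms of
    every other-chain residue with at least one heavy atom within ``cutoff``
    of any nucleotide heavy atom, measured in the reference frame."""
    residues = set(rna_residues)
    coords = ens.frames[reference_frame].coordinates
    nuc_idx = [
        r.atom_index
        for r in ens.topology
        if r.chain_id == rna_chain and r.residue_index in residues
    ]
    if not nuc_idx:
        raise ValueError("no atoms match the requested nucleotides")
    nuc_heavy = [i for i in nuc_idx if ens.topology[i].element.upper() != "H"]

    shell_residues: set[tuple[str, int]] = set()
    for r in ens.topology:
        if r.chain_id == rna_chain or r.element.upper() == "H":
            continue
        d = np.linalg.norm(coords[nuc_heavy] - coords[r.atom_index], axis=1)
        if d.min() <= cutoff:
            shell_residues.add((r.chain_id, r.residue_index))

    indices = [
        r.atom_index
        for r in ens.topology
        if (r.chain_id == rna_chain and r.residue_index in residues)
        or (r.chain_id, r.residue_index) in shell_residues
    ]
    expr = f"interface(chain {rna_chain} resi {min(residues)}-{max(residues)}, cutoff {cutoff} nm)"
    return Selection(atom_indices=sorted(indices), expression=expr)


def _superposed_coords(ens: Ensemble, on: Selection) -> np.ndarray:
    """Selection coordinates of every frame after fitting onto frame 0."""
    ref = ens.frames[0]
    idx = on.as_array()
    out = np.empty((ens.n_frames, len(idx), 3))
    out[0] = ref.coordinates[idx]
    for f in range(1, ens.n_frames):
        fit = kabsch_superpose(ens.frames[f], ref, on)
        out[f] = fit.transform(ens.frames[f].coordinates[idx])
    return out


def kmeans_conformers(
    ens: Ensemble, on: Selection, k: int, seed: int = 0
) -> ClusterResult:
    """Seeded k-means clustering of superposed interface coordinates."""
    from sklearn.cluster import KMeans

    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ens.n_frames:
        raise ValueError("k exceeds the number of frames")
    if len(on) == 0:
        raise ValueError("empty selection")

    X = _superposed_coords(ens, on).reshape(ens.n_frames, -1)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        max_iter=500,
        tol=1e-8,
        random_state=seed,
    ).fit(X)
    labels = km.labels_.astype(int)
    populations = np.array([np.mean(labels == c) for c in range(k)])
    centroids = [
        centroid_frame(ens, on, [int(i) for i in np.nonzero(labels == c)[0]])
        for c in range(k)
    ]
    return ClusterResult(
        labels=labels,
        populations=populations,
        centroid_frame_indices=centroids,
        inertia=float(km.inertia_),
    )


def centroid_frame(ens: Ensemble, on: Selection, members: list[int]) -> int:
    """Medoid of the member frames under pairwise superposed RMSD on the
    selection; ties broken by the lowest frame index."""
    members = sorted(members)
    if not members:
        raise ValueError("empty member set")
    if len(members) == 1:
        return members[0]
    m = len(members)
    d = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            r = superposed_rmsd(ens.frames[members[a]], ens.frames[members[b]], on)
            d[a, b] = d[b, a] = r
    cumulative = d.sum(axis=1)
    best = int(np.argmin(cumulative))  # argmin takes the first (lowest index) tie
    return members[best]
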