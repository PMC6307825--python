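"""Collective variables for comparing conformational sampling.

* DRID — distribution of reciprocal interatomic distances.  For anchor
  atoms (Cα and P), each anchor gets three features of its inverse-distance
  distribution to all other anchors: the mean μ, the square root of the
  second central moment ν and the (signed) cube root of the third central
  moment ξ.  The distance between a configuration and a reference is the
  per-anchor Euclidean norm of the feature difference averaged with a
  1/(3N) prefactor.
* Q — smoothed fraction of native contacts,
  Q = (1/N) Σ 1/(1 + exp[β(r_ij − λ·r⁰_ij)]), with β = 50 nm⁻¹ and
  λ = 1.8 by default.
* A 2-D Gaussian kernel density estimate over (Q, DRID) points for
  sampling-coverage maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Frame, Selection

__all__ = [
    "DRIDFeatures",
    "ContactList",
    "drid_features",
    "drid_distance",
    "native_contacts",
    "q_fraction",
    "kde_density",
]

#: default smoothing constant of the native-contact logistic, nm⁻¹
DEFAULT_BETA = 50.0
#: default tolerance factor on the reference contact distance
DEFAULT_LAMBDA = 1.8


@dataclass
class DRIDFeatures:
    """3×N feature matrix (μ, ν, ξ per anchor), units nm⁻¹."""

    anchors: Selection
    matrix: np.ndarray  # shape (3, n_anchors)


def drid_features(frame: Frame, anchors: Selection) -> DRIDFeatures:
    """Per-anchor moments of the inverse distances to all other anchors."""
    idx = anchors.as_array()
    if len(idx) < 3:
        raise ValueError("DRID needs at least 3 anchor atoms")
    pts = frame.coordinates[idx]
    diff = pts[:, None, :] - pts[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    off = ~np.eye(len(idx), dtype=bool)
    if np.any(r[off] < 1e-9):
        raise ValueError("coincident anchor atoms (zero distance)")
    inv = np.where(off, 1.0 / np.where(off, r, 1.0), 0.0)
    n_other = len(idx) - 1
    mu = inv.sum(axis=1) / n_other
    dev = np.where(off, inv - mu[:, None], 0.0)
    m2 = (dev**2).sum(axis=1) / n_other
    m3 = (dev**3).sum(axis=1) / n_other
    nu = np.sqrt(m2)
    xi = np.cbrt(m3)  # signed cube root preserves skew direction
    return DRIDFeatures(anchors=anchors, matrix=np.vstack([mu, nu, xi]))


def drid_distance(
    frame_n: Frame, reference: Frame, anchors: Selection
) -> float:
    """DRID score between a frame and a reference configuration:
    (1/(3N)) Σ_i ‖v_n(·,i) − v₀(·,i)‖ over the N anchors."""
    vn = drid_features(frame_n, anchors).matrix
    v0 = drid_features(reference, anchors).matrix
    n = vn.shape[1]
    norms = np.linalg.norm(vn - v0, axis=0)
    return float(norms.sum() / (3.0 * n))


@dataclass
class ContactList:
    """Reference heavy-atom contact pairs with their native distances."""

    pairs: np.ndarray  # (N, 2) atom indices
    r0: np.ndarray  # (N,) reference distances, nm
    beta: float = DEFAULT_BETA
    lam: float = DEFAULT_LAMBDA
    empty_flag: bool = False

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=float)
        if np.any(self.r0 <= 0):
            raise ValueError("reference distances must be positive")
        seen = {tuple(p) for p in self.pairs}
        if len(seen) != len(self.pairs):
            raise ValueError("duplicate contact pairs")

    def __len__(self) -> int:
        return len(self.pairs)


def native_contacts(
    topology,
    reference: Frame,
    rna_sel: Selection,
    protein_sel: Selection,
    r_define: float = 0.45,
    beta: float = DEFAULT_BETA,
    lam: float = DEFAULT_LAMBDA,
) -> ContactList:
    """All cross heavy-atom pairs closer than ``r_define`` in the reference
    frame, with their native distances r⁰ recorded."""
    set1 = [i for i in rna_sel.atom_indices if topology[i].element.upper() != "H"]
    set2 = [i for i in protein_sel.atom_indices if topology[i].element.upper() != "H"]
    if set(set1) & set(set2):
        raise ValueError("selections must be disjoint")
    pairs = []
    r0 = []
    for i in set1:
        d = np.linalg.norm(reference.coordinates[set2] - reference.coordinates[i], axis=1)
        for j_local in np.nonzero(d < r_define)[0]:
            pairs.append((i, set2[j_local]))
            r0.append(float(d[j_local]))
    empty = len(pairs) == 0
    return ContactList(
        pairs=np.array(pairs).reshape(-1, 2),
        r0=np.array(r0),
        beta=beta,
        lam=lam,
        empty_flag=empty,
    )


def q_fraction(frame: Frame, contacts: ContactList) -> float:
    """Smoothed fraction of native contacts preserved in the frame."""
    if len(contacts) == 0:
        raise ValueError("contact list is empty")
    pi = frame.coordinates[contacts.pairs[:, 0]]
    pj = frame.coordinates[contacts.pairs[:, 1]]
    r = np.linalg.norm(pi - pj, axis=1)
    x = contacts.beta * (r - contacts.lam * contacts.r0)
    # stable logistic
    from scipy.special import expit

    return float(np.mean(expit(-x)))


def kde_density(
    points: np.ndarray,
    grid_size: int = 100,
    padding: float = 3.0,
) -> dict:
    """2-D Gaussian KDE (Scott bandwidth) of (Q, DRID) points on a regular
    grid.  The returned density is normalised so its grid integral is 1.

    Returns a dict with ``x``, ``y`` (grid axes), ``density`` (grid_size ×
    grid_size), ``bandwidth_factor`` and ``integral``.
    """
    from scipy.stats import gaussian_kde

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if np.any(pts.std(axis=0) < 1e-12):
        raise ValueError(
            "zero variance along one collective variable; add jitter or more frames"
        )
    kde = gaussian_kde(pts.T, bw_method="scott")
    sd = pts.std(axis=0)
    lo = pts.min(axis=0) - padding * sd
    hi = pts.max(axis=0) + padding * sd
    x = np.linspace(lo[0], hi[0], grid_size)
    y = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    cell = (x[1] - x[0]) * (y[1] - y[0])
    integral = float(dens.sum() * cell)
    dens = dens / integral
    return {
        "x": x,
        "y": y,
        "density": dens,
        "bandwidth_factor": float(kde.factor),
        "integral": float(dens.sum() * cell),
    }
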