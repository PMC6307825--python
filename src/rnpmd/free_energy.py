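"""Free-energy estimation from bidirectional non-equilibrium work values.

The Crooks fluctuation theorem, P_F(W)/P_R(−W) = exp[(W − ΔG)/kT], links
the forward and reverse work distributions of an alchemical transformation
to the equilibrium free-energy difference.  The maximum-likelihood (Bennett
acceptance ratio) estimator solves the self-consistent equation

    Σ_F 1/(1 + exp[ln(n_F/n_R) + β(W_F − ΔG)])
  = Σ_R 1/(1 + exp[−ln(n_F/n_R) + β(W_R + ΔG)])

for ΔG.  A Gaussian-intersection estimator (crossing point of normal fits
to P_F(W) and P_R(−W)) is provided as an independent cross-check, and the
binding thermodynamic cycle combines two estimates into
ΔΔG = ΔG_complex − ΔG_free.

Energies are kcal/mol externally; temperature defaults to 298 K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "GAS_CONSTANT_KCAL",
    "WorkSet",
    "FreeEnergyEstimate",
    "OverlapError",
    "crooks_mle",
    "crooks_gaussian_intersection",
    "thermo_cycle_ddg",
    "read_work_table",
    "write_work_table",
    "work_overlap",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal mol^-1 K^-1


class OverlapError(RuntimeError):
    """Forward and reverse work distributions do not overlap enough to
    bracket the maximum-likelihood solution."""

    def __init__(self, message: str, overlap: float):
        super().__init__(f"{message} (histogram overlap = {overlap:.4f})")
        self.overlap = overlap


@dataclass
class WorkSet:
    """Forward (A→B) and reverse (B→A) work samples at one temperature."""

    forward: np.ndarray  # kcal/mol
    reverse: np.ndarray  # kcal/mol
    temperature_k: float = 298.0
    label_a: str = "A"
    label_b: str = "B"
    forward_replicates: np.ndarray | None = None
    reverse_replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.reverse = np.asarray(self.reverse, dtype=float)
        if len(self.forward) < 2 or len(self.reverse) < 2:
            raise ValueError("need at least 2 work values in each direction")
        if not (np.all(np.isfinite(self.forward)) and np.all(np.isfinite(self.reverse))):
            raise ValueError("work values must be finite")

    @property
    def kt(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature_k

    def swapped(self) -> "WorkSet":
        return WorkSet(
            forward=self.reverse.copy(),
            reverse=self.forward.copy(),
            temperature_k=self.temperature_k,
            label_a=self.label_b,
            label_b=self.label_a,
            forward_replicates=self.reverse_replicates,
            reverse_replicates=self.forward_replicates,
        )


@dataclass
class FreeEnergyEstimate:
    delta_g: float  # kcal/mol
    stderr: float  # kcal/mol (bootstrap)
    estimator: str
    overlap: float  # forward / mirrored-reverse histogram overlap in [0, 1]
    n_forward: int
    n_reverse: int
    temperature_k: float

    def to_json(self) -> dict:
        return {
            "delta_g": self.delta_g,
            "stderr": self.stderr,
            "estimator": self.estimator,
            "overlap": self.overlap,
            "n_f": self.n_forward,
            "n_r": self.n_reverse,
            "temperature_k": self.temperature_k,
        }


def work_overlap(ws: WorkSet, n_bins: int = 50) -> float:
    """Overlap coefficient of the normalised histograms of W_F and −W_R."""
    a = ws.forward
    b = -ws.reverse
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=False)
    pb, _ = np.histogram(b, bins=edges, density=False)
    return float(np.minimum(pa / len(a), pb / len(b)).sum())


def _bar_residual(dg, wf, wr, beta, log_ratio):
    """Monotone-increasing BAR self-consistency residual at ΔG."""
    term_f = expit(beta * (dg - wf) - log_ratio)
    term_r = expit(-beta * (dg + wr) + log_ratio)
    return term_f.sum() - term_r.sum()


def _solve_bar(wf: np.ndarray, wr: np.ndarray, kt: float) -> float:
    beta = 1.0 / kt
    log_ratio = np.log(len(wf) / len(wr))
    lo = float(np.min(-wr))
    hi = float(np.max(wf))
    if hi < lo:
        lo, hi = hi, lo
    # pad by a few kT: the discrete MLE root can sit slightly outside the
    # raw sample range when sample sizes are unbalanced
    pad = 10.0 * kt
    lo -= pad
    hi += pad
    if hi - lo < 1e-12:
        return 0.5 * (lo + hi)
    flo = _bar_residual(lo, wf, wr, beta, log_ratio)
    fhi = _bar_residual(hi, wf, wr, beta, log_ratio)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise _NoRoot()
    return float(brentq(_bar_residual, lo, hi, args=(wf, wr, beta, log_ratio), xtol=1e-12, rtol=8.9e-16))


class _NoRoot(Exception):
    pass


def _solve_bar_many(
    wf_mat: np.ndarray, wr_mat: np.ndarray, kt: float, n_iter: int = 80
) -> np.ndarray:
    """Vectorised bisection of the BAR equation for many bootstrap
    resamples at once.  wf_mat: (B, n_F); wr_mat: (B, n_R)."""
    beta = 1.0 / kt
    log_ratio = np.log(wf_mat.shape[1] / wr_mat.shape[1])
    lo = np.minimum((-wr_mat).min(axis=1), wf_mat.min(axis=1)) - 10.0 * kt
    hi = np.maximum((-wr_mat).max(axis=1), wf_mat.max(axis=1)) + 10.0 * kt
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        g = (
            expit(beta * (mid[:, None] - wf_mat) - log_ratio).sum(axis=1)
            - expit(-beta * (mid[:, None] + wr_mat) + log_ratio).sum(axis=1)
        )
        neg = g < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi)


def _bootstrap_se(
    ws: WorkSet, solver, n_boot: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    if ws.forward_replicates is not None and ws.reverse_replicates is not None:
        # hierarchical: resample replicate groups with replacement
        estimates = []
        f_groups = [ws.forward[ws.forward_replicates == g] for g in np.unique(ws.forward_replicates)]
        r_groups = [ws.reverse[ws.reverse_replicates == g] for g in np.unique(ws.reverse_replicates)]
        for _ in range(n_boot):
            wf = np.concatenate(
                [f_groups[i] for i in rng.integers(0, len(f_groups), len(f_groups))]
            )
            wr = np.concatenate(
                [r_groups[i] for i in rng.integers(0, len(r_groups), len(r_groups))]
            )
            estimates.append(solver(wf, wr))
        return float(np.std(estimates, ddof=1))
    idx_f = rng.integers(0, len(ws.forward), size=(n_boot, len(ws.forward)))
    idx_r = rng.integers(0, len(ws.reverse), size=(n_boot, len(ws.reverse)))
    wf_mat = ws.forward[idx_f]
    wr_mat = ws.reverse[idx_r]
    if solver is None:  # vectorised BAR path
        ests = _solve_bar_many(wf_mat, wr_mat, ws.kt)
        return float(np.std(ests, ddof=1))
    ests = np.array([solver(wf_mat[b], wr_mat[b]) for b in range(n_boot)])
    return float(np.std(ests, ddof=1))


def crooks_mle(
    ws: WorkSet, n_boot: int = 1000, seed: int = 0, min_overlap: float = 0.01
) -> FreeEnergyEstimate:
    """Maximum-likelihood (BAR) ΔG from bidirectional work values.

    The root of the self-consistency equation is bracketed on the sample
    range [min(−W_R), max(W_F)] (padded by 10 kT) and solved to machine
    precision.  Catastrophic non-overlap — the forward and mirrored-reverse
    work histograms share less than ``min_overlap`` of their mass, or no
    root lies in the bracket — raises :class:`OverlapError` carrying the
    overlap diagnostic instead of returning a meaningless number.  The
    standard error is a seeded bootstrap over work values (or replicate
    groups when tagged).
    """
    overlap = work_overlap(ws)
    if np.std(ws.forward) > 0 and overlap < min_overlap:
        raise OverlapError(
            "forward and reverse work distributions do not overlap", overlap
        )
    try:
        dg = _solve_bar(ws.forward, ws.reverse, ws.kt)
    except _NoRoot:
        raise OverlapError(
            "no maximum-likelihood solution in the work-value bracket", overlap
        ) from None
    if ws.forward_replicates is not None and ws.reverse_replicates is not None:
        se = _bootstrap_se(ws, lambda wf, wr: _solve_bar(wf, wr, ws.kt), n_boot, seed)
    else:
        se = _bootstrap_se(ws, None, n_boot, seed)
    return FreeEnergyEstimate(
        delta_g=dg,
        stderr=se,
        estimator="crooks_mle",
        overlap=overlap,
        n_forward=len(ws.forward),
        n_reverse=len(ws.reverse),
        temperature_k=ws.temperature_k,
    )


def _gaussian_intersection(wf: np.ndarray, wr: np.ndarray) -> float:
    """Crossing point of normal fits to P_F(W) and P_R(−W)."""
    m1, s1 = float(np.mean(wf)), float(np.std(wf, ddof=1))
    m2, s2 = float(np.mean(-wr)), float(np.std(-wr, ddof=1))
    if abs(s1 - s2) < 1e-9 * max(s1, s2, 1.0):
        return 0.5 * (m1 + m2)
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 + 2.0 * np.log(s2 / s1)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return 0.5 * (m1 + m2)
    roots = np.array([(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)])
    lo, hi = min(m1, m2), max(m1, m2)
    inside = roots[(roots >= lo) & (roots <= hi)]
    if len(inside):
        return float(inside[0])
    return float(roots[np.argmin(np.abs(roots - 0.5 * (m1 + m2)))])


def crooks_gaussian_intersection(
    ws: WorkSet, n_boot: int = 1000, seed: int = 0
) -> FreeEnergyEstimate:
    """ΔG at the intersection of Gaussian fits to the forward and the
    mirrored reverse work distributions.  With equal variances this is the
    midpoint of the two means; used as a cross-check of the MLE."""
    dg = _gaussian_intersection(ws.forward, ws.reverse)
    se = _bootstrap_se(ws, _gaussian_intersection, n_boot, seed)
    return FreeEnergyEstimate(
        delta_g=dg,
        stderr=se,
        estimator="crooks_gaussian_intersection",
        overlap=work_overlap(ws),
        n_forward=len(ws.forward),
        n_reverse=len(ws.reverse),
        temperature_k=ws.temperature_k,
    )


def thermo_cycle_ddg(
    dg_complex: FreeEnergyEstimate, dg_free: FreeEnergyEstimate
) -> tuple[float, float]:
    """Binding-affinity change of a mutation from the thermodynamic cycle:
    ΔΔG = ΔG(mutation in complex) − ΔG(mutation in free molecule), errors
    combined in quadrature.  Negative ΔΔG means the mutation favours
    binding."""
    if abs(dg_complex.temperature_k - dg_free.temperature_k) > 1e-9:
        raise ValueError("temperature mismatch between the two legs")
    ddg = dg_complex.delta_g - dg_free.delta_g
    err = float(np.sqrt(dg_complex.stderr**2 + dg_free.stderr**2))
    return float(ddg), err


def read_work_table(path: str, temperature_k: float = 298.0) -> WorkSet:
    """Read a TSV of work values: columns ``direction`` (forward/reverse),
    ``work_kcal_mol`` and optional ``replicate``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"direction", "work_kcal_mol"}
    if not required <= set(df.columns):
        raise ValueError(f"work table needs columns {sorted(required)}")
    bad = set(df["direction"]) - {"forward", "reverse"}
    if bad:
        raise ValueError(f"unknown direction token(s): {sorted(bad)}")
    fw = df[df["direction"] == "forward"]
    rv = df[df["direction"] == "reverse"]
    for name, sub in (("forward", fw), ("reverse", rv)):
        if len(sub) == 0:
            raise ValueError(f"no {name} work values in {path}")
    kwargs = {}
    if "replicate" in df.columns and df["replicate"].notna().all():
        kwargs["forward_replicates"] = fw["replicate"].to_numpy()
        kwargs["reverse_replicates"] = rv["replicate"].to_numpy()
    return WorkSet(
        forward=fw["work_kcal_mol"].to_numpy(),
        reverse=rv["work_kcal_mol"].to_numpy(),
        temperature_k=temperature_k,
        **kwargs,
    )


def write_work_table(ws: WorkSet, path: str) -> str:
    with open(path, "w") as fh:
        fh.write("direction\twork_kcal_mol\n")
        for w in ws.forward:
            fh.write(f"forward\t{w:.6f}\n")
        for w in ws.reverse:
            fh.write(f"reverse\t{w:.6f}\n")
    return path
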