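"""D-RESP atomic point-charge fitting.

Point charges for the QM atoms are fitted to reproduce the QM electrostatic
potential and field recorded at the short-range (SR) MM atom positions
across all reference snapshots, by minimizing

    chi^2({q}) = sum_l sum_{beta in SR_l} [ w_V (V^rho - V^MM)^2
                                          + w_E |E^rho - E^MM|^2 ]
               + w_H sum_alpha (q_alpha - q_alpha^H)^2
               + w_Q (sum_alpha q_alpha - Q_tot)^2

with q^H the restraint charges (typically the original force-field or
Hirshfeld charges).  The restraint term is quadratic: a linear term cannot
regularize a least-squares problem.

Chemical symmetry (equivalent atoms share one charge variable) and total
charge conservation are imposed exactly by variable elimination; the w_Q
penalty is kept in the reported chi^2 so weight grids over w_Q remain
meaningful.  Total charge conservation is checked after every solve and a
hard error is raised on violation.

For covalent QM/MM boundaries a charge-redistribution scheme is provided:
charges on QM atoms within a user-chosen number of bond-graph shells of a
boundary atom are reset to their original force-field values and the
ensuing excess charge is spread uniformly over the remaining QM atoms.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .units import KC
from .refdata import FMDataSet
from .topology import QMRegion

log = logging.getLogger(__name__)

__all__ = [
    "DRESPWeights", "ChargeSet", "DRESPResult",
    "electrostatics_from_charges", "solve_dresp",
    "redistribute_boundary_charges", "grid_search_dresp",
    "ChargeConservationError",
]

CHARGE_TOL = 1e-8  # e


class ChargeConservationError(RuntimeError):
    """Total QM charge deviates from Q_tot beyond tolerance."""


@dataclass
class DRESPWeights:
    """Weights of the four penalty terms (potential, field, restraint,
    total charge).  Defaults follow a published protein application.
    Each weight may also be a list of candidate values for a grid search."""

    w_V: float | Sequence[float] = 1.0
    w_E: float | Sequence[float] = 0.1
    w_H: float | Sequence[float] = 100.0
    w_Q: float | Sequence[float] = 100_000.0

    def is_grid(self) -> bool:
        return any(np.ndim(w) > 0 for w in (self.w_V, self.w_E, self.w_H, self.w_Q))

    def grid_points(self) -> List["DRESPWeights"]:
        axes = [np.atleast_1d(w).tolist()
                for w in (self.w_V, self.w_E, self.w_H, self.w_Q)]
        return [DRESPWeights(*combo) for combo in itertools.product(*axes)]

    def validate(self) -> None:
        for name in ("w_V", "w_E", "w_H", "w_Q"):
            vals = np.atleast_1d(getattr(self, name))
            if (vals < 0).any():
                raise ValueError(f"{name} must be nonnegative")
        if (np.atleast_1d(self.w_Q) <= 0).any():
            raise ValueError("w_Q must be positive")


@dataclass
class ChargeSet:
    """Fitted charges q per QM atom [e], aligned with ``atom_ids``."""

    q: np.ndarray
    atom_ids: np.ndarray
    q_total: float
    q_restraint: Optional[np.ndarray] = None
    equivalence_groups: Optional[List[List[int]]] = None

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.atom_ids = np.asarray(self.atom_ids, int)

    def validate(self, tol: float = CHARGE_TOL) -> None:
        dev = abs(float(self.q.sum()) - self.q_total)
        if dev > tol:
            raise ChargeConservationError(
                f"total charge {self.q.sum():.12f} deviates from "
                f"Q_tot={self.q_total} by {dev:.3e} e (tol {tol:.0e})")


@dataclass
class DRESPResult:
    charges: ChargeSet
    chi2: float
    msd_V: float
    msd_E: float
    sigma_V: float
    sigma_E: float
    weights: DRESPWeights = field(default_factory=DRESPWeights)
    n_data: int = 0
    rank_deficient: bool = False


# ---------------------------------------------------------------------------

def electrostatics_from_charges(charges: np.ndarray, qm_positions: np.ndarray,
                                sr_positions: np.ndarray
                                ) -> Tuple[np.ndarray, np.ndarray]:
    """Coulomb potential and field of point charges at probe positions.

    V_beta = k_C sum_a q_a / r_ab ;  E_beta = k_C sum_a q_a (r_b - r_a)/r_ab^3.
    The field is the negative gradient of the returned potential.
    """
    q = np.asarray(charges, float)
    qm = np.asarray(qm_positions, float).reshape(-1, 3)
    sr = np.asarray(sr_positions, float).reshape(-1, 3)
    d = sr[:, None, :] - qm[None, :, :]          # (M, N, 3)
    r = np.sqrt(np.einsum("mni,mni->mn", d, d))  # (M, N)
    bad = np.argwhere(r < 1e-9)
    if bad.size:
        m, n = bad[0]
        raise ValueError(
            f"QM atom {n} and probe {m} coincide (r={r[m, n]:.2e} nm)")
    V = KC * (q[None, :] / r).sum(axis=1)
    E = KC * np.einsum("n,mn,mni->mi", q, r ** -3, d)
    return V, E


def _influence_matrices(dataset: FMDataSet):
    """Stacked potential/field design rows and reference vectors."""
    A_V, b_V, A_E, b_E = [], [], [], []
    for snap in dataset:
        if snap.n_sr == 0:
            continue
        d = snap.sr_positions[:, None, :] - snap.qm_positions[None, :, :]
        r = np.sqrt(np.einsum("mni,mni->mn", d, d))
        if np.any(r < 1e-9):
            raise ValueError(f"snapshot {snap.index}: coincident QM/SR pair")
        A_V.append(KC / r)                               # (M, N)
        b_V.append(snap.sr_potential)
        AE = KC * d / (r ** 3)[:, :, None]               # (M, N, 3)
        A_E.append(np.moveaxis(AE, 2, 1).reshape(-1, snap.n_qm))  # (3M, N)
        b_E.append(snap.sr_field.reshape(-1))
    n = dataset.n_qm
    cat = (lambda xs, w: np.concatenate(xs) if xs else np.empty((0, w)))
    catv = (lambda xs: np.concatenate(xs) if xs else np.empty(0))
    return cat(A_V, n), catv(b_V), cat(A_E, n), catv(b_E)


def solve_dresp(dataset: FMDataSet, region: QMRegion, weights: DRESPWeights,
                restraints: Optional[np.ndarray] = None,
                Q_tot: Optional[float] = None) -> DRESPResult:
    """Minimize the D-RESP penalty over the QM charges.

    Equivalent atoms share one free variable and the total-charge constraint
    is eliminated exactly, so the returned charges satisfy both by
    construction; the conservation check runs regardless and raises
    :class:`ChargeConservationError` on violation.
    """
    weights.validate()
    if len(dataset) < 1:
        raise ValueError("empty data set")
    n = dataset.n_qm
    order = region.index_maps.dataset_order(dataset.qm_atom_ids)  # ds i -> slot
    if restraints is None:
        rest_slots = region.original_charges()
    else:
        rest_slots = np.empty(n)
        rest_slots[order] = np.asarray(restraints, float)
    if Q_tot is None:
        Q_tot = float(np.round(rest_slots.sum(), 6))

    gi_slots = region.group_index()
    # design rows are in dataset atom order; map group index accordingly
    gi_ds = gi_slots[order]
    G = gi_slots.max() + 1
    S = np.zeros((n, G))
    S[np.arange(n), gi_ds] = 1.0
    counts = S.sum(axis=0)

    A_V, b_V, A_E, b_E = _influence_matrices(dataset)
    if (np.ndim(weights.w_V) or np.ndim(weights.w_E)):
        raise ValueError("grid weights passed to solve_dresp; use "
                         "grid_search_dresp")
    wV, wE, wH, wQ = (float(weights.w_V), float(weights.w_E),
                      float(weights.w_H), float(weights.w_Q))
    if (wV > 0 or wE > 0) and A_V.shape[0] == 0:
        raise ValueError("w_V/w_E > 0 but the data set has no SR atoms")

    rest_ds = rest_slots[order]
    rows = [np.sqrt(wV) * A_V, np.sqrt(wE) * A_E,
            np.sqrt(wH) * np.eye(n), np.sqrt(wQ) * np.ones((1, n))]
    rhs = [np.sqrt(wV) * b_V, np.sqrt(wE) * b_E,
           np.sqrt(wH) * rest_ds, np.sqrt(wQ) * np.array([Q_tot])]
    A = np.concatenate([r for r in rows if r.shape[0]])
    b = np.concatenate(rhs)

    # eliminate: q = S g,  sum q = counts . g = Q_tot  ->  g = g0 + B h
    g0 = np.zeros(G)
    g0[-1] = Q_tot / counts[-1]
    if G > 1:
        B = np.zeros((G, G - 1))
        B[:-1] = np.eye(G - 1)
        B[-1] = -counts[:-1] / counts[-1]
        ASB = A @ S @ B
        rhs_red = b - A @ (S @ g0)
        h, residuals, rank, sv = np.linalg.lstsq(ASB, rhs_red, rcond=None)
        rank_deficient = rank < G - 1
        if rank_deficient:
            log.warning("D-RESP system is rank deficient (rank %d < %d); "
                        "minimum-norm solution returned", rank, G - 1)
        g = g0 + B @ h
    else:
        g = g0
        rank_deficient = False
    q_ds = S @ g

    groups_ds = [[int(dataset.qm_atom_ids[i]) for i in np.where(gi_ds == k)[0]]
                 for k in range(G)]
    charges = ChargeSet(q=q_ds, atom_ids=dataset.qm_atom_ids.copy(),
                        q_total=Q_tot, q_restraint=rest_ds,
                        equivalence_groups=groups_ds)
    charges.validate()

    chi2, msd_V, msd_E, sig_V, sig_E, n_data = _score(
        q_ds, A_V, b_V, A_E, b_E, rest_ds, Q_tot, wV, wE, wH, wQ)
    return DRESPResult(charges=charges, chi2=chi2, msd_V=msd_V, msd_E=msd_E,
                       sigma_V=sig_V, sigma_E=sig_E, weights=weights,
                       n_data=n_data, rank_deficient=rank_deficient)


def chi_squared(q: np.ndarray, dataset: FMDataSet, region: QMRegion,
                weights: DRESPWeights, restraints: np.ndarray,
                Q_tot: float) -> float:
    """The penalty function evaluated at arbitrary charges (dataset order)."""
    A_V, b_V, A_E, b_E = _influence_matrices(dataset)
    chi2, *_ = _score(np.asarray(q, float), A_V, b_V, A_E, b_E,
                      np.asarray(restraints, float), Q_tot,
                      float(weights.w_V), float(weights.w_E),
                      float(weights.w_H), float(weights.w_Q))
    return chi2


def _score(q, A_V, b_V, A_E, b_E, rest, Q_tot, wV, wE, wH, wQ):
    res_V = A_V @ q - b_V
    res_E = A_E @ q - b_E
    chi2 = (wV * float(res_V @ res_V) + wE * float(res_E @ res_E)
            + wH * float(((q - rest) ** 2).sum())
            + wQ * float((q.sum() - Q_tot) ** 2))
    n_V = res_V.size
    n_E3 = res_E.size
    msd_V = float(res_V @ res_V) / n_V if n_V else 0.0
    msd_E = float(res_E @ res_E) / (n_E3 // 3) if n_E3 else 0.0
    sig_V = (np.sqrt(float(res_V @ res_V) / float(b_V @ b_V))
             if n_V and float(b_V @ b_V) > 0 else 0.0)
    sig_E = (np.sqrt(float(res_E @ res_E) / float(b_E @ b_E))
             if n_E3 and float(b_E @ b_E) > 0 else 0.0)
    return chi2, msd_V, msd_E, sig_V, sig_E, n_V + n_E3


# ---------------------------------------------------------------------------

def redistribute_boundary_charges(result, region: QMRegion,
                                  n_neighbor_shells: int,
                                  original_charges: np.ndarray) -> ChargeSet:
    """Reset charges near covalent QM/MM boundary atoms and redistribute.

    QM atoms within ``n_neighbor_shells`` bond-graph steps of any boundary
    atom (the boundary atom itself counts as shell 0) are reset to their
    original force-field charges; the resulting excess charge is spread
    uniformly over the remaining QM atoms so that the total is restored
    exactly.  Identity when the region has no boundary atoms.
    """
    charges = result.charges if isinstance(result, DRESPResult) else result
    if not region.boundary_atoms:
        return charges
    ids = charges.atom_ids
    slot_of = {int(g): i for i, g in enumerate(ids)}
    orig = np.asarray(original_charges, float)
    if orig.shape != charges.q.shape:
        raise ValueError("original_charges shape mismatch")

    reset: set = set()
    frontier = set(int(b) for b in region.boundary_atoms)
    reset |= frontier
    for _ in range(n_neighbor_shells):
        frontier = {n for f in frontier
                    for n in region.bond_graph.get(f, ())} - reset
        reset |= frontier
    remaining = [int(g) for g in ids if int(g) not in reset]
    if not remaining:
        raise ValueError("boundary redistribution left no atom to absorb the "
                         "excess charge; reduce n_neighbor_shells")
    q = charges.q.copy()
    for g in reset:
        q[slot_of[g]] = orig[slot_of[g]]
    excess = charges.q_total - q.sum()
    for g in remaining:
        q[slot_of[g]] += excess / len(remaining)
    out = ChargeSet(q=q, atom_ids=ids.copy(), q_total=charges.q_total,
                    q_restraint=charges.q_restraint,
                    equivalence_groups=charges.equivalence_groups)
    out.validate(tol=1e-12)
    return out


# ---------------------------------------------------------------------------

GRID_CSV_COLUMNS = ["w_V", "w_E", "w_H", "w_Q", "msd_V", "msd_E", "score",
                    "total_charge", "status"]


def grid_search_dresp(dataset: FMDataSet, region: QMRegion,
                      weight_grid: DRESPWeights,
                      restraints: Optional[np.ndarray] = None,
                      Q_tot: Optional[float] = None,
                      csv_path=None) -> Tuple[DRESPResult, pd.DataFrame]:
    """Evaluate the Cartesian product of weight candidates.

    The best grid point minimizes MSD(V) + MSD(E) computed with the final
    optimized charges; ties break to the first point in row-major order
    (w_V outermost, w_Q innermost).  Failed solves are recorded in the table
    with their error and excluded from the argmin.
    """
    points = weight_grid.grid_points()
    rows = []
    best: Optional[DRESPResult] = None
    best_score = np.inf
    for w in points:
        try:
            res = solve_dresp(dataset, region, w, restraints, Q_tot)
        except Exception as exc:  # noqa: BLE001 - recorded per grid point
            rows.append([w.w_V, w.w_E, w.w_H, w.w_Q, np.nan, np.nan, np.nan,
                         np.nan, f"failed: {exc}"])
            continue
        score = res.msd_V + res.msd_E
        rows.append([w.w_V, w.w_E, w.w_H, w.w_Q, res.msd_V, res.msd_E,
                     score, float(res.charges.q.sum()), "ok"])
        if score < best_score:
            best, best_score = res, score
    table = pd.DataFrame(rows, columns=GRID_CSV_COLUMNS)
    if best is None:
        raise RuntimeError("every grid point failed:\n" +
                           "\n".join(table["status"].tolist()))
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return best, table
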