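"""Bonded force-field parameter optimization by force matching.

The reference bonded forces are obtained per snapshot as the difference
between the total QM/MM forces on the QM atoms and the model nonbonded
forces computed with the fitted charges.  The bonded parameters tau are
then obtained by minimizing

    sigma^2({tau}) = sum_l sum_{alpha in QM} |F^ref_bonded - F^MM,bonded(tau)|^2
                   + lambda sum_n ((tau_n - tau_n^orig) / s_n)^2

with an optional L2 regularization toward the original parameters; the
per-slot scale s_n is the original value when nonzero (else 1) so lambda is
unitless across parameter kinds.

Free parameter slots: force constants and equilibrium values for bonds,
angles and impropers; only the force constant for periodic dihedrals
(phase and multiplicity stay fixed); all six Ryckaert-Bellemans
coefficients.  Bonded terms with the same (kind, funct, atom-type
signature) share parameters, mirroring equivalent-atom charge tying; the
tying is overridable.

Strategies: "hierarchical" fits in stages (bonds, then angles, then
impropers, then dihedrals, each stage freezing the previous kinds at their
fitted values), "simultaneous" fits everything at once, or a custom stage
sequence may be given.  The initial guess is always the original
force-field values, so results are reproducible without seeds.  Dihedrals
are excluded by default: short reference trajectories rarely sample the
torsional space well enough for stable dihedral fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .refdata import FMDataSet
from .topology import QMRegion, Topology, BondedTerm, FittableTerm
from . import engine
from .engine import ForceSet

log = logging.getLogger(__name__)

__all__ = [
    "BondedParameterSet", "FitResult", "StageRecord",
    "reference_bonded_forces", "objective_sigma2", "fit_bonded",
    "fit_quality", "normalized_deviation",
]

#: free-slot layout per (kind): (slot indices into params, lower, upper)
_FREE_SLOTS = {
    "bond": ([0, 1], [0.0, 0.0], [np.inf, np.inf]),            # b0, kb
    "angle": ([0, 1], [0.0, 0.0], [180.0, np.inf]),            # theta0, ktheta
    "improper": ([0, 1], [-360.0, 0.0], [360.0, np.inf]),      # xi0, kxi
    "dihedral_periodic": ([1], [0.0], [np.inf]),               # kphi only
    "dihedral_RB": ([0, 1, 2, 3, 4, 5],
                    [-np.inf] * 6, [np.inf] * 6),              # C0..C5
}
_KIND_OF_INCLUDE = {
    "bonds": ("bond",),
    "angles": ("angle",),
    "impropers": ("improper",),
    "dihedrals": ("dihedral_periodic", "dihedral_RB"),
}
_STAGE_ORDER = ("bonds", "angles", "impropers", "dihedrals")


@dataclass
class ParamGroup:
    """One set of tied bonded terms sharing parameter values."""

    kind: str
    signature: Tuple[str, ...]
    terms: List[FittableTerm]
    free_slots: List[int]
    values: np.ndarray          # full parameter vector of the term
    original: np.ndarray
    lower: np.ndarray           # per free slot
    upper: np.ndarray

    @property
    def n_free(self) -> int:
        return len(self.free_slots)

    def full_params(self) -> List[float]:
        return [float(v) for v in self.values]

    def free_values(self) -> np.ndarray:
        return self.values[self.free_slots]

    def set_free_values(self, x: np.ndarray) -> None:
        self.values[self.free_slots] = x


@dataclass
class BondedParameterSet:
    """Fittable bonded parameters organized into tied groups."""

    groups: List[ParamGroup] = field(default_factory=list)

    @classmethod
    def from_region(cls, region: QMRegion,
                    include: Sequence[str] = ("bonds", "angles", "impropers"),
                    tie_equivalent: bool = True) -> "BondedParameterSet":
        kinds = {k for inc in include for k in _KIND_OF_INCLUDE[inc]}
        buckets: Dict[tuple, List[FittableTerm]] = {}
        for i, ft in enumerate(region.fittable):
            if ft.kind not in kinds or ft.kind not in _FREE_SLOTS:
                continue
            key = ft.type_signature if tie_equivalent else \
                ft.type_signature + ("#", str(i))
            buckets.setdefault(key, []).append(ft)
        groups = []
        for key in sorted(buckets):
            terms = buckets[key]
            kind = terms[0].kind
            slots, lo, hi = _FREE_SLOTS[kind]
            params = np.asarray(terms[0].params, float)
            if any(not np.allclose(t.params, params) for t in terms[1:]):
                log.warning("tied %s terms %s start from differing parameters; "
                            "using the first term's values", kind, key)
            slots = [s for s in slots if s < params.size]
            groups.append(ParamGroup(
                kind=kind, signature=key, terms=terms, free_slots=slots,
                values=params.copy(), original=params.copy(),
                lower=np.asarray(lo, float)[:len(slots)],
                upper=np.asarray(hi, float)[:len(slots)]))
        return cls(groups=groups)

    def select(self, kinds: Sequence[str]) -> List[ParamGroup]:
        wanted = {k for inc in kinds for k in _KIND_OF_INCLUDE[inc]}
        return [g for g in self.groups if g.kind in wanted]

    # -- vector interface over a subset of groups -------------------------
    @staticmethod
    def pack(groups: List[ParamGroup]) -> np.ndarray:
        if not groups:
            return np.empty(0)
        return np.concatenate([g.free_values() for g in groups])

    @staticmethod
    def unpack(groups: List[ParamGroup], x: np.ndarray) -> None:
        i = 0
        for g in groups:
            g.set_free_values(x[i:i + g.n_free])
            i += g.n_free

    @staticmethod
    def bounds(groups: List[ParamGroup]) -> Tuple[np.ndarray, np.ndarray]:
        if not groups:
            return np.empty(0), np.empty(0)
        return (np.concatenate([g.lower for g in groups]),
                np.concatenate([g.upper for g in groups]))

    def regularization_residuals(self, l2_lambda: float) -> np.ndarray:
        """sqrt(lambda) (tau - tau_orig)/s_n over every free slot."""
        if l2_lambda == 0.0 or not self.groups:
            return np.empty(0)
        rows = []
        for g in self.groups:
            s = np.where(g.original[g.free_slots] != 0.0,
                         np.abs(g.original[g.free_slots]), 1.0)
            rows.append(np.sqrt(l2_lambda)
                        * (g.values[g.free_slots] - g.original[g.free_slots]) / s)
        return np.concatenate(rows)

    def engine_terms(self) -> List[BondedTerm]:
        """Terms (QM slot indices) with the current parameter values."""
        out = []
        for g in self.groups:
            for ft in g.terms:
                out.append(BondedTerm(ft.kind, ft.slots, ft.funct,
                                      g.full_params()))
        return out

    def copy_values_from(self, other: "BondedParameterSet") -> None:
        for g, o in zip(self.groups, other.groups):
            g.values[:] = o.values


@dataclass
class StageRecord:
    stage: str
    sigma2_before: float
    sigma2_after: float
    converged: bool
    message: str
    nfev: int


@dataclass
class FitResult:
    params: BondedParameterSet
    sigma2: float
    sigma2_initial: float
    sigma_F: float
    stages: List[StageRecord]
    residual_per_snapshot: np.ndarray
    converged: bool


# ---------------------------------------------------------------------------

def reference_bonded_forces(dataset: FMDataSet, nonbonded: ForceSet) -> ForceSet:
    """F^QM - F^MM,nb, element-wise, per snapshot per QM atom."""
    L = len(dataset)
    if nonbonded.n_frames != L:
        raise ValueError(f"{nonbonded.n_frames} nonbonded frames for "
                         f"{L} snapshots")
    out = np.empty((L, dataset.n_qm, 3))
    for l in range(L):
        snap = dataset.get_snapshot(l)
        if snap.qm_forces.shape != nonbonded.forces[l].shape:
            raise ValueError(f"snapshot {l}: force shape mismatch")
        out[l] = snap.qm_forces - nonbonded.forces[l]
    return ForceSet(out, component="bonded")


def _qm_positions_slots(dataset: FMDataSet, region: QMRegion) -> np.ndarray:
    """(L, n_qm, 3) QM positions in region slot order."""
    order = region.index_maps.dataset_order(dataset.qm_atom_ids)
    out = np.empty((len(dataset), dataset.n_qm, 3))
    for l in range(len(dataset)):
        out[l, order] = dataset.get_snapshot(l).qm_positions
    return out


def _fixed_terms(region: QMRegion, params: BondedParameterSet) -> List[BondedTerm]:
    """Fittable-inventory terms not covered by any parameter group; they
    contribute at their original values."""
    covered = {id(ft) for g in params.groups for ft in g.terms}
    out = []
    for ft in region.fittable:
        if id(ft) not in covered:
            out.append(BondedTerm(ft.kind, ft.slots, ft.funct, list(ft.params)))
    return out


def _model_forces(pos_slots: np.ndarray, params: BondedParameterSet,
                  fixed: List[BondedTerm]) -> np.ndarray:
    terms = params.engine_terms() + fixed
    if not terms:
        return np.zeros_like(pos_slots)
    return engine.bonded_forces(pos_slots, terms)


def objective_sigma2(params: BondedParameterSet, dataset: FMDataSet,
                     ref_bonded: ForceSet, topology: Topology,
                     region: QMRegion, l2_lambda: float = 0.0) -> float:
    """The force-matching objective at the given parameters."""
    pos = _qm_positions_slots(dataset, region)
    order = region.index_maps.dataset_order(dataset.qm_atom_ids)
    fixed = _fixed_terms(region, params)
    model = _model_forces(pos, params, fixed)          # slot order
    ref = np.empty_like(model)
    ref[:, order] = ref_bonded.forces                  # dataset -> slot order
    resid = (model - ref).ravel()
    reg = params.regularization_residuals(l2_lambda)
    return float(resid @ resid) + float(reg @ reg)


# ---------------------------------------------------------------------------

def _stage_list(strategy, include: Sequence[str]) -> List[List[str]]:
    include = list(include)
    unknown = set(include) - set(_STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown term kinds {sorted(unknown)}; "
                         f"valid: {list(_STAGE_ORDER)}")
    ordered = [k for k in _STAGE_ORDER if k in include]
    if strategy == "hierarchical":
        return [[k] for k in ordered]
    if strategy == "simultaneous":
        return [ordered]
    if isinstance(strategy, (list, tuple)):   # custom sequence of stages
        stages = [[s] if isinstance(s, str) else list(s) for s in strategy]
        for st in stages:
            bad = set(st) - set(include)
            if bad:
                raise ValueError(f"custom stage {st} uses excluded kinds {bad}")
        return stages
    raise ValueError(f"unknown strategy {strategy!r}")


def fit_bonded(dataset: FMDataSet, topology: Topology, region: QMRegion,
               charges, strategy="hierarchical",
               include: Sequence[str] = ("bonds", "angles", "impropers"),
               l2_lambda: float = 0.0,
               nonbonded_source: str = "internal",
               nonbonded: Optional[ForceSet] = None,
               cutoff: Optional[float] = None,
               rf_epsilon: Optional[float] = None,
               tie_equivalent: bool = True,
               ftol: float = 1e-10, xtol: float = 1e-10, gtol: float = 1e-10,
               max_iterations: int = 1000, max_sweeps_default: int = 50
               ) -> FitResult:
    """Fit bonded parameters of the QM region to the reference forces.

    ``charges`` (a ChargeSet) feeds the internal nonbonded engine; pass
    ``nonbonded_source="imported"`` plus a ``nonbonded`` ForceSet to use an
    externally computed rerun instead.  Trust-region least squares from the
    original parameters; each hierarchical stage freezes the kinds fitted
    before it, so sigma^2 is monotone non-increasing across stages.
    """
    if nonbonded_source == "internal":
        nb = engine.nonbonded_force_set(dataset, topology, charges,
                                        cutoff=cutoff, region=region,
                                        rf_epsilon=rf_epsilon)
    elif nonbonded_source == "imported":
        if nonbonded is None:
            raise ValueError("nonbonded_source='imported' requires a "
                             "nonbonded ForceSet")
        nb = nonbonded
    else:
        raise ValueError(f"unknown nonbonded_source {nonbonded_source!r}")

    ref = reference_bonded_forces(dataset, nb)
    params = BondedParameterSet.from_region(region, include=include,
                                            tie_equivalent=tie_equivalent)
    stages = _stage_list(strategy, include)
    if not any(params.select(st) for st in stages):
        raise ValueError(f"no fittable terms among {list(include)}")

    pos = _qm_positions_slots(dataset, region)
    order = region.index_maps.dataset_order(dataset.qm_atom_ids)
    ref_slots = np.empty_like(ref.forces)
    ref_slots[:, order] = ref.forces
    fixed = _fixed_terms(region, params)

    def full_objective() -> float:
        resid = (_model_forces(pos, params, fixed) - ref_slots).ravel()
        reg = params.regularization_residuals(l2_lambda)
        return float(resid @ resid) + float(reg @ reg)

    sigma2_initial = full_objective()
    records: List[StageRecord] = []
    converged_all = True
    # staged strategies are swept repeatedly: sequential stages only decouple
    # exactly when the term kinds are independent, so sweeps are repeated
    # until the objective stops improving (a single sweep for "simultaneous")
    max_sweeps = 1 if len(stages) == 1 else max_sweeps_default
    current = sigma2_initial
    for sweep in range(max_sweeps):
        sweep_start = current
        for stage in stages:
            groups = params.select(stage)
            if not groups:
                continue
            before = full_objective()
            x0 = BondedParameterSet.pack(groups)
            lo, hi = BondedParameterSet.bounds(groups)
            x0 = np.clip(x0, lo, hi)

            def residuals(x, groups=groups):
                BondedParameterSet.unpack(groups, x)
                r = (_model_forces(pos, params, fixed) - ref_slots).ravel()
                reg = params.regularization_residuals(l2_lambda)
                return np.concatenate([r, reg])

            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                ftol=ftol, xtol=xtol, gtol=gtol,
                                max_nfev=max_iterations * max(1, x0.size))
            BondedParameterSet.unpack(groups, sol.x)
            after = full_objective()
            if after > before:       # trust region never accepts an increase,
                BondedParameterSet.unpack(groups, x0)  # but guard regardless
                after = before
            ok = bool(sol.status > 0)
            converged_all &= ok
            if not ok:
                log.warning("stage %s did not converge: %s", stage, sol.message)
            name = "+".join(stage) + (f" (sweep {sweep + 1})"
                                      if max_sweeps > 1 else "")
            records.append(StageRecord(stage=name, sigma2_before=before,
                                       sigma2_after=after, converged=ok,
                                       message=str(sol.message),
                                       nfev=int(sol.nfev)))
        current = full_objective()
        if sweep_start - current <= ftol * max(sweep_start, 1e-300):
            break

    model = _model_forces(pos, params, fixed)
    resid = model - ref_slots
    per_snap = np.sqrt((resid ** 2).sum(axis=(1, 2)))
    denom = float((ref_slots ** 2).sum())
    sigma_F = float(np.sqrt((resid ** 2).sum() / denom)) if denom > 0 else 0.0
    return FitResult(params=params, sigma2=full_objective(),
                     sigma2_initial=sigma2_initial, sigma_F=sigma_F,
                     stages=records, residual_per_snapshot=per_snap,
                     converged=converged_all)


# ---------------------------------------------------------------------------

def normalized_deviation(fit: np.ndarray, ref: np.ndarray) -> float:
    """sigma_X = sqrt( sum |X_fit - X_ref|^2 / sum |X_ref|^2 )."""
    fit = np.asarray(fit, float)
    ref = np.asarray(ref, float)
    if fit.shape != ref.shape:
        raise ValueError(f"shape mismatch {fit.shape} vs {ref.shape}")
    denom = float((ref ** 2).sum())
    if denom == 0.0:
        raise ValueError("all-zero reference: normalized deviation undefined")
    return float(np.sqrt(((fit - ref) ** 2).sum() / denom))


def fit_quality(V_fit, V_ref, E_fit, E_ref, F_fit, F_ref
                ) -> Tuple[float, float, float]:
    """Normalized standard deviations (sigma_V, sigma_E, sigma_F) of fitted
    potential, field and forces from the reference values."""
    return (normalized_deviation(V_fit, V_ref),
            normalized_deviation(E_fit, E_ref),
            normalized_deviation(F_fit, F_ref))
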