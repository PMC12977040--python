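"""Model force computation.

Bonded terms (analytical negative energy gradients, GROMACS functional
forms and conventions):

* bond (type 1):        E = 1/2 k_b (b - b0)^2
* angle (type 1):       E = 1/2 k_th (theta - theta0)^2
* proper dihedral (1/9):E = k_phi (1 + cos(n phi - phi_s))
* Ryckaert-Bellemans(3):E = sum_m C_m cos^m(psi),  psi = phi - 180 deg
* improper (type 2):    E = 1/2 k_xi (xi - xi0)^2, xi wrapped to (-180,180]
* periodic improper (4): same form as the proper periodic dihedral

Angle-type parameters are stored in degrees (topology convention) with
force constants per rad^2; conversion to radians happens here.

The nonbonded engine computes Coulomb + Lennard-Jones forces acting on the
QM atoms from (a) other QM atoms, honoring exclusions generated from the
bond graph out to nrexcl plus explicit [exclusions], with [pairs]
interactions scaled by fudge_QQ/fudge_LJ, and (b) SR atoms within an
optional cutoff, with minimum-image convention when a box is present.
Plain (cutoff-truncated) electrostatics with an optional reaction-field
correction; no mesh Ewald — externally computed force trajectories can be
imported for exact parity with a mesh-Ewald rerun.

SR indices that do not resolve to a topology atom are treated as inert
probe points (zero charge, no LJ); this is how synthetic massless probes
flow through the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .units import KC
from .refdata import Snapshot, FMDataSet
from .topology import Topology, BondedTerm, QMRegion

__all__ = [
    "ForceSet", "bonded_forces", "bonded_energy", "nonbonded_forces",
    "nonbonded_energy", "NonbondedModel", "nonbonded_force_set",
    "import_nonbonded_forces", "write_force_trajectory",
]

_SIN_TOL = 1e-9
_OVERLAP_NM = 1e-5


class GeometryError(ValueError):
    """Degenerate (collinear/overlapping) geometry."""


@dataclass
class ForceSet:
    """Per-snapshot, per-QM-atom force vectors [kJ/mol/nm]."""

    forces: np.ndarray     # (L, n_qm, 3)
    component: str = "total"   # nonbonded | bonded | total

    def __post_init__(self):
        self.forces = np.asarray(self.forces, float)
        if self.forces.ndim != 3 or self.forces.shape[2] != 3:
            raise ValueError(f"ForceSet shape {self.forces.shape}")
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("non-finite forces")

    @property
    def n_frames(self) -> int:
        return self.forces.shape[0]


# ---------------------------------------------------------------------------
# bonded terms, batched over configurations

def _norm(v):
    return np.sqrt(np.einsum("...i,...i->...", v, v))


def _bond(pos, t, e, f):
    i, j = t.atoms
    b0, kb = t.params[0], t.params[1]
    rij = pos[:, j] - pos[:, i]
    r = _norm(rij)
    if np.any(r < _OVERLAP_NM):
        raise GeometryError(f"bond {t.atoms}: overlapping atoms")
    d = r - b0
    e += 0.5 * kb * d * d
    fj = -(kb * d / r)[:, None] * rij
    f[:, j] += fj
    f[:, i] -= fj


def _angle_theta(pos, i, j, k):
    a = pos[:, i] - pos[:, j]
    b = pos[:, k] - pos[:, j]
    na, nb = _norm(a), _norm(b)
    cos = np.einsum("li,li->l", a, b) / (na * nb)
    cos = np.clip(cos, -1.0, 1.0)
    theta = np.arccos(cos)
    return a, b, na, nb, cos, theta


def _angle(pos, t, e, f):
    i, j, k = t.atoms
    th0 = np.deg2rad(t.params[0])
    kth = t.params[1]
    a, b, na, nb, cos, theta = _angle_theta(pos, i, j, k)
    sin = np.sqrt(1.0 - cos * cos)
    if np.any(sin < _SIN_TOL):
        raise GeometryError(f"angle {t.atoms}: collinear geometry")
    dE = kth * (theta - th0)
    e += 0.5 * kth * (theta - th0) ** 2
    ah = a / na[:, None]
    bh = b / nb[:, None]
    dth_di = (cos[:, None] * ah - bh) / (na * sin)[:, None]
    dth_dk = (cos[:, None] * bh - ah) / (nb * sin)[:, None]
    f[:, i] -= dE[:, None] * dth_di
    f[:, k] -= dE[:, None] * dth_dk
    f[:, j] += dE[:, None] * (dth_di + dth_dk)


def _dihedral_phi(pos, i, j, k, l):
    b1 = pos[:, j] - pos[:, i]
    b2 = pos[:, k] - pos[:, j]
    b3 = pos[:, l] - pos[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = _norm(b2)
    x = np.einsum("li,li->l", n1, n2)
    y = np.einsum("li,li->l", np.cross(n1, n2), b2) / nb2
    phi = np.arctan2(y, x)
    return b1, b2, b3, n1, n2, nb2, phi


def _dihedral_forces(pos, atoms, dE_dphi, f, b1, b2, b3, n1, n2, nb2):
    i, j, k, l = atoms
    sn1 = np.einsum("li,li->l", n1, n1)
    sn2 = np.einsum("li,li->l", n2, n2)
    if np.any(sn1 < _SIN_TOL ** 2) or np.any(sn2 < _SIN_TOL ** 2):
        raise GeometryError(f"dihedral {atoms}: collinear geometry")
    dphi_di = -(nb2 / sn1)[:, None] * n1
    dphi_dl = (nb2 / sn2)[:, None] * n2
    t = (np.einsum("li,li->l", b1, b2) / nb2 ** 2)[:, None]
    s = (np.einsum("li,li->l", b3, b2) / nb2 ** 2)[:, None]
    dphi_dj = -(1.0 + t) * dphi_di + s * dphi_dl
    dphi_dk = t * dphi_di - (1.0 + s) * dphi_dl
    g = dE_dphi[:, None]
    f[:, i] -= g * dphi_di
    f[:, j] -= g * dphi_dj
    f[:, k] -= g * dphi_dk
    f[:, l] -= g * dphi_dl


def _dihedral_periodic(pos, t, e, f):
    phis = np.deg2rad(t.params[0])
    k = t.params[1]
    n = int(round(t.params[2])) if len(t.params) > 2 else 1
    b1, b2, b3, n1, n2, nb2, phi = _dihedral_phi(pos, *t.atoms)
    e += k * (1.0 + np.cos(n * phi - phis))
    dE = -k * n * np.sin(n * phi - phis)
    _dihedral_forces(pos, t.atoms, dE, f, b1, b2, b3, n1, n2, nb2)


def _dihedral_rb(pos, t, e, f):
    C = list(t.params[:6]) + [0.0] * (6 - len(t.params[:6]))
    b1, b2, b3, n1, n2, nb2, phi = _dihedral_phi(pos, *t.atoms)
    cpsi = -np.cos(phi)          # psi = phi - pi
    ene = np.zeros_like(phi)
    dpoly = np.zeros_like(phi)   # dE/dcos(psi)
    p = np.ones_like(phi)
    for m in range(6):
        ene += C[m] * p
        if m < 5:
            dpoly += (m + 1) * C[m + 1] * p
        p = p * cpsi
    e += ene
    dE = dpoly * np.sin(phi)     # dcos(psi)/dphi = sin(phi)
    _dihedral_forces(pos, t.atoms, dE, f, b1, b2, b3, n1, n2, nb2)


def _improper(pos, t, e, f):
    xi0 = np.deg2rad(t.params[0])
    k = t.params[1]
    b1, b2, b3, n1, n2, nb2, phi = _dihedral_phi(pos, *t.atoms)
    d = phi - xi0
    d = d - 2.0 * np.pi * np.round(d / (2.0 * np.pi))
    e += 0.5 * k * d * d
    _dihedral_forces(pos, t.atoms, k * d, f, b1, b2, b3, n1, n2, nb2)


_KERNELS = {
    "bond": _bond,
    "angle": _angle,
    "dihedral_periodic": _dihedral_periodic,
    "dihedral_RB": _dihedral_rb,
    "improper": _improper,
    "improper_periodic": _dihedral_periodic,
}


def _as_batch(positions) -> Tuple[np.ndarray, bool]:
    pos = np.asarray(positions, float)
    if pos.ndim == 2:
        return pos[None], True
    return pos, False


def bonded_forces(positions, terms: Sequence[BondedTerm]) -> np.ndarray:
    """Analytical bonded forces, exact negative gradients of the energy.

    ``positions`` may be a single configuration (n, 3) or a batch
    (L, n, 3); the returned array has the same leading shape.
    """
    pos, single = _as_batch(positions)
    f = np.zeros_like(pos)
    e = np.zeros(pos.shape[0])
    for t in terms:
        kernel = _KERNELS.get(t.kind)
        if kernel is None:
            raise ValueError(f"unsupported bonded term kind {t.kind!r}")
        kernel(pos, t, e, f)
    return f[0] if single else f


def bonded_energy(positions, terms: Sequence[BondedTerm]) -> np.ndarray:
    pos, single = _as_batch(positions)
    f = np.zeros_like(pos)
    e = np.zeros(pos.shape[0])
    for t in terms:
        _KERNELS[t.kind](pos, t, e, f)
    return float(e[0]) if single else e


# ---------------------------------------------------------------------------
# nonbonded engine

def _combine_lj(s1, e1, s2, e2, comb_rule: int) -> Tuple[float, float]:
    if comb_rule == 3:
        return np.sqrt(s1 * s2), np.sqrt(e1 * e2)
    if comb_rule == 2:
        return 0.5 * (s1 + s2), np.sqrt(e1 * e2)
    raise ValueError(f"unsupported combination rule {comb_rule} "
                     "(supported: 2 Lorentz-Berthelot, 3 geometric)")


class NonbondedModel:
    """Precomputed interaction lists for a fixed topology + QM region."""

    def __init__(self, topology: Topology, region: QMRegion,
                 charges: Optional[np.ndarray] = None,
                 cutoff: Optional[float] = None,
                 rf_epsilon: Optional[float] = None):
        self.topology = topology
        self.region = region
        self.cutoff = cutoff
        self.rf_epsilon = rf_epsilon
        self.q = (np.asarray(charges, float) if charges is not None
                  else region.original_charges())
        if self.q.shape != (region.n_atoms,):
            raise ValueError("charge array does not match the QM region")
        atoms = topology.expand_atoms()
        self._by_gid = {a.global_index: a for a in atoms}
        self._excl_cache: Dict[str, set] = {}
        self._pair_cache: Dict[str, dict] = {}
        self._build_qm_pairs()

    # -- exclusion bookkeeping --------------------------------------------
    def _mol_exclusions(self, molname: str) -> set:
        if molname not in self._excl_cache:
            self._excl_cache[molname] = \
                self.topology.moleculetypes[molname].build_exclusions()
        return self._excl_cache[molname]

    def _mol_pairs(self, molname: str) -> dict:
        if molname not in self._pair_cache:
            mt = self.topology.moleculetypes[molname]
            self._pair_cache[molname] = {
                frozenset(p.atoms): True for p in mt.pairs}
        return self._pair_cache[molname]

    def _pair_scale(self, a1, a2) -> Tuple[float, float]:
        """(qq_scale, lj_scale) for a global atom pair; 0 if excluded."""
        if a1.mol_instance != a2.mol_instance:
            return 1.0, 1.0
        key = frozenset((a1.local_index, a2.local_index))
        if key in self._mol_pairs(a1.molecule):
            return self.topology.fudge_qq, self.topology.fudge_lj
        if key in self._mol_exclusions(a1.molecule):
            return 0.0, 0.0
        return 1.0, 1.0

    def _build_qm_pairs(self) -> None:
        reg = self.region
        n = reg.n_atoms
        pairs = []
        for s1 in range(n):
            for s2 in range(s1 + 1, n):
                a1 = reg.atom_records[s1]
                a2 = reg.atom_records[s2]
                qq, lj = self._pair_scale(a1, a2)
                if qq == 0.0 and lj == 0.0:
                    continue
                s, e = _combine_lj(*self.topology.lj_parameters(a1.type),
                                   *self.topology.lj_parameters(a2.type),
                                   self.topology.comb_rule)
                pairs.append((s1, s2, qq, lj, s, e))
        self._qm_pairs = pairs

    # -- SR lookup ---------------------------------------------------------
    def _sr_tables(self, sr_indices: np.ndarray):
        q = np.zeros(sr_indices.size)
        sig = np.zeros(sr_indices.size)
        eps = np.zeros(sr_indices.size)
        recs = []
        for m, gid in enumerate(sr_indices):
            a = self._by_gid.get(int(gid))
            recs.append(a)
            if a is None:
                continue  # inert probe point
            q[m] = a.charge
            s, e = self.topology.lj_parameters(a.type)
            sig[m] = s
            eps[m] = e
        return q, sig, eps, recs

    # -- evaluation --------------------------------------------------------
    def _rf_terms(self):
        if self.rf_epsilon is None or self.cutoff is None:
            return 0.0, 0.0
        rc = self.cutoff
        krf = (self.rf_epsilon - 1.0) / (2.0 * self.rf_epsilon + 1.0) / rc ** 3
        crf = 1.0 / rc + krf * rc ** 2
        return krf, crf

    def forces(self, snapshot: Snapshot) -> np.ndarray:
        f, _ = self._eval(snapshot, want_energy=False)
        return f

    def energy(self, snapshot: Snapshot) -> float:
        _, e = self._eval(snapshot, want_energy=True)
        return e

    def _eval(self, snapshot: Snapshot, want_energy: bool):
        # snapshot.qm_positions must follow region slot order (ascending
        # global index); nonbonded_force_set handles reordering for datasets
        # whose qm_atom_ids are stored in a different order.
        reg = self.region
        pos = snapshot.qm_positions
        box = snapshot.box
        krf, crf = self._rf_terms()
        f = np.zeros_like(pos)
        energy = 0.0

        def mi(delta):
            if box is None:
                return delta
            return delta - box * np.round(delta / box)

        # QM-QM
        for s1, s2, qq, lj, sig, eps in self._qm_pairs:
            d = mi(pos[s2] - pos[s1])
            r2 = float(d @ d)
            r = np.sqrt(r2)
            if r < _OVERLAP_NM:
                raise GeometryError(
                    f"overlapping QM atoms {reg.index_maps.global_of(s1)} and "
                    f"{reg.index_maps.global_of(s2)} (r={r:.2e} nm)")
            qqk = KC * self.q[s1] * self.q[s2] * qq
            fmag = qqk / (r2 * r)   # -dV/dr / r for plain Coulomb
            if eps > 0.0 and lj > 0.0:
                sr6 = (sig / r) ** 6
                fmag += lj * 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
            fv = fmag * d
            f[s2] += fv
            f[s1] -= fv
            if want_energy:
                energy += qqk / r
                if eps > 0.0 and lj > 0.0:
                    sr6 = (sig / r) ** 6
                    energy += lj * 4.0 * eps * (sr6 * sr6 - sr6)

        # QM-SR
        q_sr, sig_sr, eps_sr, recs = self._sr_tables(snapshot.sr_indices)
        for s1 in range(reg.n_atoms):
            a1 = reg.atom_records[s1]
            d = mi(snapshot.sr_positions - pos[s1])      # (M, 3)
            r2 = np.einsum("mi,mi->m", d, d)
            r = np.sqrt(r2)
            active = np.ones(r.size, bool)
            if self.cutoff is not None:
                active &= r <= self.cutoff
            qq_scale = np.ones(r.size)
            lj_scale = np.ones(r.size)
            for m, a2 in enumerate(recs):
                if a2 is None:
                    active[m] = False
                    continue
                qs, ls = self._pair_scale(a1, a2)
                qq_scale[m] = qs
                lj_scale[m] = ls
            if not active.any():
                continue
            rs = r[active]
            if np.any(rs < _OVERLAP_NM):
                bad = snapshot.sr_indices[active][rs < _OVERLAP_NM][0]
                raise GeometryError(
                    f"QM atom {a1.global_index} overlaps SR atom {bad}")
            dv = d[active]
            qqk = KC * self.q[s1] * q_sr[active] * qq_scale[active]
            fmag = qqk / (r2[active] * rs)
            if krf:
                fmag = qqk * (1.0 / (r2[active] * rs) - 2.0 * krf)
            epair = np.zeros(rs.size)
            if want_energy:
                if krf:
                    epair += qqk * (1.0 / rs + krf * rs ** 2 - crf)
                else:
                    epair += qqk / rs
            has_lj = (eps_sr[active] > 0.0) & (lj_scale[active] > 0.0)
            if has_lj.any():
                sm = _combine_lj(
                    np.full(rs.size, self.topology.lj_parameters(a1.type)[0]),
                    np.full(rs.size, self.topology.lj_parameters(a1.type)[1]),
                    sig_sr[active], eps_sr[active], self.topology.comb_rule)
                sij, eij = sm
                sr6 = np.where(has_lj, (sij / rs) ** 6, 0.0)
                fmag = fmag + lj_scale[active] * 24.0 * eij * \
                    (2.0 * sr6 * sr6 - sr6) / r2[active]
                if want_energy:
                    epair += lj_scale[active] * 4.0 * eij * (sr6 * sr6 - sr6)
            # force on QM atom s1 from fixed SR atoms: -dV/dpos[s1]
            f[s1] -= (fmag[:, None] * dv).sum(axis=0)
            if want_energy:
                energy += float(epair.sum())
        return f, energy


def nonbonded_forces(snapshot: Snapshot, topology: Topology, charges,
                     cutoff: Optional[float] = None, *,
                     region: Optional[QMRegion] = None,
                     rf_epsilon: Optional[float] = None) -> np.ndarray:
    """Coulomb + LJ forces on the QM atoms for one snapshot.

    ``charges`` is a ChargeSet (its ``atom_ids`` identify the QM atoms) or a
    bare array combined with an explicit ``region``.
    """
    q, region = _charges_and_region(charges, region, topology)
    model = NonbondedModel(topology, region, q, cutoff, rf_epsilon)
    return model.forces(snapshot)


def nonbonded_energy(snapshot: Snapshot, topology: Topology, charges,
                     cutoff: Optional[float] = None, *,
                     region: Optional[QMRegion] = None,
                     rf_epsilon: Optional[float] = None) -> float:
    q, region = _charges_and_region(charges, region, topology)
    model = NonbondedModel(topology, region, q, cutoff, rf_epsilon)
    return model.energy(snapshot)


def _charges_and_region(charges, region, topology):
    from .topology import select_qm_region
    if hasattr(charges, "q") and hasattr(charges, "atom_ids"):
        q = np.asarray(charges.q, float)
        if region is None:
            ids = " ".join(str(int(i)) for i in charges.atom_ids)
            region = select_qm_region(topology, None, f"index {ids}")
        order = region.index_maps.dataset_order(charges.atom_ids)
        qs = np.empty_like(q)
        qs[order] = q
        return qs, region
    if region is None:
        raise ValueError("bare charge arrays require an explicit region")
    return np.asarray(charges, float), region


def nonbonded_force_set(dataset: FMDataSet, topology: Topology, charges,
                        cutoff: Optional[float] = None, *,
                        region: Optional[QMRegion] = None,
                        rf_epsilon: Optional[float] = None) -> ForceSet:
    """Nonbonded forces for every snapshot, in dataset atom order."""
    q, region = _charges_and_region(charges, region, topology)
    model = NonbondedModel(topology, region, q, cutoff, rf_epsilon)
    order = region.index_maps.dataset_order(dataset.qm_atom_ids)
    out = np.empty((len(dataset), dataset.n_qm, 3))
    for l in range(len(dataset)):
        snap = dataset.get_snapshot(l)
        # reorder snapshot QM arrays into region slots, evaluate, map back
        pos_slots = np.empty_like(snap.qm_positions)
        pos_slots[order] = snap.qm_positions
        aligned = Snapshot(index=snap.index, qm_positions=pos_slots,
                           qm_forces=np.zeros_like(pos_slots),
                           sr_indices=snap.sr_indices,
                           sr_positions=snap.sr_positions,
                           sr_potential=snap.sr_potential,
                           sr_field=snap.sr_field, box=snap.box)
        f_slots = model.forces(aligned)
        out[l] = f_slots[order]
    return ForceSet(out, component="nonbonded")


# ---------------------------------------------------------------------------
# external force-trajectory import

def write_force_trajectory(forces: ForceSet, path, units: str = "internal") -> None:
    """Write a force trajectory; JSON frame format, or TRR when the path
    ends in .trr (via MDAnalysis)."""
    path = Path(path)
    if path.suffix.lower() == ".trr":
        _write_trr(forces, path)
        return
    obj = {"units": units, "frames": forces.forces.tolist()}
    path.write_text(json.dumps(obj))


def import_nonbonded_forces(force_trajectory, region: QMRegion,
                            expected_frames: Optional[int] = None) -> ForceSet:
    """Extract per-frame QM-atom forces from an externally computed
    nonbonded force trajectory (e.g. a mesh-Ewald rerun).

    Frames holding the full system are sliced down to the QM atoms by
    global index; frames holding exactly the QM atoms are taken as-is.
    """
    path = Path(force_trajectory)
    if path.suffix.lower() == ".trr":
        frames = _read_trr_forces(path)
    else:
        obj = json.loads(path.read_text())
        frames = np.asarray(obj["frames"], float)
        if obj.get("units", "internal") not in ("internal", "gromacs"):
            from .units import conversion_factors
            frames = frames * conversion_factors(obj["units"])["force"]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected (frames, atoms, 3) forces")
    if expected_frames is not None and frames.shape[0] != expected_frames:
        raise ValueError(
            f"{path}: {frames.shape[0]} frames but {expected_frames} snapshots")
    n_atoms = frames.shape[1]
    n_qm = region.n_atoms
    if n_atoms == n_qm:
        out = frames
    elif n_atoms >= int(region.qm_atom_ids.max()):
        out = frames[:, region.qm_atom_ids - 1, :]
    else:
        raise ValueError(
            f"{path}: frames have {n_atoms} atoms, fewer than the largest "
            f"QM index {int(region.qm_atom_ids.max())}")
    return ForceSet(np.array(out, float), component="nonbonded")


def _write_trr(forces: ForceSet, path) -> None:
    import MDAnalysis as mda
    n = forces.forces.shape[1]
    with mda.coordinates.TRR.TRRWriter(str(path), n_atoms=n) as w:
        u = mda.Universe.empty(n, trajectory=True, forces=True)
        for frame in forces.forces:
            u.atoms.positions = np.zeros((n, 3), dtype=np.float32)
            # MDAnalysis uses kJ/mol/A; internal forces are kJ/mol/nm
            u.atoms.forces = (frame / 10.0).astype(np.float32)
            u.trajectory.ts.frame += 1
            w.write(u.atoms)


def _read_trr_forces(path) -> np.ndarray:
    import MDAnalysis as mda
    reader = mda.coordinates.TRR.TRRReader(str(path))
    frames = []
    for ts in reader:
        if not ts.has_forces:
            raise ValueError(f"{path}: frame {ts.frame} carries no forces")
        frames.append(np.asarray(ts.forces, float) * 10.0)  # kJ/mol/A -> nm
    reader.close()
    return np.asarray(frames)
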