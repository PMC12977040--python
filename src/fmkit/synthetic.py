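"""Self-consistent synthetic reference data from known force fields.

Stands in for the QM/MM producer: configurations are sampled by Gaussian
perturbation around an equilibrium geometry, reference forces are computed
from a known (true) force field with the package's own engine, and
potentials/fields at probe points are computed from the known charges with
the same electrostatics used during fitting.  With zero noise every stored
quantity is exactly reproducible from the stored positions and the truth
parameters, so charge and bonded-parameter fits can be validated by
recovery.

Templates:

* ``diatomic``           2 atoms, 1 bond
* ``triatomic``          water-like, 2 bonds + 1 angle
* ``butane``             4-site chain: 3 bonds, 2 angles, 1 proper dihedral
* ``acetone``            10 atoms with two equivalent methyl groups
                         (6 equivalent H, 2 equivalent C), plus an improper
* ``chain``              linear zig-zag of ``chain_length`` distinct-type
                         atoms, bonds + angles only

SR probe points are massless charge probes with no LJ type; their global
indices lie beyond the topology so the nonbonded engine treats them as
inert, unless ``sr_charge`` is nonzero, in which case real probe particles
are appended to the topology and contribute nonbonded forces on the QM
atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .refdata import FMDataSet, Snapshot
from .topology import Topology, QMRegion, parse_topology_string, select_qm_region
from .dresp import electrostatics_from_charges
from . import engine
from .topology import BondedTerm

__all__ = ["ToySystemSpec", "ToySystem", "SampledConfigurations",
           "make_toy_system", "sample_configurations",
           "generate_reference_data"]

_TEMPLATE_ALIASES = {
    "diatomic": "diatomic",
    "triatomic": "triatomic", "water-like": "triatomic", "water": "triatomic",
    "butane": "butane", "butane-like": "butane",
    "acetone": "acetone", "acetone-like": "acetone",
    "chain": "chain",
}


@dataclass
class ToySystemSpec:
    """Study conditions for one synthetic system.

    ``noise`` holds relative Gaussian noise levels for (V, E, F); the
    defaults (no noise, 50 probes in a 0.5-1.0 nm shell) are the standard
    fixture conditions used throughout the test suite.
    """

    template: str = "triatomic"
    chain_length: int = 6
    n_sr_probes: int = 50
    sr_shell: Tuple[float, float] = (0.5, 1.0)   # nm
    noise: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    sr_charge: float = 0.0
    seed: int = 2025


@dataclass
class SampledConfigurations:
    qm_positions: np.ndarray   # (L, N, 3)
    sr_positions: np.ndarray   # (L, M, 3)


@dataclass
class ToySystem:
    spec: ToySystemSpec
    topology: Topology
    equilibrium_positions: np.ndarray   # (N, 3), molecule atoms only
    true_charges: np.ndarray            # per molecule atom [e]

    _region: Optional[QMRegion] = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return self.equilibrium_positions.shape[0]

    @property
    def region(self) -> QMRegion:
        if self._region is None:
            self._region = select_qm_region(self.topology, None, "resname MOL")
        return self._region

    def truth_terms(self) -> List[BondedTerm]:
        """Bonded terms with true parameters, indexed by QM slot."""
        return [BondedTerm(ft.kind, ft.slots, ft.funct, list(ft.params))
                for ft in self.region.fittable]


# ---------------------------------------------------------------------------
# geometry helpers

def _place(a, b, c, r, theta_deg, phi_deg):
    """NeRF placement: new atom D bonded to c (length r), angle D-c-b, and
    dihedral D-c-b-a."""
    theta = np.deg2rad(theta_deg)
    phi = np.deg2rad(phi_deg)
    b1 = b - a
    b2 = c - b
    bc = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(theta),
                  r * np.sin(theta) * np.cos(phi),
                  r * np.sin(theta) * np.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _distance(p, i, j):
    return float(np.linalg.norm(p[j] - p[i]))


def _angle_deg(p, i, j, k):
    a = p[i] - p[j]
    b = p[k] - p[j]
    cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cos, -1, 1))))


def _dihedral_deg(p, i, j, k, l):
    b1, b2, b3 = p[j] - p[i], p[k] - p[j], p[l] - p[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.cross(n1, n2) @ b2 / np.linalg.norm(b2)
    x = n1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def _zigzag(n: int, b0: float, theta0_deg: float) -> np.ndarray:
    half = np.deg2rad(180.0 - theta0_deg) / 2.0
    pos = np.zeros((n, 3))
    for i in range(1, n):
        sign = 1.0 if i % 2 else -1.0
        step = b0 * np.array([np.cos(half), sign * np.sin(half), 0.0])
        pos[i] = pos[i - 1] + step
    return pos


# ---------------------------------------------------------------------------
# templates: (atoms, positions, bonds, angles, dihedrals, lj, nrexcl)
# atoms: (name, type, charge, mass); bonds: (i, j, kb); angles: (i, j, k, kth)
# dihedrals: (atoms..., funct, params)

def _template_diatomic(spec):
    atoms = [("A1", "XA", 0.2, 12.0), ("B1", "XB", -0.2, 16.0)]
    pos = np.array([[0.0, 0.0, 0.0], [0.11, 0.0, 0.0]])
    return atoms, pos, [(0, 1, 2.5e5)], [], [], \
        {"XA": (0.30, 0.50, 12.0), "XB": (0.31, 0.40, 16.0)}, 3


def _template_triatomic(spec):
    atoms = [("OW", "OT", -0.8, 16.0), ("HW1", "HT", 0.4, 1.008),
             ("HW2", "HT", 0.4, 1.008)]
    b0, th0 = 0.09572, 104.52
    pos = np.array([
        [0.0, 0.0, 0.0],
        [b0, 0.0, 0.0],
        [b0 * np.cos(np.deg2rad(th0)), b0 * np.sin(np.deg2rad(th0)), 0.0]])
    bonds = [(0, 1, 4.6e5), (0, 2, 4.6e5)]
    angles = [(1, 0, 2, 383.0)]
    return atoms, pos, bonds, angles, [], \
        {"OT": (0.3166, 0.65, 16.0), "HT": (0.12, 0.05, 1.008)}, 3


def _template_butane(spec):
    atoms = [(f"C{i+1}", "CT", q, 14.0)
             for i, q in enumerate((0.08, -0.08, -0.08, 0.08))]
    pos = _zigzag(4, 0.153, 111.0)
    bonds = [(0, 1, 2.2e5), (1, 2, 2.2e5), (2, 3, 2.2e5)]
    angles = [(0, 1, 2, 530.0), (1, 2, 3, 530.0)]
    dihedrals = [((0, 1, 2, 3), 1, [0.0, 5.9, 3])]
    return atoms, pos, bonds, angles, dihedrals, \
        {"CT": (0.35, 0.45, 14.0)}, 3


def _template_acetone(spec):
    # C2 carbonyl carbon at origin; O along +x; methyl carbons in the plane
    d_co, d_cc, d_ch = 0.1229, 0.1522, 0.109
    theta_occ = 122.0
    pos = np.zeros((10, 3))
    pos[1] = [d_co, 0.0, 0.0]                       # O
    a = np.deg2rad(theta_occ)
    pos[2] = d_cc * np.array([np.cos(a), np.sin(a), 0.0])    # CT1
    pos[3] = d_cc * np.array([np.cos(a), -np.sin(a), 0.0])   # CT2
    h = 4
    for ct in (2, 3):
        for phi in (60.0, 180.0, 300.0):
            pos[h] = _place(pos[1], pos[0], pos[ct], d_ch, 109.5, phi)
            h += 1
    atoms = [("C", "CK", 0.55, 12.0), ("O", "OK", -0.45, 16.0),
             ("CT1", "CM", -0.23, 12.0), ("CT2", "CM", -0.23, 12.0)]
    atoms += [(f"H{i+1}", "HM", 0.06, 1.008) for i in range(6)]
    bonds = [(0, 1, 4.76e5), (0, 2, 2.65e5), (0, 3, 2.65e5)]
    bonds += [(2, 4 + i, 2.84e5) for i in range(3)]
    bonds += [(3, 7 + i, 2.84e5) for i in range(3)]
    angles = [(1, 0, 2, 670.0), (1, 0, 3, 670.0), (2, 0, 3, 590.0)]
    angles += [(0, 2, 4 + i, 390.0) for i in range(3)]
    angles += [(0, 3, 7 + i, 390.0) for i in range(3)]
    angles += [(4, 2, 5, 330.0), (4, 2, 6, 330.0), (5, 2, 6, 330.0)]
    angles += [(7, 3, 8, 330.0), (7, 3, 9, 330.0), (8, 3, 9, 330.0)]
    dihedrals = [((1, 0, 2, 4 + i), 1, [0.0, 0.65, 3]) for i in range(3)]
    dihedrals += [((1, 0, 3, 7 + i), 1, [0.0, 0.65, 3]) for i in range(3)]
    # improper keeping the carbonyl centre planar; xi0 measured from geometry
    xi0 = _dihedral_deg(pos, 2, 3, 0, 1)
    dihedrals += [((2, 3, 0, 1), 2, [xi0, 40.0])]
    lj = {"CK": (0.34, 0.36, 12.0), "OK": (0.296, 0.88, 16.0),
          "CM": (0.34, 0.46, 12.0), "HM": (0.265, 0.066, 1.008)}
    return atoms, pos, bonds, angles, dihedrals, lj, 3


def _template_chain(spec):
    n = spec.chain_length
    if n < 2:
        raise ValueError("chain template needs at least 2 atoms")
    pos = _zigzag(n, 0.15, 111.0)
    q = np.array([0.1 * (-1) ** i for i in range(n)])
    q -= q.mean()      # neutral by construction
    atoms = [(f"X{i+1}", f"T{i+1}", float(q[i]), 12.0) for i in range(n)]
    bonds = [(i, i + 1, 2.5e5) for i in range(n - 1)]
    angles = [(i, i + 1, i + 2, 450.0) for i in range(n - 2)]
    lj = {f"T{i+1}": (0.33, 0.40, 12.0) for i in range(n)}
    return atoms, pos, bonds, angles, [], lj, 3


_TEMPLATES = {
    "diatomic": _template_diatomic,
    "triatomic": _template_triatomic,
    "butane": _template_butane,
    "acetone": _template_acetone,
    "chain": _template_chain,
}


def _pairs_at_distance_3(bonds, n: int) -> List[Tuple[int, int]]:
    adj = {i: set() for i in range(n)}
    for i, j, _ in bonds:
        adj[i].add(j)
        adj[j].add(i)
    pairs = []
    for start in range(n):
        dist = {start: 0}
        frontier = [start]
        for d in (1, 2, 3):
            nxt = []
            for f in frontier:
                for nb in adj[f]:
                    if nb not in dist:
                        dist[nb] = d
                        nxt.append(nb)
            frontier = nxt
        pairs.extend((start, j) for j, d in dist.items()
                     if d == 3 and start < j)
    return sorted(pairs)


def make_toy_system(spec: ToySystemSpec) -> ToySystem:
    """Build a toy system: a GROMACS-dialect topology (round-tripped through
    the topology parser, so its dialect validity is checked at construction)
    plus an equilibrium geometry that satisfies every b0/theta0 exactly
    (equilibrium values are measured from the constructed geometry)."""
    key = _TEMPLATE_ALIASES.get(spec.template)
    if key is None:
        raise ValueError(f"unknown template {spec.template!r}; "
                         f"known: {sorted(set(_TEMPLATE_ALIASES))}")
    atoms, pos, bonds, angles, dihedrals, lj, nrexcl = _TEMPLATES[key](spec)
    n = len(atoms)
    pairs = _pairs_at_distance_3(bonds, n)

    lines = ["[ defaults ]", "1 2 yes 0.5 0.8333", "", "[ atomtypes ]"]
    for t, (sigma, eps, mass) in lj.items():
        lines.append(f"{t} {mass:.6f} 0.0 A {sigma:.8g} {eps:.8g}")
    lines += ["", "[ moleculetype ]", f"MOL {nrexcl}", "", "[ atoms ]"]
    for i, (name, type_, charge, mass) in enumerate(atoms):
        lines.append(f"{i+1} {type_} 1 MOL {name} {i+1} "
                     f"{charge:.10f} {mass:.6f}")
    if bonds:
        lines += ["", "[ bonds ]"]
        for i, j, kb in bonds:
            lines.append(f"{i+1} {j+1} 1 {_distance(pos, i, j):.12g} {kb:.12g}")
    if pairs:
        lines += ["", "[ pairs ]"]
        for i, j in pairs:
            lines.append(f"{i+1} {j+1} 1")
    if angles:
        lines += ["", "[ angles ]"]
        for i, j, k, kth in angles:
            lines.append(f"{i+1} {j+1} {k+1} 1 "
                         f"{_angle_deg(pos, i, j, k):.12g} {kth:.12g}")
    if dihedrals:
        lines += ["", "[ dihedrals ]"]
        for idx, funct, params in dihedrals:
            lines.append(" ".join(str(x + 1) for x in idx) + f" {funct} "
                         + " ".join(f"{p:.12g}" for p in params))
    lines += ["", "[ system ]", "fmkit toy system", "", "[ molecules ]",
              "MOL 1"]
    if spec.sr_charge != 0.0:
        lines = _add_probe_molecules(lines, spec)
    topology = parse_topology_string("\n".join(lines) + "\n")
    charges = np.array([a[2] for a in atoms])
    return ToySystem(spec=spec, topology=topology,
                     equilibrium_positions=pos, true_charges=charges)


def _add_probe_molecules(lines: List[str], spec: ToySystemSpec) -> List[str]:
    at_idx = lines.index("[ moleculetype ]")
    lines = (lines[:at_idx]
             + ["[ moleculetype ]", "PRB 1", "", "[ atoms ]",
                f"1 PT 1 PRB P 1 {spec.sr_charge:.10f} 1.0", ""]
             + lines[at_idx:])
    at_idx = lines.index("[ atomtypes ]")
    lines.insert(at_idx + 1, "PT 1.0 0.0 A 0.0 0.0")
    lines.append(f"PRB {spec.n_sr_probes}")
    return lines


def sample_configurations(system: ToySystem, n: int, amplitude: float = 0.005,
                          seed: int = 0) -> SampledConfigurations:
    """Gaussian displacements around equilibrium plus fresh probe positions.

    Atom displacements are i.i.d. normal with standard deviation
    ``amplitude`` per coordinate; probe points are drawn uniformly in the
    spherical shell ``spec.sr_shell`` around the equilibrium centroid.
    Snapshots creating interatomic overlaps (< 0.03 nm) are resampled, with
    a cap.
    """
    if n < 1:
        raise ValueError("need n >= 1 snapshots")
    spec = system.spec
    eq = system.equilibrium_positions
    center = eq.mean(axis=0)
    extent = float(np.max(np.linalg.norm(eq - center, axis=1)))
    r_in, r_out = spec.sr_shell
    if not (r_out > r_in > extent):
        raise ValueError(
            f"sr_shell {spec.sr_shell} must satisfy outer > inner > "
            f"molecular extent ({extent:.3f} nm)")
    rng = np.random.default_rng(seed)
    N = eq.shape[0]
    qm = np.empty((n, N, 3))
    for l in range(n):
        for attempt in range(1000):
            trial = eq + rng.normal(0.0, amplitude, size=(N, 3))
            d = trial[:, None, :] - trial[None, :, :]
            r = np.sqrt((d ** 2).sum(-1)) + np.eye(N)
            if r.min() > 0.03:
                qm[l] = trial
                break
        else:
            raise RuntimeError(
                f"could not sample snapshot {l} without atomic overlaps; "
                f"amplitude {amplitude} nm is too large")
    M = spec.n_sr_probes
    u = rng.random((n, M))
    radius = (u * (r_out ** 3 - r_in ** 3) + r_in ** 3) ** (1.0 / 3.0)
    v = rng.normal(size=(n, M, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    sr = center + radius[..., None] * v
    return SampledConfigurations(qm_positions=qm, sr_positions=sr)


def generate_reference_data(system: ToySystem,
                            configurations: SampledConfigurations,
                            noise: Optional[Tuple[float, float, float]] = None,
                            seed: int = 0) -> FMDataSet:
    """Reference forces/potentials/fields from the truth parameters.

    qm_forces = bonded(true tau) + nonbonded(true q); sr_potential/sr_field
    from the true charges via the same electrostatics the charge fit uses.
    Optional multiplicative Gaussian noise at the stated relative levels for
    (V, E, F).
    """
    spec = system.spec
    noise = spec.noise if noise is None else noise
    rng = np.random.default_rng(seed)
    region = system.region
    model = engine.NonbondedModel(system.topology, region,
                                  system.true_charges)
    truth_terms = system.truth_terms()
    qm = configurations.qm_positions
    sr = configurations.sr_positions
    L, N, _ = qm.shape
    M = sr.shape[1]
    f_bonded = (engine.bonded_forces(qm, truth_terms)
                if truth_terms else np.zeros_like(qm))
    sr_ids = np.arange(N + 1, N + M + 1)
    snaps = []
    for l in range(L):
        V, E = electrostatics_from_charges(system.true_charges, qm[l], sr[l])
        probe = Snapshot(index=l, qm_positions=qm[l],
                         qm_forces=np.zeros((N, 3)), sr_indices=sr_ids,
                         sr_positions=sr[l], sr_potential=V, sr_field=E)
        forces = f_bonded[l] + model.forces(probe)
        sV, sE, sF = noise
        if sV:
            V = V * (1.0 + sV * rng.standard_normal(V.shape))
        if sE:
            E = E * (1.0 + sE * rng.standard_normal(E.shape))
        if sF:
            forces = forces * (1.0 + sF * rng.standard_normal(forces.shape))
        snaps.append(Snapshot(index=l, qm_positions=qm[l], qm_forces=forces,
                              sr_indices=sr_ids, sr_positions=sr[l],
                              sr_potential=V, sr_field=E))
    ds = FMDataSet(snapshots=snaps, qm_atom_ids=np.arange(1, N + 1),
                   units="internal")
    ds.validate()
    return ds
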