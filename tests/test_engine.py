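import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmkit.engine import (ForceSet, GeometryError, NonbondedModel,
                          bonded_energy, bonded_forces,
                          import_nonbonded_forces, nonbonded_energy,
                          nonbonded_forces, write_force_trajectory)
from fmkit.refdata import Snapshot
from fmkit.synthetic import ToySystemSpec, make_toy_system
from fmkit.topology import BondedTerm, parse_topology_string
from fmkit.units import KC

ALL_TERMS = [
    BondedTerm("bond", (0, 1), 1, [0.15, 2.5e5]),
    BondedTerm("angle", (0, 1, 2), 1, [109.5, 450.0]),
    BondedTerm("dihedral_periodic", (0, 1, 2, 3), 1, [30.0, 5.9, 3]),
    BondedTerm("dihedral_RB", (0, 1, 2, 3), 3,
               [9.28, 12.16, -13.12, -3.06, 3.54, 0.0]),
    BondedTerm("improper", (0, 1, 2, 3), 2, [35.0, 40.0]),
]


def _numerical_forces(pos, terms, h=1e-6):
    num = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for d in range(3):
            pp, pm = pos.copy(), pos.copy()
            pp[i, d] += h
            pm[i, d] -= h
            num[i, d] = -(bonded_energy(pp, terms)
                          - bonded_energy(pm, terms)) / (2 * h)
    return num


# ---------------------------------------------------------------------------
# bonded closed forms

def test_bond_at_equilibrium_has_zero_force():
    term = BondedTerm("bond", (0, 1), 1, [0.15, 2.5e5])
    pos = np.array([[0.0, 0.0, 0.0], [0.15, 0.0, 0.0]])
    np.testing.assert_allclose(bonded_forces(pos, [term]), 0.0, atol=1e-10)


def test_stretched_bond_restoring_force():
    kb, b0, delta = 2.5e5, 0.15, 0.004
    term = BondedTerm("bond", (0, 1), 1, [b0, kb])
    pos = np.array([[0.0, 0.0, 0.0], [b0 + delta, 0.0, 0.0]])
    f = bonded_forces(pos, [term])
    np.testing.assert_allclose(f[1], [-kb * delta, 0.0, 0.0], rtol=1e-12)
    np.testing.assert_allclose(f[0], -f[1], rtol=1e-12)


@pytest.mark.parametrize("term", ALL_TERMS, ids=lambda t: t.kind)
def test_forces_match_numerical_gradient(term):
    """Analytical force = -grad(energy) on random geometries for every
    supported functional form."""
    rng = np.random.default_rng(7)
    n = max(term.atoms) + 1
    checked = 0
    while checked < 30:
        pos = rng.normal(0, 0.2, (n, 3))
        try:
            f = bonded_forces(pos, [term])
        except GeometryError:
            continue
        num = _numerical_forces(pos, [term])
        scale = max(np.abs(num).max(), 1e-10)
        assert np.abs(f - num).max() / scale <= 1e-5
        checked += 1


@pytest.mark.parametrize("term", ALL_TERMS, ids=lambda t: t.kind)
def test_per_term_force_sum_and_torque_vanish(term):
    rng = np.random.default_rng(8)
    n = max(term.atoms) + 1
    for _ in range(20):
        pos = rng.normal(0, 0.2, (n, 3))
        try:
            f = bonded_forces(pos, [term])
        except GeometryError:
            continue
        assert np.abs(f.sum(axis=0)).max() <= 1e-10
        centroid = pos.mean(axis=0)
        torque = np.cross(pos - centroid, f).sum(axis=0)
        assert np.abs(torque).max() <= 1e-8


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_translation_and_rotation_equivariance(seed):
    rng = np.random.default_rng(seed)
    pos = rng.normal(0, 0.2, (4, 3))
    try:
        f = bonded_forces(pos, ALL_TERMS)
    except GeometryError:
        return
    shift = rng.normal(0, 5.0, 3)
    np.testing.assert_allclose(bonded_forces(pos + shift, ALL_TERMS), f,
                               atol=1e-12 + 1e-12 * np.abs(f).max())
    # random rotation via QR
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    f_rot = bonded_forces(pos @ Q.T, ALL_TERMS)
    np.testing.assert_allclose(f_rot, f @ Q.T, atol=1e-10 * max(1, np.abs(f).max()))


def test_batched_equals_per_frame():
    rng = np.random.default_rng(12)
    pos = rng.normal(0, 0.2, (6, 4, 3))
    batch = bonded_forces(pos, ALL_TERMS)
    for l in range(6):
        np.testing.assert_allclose(batch[l], bonded_forces(pos[l], ALL_TERMS),
                                   rtol=1e-14)


def test_collinear_angle_raises():
    term = BondedTerm("angle", (0, 1, 2), 1, [120.0, 400.0])
    pos = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [0.2, 0.0, 0.0]])
    with pytest.raises(GeometryError, match="collinear"):
        bonded_forces(pos, [term])


def test_unknown_term_kind_rejected():
    with pytest.raises(ValueError, match="unsupported bonded term"):
        bonded_forces(np.zeros((2, 3)),
                      [BondedTerm("morse", (0, 1), 3, [1.0])])


# ---------------------------------------------------------------------------
# nonbonded

TWO_ATOMS = """
[ defaults ]
1 2 yes 0.5 0.8333

[ atomtypes ]
XA {ma} {qa} A {sa} {ea}
XB {mb} {qb} A {sb} {eb}

[ moleculetype ]
M1 0

[ atoms ]
1 XA 1 M1 A 1 {qa} {ma}

[ moleculetype ]
M2 0

[ atoms ]
1 XB 1 M2 B 1 {qb} {mb}

[ system ]
two

[ molecules ]
M1 1
M2 1
"""


def _two_atom_setup(qa, qb, sa=0.0, ea=0.0, sb=0.0, eb=0.0):
    from fmkit.topology import select_qm_region
    text = TWO_ATOMS.format(ma=12.0, mb=12.0, qa=qa, qb=qb, sa=sa, ea=ea,
                            sb=sb, eb=eb)
    top = parse_topology_string(text)
    region = select_qm_region(top, None, "all")
    return top, region


def _snap(pos, sr_pos=None, sr_ids=None, box=None):
    sr_pos = np.empty((0, 3)) if sr_pos is None else np.asarray(sr_pos, float)
    m = sr_pos.shape[0]
    return Snapshot(index=0, qm_positions=pos,
                    qm_forces=np.zeros((np.asarray(pos).shape[0], 3)),
                    sr_indices=np.arange(100, 100 + m) if sr_ids is None
                    else sr_ids,
                    sr_positions=sr_pos, sr_potential=np.zeros(m),
                    sr_field=np.zeros((m, 3)), box=box)


def test_uncharged_epsilonless_atoms_feel_nothing():
    top, region = _two_atom_setup(0.0, 0.0)
    f = nonbonded_forces(_snap(np.array([[0.0, 0, 0], [0.4, 0, 0]])), top,
                        region.original_charges(), region=region)
    np.testing.assert_allclose(f, 0.0)


def test_two_point_charges_coulomb_closed_form():
    top, region = _two_atom_setup(0.3, -0.5)
    r = 0.47
    f = nonbonded_forces(_snap(np.array([[0.0, 0, 0], [r, 0, 0]])), top,
                        region.original_charges(), region=region)
    expected = KC * 0.3 * (-0.5) / r ** 2
    np.testing.assert_allclose(f[1, 0], expected, rtol=1e-12)   # attractive
    np.testing.assert_allclose(f[0], -f[1], rtol=1e-12)


def test_lj_force_zero_at_minimum():
    sigma = 0.34
    top, region = _two_atom_setup(0.0, 0.0, sa=sigma, ea=0.5, sb=sigma, eb=0.5)
    r = 2 ** (1 / 6) * sigma
    f = nonbonded_forces(_snap(np.array([[0.0, 0, 0], [r, 0, 0]])), top,
                        region.original_charges(), region=region)
    np.testing.assert_allclose(f, 0.0, atol=1e-9)


def test_overlapping_atoms_rejected():
    top, region = _two_atom_setup(0.1, 0.1)
    with pytest.raises(GeometryError, match="overlap"):
        nonbonded_forces(_snap(np.array([[0.0, 0, 0], [1e-7, 0, 0]])), top,
                         region.original_charges(), region=region)


def _naive_nonbonded(top, region, snap, q, cutoff=None):
    """Independent all-pairs oracle applying the same exclusion/scaling
    rules from scratch."""
    atoms = top.expand_atoms()
    by_gid = {a.global_index: a for a in atoms}
    excl = {name: mt.build_exclusions() for name, mt in top.moleculetypes.items()}
    pair_sets = {name: {frozenset(p.atoms) for p in mt.pairs}
                 for name, mt in top.moleculetypes.items()}
    slots = {int(g): s for s, g in enumerate(region.qm_atom_ids)}
    n = region.n_atoms
    f = np.zeros((n, 3))

    def scale(a1, a2):
        if a1.mol_instance != a2.mol_instance:
            return 1.0, 1.0
        key = frozenset((a1.local_index, a2.local_index))
        if key in pair_sets[a1.molecule]:
            return top.fudge_qq, top.fudge_lj
        if key in excl[a1.molecule]:
            return 0.0, 0.0
        return 1.0, 1.0

    def add(i_slot, pi, pj, qi, qj, ti, tj, qqs, ljs, one_sided):
        d = pj - pi
        r = np.linalg.norm(d)
        if cutoff is not None and one_sided and r > cutoff:
            return
        fmag = KC * qi * qj * qqs / r ** 3
        s1, e1 = top.lj_parameters(ti)
        s2, e2 = top.lj_parameters(tj)
        sij, eij = 0.5 * (s1 + s2), np.sqrt(e1 * e2)
        if eij > 0 and ljs > 0:
            sr6 = (sij / r) ** 6
            fmag += ljs * 24 * eij * (2 * sr6 ** 2 - sr6) / r ** 2
        f[i_slot] -= fmag * d

    qm_ids = [int(g) for g in region.qm_atom_ids]
    for gi in qm_ids:
        ai = by_gid[gi]
        pi = snap.qm_positions[slots[gi]]
        for gj in qm_ids:
            if gi == gj:
                continue
            aj = by_gid[gj]
            qqs, ljs = scale(ai, aj)
            add(slots[gi], pi, snap.qm_positions[slots[gj]],
                q[slots[gi]], q[slots[gj]], ai.type, aj.type, qqs, ljs, False)
        for m, gj in enumerate(snap.sr_indices):
            aj = by_gid.get(int(gj))
            if aj is None:
                continue
            qqs, ljs = scale(ai, aj)
            add(slots[gi], pi, snap.sr_positions[m], q[slots[gi]], aj.charge,
                ai.type, aj.type, qqs, ljs, True)
    return f


def test_nonbonded_matches_all_pairs_oracle():
    """Random acetone + charged SR probes: engine equals a naive double loop
    applying the same exclusion and 1-4 scaling rules."""
    system = make_toy_system(ToySystemSpec(template="acetone", sr_charge=0.25,
                                           n_sr_probes=30))
    top, region = system.topology, system.region
    rng = np.random.default_rng(17)
    pos = system.equilibrium_positions + rng.normal(0, 0.01, (10, 3))
    sr = rng.normal(0, 0.5, (30, 3)) + np.array([2.5, 0, 0])
    snap = _snap(pos, sr, sr_ids=np.arange(11, 41))
    q = system.true_charges
    f = NonbondedModel(top, region, q).forces(snap)
    f_ref = _naive_nonbonded(top, region, snap, q)
    np.testing.assert_allclose(f, f_ref, rtol=1e-10, atol=1e-10)


def test_nonbonded_cutoff_and_minimum_image():
    top, region = _two_atom_setup(0.4, 0.0)
    box = np.array([3.0, 3.0, 3.0])
    # SR probe at 2.8 nm: minimum image distance is 0.2 nm
    sr = np.array([[2.8, 0.0, 0.0]])
    snap = _snap(np.array([[0.0, 0, 0], [0.0, 1.0, 0.0]]), sr,
                 sr_ids=np.array([2]), box=box)
    region1 = __import__("fmkit.topology", fromlist=["select_qm_region"]) \
        .select_qm_region(top, None, "index 1")
    f = nonbonded_forces(snap_one := Snapshot(
        index=0, qm_positions=np.array([[0.0, 0.0, 0.0]]),
        qm_forces=np.zeros((1, 3)), sr_indices=np.array([2]),
        sr_positions=sr, sr_potential=np.zeros(1),
        sr_field=np.zeros((1, 3)), box=box), top, np.array([0.4]),
        cutoff=1.0, region=region1)
    # image at -0.2 nm: repulsive force (0.4 * 0.0 charge ... B has q 0)
    # use charges directly: B charge is 0 -> zero force regardless
    np.testing.assert_allclose(f, 0.0)
    # now with a charged partner
    top2, _ = _two_atom_setup(0.4, 0.3)
    region2 = __import__("fmkit.topology", fromlist=["select_qm_region"]) \
        .select_qm_region(top2, None, "index 1")
    f2 = nonbonded_forces(snap_one, top2, np.array([0.4]), cutoff=1.0,
                          region=region2)
    # like charges, image on the -x side: repulsion pushes the QM atom +x
    expected = KC * 0.4 * 0.3 / 0.2 ** 2
    np.testing.assert_allclose(f2[0, 0], expected, rtol=1e-10)
    # beyond the cutoff nothing survives
    f3 = nonbonded_forces(snap_one, top2, np.array([0.4]), cutoff=0.1,
                          region=region2)
    np.testing.assert_allclose(f3, 0.0)


def test_nonbonded_force_is_energy_gradient_with_rf():
    """Coulomb + LJ + reaction-field: forces equal the numerical gradient of
    the engine's own energy."""
    system = make_toy_system(ToySystemSpec(template="butane", sr_charge=0.2,
                                           n_sr_probes=6))
    model = NonbondedModel(system.topology, system.region,
                           system.true_charges, cutoff=2.0, rf_epsilon=78.0)
    rng = np.random.default_rng(23)
    pos = system.equilibrium_positions + rng.normal(0, 0.01, (4, 3))
    sr = rng.normal(0, 0.3, (6, 3)) + np.array([1.2, 0, 0])
    snap = lambda p: _snap(p, sr, sr_ids=np.arange(5, 11))
    f = model.forces(snap(pos))
    h = 1e-6
    num = np.zeros_like(f)
    for i in range(4):
        for d in range(3):
            pp, pm = pos.copy(), pos.copy()
            pp[i, d] += h
            pm[i, d] -= h
            num[i, d] = -(model.energy(snap(pp)) - model.energy(snap(pm))) / (2 * h)
    np.testing.assert_allclose(f, num, rtol=1e-5, atol=1e-6)


def test_out_of_topology_sr_indices_are_inert_probes():
    top, region = _two_atom_setup(0.3, -0.3)
    sr = np.array([[1.0, 0.0, 0.0]])
    pos = np.array([[0.0, 0, 0], [0.0, 0.5, 0.0]])
    f_probe = nonbonded_forces(_snap(pos, sr, sr_ids=np.array([999])), top,
                               region.original_charges(), region=region)
    f_none = nonbonded_forces(_snap(pos), top, region.original_charges(),
                              region=region)
    np.testing.assert_allclose(f_probe, f_none)


# ---------------------------------------------------------------------------
# force trajectory import

def test_force_import_round_trip(tmp_path, butane_system):
    rng = np.random.default_rng(31)
    fs = ForceSet(rng.normal(0, 100, (3, 4, 3)), component="nonbonded")
    write_force_trajectory(fs, tmp_path / "f.json")
    back = import_nonbonded_forces(tmp_path / "f.json", butane_system.region,
                                   expected_frames=3)
    np.testing.assert_allclose(back.forces, fs.forces, rtol=1e-15)


def test_force_import_frame_mismatch(tmp_path, butane_system):
    fs = ForceSet(np.zeros((3, 4, 3)))
    write_force_trajectory(fs, tmp_path / "f.json")
    with pytest.raises(ValueError, match="3 frames but 4"):
        import_nonbonded_forces(tmp_path / "f.json", butane_system.region,
                                expected_frames=4)


def test_force_import_slices_full_system_frames(tmp_path, butane_system):
    rng = np.random.default_rng(32)
    full = rng.normal(0, 10, (2, 9, 3))     # more atoms than the QM region
    fs = ForceSet(full)
    write_force_trajectory(fs, tmp_path / "f.json")
    back = import_nonbonded_forces(tmp_path / "f.json", butane_system.region)
    np.testing.assert_allclose(
        back.forces, full[:, butane_system.region.qm_atom_ids - 1, :])


def test_force_import_trr_round_trip(tmp_path, butane_system):
    pytest.importorskip("MDAnalysis")
    rng = np.random.default_rng(33)
    fs = ForceSet(rng.normal(0, 100, (3, 4, 3)).astype(np.float32).astype(float))
    write_force_trajectory(fs, tmp_path / "f.trr")
    back = import_nonbonded_forces(tmp_path / "f.trr", butane_system.region,
                                   expected_frames=3)
    np.testing.assert_allclose(back.forces, fs.forces, rtol=1e-5, atol=1e-3)
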