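import numpy as np
import pytest

from fmkit.dresp import (ChargeConservationError, ChargeSet, DRESPWeights,
                         electrostatics_from_charges, grid_search_dresp,
                         redistribute_boundary_charges, solve_dresp,
                         chi_squared)
from fmkit.synthetic import (ToySystemSpec, make_toy_system,
                             sample_configurations, generate_reference_data)
from fmkit.topology import parse_topology_string, select_qm_region
from fmkit.units import KC


# ---------------------------------------------------------------------------
# electrostatics

def test_single_charge_closed_form():
    V, E = electrostatics_from_charges([1.0], [[0.0, 0.0, 0.0]],
                                       [[1.0, 0.0, 0.0]])
    np.testing.assert_allclose(V, [KC])
    np.testing.assert_allclose(E, [[KC, 0.0, 0.0]])


def test_mirror_symmetric_charges_cancel_potential():
    qm = [[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]
    V, E = electrostatics_from_charges([1.0, -1.0], qm, [[0.0, 0.0, 0.0]])
    np.testing.assert_allclose(V, [0.0], atol=1e-12)
    # field from +q at -x and -q at +x both point along +x
    assert E[0, 0] > 0
    np.testing.assert_allclose(E[0, 1:], 0.0, atol=1e-12)


def test_electrostatics_match_double_loop_oracle():
    rng = np.random.default_rng(11)
    q = rng.normal(0, 0.5, 5)
    qm = rng.normal(0, 0.2, (5, 3))
    sr = rng.normal(0, 1.0, (20, 3)) + 3.0
    V, E = electrostatics_from_charges(q, qm, sr)
    V_ref = np.zeros(20)
    E_ref = np.zeros((20, 3))
    for b in range(20):
        for a in range(5):
            d = sr[b] - qm[a]
            r = np.linalg.norm(d)
            V_ref[b] += KC * q[a] / r
            E_ref[b] += KC * q[a] * d / r ** 3
    np.testing.assert_allclose(V, V_ref, rtol=1e-12)
    np.testing.assert_allclose(E, E_ref, rtol=1e-12)


def test_field_is_negative_potential_gradient():
    rng = np.random.default_rng(4)
    q = rng.normal(0, 0.5, 4)
    qm = rng.normal(0, 0.2, (4, 3))
    probe = np.array([[1.5, -0.3, 0.8]])
    _, E = electrostatics_from_charges(q, qm, probe)
    h = 1e-7
    grad = np.zeros(3)
    for d in range(3):
        pp, pm = probe.copy(), probe.copy()
        pp[0, d] += h
        pm[0, d] -= h
        grad[d] = (electrostatics_from_charges(q, qm, pp)[0][0]
                   - electrostatics_from_charges(q, qm, pm)[0][0]) / (2 * h)
    np.testing.assert_allclose(E[0], -grad, rtol=1e-6)


def test_coincident_atoms_rejected():
    with pytest.raises(ValueError, match="coincide"):
        electrostatics_from_charges([1.0], [[0.0, 0.0, 0.0]],
                                    [[0.0, 0.0, 0.0]])


# ---------------------------------------------------------------------------
# solve_dresp

def _truth_weights():
    return DRESPWeights(w_V=1.0, w_E=1.0, w_H=0.0, w_Q=1e6)


def test_exact_charge_recovery(chain5_system, chain5_dataset):
    truth = chain5_system.true_charges
    res = solve_dresp(chain5_dataset, chain5_system.region, _truth_weights(),
                      restraints=truth, Q_tot=float(truth.sum()))
    np.testing.assert_allclose(res.charges.q, truth, atol=1e-8)
    assert abs(res.charges.q.sum() - truth.sum()) <= 1e-8
    assert res.sigma_V < 1e-10 and res.sigma_E < 1e-10


def test_restraint_dominated_limit(chain5_system, chain5_dataset):
    """With w_V = w_E = 0 the minimum is analytically the restraints."""
    rng = np.random.default_rng(5)
    restraints = rng.normal(0, 0.3, 5)
    res = solve_dresp(chain5_dataset, chain5_system.region,
                      DRESPWeights(0.0, 0.0, 10.0, 100.0),
                      restraints=restraints, Q_tot=float(restraints.sum()))
    np.testing.assert_allclose(res.charges.q, restraints, atol=1e-10)


def test_published_protein_weight_set_accepted(chain5_system, chain5_dataset):
    res = solve_dresp(chain5_dataset, chain5_system.region,
                      DRESPWeights(w_V=1.0, w_E=0.1, w_H=100.0, w_Q=100_000.0),
                      restraints=chain5_system.true_charges,
                      Q_tot=float(chain5_system.true_charges.sum()))
    assert np.isfinite(res.chi2) and res.chi2 >= 0
    res.charges.validate()


def test_chi2_not_above_restraint_point(chain5_system, chain5_dataset):
    truth = chain5_system.true_charges
    w = DRESPWeights(1.0, 0.5, 10.0, 1000.0)
    rng = np.random.default_rng(9)
    restraints = truth + rng.normal(0, 0.05, truth.size)
    res = solve_dresp(chain5_dataset, chain5_system.region, w,
                      restraints=restraints, Q_tot=float(truth.sum()))
    chi2_rest = chi_squared(restraints, chain5_dataset, chain5_system.region,
                            w, restraints, float(truth.sum()))
    assert res.chi2 <= chi2_rest + 1e-9


def test_weight_scaling_invariance(chain5_system, chain5_dataset):
    truth = chain5_system.true_charges
    kw = dict(restraints=truth + 0.01, Q_tot=float(truth.sum()))
    r1 = solve_dresp(chain5_dataset, chain5_system.region,
                     DRESPWeights(1.0, 0.5, 2.0, 1e4), **kw)
    r2 = solve_dresp(chain5_dataset, chain5_system.region,
                     DRESPWeights(7.0, 3.5, 14.0, 7e4), **kw)
    np.testing.assert_allclose(r1.charges.q, r2.charges.q, atol=1e-12)


def test_solution_is_local_minimum(chain5_system, chain5_dataset):
    """Perturbing any free variable (re-projecting the total) never
    decreases chi^2."""
    truth = chain5_system.true_charges
    w = DRESPWeights(1.0, 0.3, 5.0, 100.0)
    restraints = truth + 0.02
    Q = float(truth.sum())
    res = solve_dresp(chain5_dataset, chain5_system.region, w,
                      restraints=restraints, Q_tot=Q)
    chi0 = res.chi2
    n = truth.size
    for i in range(n - 1):
        for delta in (1e-4, -1e-4):
            q = res.charges.q.copy()
            q[i] += delta
            q[-1] -= delta      # re-project the total charge
            chi = chi_squared(q, chain5_dataset, chain5_system.region, w,
                              restraints, Q)
            assert chi >= chi0 - 1e-12


def test_equivalent_atoms_share_exactly_one_charge(butane_system,
                                                   butane_dataset):
    res = solve_dresp(butane_dataset, butane_system.region, _truth_weights(),
                      restraints=butane_system.true_charges,
                      Q_tot=float(butane_system.true_charges.sum()))
    groups = butane_system.region.equivalence_groups
    assert sorted(len(g) for g in groups) == [2, 2]
    ids = res.charges.atom_ids.tolist()
    for grp in groups:
        vals = [res.charges.q[ids.index(g)] for g in grp]
        assert max(vals) - min(vals) == 0.0   # shared variable, not averaged


def test_noise_robust_recovery(chain5_system):
    """1% relative Gaussian noise on V and E: charges within 2% of truth."""
    cfg = sample_configurations(chain5_system, 20, amplitude=0.005, seed=21)
    ds = generate_reference_data(chain5_system, cfg,
                                 noise=(0.01, 0.01, 0.0), seed=22)
    truth = chain5_system.true_charges
    res = solve_dresp(ds, chain5_system.region, _truth_weights(),
                      restraints=truth, Q_tot=float(truth.sum()))
    rel = np.abs(res.charges.q - truth) / np.abs(truth)
    assert rel.max() <= 0.02
    assert abs(res.charges.q.sum() - truth.sum()) <= 1e-8


def test_charge_conservation_violation_raises():
    cs = ChargeSet(q=np.array([0.5, 0.6]), atom_ids=np.array([1, 2]),
                   q_total=0.0)
    with pytest.raises(ChargeConservationError, match="deviates"):
        cs.validate()


def test_weight_validation():
    with pytest.raises(ValueError, match="w_Q"):
        DRESPWeights(1.0, 1.0, 1.0, 0.0).validate()
    with pytest.raises(ValueError, match="nonnegative"):
        DRESPWeights(-1.0, 1.0, 1.0, 1.0).validate()


def test_sr_free_dataset_needs_zero_electrostatic_weights(chain5_system,
                                                          chain5_dataset):
    from fmkit.refdata import FMDataSet, Snapshot
    snaps = []
    for snap in chain5_dataset:
        snaps.append(Snapshot(index=snap.index,
                              qm_positions=snap.qm_positions,
                              qm_forces=snap.qm_forces, sr_indices=[],
                              sr_positions=np.empty((0, 3)), sr_potential=[],
                              sr_field=np.empty((0, 3))))
    bare = FMDataSet(snapshots=snaps, qm_atom_ids=chain5_dataset.qm_atom_ids)
    with pytest.raises(ValueError, match="no SR atoms"):
        solve_dresp(bare, chain5_system.region, _truth_weights(),
                    restraints=chain5_system.true_charges, Q_tot=0.0)


# ---------------------------------------------------------------------------
# boundary redistribution

BRANCHED = """
[ defaults ]
1 2

[ atomtypes ]
C1 12.0 0.0 A 0.33 0.4
C2 12.0 0.0 A 0.33 0.4
C3 12.0 0.0 A 0.33 0.4
C4 12.0 0.0 A 0.33 0.4
C5 12.0 0.0 A 0.33 0.4
C6 12.0 0.0 A 0.33 0.4
C7 12.0 0.0 A 0.33 0.4

[ moleculetype ]
BR 3

[ atoms ]
1 C1 1 BR A1 1 0.10 12.0
2 C2 1 BR A2 2 -0.20 12.0
3 C3 1 BR A3 3 0.30 12.0
4 C4 1 BR A4 4 -0.10 12.0
5 C5 1 BR A5 5 0.05 12.0
6 C6 1 BR A6 6 -0.15 12.0
7 C7 1 BR A7 7 0.00 12.0

[ bonds ]
1 2 1 0.15 1000.0
2 3 1 0.15 1000.0
3 4 1 0.15 1000.0
4 5 1 0.15 1000.0
5 6 1 0.15 1000.0
3 7 1 0.15 1000.0

[ system ]
branched

[ molecules ]
BR 1
"""


def test_boundary_redistribution_hand_worked_example():
    """6-atom QM chain with one boundary atom in the middle (atom 3, bonded
    to MM atom 7): with n=1 the two neighbors (2, 4) and the boundary atom
    reset to their originals; the excess splits over the remaining 3."""
    top = parse_topology_string(BRANCHED)
    region = select_qm_region(top, None, "index 1 to 6")
    assert region.boundary_atoms == [3]
    fitted = np.array([0.12, -0.25, 0.41, -0.07, 0.02, -0.23])
    orig = np.array([0.10, -0.20, 0.30, -0.10, 0.05, -0.15])
    Q = 0.0
    cs = ChargeSet(q=fitted, atom_ids=np.arange(1, 7), q_total=Q)
    out = redistribute_boundary_charges(cs, region, 1, orig)
    # hand arithmetic: q' = (0.12, -0.20, 0.30, -0.10, 0.02, -0.23)
    # sum q' = -0.09 -> excess 0.09 over atoms {1, 5, 6}: +0.03 each
    expected = np.array([0.15, -0.20, 0.30, -0.10, 0.05, -0.20])
    np.testing.assert_allclose(out.q, expected, atol=1e-14)
    assert abs(out.q.sum() - Q) <= 1e-12


def test_boundary_redistribution_identity_without_boundary(chain5_system):
    cs = ChargeSet(q=chain5_system.true_charges, atom_ids=np.arange(1, 6),
                   q_total=float(chain5_system.true_charges.sum()))
    out = redistribute_boundary_charges(cs, chain5_system.region, 2,
                                        chain5_system.true_charges)
    assert out is cs


def test_boundary_redistribution_conserves_any_input():
    top = parse_topology_string(BRANCHED)
    region = select_qm_region(top, None, "index 1 to 6")
    rng = np.random.default_rng(33)
    for _ in range(5):
        fitted = rng.normal(0, 0.3, 6)
        orig = rng.normal(0, 0.2, 6)
        Q = float(rng.normal())
        cs = ChargeSet(q=fitted, atom_ids=np.arange(1, 7), q_total=Q)
        out = redistribute_boundary_charges(cs, region, 1, orig)
        assert abs(out.q.sum() - Q) <= 1e-12


def test_boundary_redistribution_all_reset_raises():
    top = parse_topology_string(BRANCHED)
    region = select_qm_region(top, None, "index 1 to 6")
    cs = ChargeSet(q=np.zeros(6), atom_ids=np.arange(1, 7), q_total=0.0)
    with pytest.raises(ValueError, match="no atom to absorb"):
        redistribute_boundary_charges(cs, region, 5, np.zeros(6))


# ---------------------------------------------------------------------------
# grid search

def test_single_point_grid_equals_solve(chain5_system, chain5_dataset):
    truth = chain5_system.true_charges
    w = DRESPWeights(1.0, 1.0, 0.0, 1e6)
    direct = solve_dresp(chain5_dataset, chain5_system.region, w,
                         restraints=truth, Q_tot=float(truth.sum()))
    grid = DRESPWeights([1.0], [1.0], [0.0], [1e6])
    best, table = grid_search_dresp(chain5_dataset, chain5_system.region, grid,
                                    restraints=truth, Q_tot=float(truth.sum()))
    assert len(table) == 1
    np.testing.assert_allclose(best.charges.q, direct.charges.q, atol=1e-14)


def test_grid_table_row_count(chain5_system, chain5_dataset, tmp_path):
    truth = chain5_system.true_charges
    grid = DRESPWeights([1.0, 2.0], [0.1, 1.0], [0.0, 10.0], [1e5])
    csv = tmp_path / "grid.csv"
    best, table = grid_search_dresp(chain5_dataset, chain5_system.region, grid,
                                    restraints=truth,
                                    Q_tot=float(truth.sum()), csv_path=csv)
    assert len(table) == 8
    assert csv.exists()
    import pandas as pd
    back = pd.read_csv(csv)
    assert list(back.columns) == ["w_V", "w_E", "w_H", "w_Q", "msd_V",
                                  "msd_E", "score", "total_charge", "status"]
    assert len(back) == 8


def test_grid_selects_generating_weight_combination(chain5_system):
    """Data generated noiselessly is explained exactly with zero restraint
    weight; a grid mixing in a strong wrong-target restraint must pick the
    no-restraint corner, confirmed by exhaustive rescoring."""
    cfg = sample_configurations(chain5_system, 10, amplitude=0.005, seed=41)
    ds = generate_reference_data(chain5_system, cfg, seed=42)
    truth = chain5_system.true_charges
    # non-uniform wrong restraints (a uniform shift would be annihilated by
    # the exact total-charge constraint and could not bias the fit)
    wrong_restraints = truth + np.array([0.3, -0.2, 0.15, -0.25, 0.0])
    grid = DRESPWeights([1.0, 0.01], [1.0, 0.01], [50.0, 0.0], [1e6])
    best, table = grid_search_dresp(ds, chain5_system.region, grid,
                                    restraints=wrong_restraints,
                                    Q_tot=float(truth.sum()))
    assert float(best.weights.w_H) == 0.0
    ok = table[table.status == "ok"]
    assert np.isclose(ok.score.min(), best.msd_V + best.msd_E)
    np.testing.assert_allclose(best.charges.q, truth, atol=1e-8)


def test_grid_tie_breaks_to_first_point(chain5_system, chain5_dataset):
    truth = chain5_system.true_charges
    # w_Q does not change the eliminated-constraint solution: exact tie
    grid = DRESPWeights([1.0], [1.0], [0.0], [1e5, 1e6])
    best, table = grid_search_dresp(chain5_dataset, chain5_system.region, grid,
                                    restraints=truth,
                                    Q_tot=float(truth.sum()))
    assert float(best.weights.w_Q) == 1e5
    assert len(table) == 2
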