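"""Force-field engine: closed forms, finite differences, invariants."""

import numpy as np
import pytest

from deltacg.forcefield import (
    AtomRecord, MolecularSystem, NonbondedPolicy, ParameterError,
    SingularGeometryError, compute_expansion, compute_pair_decomposition,
    finite_difference_check,
)
from conftest import lj_atom, make_water_system


def two_atom_system(r, q1=0.0, q2=0.0, eps=0.0, rmh=1.0):
    atoms = [lj_atom(0, charge=q1, eps=eps, rmh=rmh),
             lj_atom(1, charge=q2, eps=eps, rmh=rmh)]
    coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    return MolecularSystem(atoms=atoms, coordinates=coords)


# -- closed forms -----------------------------------------------------------


def test_lj_minimum_zero_force():
    # two neutral LJ atoms separated by rmin = 2^(1/6) sigma -> zero force
    rmh = 1.7
    system = two_atom_system(2 * rmh, eps=0.15, rmh=rmh)
    exp = compute_expansion(system)
    assert np.abs(exp.f).max() < 1e-12
    assert exp.V0 == pytest.approx(-0.15, rel=1e-12)


def test_coulomb_closed_form():
    # +1e / -1e at 2 A, no LJ: |F| = C * 1 * 1 / 4, attractive, elec only
    policy = NonbondedPolicy()
    system = two_atom_system(2.0, q1=1.0, q2=-1.0)
    exp = compute_expansion(system, policy)
    C = policy.coulomb_constant
    f = exp.f.reshape(2, 3)
    # atom 0 at origin, atom 1 at +x: attraction pulls 0 toward +x
    assert f[0] == pytest.approx([C / 4.0, 0.0, 0.0], abs=1e-12)
    assert f[1] == pytest.approx([-C / 4.0, 0.0, 0.0], abs=1e-12)
    pd = compute_pair_decomposition(system, policy)
    assert np.abs(pd.force_block(0, 1, "vdw")).max() == 0.0
    assert np.allclose(pd.force_block(0, 1, "elec"), f[0])


def test_excluded_pair_has_no_nonbonded_blocks():
    atoms = [lj_atom(0, charge=1.0, eps=0.1), lj_atom(1, charge=-1.0, eps=0.1)]
    coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
    system = MolecularSystem(atoms=atoms, coordinates=coords,
                             bonds=[(0, 1, 100.0, 1.5)])
    pd = compute_pair_decomposition(system)
    assert np.abs(pd.force_block(0, 1, "elec")).max() == 0.0
    assert np.abs(pd.force_block(0, 1, "vdw")).max() == 0.0
    assert np.abs(pd.hessian_block(0, 1, "elec")).max() == 0.0


def test_isolated_ideal_water_zero_internal_force():
    system = make_water_system([(0.0, 0.0, 0.0)])
    exp = compute_expansion(system)
    # equilibrium geometry: forces vanish, bonded Hessian blocks do not
    assert np.abs(exp.f).max() < 1e-9
    pd = compute_pair_decomposition(system)
    assert np.abs(pd.hessian_block(0, 1, "bonded")).max() > 1.0
    assert exp.V0 == pytest.approx(0.0, abs=1e-12)


# -- reassembly and antisymmetry contracts ----------------------------------


def test_pair_force_reassembly(small_droplet):
    exp = compute_expansion(small_droplet)
    pd = compute_pair_decomposition(small_droplet)
    assert np.abs(pd.atom_forces().ravel() - exp.f).max() < 1e-9


def test_per_term_force_antisymmetry(small_droplet):
    pd = compute_pair_decomposition(small_droplet)
    rng = np.random.default_rng(0)
    n = small_droplet.n_atoms
    for term in pd.terms():
        for _ in range(20):
            i, j = rng.integers(0, n, 2)
            if i == j:
                continue
            assert np.array_equal(pd.force_block(i, j, term),
                                  -pd.force_block(j, i, term))
            assert np.array_equal(pd.hessian_block(i, j, term),
                                  pd.hessian_block(j, i, term).T)


def test_offdiagonal_hessian_matches_pair_blocks(small_droplet):
    exp = compute_expansion(small_droplet)
    pd = compute_pair_decomposition(small_droplet)
    Hoff = pd.assemble_offdiagonal()
    n = small_droplet.n_atoms
    for a in range(n):
        sl = slice(3 * a, 3 * a + 3)
        Hoff[sl, sl] = exp.H[sl, sl]
    assert np.array_equal(Hoff, exp.H)


def test_hessian_symmetric(small_droplet):
    exp = compute_expansion(small_droplet)
    scale = np.abs(exp.H).max()
    assert np.abs(exp.H - exp.H.T).max() <= 1e-9 * scale
    assert np.isfinite(exp.f).all()


def test_translation_invariance(water_dimer):
    exp0 = compute_expansion(water_dimer)
    shifted = water_dimer.with_coordinates(
        water_dimer.coordinates + np.array([1.7, -2.3, 0.4]))
    exp1 = compute_expansion(shifted)
    assert exp1.V0 == pytest.approx(exp0.V0, rel=1e-12)
    assert np.abs(exp1.f - exp0.f).max() < 1e-8
    # H row sums over 3-blocks vanish (translating everything costs nothing)
    n = water_dimer.n_atoms
    rows = exp0.H.reshape(3 * n, n, 3).sum(axis=1)
    assert np.abs(rows).max() < 1e-8


# -- finite differences -----------------------------------------------------


def test_fd_random_five_atom_system():
    rng = np.random.default_rng(12)
    atoms = [lj_atom(k, charge=float(rng.uniform(-0.5, 0.5)),
                     eps=float(rng.uniform(0.05, 0.2)),
                     rmh=float(rng.uniform(1.5, 2.0))) for k in range(5)]
    coords = rng.uniform(-3.0, 3.0, size=(5, 3)) * np.array([1.0, 1.0, 0.6])
    system = MolecularSystem(atoms=atoms, coordinates=coords)
    rep = finite_difference_check(system, step=1e-5)
    scale = np.abs(compute_expansion(system).f).max()
    assert rep["max_force_dev"] <= 1e-6 * max(scale, 1.0)


def test_fd_water_dimer(water_dimer):
    rep = finite_difference_check(water_dimer, step=1e-5)
    assert rep["max_force_dev"] < 1e-5
    assert rep["max_hessian_dev"] < 1e-4


def test_fd_single_atom():
    system = MolecularSystem(atoms=[lj_atom(0, charge=0.3)],
                             coordinates=np.zeros((1, 3)))
    rep = finite_difference_check(system)
    assert rep["max_force_dev"] == 0.0
    assert rep["max_hessian_dev"] == 0.0


def test_fd_across_switch_region():
    # pair straddling switch_start: C2 switch keeps FD agreement
    policy = NonbondedPolicy(mode="switched", switch_start=2.5, cutoff=4.0)
    system = two_atom_system(3.1, q1=0.4, q2=-0.4, eps=0.12, rmh=1.6)
    rep = finite_difference_check(system, policy, step=1e-5)
    assert rep["max_force_dev"] < 1e-5
    assert rep["max_hessian_dev"] < 1e-4


def test_switch_endpoints_continuous():
    policy = NonbondedPolicy(mode="switched", switch_start=3.0, cutoff=5.0)
    base = NonbondedPolicy()
    inside = two_atom_system(2.999999, q1=0.3, q2=0.3)
    outside = two_atom_system(5.2, q1=0.3, q2=0.3)
    assert (compute_expansion(inside, policy).V0
            == pytest.approx(compute_expansion(inside, base).V0, rel=1e-6))
    assert compute_expansion(outside, policy).V0 == 0.0


# -- errors and validation --------------------------------------------------


def test_coincident_atoms_raise():
    system = two_atom_system(1.0, q1=0.1, q2=0.1)
    bad = system.coordinates.copy()
    bad[1] = bad[0]
    with pytest.raises(SingularGeometryError):
        compute_expansion(system.with_coordinates(bad))


def test_parameter_validation():
    with pytest.raises(ParameterError):
        lj_atom(0, mass=0.0)
    with pytest.raises(ParameterError):
        lj_atom(0, eps=-0.1)


def test_policy_validation():
    with pytest.raises(ValueError):
        NonbondedPolicy(mode="nonsense")
    with pytest.raises(ValueError):
        NonbondedPolicy(mode="switched", switch_start=5.0, cutoff=5.0)


def test_default_exclusions_cover_12_and_13(water_dimer):
    excl = water_dimer.exclusions
    # water 0: bonds 0-1, 0-2; angle pair 1-2
    for pair in ((0, 1), (0, 2), (1, 2)):
        assert frozenset(pair) in excl
    assert frozenset((0, 3)) not in excl
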