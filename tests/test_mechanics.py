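import numpy as np
import pytest

import footmech as fm
from footmech.mechanics import (
    LoadCase,
    SolverOptions,
    System,
    degrees_of_freedom,
    ground_region_loads,
    joint_contact_force,
    solve_equilibrium,
    total_potential,
)
from footmech.surgery import apply_ccda


def test_dof_layout_intact(skeleton0):
    lay = degrees_of_freedom(skeleton0)
    assert lay.n_coords == 1 + 10 * 6  # tibia 1 coordinate, 10 free units x 6


def test_dof_layout_after_arthrodesis(skeleton0):
    fused = apply_ccda(skeleton0)
    assert degrees_of_freedom(fused).n_coords == degrees_of_freedom(skeleton0).n_coords - 6


def test_dof_layout_degenerate_single_group(skeleton0):
    mono = skeleton0.copy()
    for b in mono.bones.values():
        b.fusion_group = "all"
    assert degrees_of_freedom(mono).n_coords == 1  # the tibia restraint wins


def test_analytic_gradient_matches_finite_differences(skeleton0, bands0):
    system = System(skeleton0, bands0)
    rng = np.random.default_rng(7)
    for trial in range(3):
        q = rng.normal(scale=0.4, size=system.layout.n_coords)
        E, g = system.energy_grad(q, 1.0)
        h = 1e-6
        idx = rng.choice(system.layout.n_coords, size=20, replace=False)
        for i in idx:
            qp, qm = q.copy(), q.copy()
            qp[i] += h
            qm[i] -= h
            num = (system.energy_grad(qp, 1.0)[0] - system.energy_grad(qm, 1.0)[0]) / (2 * h)
            assert np.isclose(g[i], num, rtol=1e-5, atol=1e-4), f"coordinate {i}"


def test_total_potential_zero_at_neutral_without_loads_or_prestrain(skeleton0):
    from footmech.ligaments import InSituStrainTable, calibrate_rest_lengths, build_bands

    bands = calibrate_rest_lengths(
        build_bands(skeleton0), skeleton0, InSituStrainTable(default=0.0, groups={})
    )
    system = System(skeleton0, bands, LoadCase(0.0, 0.0))
    q = np.zeros(system.layout.n_coords)
    E, g = system.energy_grad(q, 1.0)
    assert abs(E) < 1e-9
    assert np.linalg.norm(g) < 1e-9  # calibration fixed point


def test_unloaded_solve_is_fixed_point_without_prestrain(skeleton0):
    from footmech.ligaments import InSituStrainTable, calibrate_rest_lengths, build_bands

    bands = calibrate_rest_lengths(
        build_bands(skeleton0), skeleton0, InSituStrainTable(default=0.0, groups={})
    )
    res = solve_equilibrium(skeleton0, bands, LoadCase(0.0, 0.0))
    assert res.converged
    assert np.linalg.norm(res.q) < 1e-6  # stays at neutral
    assert all(t == 0.0 for t in res.band_tensions.values())
    assert all(np.allclose(f, 0.0) for (_, _, _, f) in res.joint_forces)


def test_linear_penalty_force_on_single_contact(skeleton0, bands0):
    system = System(skeleton0, bands0)
    kp = system.contacts.penalty_stiffness
    # push the whole skeleton down 0.5 mm: each ground sphere penetrates 0.5
    lay = system.layout
    q = np.zeros(lay.n_coords)
    for g in lay.groups:
        sl = lay.slices[g]
        if g == lay.tibia_group:
            q[sl.start] = -0.5
        else:
            q[sl][1] = -0.5
    system.energy_grad(q, 0.0)
    assert np.allclose(system._last_ground_normal, kp * 0.5, rtol=1e-6)


def test_loaded_equilibrium_physics(solved_normal):
    res = solved_normal.loaded
    assert res.converged
    # unilaterality
    assert all(t >= 0.0 for t in res.band_tensions.values())
    assert all(f[1] >= 0.0 for (_, _, _, f) in res.ground_forces)
    # vertical balance: plantar loads sum to the axial load within 2.5 %
    loads = ground_region_loads(res)
    total = sum(loads.values())
    assert abs(total - 690.0) <= 0.025 * 690.0
    # energy trace non-increasing within each ramp stage
    for stage in res.energy_trace:
        diffs = np.diff(stage)
        assert np.all(diffs <= 1e-6 * np.maximum(1.0, np.abs(stage[:-1])))


def test_region_loads_partition_total(solved_normal):
    res = solved_normal.loaded
    loads = ground_region_loads(res)
    total_vertical = sum(f[1] for (_, _, _, f) in res.ground_forces)
    assert np.isclose(sum(loads.values()), total_vertical, atol=1e-9)
    assert set(loads) == {"ray1", "ray2", "ray3", "ray4", "ray5", "calcaneus"}


def test_joint_contact_force_vector_sum(solved_normal):
    res = solved_normal.loaded
    pairs = [f for (j, a, b, f) in res.joint_forces if {a, b} == {"calcaneus", "cuboid"}]
    expected = float(np.linalg.norm(np.sum(pairs, axis=0)))
    assert np.isclose(joint_contact_force(res, "calcaneus", "cuboid"), expected)
    assert np.isclose(joint_contact_force(res, "cuboid", "calcaneus"), expected)
    with pytest.raises(KeyError):
        joint_contact_force(res, "talus", "ray5")


def test_unconverged_result_rejected_by_measures(solved_normal):
    import dataclasses

    bad = dataclasses.replace(solved_normal.loaded, converged=False)
    with pytest.raises(ValueError):
        ground_region_loads(bad)


def test_determinism_identical_iterates(skeleton0, bands0):
    opts = SolverOptions(n_ramp_stages=2, max_iter_per_stage=50, max_recenter=2)
    r1 = solve_equilibrium(skeleton0, bands0, options=opts)
    r2 = solve_equilibrium(skeleton0, bands0, options=opts)
    assert np.array_equal(r1.q, r2.q)
    assert r1.iterations == r2.iterations


def test_monotone_compliance_under_uniform_stiffness_scaling():
    """Doubling every stiffness while halving loads shrinks displacements.

    With zero pre-strain the neutral pose is the unloaded equilibrium, and
    scaling all stiffnesses by 2 with loads halved is energy-equivalent to
    quartering the load: displacements from neutral must shrink.
    """
    from footmech.analysis import scale_band_stiffness
    from footmech.ligaments import InSituStrainTable, build_bands, calibrate_rest_lengths

    sk = fm.build_skeleton(seed=0)
    bands = calibrate_rest_lengths(
        build_bands(sk), sk, InSituStrainTable(default=0.0, groups={})
    )
    soft = solve_equilibrium(
        sk, bands, LoadCase(138.0, 69.0), options=SolverOptions(n_ramp_stages=5)
    )
    stiff = solve_equilibrium(
        sk,
        scale_band_stiffness(bands, 2.0),
        LoadCase(69.0, 34.5),
        options=SolverOptions(n_ramp_stages=5, penalty_stiffness=4000.0, tangential_stiffness=80.0),
    )
    assert stiff.converged and soft.converged
    assert np.linalg.norm(stiff.q) < np.linalg.norm(soft.q)


def test_total_potential_api(skeleton0, bands0):
    system = System(skeleton0, bands0)
    q = np.zeros(system.layout.n_coords)
    assert np.isfinite(total_potential(q, system))
    with pytest.raises(FloatingPointError):
        system.energy_grad(np.full(system.layout.n_coords, np.nan), 1.0)
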