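"""Brownian-dynamics engine: integration, boundaries, reaction firing."""

import numpy as np
import pytest

from spatialrules import (
    ForceParams,
    GeometrySpec,
    SimProtocol,
    WorldState,
    init_world,
    parse_model,
    run_protocol,
    step_dynamics,
)
from spatialrules.toymodels import toy_polymer_fixture

from conftest import TOY_MODEL, make_world


class TestStepDynamics:
    def test_zero_temperature_no_forces_leaves_particle_in_place(self, toy_model, toy_geometry):
        world = make_world(toy_model, toy_geometry, 1)
        world.force = ForceParams(pair_style="none", temperature=0.0)
        p0 = world.pos.copy()
        step_dynamics(world, 500)
        assert np.array_equal(world.pos, p0)

    def test_reflective_wall_mirrors_particle_back_inside(self, toy_model, toy_geometry):
        world = WorldState(toy_model, toy_geometry, box=((-20, 20),) * 3, seed=3,
                           force=ForceParams(pair_style="none"))
        world.add_molecule("A", (19.5, 0.0, 0.0))
        for _ in range(200):
            step_dynamics(world, 10)
            assert np.all(world.pos >= world.box[:, 0]) and np.all(world.pos <= world.box[:, 1])

    def test_bonded_pair_at_rest_length_is_stationary_at_zero_temperature(
            self, toy_model, toy_geometry):
        world = WorldState(toy_model, toy_geometry, box=((-100, 100),) * 3, seed=0,
                           force=ForceParams(pair_style="none", temperature=0.0))
        a = world.add_molecule("A", (0.0, 0.0, 0.0))
        b = world.add_molecule("A", (20.0, 0.0, 0.0))  # rest length = 10 + 10
        world.form_bond(list(world.particle_sites(a))[0], list(world.particle_sites(b))[0])
        p0 = world.pos.copy()
        step_dynamics(world, 200)
        assert np.allclose(world.pos, p0, atol=1e-12)

    def test_stretched_bond_relaxes_toward_rest_length(self, toy_model, toy_geometry):
        world = WorldState(toy_model, toy_geometry, box=((-200, 200),) * 3, seed=0,
                           force=ForceParams(pair_style="none", temperature=0.0))
        a = world.add_molecule("A", (0.0, 0.0, 0.0))
        b = world.add_molecule("A", (60.0, 0.0, 0.0))
        world.form_bond(list(world.particle_sites(a))[0], list(world.particle_sites(b))[0])
        step_dynamics(world, 300)
        d = np.linalg.norm(world.pos[1] - world.pos[0])
        assert d == pytest.approx(20.0, abs=0.1)

    def test_free_diffusion_msd_matches_configured_coefficient(self, toy_model, toy_geometry):
        # MSD(t) = 6 D t with D = kT / gamma, within 10%
        f = ForceParams(pair_style="none", temperature=1.0, gamma=1.0, dt=0.5)
        world = WorldState(toy_model, toy_geometry, box=((-5000, 5000),) * 3, seed=42, force=f)
        rng = np.random.default_rng(0)
        for _ in range(300):
            world.add_molecule("A", rng.uniform(-100, 100, size=3))
        p0 = world.pos.copy()
        nsteps = 400
        step_dynamics(world, nsteps)
        msd = float(np.mean(np.sum((world.pos - p0) ** 2, axis=1)))
        expected = 6.0 * (f.temperature / f.gamma) * f.dt * nsteps
        assert msd == pytest.approx(expected, rel=0.10)

    def test_unstable_step_aborts_with_diagnostic(self, toy_model, toy_geometry):
        world = WorldState(toy_model, toy_geometry, box=((-30, 30),) * 3, seed=0,
                           force=ForceParams(pair_style="none", temperature=0.0,
                                             bond_k=50.0, dt=1.0, max_step=1e9))
        a = world.add_molecule("A", (-25.0, 0.0, 0.0))
        b = world.add_molecule("A", (25.0, 0.0, 0.0))
        world.form_bond(list(world.particle_sites(a))[0], list(world.particle_sites(b))[0])
        with pytest.raises(RuntimeError, match="unstable"):
            step_dynamics(world, 50)


class TestKernelPaths:
    def test_compiled_and_python_kernels_agree_bitwise(self, toy_model, toy_geometry):
        """The numba-compiled integrator and its plain-Python source produce
        identical trajectories for identical inputs (noise is pre-generated,
        so the two paths are interchangeable)."""
        from spatialrules import engine as eng

        results = []
        for kernel in (eng._bd_chunk, eng._bd_chunk_impl):
            orig = eng._bd_chunk
            eng._bd_chunk = kernel
            try:
                model, geometry, world = __import__("spatialrules.toymodels",
                                                    fromlist=["x"]).toy_polymer_fixture(
                    6, seed=13)
                world.advance(300)
                results.append(world.pos.copy())
            finally:
                eng._bd_chunk = orig
        assert np.array_equal(results[0], results[1])


class TestReactions:
    def test_out_of_reach_pair_does_not_react(self, toy_model, toy_geometry):
        world = WorldState(toy_model, toy_geometry, box=((-200, 200),) * 3, seed=0)
        world.add_molecule("A", (-50.0, 0.0, 0.0))
        world.add_molecule("A", (50.0, 0.0, 0.0))
        assert world.fire_reactions() == []
        assert world.bond_count() == 0

    def test_pair_within_reach_binds_and_logs_event(self, toy_model, toy_geometry):
        world = WorldState(toy_model, toy_geometry, box=((-200, 200),) * 3, seed=0)
        world.add_molecule("A", (0.0, 0.0, 0.0))
        world.add_molecule("A", (19.0, 0.0, 0.0))  # within 20 Å reach
        events = world.fire_reactions()
        assert len(events) == 1 and events[0].action == "formed"
        assert world.bond_count() == 1
        assert world.bond_log == events

    def test_switch_gated_rule_does_not_fire_when_off(self, toy_geometry):
        model = parse_model(
            "begin molecule types\nA(a,a,b~none~mod)\nend molecule types\n"
            "begin reaction rules\npoly: A(a) + A(a) -> A(a!1).A(a!1) 1.0 @SAC\n"
            "end reaction rules\n"
        )
        world = WorldState(model, toy_geometry, box=((-200, 200),) * 3, seed=0)
        world.add_molecule("A", (0.0, 0.0, 0.0))
        world.add_molecule("A", (15.0, 0.0, 0.0))
        world.switches["SAC"] = False
        assert world.fire_reactions() == []
        world.switches["SAC"] = True
        assert len(world.fire_reactions()) == 1

    def test_site_binds_at_most_once_per_sweep(self, toy_model, toy_geometry):
        world = WorldState(toy_model, toy_geometry, box=((-200, 200),) * 3, seed=5)
        world.add_molecule("A", (0.0, 0.0, 0.0))
        world.add_molecule("A", (18.0, 0.0, 0.0))
        world.add_molecule("A", (-18.0, 0.0, 0.0))
        world.fire_reactions()
        # centre particle has two a-sites: it may bind both neighbours, but
        # each site at most once; total new bonds <= 2 and sites consistent
        assert world.bond_count() <= 2
        for s in range(len(world.site_bond)):
            partner = world.site_partner(s)
            if partner != -1:
                assert world.site_partner(partner) == s

    def test_bond_bookkeeping_formed_minus_broken_equals_current(self):
        model, geometry, world = toy_polymer_fixture(10, seed=9)
        run_protocol(world, SimProtocol([("run", 5000)], dump_interval=5000))
        formed = sum(1 for e in world.bond_log if e.action == "formed")
        broken = sum(1 for e in world.bond_log if e.action == "broken")
        assert formed - broken == world.bond_count()

    def test_spatial_engine_reaches_nonspatial_fixpoint_on_small_worlds(self, toy_model,
                                                                        toy_geometry):
        """With p=1 and long mixing, the final bond graph matches exhaustive
        non-spatial rule application: no applicable rule instance remains."""
        from spatialrules.matching import match_lhs

        for seed in range(4):
            model, geometry, world = toy_polymer_fixture(5, seed=seed, box_side=80.0)
            run_protocol(world, SimProtocol([("run", 60000)], dump_interval=60000))
            # exhaustive check: no LHS embedding may remain on the final state
            assert match_lhs(model.rules[0], world) == []


class TestWorldConstruction:
    def test_random_placement_within_ranges(self, toy_model, toy_geometry):
        ranges = ((-40, 40), (-40, 80), (-40, 40))
        world = init_world(toy_model, toy_geometry, box=((-50, 50), (-50, 90), (-50, 50)),
                           counts={"A": 12}, placement_ranges=ranges, seed=8)
        for ax in range(3):
            assert np.all(world.pos[:, ax] >= ranges[ax][0])
            assert np.all(world.pos[:, ax] <= ranges[ax][1])

    def test_explicit_placement_honoured_exactly(self, toy_model, toy_geometry):
        world = init_world(toy_model, toy_geometry, box=((-50, 50),) * 3,
                           placements=[("A", (1.0, 2.0, 3.0))], seed=0)
        assert np.allclose(world.pos[0], (1.0, 2.0, 3.0))

    def test_zero_counts_gives_empty_world(self, toy_model, toy_geometry):
        world = init_world(toy_model, toy_geometry, box=((-50, 50),) * 3,
                           counts={"A": 0}, seed=0)
        assert world.n_particles == 0

    def test_placement_failure_raises_when_box_too_small(self, toy_model, toy_geometry):
        with pytest.raises(RuntimeError, match="place"):
            init_world(toy_model, toy_geometry, box=((-12, 12),) * 3,
                       counts={"A": 60}, seed=0, max_tries=30)

    def test_fixed_template_keeps_centroid(self, toy_geometry):
        from spatialrules import TemplateDef, TemplateMember, build_template

        model = parse_model("begin molecule types\nA(a,a,b~none~mod)\nend molecule types\n"
                            "begin reaction rules\nend reaction rules\n")
        tdef = TemplateDef("pair", [TemplateMember("A", (-10, 0, 0)),
                                    TemplateMember("A", (10, 0, 0))],
                           rigid=True, fixed_position=True, free_rotation=True)
        built = build_template(tdef, toy_geometry)
        world = WorldState(model, toy_geometry, box=((-100, 100),) * 3, seed=1)
        world.add_template_instance(built, (5.0, 5.0, 5.0))
        step_dynamics(world, 2000)
        assert np.allclose(world.pos.mean(axis=0), (5.0, 5.0, 5.0), atol=1e-9)
        # free rotation: member positions do change
        assert not np.allclose(world.pos[0], (-5.0, 5.0, 5.0), atol=1e-3)


class TestProtocols:
    def test_run_zero_steps_dumps_initial_snapshot_only(self, toy_model, toy_geometry):
        world = make_world(toy_model, toy_geometry, 3)
        snaps, events = run_protocol(world, SimProtocol([("run", 0)], dump_interval=100))
        assert len(snaps) == 1 and snaps[0].step == 0 and events == []

    def test_add_phase_increases_particle_count_exactly(self, toy_model, toy_geometry):
        world = make_world(toy_model, toy_geometry, 2)
        protocol = SimProtocol([("run", 100), ("add", 5, "A"), ("run", 100)],
                               dump_interval=100)
        run_protocol(world, protocol)
        assert world.n_particles == 7

    def test_same_seed_gives_identical_trajectories_and_logs(self):
        results = []
        for _ in range(2):
            model, geometry, world = toy_polymer_fixture(8, seed=4)
            snaps, events = run_protocol(world, SimProtocol([("run", 10000)],
                                                            dump_interval=2000))
            results.append((snaps, events))
        (s1, e1), (s2, e2) = results
        assert e1 == e2
        assert len(s1) == len(s2)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.pos, b.pos)

    def test_all_dumped_snapshots_inside_box(self):
        model, geometry, world = toy_polymer_fixture(12, seed=6, box_side=100.0)
        snaps, _ = run_protocol(world, SimProtocol([("run", 20000)], dump_interval=2000))
        for s in snaps:
            assert np.all(s.pos >= s.box[:, 0]) and np.all(s.pos <= s.box[:, 1])

    def test_switch_phase_toggles_rule(self, toy_geometry):
        model = parse_model(
            "begin molecule types\nA(a,a,b~none~mod)\nend molecule types\n"
            "begin reaction rules\npoly: A(a) + A(a) -> A(a!1).A(a!1) 1.0 @S\n"
            "end reaction rules\n")
        world = WorldState(model, toy_geometry, box=((-30, 30),) * 3, seed=2)
        world.switches["S"] = False
        world.add_molecule("A", (0.0, 0.0, 0.0))
        world.add_molecule("A", (15.0, 0.0, 0.0))
        run_protocol(world, SimProtocol([("run", 500)], dump_interval=500))
        assert world.bond_count() == 0
        run_protocol(world, SimProtocol([("switch", "S", True), ("run", 500)],
                                        dump_interval=500))
        assert world.bond_count() >= 1
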