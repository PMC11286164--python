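import numpy as np
import pytest

from loopfbm.bundle import Bundle, classic_fbm_force, simulate
from loopfbm.config import build_bundle, default_kukulcania_config
from loopfbm.constitutive import ConstitutiveLaw
from loopfbm.elements import Loop, LoopedElement, StraightElement

LINEAR1 = ConstitutiveLaw.linear(1.0)
LINEAR7 = ConstitutiveLaw.linear(7.0)


def straight(eid, xc, diam=1.0, law=LINEAR1):
    return StraightElement(id=eid, rel_diameter=diam, law=law, critical_strain=xc)


class TestClassicFBM:
    def test_uniform_cdf_hand_value(self):
        # F = 10·1·0.5·(1 − 0.5) = 2.5 for thresholds uniform on [0, 1]
        assert classic_fbm_force(10, 1.0, 0.5, lambda x: np.clip(x, 0, 1)) == pytest.approx(2.5)

    def test_zero_elongation(self):
        assert classic_fbm_force(10, 1.0, 0.0, lambda x: np.clip(x, 0, 1)) == 0.0

    def test_all_thresholds_exceeded(self):
        assert classic_fbm_force(10, 1.0, 1.2, lambda x: np.clip(x, 0, 1)) == pytest.approx(0.0)

    def test_tabulated_cdf(self):
        xs = np.linspace(0, 1, 11)
        assert classic_fbm_force(10, 1.0, 0.5, (xs, xs)) == pytest.approx(2.5)

    def test_non_monotone_tabulation_rejected(self):
        xs = np.linspace(0, 1, 5)
        ps = np.array([0.0, 0.5, 0.4, 0.8, 1.0])
        with pytest.raises(ValueError, match="monotone"):
            classic_fbm_force(10, 1.0, 0.5, (xs, ps))

    def test_monte_carlo_bundle_matches_closed_form(self):
        """10⁴ linear fibres with uniform [0,1] thresholds follow
        F = N·k·x·(1−x) within 2% sup-norm away from x = 1."""
        n = 10_000
        rng = np.random.default_rng(42)
        thresholds = rng.uniform(0.0, 1.0, n)
        bundle = Bundle([straight(f"f{i}", t) for i, t in enumerate(thresholds)])
        xs = np.arange(0.0, 0.901, 0.01)
        forces = np.array([bundle.step(x)[0] for x in xs])
        predicted = classic_fbm_force(n, 1.0, xs, lambda x: np.clip(x, 0, 1))
        scale = n * 1.0 / 4.0  # peak of the closed form
        assert np.max(np.abs(forces - predicted)) / scale < 0.02
        i_peak = int(np.argmax(forces))
        assert xs[i_peak] == pytest.approx(0.5, abs=0.05)
        assert forces[i_peak] == pytest.approx(scale, rel=0.02)


class TestBundleValidation:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Bundle([straight("a", 0.5), straight("a", 0.5)])

    def test_unresolved_coupling_rejected(self):
        e = StraightElement(id="ax", rel_diameter=1.0, law=LINEAR1, critical_strain=0.5,
                            coupling_sources=("ghost",), cs=0.9)
        with pytest.raises(ValueError, match="ghost"):
            Bundle([e])

    def test_coupling_to_straight_element_rejected(self):
        e = StraightElement(id="ax", rel_diameter=1.0, law=LINEAR1, critical_strain=0.5,
                            coupling_sources=("ra",), cs=0.9)
        with pytest.raises(ValueError, match="not a looped"):
            Bundle([e, straight("ra", 0.2)])


class TestTotalForce:
    def test_empty_bundle(self):
        assert Bundle([]).total_force(0.3) == 0.0

    def test_default_bundle_pre_event_force(self, default_config):
        bundle = build_bundle(default_config, seed=0)
        f = bundle.total_force(0.1)
        assert f > 7 * 0.1 * 1.0  # radial contribution alone is 0.7

    def test_all_failed_carries_nothing(self):
        b = Bundle([straight("a", 0.2), straight("b", 0.3)])
        b.step(0.5)
        assert b.all_failed
        assert b.total_force(1.0) == 0.0


class TestStep:
    def test_subthreshold_no_events(self):
        e = LoopedElement(id="l", rel_diameter=1.0, law=LINEAR1, loops=[Loop(0.1, 0.05)])
        force, events = Bundle([e]).step(0.09)
        assert force > 0 and events == []

    def test_threshold_opens_loop_and_zeroes_force(self):
        e = LoopedElement(id="l", rel_diameter=1.0, law=LINEAR1, loops=[Loop(0.1, 0.05)])
        force, events = Bundle([e]).step(0.1)
        assert force == 0.0
        assert [ev.kind for ev in events] == ["loop_open"]

    def test_radial_failure_event(self):
        b = Bundle([straight("ra", 0.2, law=LINEAR7)])
        force, events = b.step(0.21)
        assert force == 0.0
        assert [(ev.element_id, ev.kind) for ev in events] == [("ra", "element_fail")]

    def test_coupled_element_sees_largest_source_slack(self):
        """The axial-style member reads the most elongating looped source."""
        s1 = LoopedElement(id="s1", rel_diameter=1.0, law=LINEAR1, loops=[Loop(0.05, 0.3)],
                           post_loop_critical_strain=10.0)
        s2 = LoopedElement(id="s2", rel_diameter=1.0, law=LINEAR1, loops=[Loop(0.2, 0.1)],
                           post_loop_critical_strain=10.0)
        ax = StraightElement(id="ax", rel_diameter=1.0, law=LINEAR1, critical_strain=10.0,
                             coupling_sources=("s1", "s2"), cs=1.0)
        b = Bundle([s1, s2, ax])
        b.step(0.05)  # s1 opens: slack 0.35; s2 untouched
        assert s1.accumulated_slack == pytest.approx(0.35)
        assert b.upstream_slack(ax) == pytest.approx(0.35)
        assert ax.effective_elongation(0.4, b.upstream_slack(ax)) == pytest.approx(0.05)


class TestSimulate:
    def test_single_fibre_closed_form(self):
        """One linear fibre (E=1, x_c=0.5): force ramps to 0.5 then drops."""
        res = simulate(Bundle([straight("f", 0.5)]), x_max=1.0, dx=0.01)
        assert res.peak_force == pytest.approx(0.5, abs=0.011)
        assert res.strain_at_peak == pytest.approx(0.5, abs=0.011)
        assert res.forces[-1] == 0.0
        assert res.final_strain == pytest.approx(0.5, abs=0.011)

    def test_strains_increasing_forces_nonnegative(self, default_run):
        assert np.all(np.diff(default_run.strains) > 0)
        assert np.all(default_run.forces >= 0)
        assert default_run.forces[-1] == 0.0

    def test_sawtooth_cardinality(self, default_run):
        """Every one of the 8·200 loops opens before total failure."""
        assert default_run.n_events("loop_open") == 1600
        assert default_run.n_events("element_fail") == 11

    def test_degenerate_thresholds_give_zero_force_plateau(self):
        """Many near-identical thresholds: all loops open in a burst and the
        force stays ~0 over the strain interval the slack released."""
        loops = [Loop(0.1, 0.05) for _ in range(20)]
        e = LoopedElement(id="l", rel_diameter=1.0, law=LINEAR1, loops=loops,
                          post_loop_critical_strain=10.0)
        res = simulate(Bundle([e]), x_max=4.0, dx=0.005)
        # loops open back-to-back: after each opening the next identical
        # threshold is reached only one threshold-width later
        mask = (res.strains > 0.1) & (res.strains < 2.0)
        # never above one tooth height (E·t = 0.1) — tiny next to the ~2.0 an
        # unlooped fibre would reach — and exactly zero while slack straightens
        assert res.forces[mask].max() <= 0.1 + 0.011
        assert np.mean(res.forces[mask] == 0.0) > 0.25

    def test_multiple_looped_structures_interleave_events(self, default_run):
        opener_ids = [ev.element_id for ev in default_run.events if ev.kind == "loop_open"]
        # events are not sorted by element: openings interleave across fibres
        assert opener_ids != sorted(opener_ids)
        assert len(set(opener_ids)) == 8

    def test_reduction_to_plain_fbm_without_loops(self, default_config):
        cfg = default_config.model_copy(deep=True)
        for g in cfg.groups:
            if g.loops is not None:
                g.loops = g.loops.model_copy(update={"count": 0})
            if g.coupling is not None:
                g.coupling = None
        bundle = build_bundle(cfg, seed=0)
        res = simulate(bundle, x_max=5.0, dx=0.005)
        assert res.n_events("loop_open") == 0
        assert res.n_events("element_fail") == 11
        # final strain bounded by the largest critical strain in the bundle
        assert res.final_strain <= 0.5 + 0.0051

    def test_step_size_robustness(self, default_config):
        """Halving dx changes the default bundle's final strain by < 1%."""
        b1 = build_bundle(default_config, seed=4)
        b2 = build_bundle(default_config, seed=4)
        r1 = simulate(b1, x_max=50.0, dx=0.005)
        r2 = simulate(b2, x_max=50.0, dx=0.0025)
        assert abs(r1.final_strain - r2.final_strain) / r1.final_strain < 0.01

    @pytest.mark.parametrize("dx,x_max", [(-0.1, 1.0), (0.0, 1.0), (0.01, 0.0)])
    def test_invalid_grid_rejected(self, dx, x_max):
        with pytest.raises(ValueError):
            simulate(Bundle([straight("f", 0.5)]), x_max=x_max, dx=dx)


class TestSimulationResult:
    def test_save_round_trips_through_curve_reader(self, tmp_path, default_config):
        from loopfbm.curves import read_curve

        cfg = default_config.model_copy(deep=True)
        for g in cfg.groups:
            if g.loops is not None:
                g.loops = g.loops.model_copy(update={"count": 3})
        bundle = build_bundle(cfg, seed=0)
        res = simulate(bundle, x_max=5.0, dx=0.01, seed=0, config_fingerprint="abc")
        paths = res.save(tmp_path / "run")
        curve = read_curve(paths["curve"])
        assert curve.units == "relative"
        np.testing.assert_allclose(curve.strain, res.strains)
        np.testing.assert_allclose(curve.force, res.forces)
        events = paths["events"].read_text().splitlines()
        assert events[0] == "strain,element_id,event_kind,threshold,hidden_length"
        import json

        summary = json.loads(paths["summary"].read_text())
        assert summary["seed"] == 0 and summary["config_fingerprint"] == "abc"
        assert summary["n_elements"] == 11
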