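"""Morphogen gradient, force, extrusion, activation and collinearity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hoxphys as hp
from hoxphys.biophysics import DEFAULTS


@pytest.fixture(scope="module")
def field():
    return hp.MorphogenField()


@pytest.fixture(scope="module")
def components(field):
    mouse = hp.load_mouse_hoxd()
    charges = hp.ChargeModel.for_cluster(mouse)
    profile = hp.ElasticityProfile.uniform(hp.cluster_span(mouse))
    kernel = hp.ActivationKernel()
    return mouse, field, charges, profile, kernel


step_profiles = st.lists(
    st.floats(0.1, 10.0), min_size=1, max_size=6
).map(
    lambda s: hp.ElasticityProfile(
        edges=tuple(10.0 * i for i in range(len(s) + 1)), stiffness=tuple(s)
    )
)


class TestMorphogen:
    def test_peak_at_posterior_end(self, field):
        assert hp.morphogen_at(field, field.axis_length) == field.peak_value

    def test_strictly_increasing(self, field):
        x = np.linspace(0.0, field.axis_length, 50)
        m = hp.morphogen_at(field, x)
        assert np.all(np.diff(m) > 0)

    def test_position_outside_axis_rejected(self, field):
        with pytest.raises(hp.HoxValidationError):
            hp.morphogen_at(field, field.axis_length + 1.0)

    def test_flat_gradient_limit(self):
        flat = hp.MorphogenField(decay_lambda=1e9)
        m = hp.morphogen_at(flat, np.array([0.0, 50.0, 100.0]))
        assert m == pytest.approx(flat.peak_value, rel=1e-6)


class TestExpressionDomains:
    def test_nested_domains_share_posterior_end(self, field):
        schedule = hp.ThresholdSchedule(
            thresholds=(0.1, 0.3, 0.6), times=(1.0, 2.0, 3.0)
        )
        domains = [hp.expression_domain(field, schedule, k) for k in (1, 2, 3)]
        for outer, inner in zip(domains, domains[1:]):
            assert inner[0] > outer[0]  # anterior boundary recedes
            assert inner[1] == outer[1] == field.axis_length
        assert all(d[1] == field.axis_length for d in domains)

    def test_threshold_above_peak_is_empty(self, field):
        schedule = hp.ThresholdSchedule(thresholds=(2.0,), times=(1.0,))
        assert hp.expression_domain(field, schedule, 1) is None

    def test_threshold_at_anterior_concentration_covers_axis(self, field):
        t_ant = hp.morphogen_at(field, 0.0)
        schedule = hp.ThresholdSchedule(thresholds=(t_ant,), times=(1.0,))
        lo, hi = hp.expression_domain(field, schedule, 1)
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == field.axis_length

    def test_rank_out_of_range_rejected(self, field):
        schedule = hp.ThresholdSchedule(thresholds=(0.5,), times=(1.0,))
        with pytest.raises(hp.HoxValidationError):
            hp.expression_domain(field, schedule, 2)

    @given(
        lam=st.floats(5.0, 200.0),
        raw=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=8, unique=True),
    )
    def test_nesting_property(self, lam, raw):
        field = hp.MorphogenField(decay_lambda=lam)
        thresholds = tuple(sorted(raw))
        schedule = hp.ThresholdSchedule(
            thresholds=thresholds,
            times=tuple(float(i + 1) for i in range(len(thresholds))),
        )
        domains = [
            hp.expression_domain(field, schedule, k)
            for k in range(1, len(thresholds) + 1)
        ]
        anterior = [d[0] for d in domains]
        assert anterior == sorted(anterior)


class TestPullForce:
    def test_no_force_in_ground_state(self, components):
        _, field, charges, _, _ = components
        assert hp.pull_force(charges, field, 50.0, 0.0) == 0.0

    def test_linear_in_cluster_charge(self, components):
        mouse, field, charges, _, _ = components
        doubled = hp.ChargeModel(
            alpha=charges.alpha, kappa_N=charges.kappa_N, N=2 * charges.N
        )
        assert hp.pull_force(doubled, field, 60.0, 1.0) == pytest.approx(
            2 * hp.pull_force(charges, field, 60.0, 1.0)
        )

    def test_posterior_cells_pull_harder(self, components):
        _, field, charges, _, _ = components
        assert hp.pull_force(charges, field, 90.0, 1.0) > hp.pull_force(
            charges, field, 10.0, 1.0
        )

    def test_negative_time_rejected(self, components):
        _, field, charges, _, _ = components
        with pytest.raises(hp.HoxValidationError):
            hp.pull_force(charges, field, 50.0, -1.0)


class TestExtrusion:
    def test_zero_force_zero_extrusion(self):
        profile = hp.ElasticityProfile.uniform(100.0)
        assert hp.extrusion_length(0.0, profile) == 0.0

    def test_uniform_profile_linear_spring(self):
        profile = hp.ElasticityProfile.uniform(100.0, stiffness=1.0)
        assert hp.extrusion_length(10.0, profile) == pytest.approx(10.0)

    def test_loose_end_doubles_extrusion_at_half_resistance(self):
        profile = hp.ElasticityProfile.uniform(100.0)
        anchored = hp.extrusion_length(10.0, profile, fixed_end_intact=True)
        loose = hp.extrusion_length(
            10.0, profile, fixed_end_intact=False, loose_end_gain=0.5
        )
        assert loose == pytest.approx(2 * anchored)

    @pytest.mark.parametrize("rho", [0.0, -0.5, 1.0, 1.5, None])
    def test_invalid_loose_end_gain_rejected(self, rho):
        profile = hp.ElasticityProfile.uniform(100.0)
        with pytest.raises(hp.HoxValidationError):
            hp.extrusion_length(
                5.0, profile, fixed_end_intact=False, loose_end_gain=rho
            )

    def test_work_extrusion_inverse_on_steps(self):
        profile = hp.ElasticityProfile(
            edges=(0.0, 10.0, 30.0, 40.0), stiffness=(2.0, 0.5, 5.0)
        )
        for e in (0.0, 5.0, 10.0, 17.0, 30.0, 39.0, 60.0):
            assert profile.extrusion(profile.work(e)) == pytest.approx(e)

    @given(profile=step_profiles, forces=st.lists(st.floats(0.0, 500.0), min_size=2))
    def test_extrusion_monotone_in_force(self, profile, forces):
        ordered = sorted(forces)
        lengths = [hp.extrusion_length(F, profile) for F in ordered]
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))

    @given(profile=step_profiles, F=st.floats(0.0, 200.0), rho=st.floats(0.05, 0.95))
    def test_removing_fixed_end_never_decreases_extrusion(self, profile, F, rho):
        anchored = hp.extrusion_length(F, profile, fixed_end_intact=True)
        loose = hp.extrusion_length(
            F, profile, fixed_end_intact=False, loose_end_gain=rho
        )
        assert loose >= anchored


class TestActivationKernel:
    def test_gene_inside_territory_is_silent(self):
        kernel = hp.ActivationKernel(tf_offset=5.0, width=10.0)
        assert kernel.intensity(-0.1) == 0.0

    def test_peak_at_factory_position(self):
        kernel = hp.ActivationKernel(tf_offset=5.0, width=10.0, peak_intensity=2.0)
        assert kernel.intensity(5.0) == 2.0

    def test_intensity_drops_away_from_factory(self):
        kernel = hp.ActivationKernel(tf_offset=5.0, width=10.0)
        deltas = np.array([5.0, 8.0, 12.0, 15.0, 20.0])
        intensities = kernel.intensity(deltas)
        assert np.all(np.diff(intensities) < 0) or intensities[-1] == 0.0
        assert np.all(np.diff(intensities[:-1]) < 0)
        assert kernel.intensity(100.0) == 0.0


class TestSimulateExpression:
    def test_time_zero_everything_silent(self, components):
        mouse, field, charges, profile, kernel = components
        state = hp.simulate_expression(
            mouse, field, None, charges, profile, kernel, x=80.0, t=0.0
        )
        assert all(v == 0.0 for v in state.intensities.values())

    def test_early_anterior_cell_expresses_only_first_gene(self, components):
        mouse, field, charges, profile, kernel = components
        state = hp.simulate_expression(
            mouse, field, None, charges, profile, kernel, x=0.0, t=0.2
        )
        active = [n for n, v in state.intensities.items() if v > 0]
        assert active == [1]

    def test_late_posterior_cell_posterior_gene_strongest(self, components):
        mouse, field, charges, profile, kernel = components
        state = hp.simulate_expression(
            mouse, field, None, charges, profile, kernel,
            x=field.axis_length, t=DEFAULTS["t_max"],
        )
        assert min(state.deltas.values()) >= 0  # all genes extruded
        strongest = max(state.intensities, key=state.intensities.get)
        assert strongest == max(mouse.gene_numbers)

    def test_activation_time_nonincreasing_in_morphogen(self, components):
        mouse, field, charges, profile, kernel = components
        t_grid = np.linspace(0.0, DEFAULTS["t_max"], 120)

        def first_activation(x, g):
            for t in t_grid:
                state = hp.simulate_expression(
                    mouse, field, None, charges, profile, kernel, x, t
                )
                if state.intensities[g] > 0:
                    return t
            return np.inf

        for g in (1, 8, 13):
            anterior_t = first_activation(20.0, g)
            posterior_t = first_activation(90.0, g)
            assert posterior_t <= anterior_t


class TestCollinearityReport:
    def test_wild_type_passes_all_three(self, components):
        mouse, field, charges, profile, kernel = components
        report = hp.collinearity_report(mouse, field, charges, profile, kernel)
        assert report.all_pass

    def test_random_parameter_perturbations_preserve_collinearity(self, components):
        mouse, _, _, _, kernel = components
        span = hp.cluster_span(mouse)
        rng = np.random.default_rng(2026)
        for _ in range(50):
            fl, fa, fs = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=3))
            report = hp.collinearity_report(
                mouse,
                hp.MorphogenField(decay_lambda=DEFAULTS["decay_lambda"] * fl),
                hp.ChargeModel.for_cluster(mouse, alpha=DEFAULTS["alpha"] * fa),
                hp.ElasticityProfile.uniform(span, DEFAULTS["stiffness"] * fs),
                kernel,
            )
            assert report.all_pass, report.witnesses

    def test_inverted_kernel_flagged_on_quantitative_check(self, components):
        mouse, field, charges, profile, _ = components
        inverted = hp.ActivationKernel(inverted=True)
        report = hp.collinearity_report(mouse, field, charges, profile, inverted)
        assert not report.quantitative
        assert "quantitative" in report.witnesses

    def test_single_gene_cluster_vacuously_collinear(self, field):
        lone = hp.HoxCluster(
            organism="lone", genes=(hp.HoxGene(1),), distances_kbp=()
        )
        charges = hp.ChargeModel(alpha=DEFAULTS["alpha"], kappa_N=0.01, N=0.5)
        report = hp.collinearity_report(
            lone, field, charges, hp.ElasticityProfile.uniform(10.0),
            hp.ActivationKernel(),
        )
        assert report.all_pass

    def test_degenerate_grid_rejected(self, components):
        mouse, field, charges, profile, kernel = components
        with pytest.raises(hp.HoxValidationError):
            hp.collinearity_report(
                mouse, field, charges, profile, kernel,
                x_grid=np.array([50.0]), t_grid=np.array([1.0]),
            )
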