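import numpy as np
import pytest

from mpatimelines import (
    PopulationState,
    RecruitmentSeries,
    abundance_ratio_series,
    analytic_ratio,
    asymptotic_ratio,
    biomass_ratio_series,
    biomass_series,
    build_survival_matrix,
    constant_recruitment,
    ensemble_ratio_matrix,
    fished_equilibrium,
    project_open,
    recruitment_sd_total,
    simulate_open_ensemble,
    time_to_fraction,
    time_to_fraction_approx,
    unfished_equilibrium,
    weight_at_age,
)

from conftest import make_species


def deterministic_mpa(sp, T=None):
    T = T or sp.max_age
    return project_open(sp, fished_equilibrium(sp), constant_recruitment(T), fished=False)


class TestSurvivalMatrix:
    def test_unfished_subdiagonal_is_natural_survival(self, blue_rockfish):
        A = build_survival_matrix(blue_rockfish, fished=False)
        sub = np.diag(A, k=-1)
        assert np.allclose(sub, np.exp(-blue_rockfish.M))
        assert np.count_nonzero(A) == blue_rockfish.max_age - 1

    def test_bocaccio_fished_entries(self, bocaccio):
        # fishing starts at the source age a_c = 3
        A = build_survival_matrix(bocaccio, fished=True)
        assert A[2, 1] == pytest.approx(np.exp(-0.15), abs=1e-4)  # age 2 -> 3
        assert A[3, 2] == pytest.approx(np.exp(-0.16), abs=1e-4)  # age 3 -> 4

    def test_column_sums_are_probabilities(self, table):
        for sp in table:
            for fished in (False, True):
                A = build_survival_matrix(sp, fished)
                assert np.all(A.sum(axis=0) <= 1.0), sp.name


class TestEquilibria:
    def test_no_fishing_matches_unfished_equilibrium(self):
        sp = make_species(F=0.0)
        assert np.allclose(
            fished_equilibrium(sp).abundance_by_age,
            unfished_equilibrium(sp).abundance_by_age,
        )

    def test_geometric_decline_below_capture_age(self):
        sp = make_species(M=0.2, a_c=4)
        N = fished_equilibrium(sp, 500.0).abundance_by_age
        assert N[1] == pytest.approx(500.0 * np.exp(-0.2))

    def test_is_fixed_point_of_fished_dynamics(self, table):
        for sp in table:
            eq = fished_equilibrium(sp)
            traj = project_open(sp, eq, constant_recruitment(1), fished=True)
            assert np.allclose(traj.states[1], eq.abundance_by_age), sp.name

    def test_dimension_mismatch_rejected(self, blue_rockfish):
        bad = PopulationState(np.ones(3))
        with pytest.raises(ValueError, match="length"):
            project_open(blue_rockfish, bad, constant_recruitment(2), False)


class TestProjection:
    def test_zero_recruitment_cohorts_decay_at_M(self, synthetic):
        initial = unfished_equilibrium(synthetic)
        rec = RecruitmentSeries(np.zeros(5))
        traj = project_open(synthetic, initial, rec, fished=False)
        # each surviving cohort declines by e^-M per year
        assert np.allclose(
            traj.states[1, 1:], initial.abundance_by_age[:-1] * np.exp(-synthetic.M)
        )
        totals = traj.states.sum(axis=1)
        assert np.all(np.diff(totals) < 0)

    def test_fished_scenario_ratio_identically_one(self, table):
        for sp in table:
            traj = project_open(
                sp, fished_equilibrium(sp), constant_recruitment(30), fished=True
            )
            assert np.allclose(abundance_ratio_series(traj), 1.0), sp.name

    def test_mpa_run_converges_to_asymptotic_ratio(self, table):
        # once every pre-MPA cohort has died out the ratio is constant; the
        # shortfall from the infinite-age asymptote is the truncated
        # unfished tail, bounded by exp(-M (max_age - a_c))
        for sp in table:
            series = abundance_ratio_series(deterministic_mpa(sp))
            assert series[-1] == series[-2]
            R = asymptotic_ratio(sp)
            rel = abs(series[-1] - R) / R
            assert rel <= np.exp(-sp.M * (sp.max_age - sp.a_c)), sp.name
            if sp.max_age >= sp.a_c + 8.0 / sp.M:
                assert rel <= 1e-3, sp.name

    def test_ratio_series_starts_at_one_and_is_nondecreasing(self, table):
        for sp in table:
            series = abundance_ratio_series(deterministic_mpa(sp))
            assert series[0] == 1.0
            assert np.all(np.diff(series) >= -1e-12), sp.name

    def test_discrete_curve_follows_exponential_fill_in(self, table):
        # the discrete recursion tracks R - (R-1) e^{-Mt} with R the
        # discrete asymptote; age-truncation keeps the gap below 0.06
        for sp in table:
            series = abundance_ratio_series(deterministic_mpa(sp))
            t = np.arange(series.size)
            R = asymptotic_ratio(sp)
            curve = R - (R - 1.0) * np.exp(-sp.M * t)
            assert np.max(np.abs(series - curve)) < 0.06, sp.name


class TestAnalyticRatios:
    def test_analytic_ratio_boundaries(self, blue_rockfish):
        assert analytic_ratio(blue_rockfish, 0) == pytest.approx(1.0)
        r_inf = (blue_rockfish.M + blue_rockfish.F) / blue_rockfish.M
        assert analytic_ratio(blue_rockfish, 1e6) == pytest.approx(r_inf)

    def test_blue_rockfish_ratio_at_year_10(self, blue_rockfish):
        assert analytic_ratio(blue_rockfish, 10) == pytest.approx(1.9148, abs=1e-4)

    def test_asymptotic_ratio_values(self, bocaccio, urchin):
        assert asymptotic_ratio(make_species(F=0.0)) == pytest.approx(1.0)
        assert asymptotic_ratio(bocaccio) == pytest.approx(1.0615, abs=1e-4)
        assert asymptotic_ratio(urchin) == pytest.approx(5.169, abs=1e-3)


class TestBiomass:
    def test_empty_population_has_zero_biomass(self, synthetic):
        states = np.zeros((3, synthetic.max_age))
        traj = project_open(
            synthetic,
            PopulationState(np.zeros(synthetic.max_age)),
            RecruitmentSeries(np.zeros(2)),
            False,
        )
        assert np.allclose(biomass_series(traj), 0.0)

    def test_single_cohort_biomass_is_weight_at_age(self, synthetic):
        N = np.zeros(synthetic.max_age)
        age = 10
        N[age - 1] = 1.0
        traj = project_open(
            synthetic, PopulationState(N), RecruitmentSeries(np.zeros(0)), False
        )
        assert biomass_series(traj, all_ages=True)[0] == pytest.approx(
            float(weight_at_age(synthetic, age))
        )

    def test_all_ages_biomass_gain_exceeds_all_ages_abundance_gain(self, table):
        # weights increase with age, so filling in the old ages boosts
        # biomass at least as much as raw numbers
        for sp in table:
            traj = deterministic_mpa(sp)
            ab_all = abundance_ratio_series(traj, all_ages=True)[-1]
            bm_all = biomass_ratio_series(traj, all_ages=True)[-1]
            assert bm_all >= ab_all - 1e-12, sp.name


class TestTimeToFraction:
    def test_tiny_q_is_immediate(self, blue_rockfish):
        assert time_to_fraction(blue_rockfish, q=1e-9) == 0

    def test_closed_form_approximation(self):
        sp = make_species(M=0.14)
        assert time_to_fraction_approx(sp, 0.95) == pytest.approx(21.4, abs=0.03)

    def test_simulated_crossing_matches_discrete_oracle(self, table):
        # closed-form crossing of R - (R-1) e^{-Mt} through 0.95 R
        for sp in table:
            if sp.max_age <= 5.5 / sp.M:
                continue  # age truncation lowers the simulated asymptote
            R = asymptotic_ratio(sp)
            t_star = (np.log(20.0) + np.log((R - 1.0) / R)) / sp.M
            assert abs(time_to_fraction(sp, 0.95) - t_star) <= 2.0, sp.name

    def test_approximation_is_an_upper_bound(self, table):
        # -ln(1-q)/M measures 95% of the *increase*; the ratio crossing
        # happens no later
        for sp in table:
            assert time_to_fraction(sp, 0.95) <= np.ceil(
                time_to_fraction_approx(sp, 0.95)
            ), sp.name


class TestEnsembles:
    def test_zero_sigma_collapses_to_deterministic(self, blue_rockfish):
        det = abundance_ratio_series(deterministic_mpa(blue_rockfish, T=15))
        runs = simulate_open_ensemble(
            blue_rockfish, 5, 15, seed=3, fished=False, sigma_R=0.0
        )
        for traj in runs:
            assert np.array_equal(abundance_ratio_series(traj), det)

    def test_same_seed_reproduces_ensemble(self, blue_rockfish):
        a = simulate_open_ensemble(blue_rockfish, 4, 10, seed=42, fished=False)
        b = simulate_open_ensemble(blue_rockfish, 4, 10, seed=42, fished=False)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.states, tb.states)

    def test_mpa_and_fished_streams_are_independent(self, blue_rockfish):
        a = simulate_open_ensemble(blue_rockfish, 2, 10, seed=42, fished=False)
        b = simulate_open_ensemble(blue_rockfish, 2, 10, seed=42, fished=True)
        assert not np.array_equal(a[0].recruitment.values, b[0].recruitment.values)

    def test_recruitment_mean_matches_lognormal_moment(self, blue_rockfish):
        # no mean correction: E[R] = mean_level * exp(sigma^2 / 2)
        runs = simulate_open_ensemble(blue_rockfish, 400, 25, seed=5, fished=False)
        draws = np.concatenate([t.recruitment.values for t in runs])
        expected = 500.0 * np.exp(blue_rockfish.sigma_R**2 / 2.0)
        assert np.mean(draws) == pytest.approx(expected, rel=0.02)

    def test_deterministic_path_inside_decile_band(self, table):
        for sp in table:
            if sp.sigma_R > 0.5:
                continue
            mat = ensemble_ratio_matrix(
                simulate_open_ensemble(sp, 400, 20, seed=11, fished=False)
            )
            det = abundance_ratio_series(deterministic_mpa(sp, T=20))
            q10, q90 = np.percentile(mat, [10, 90], axis=0)
            assert np.all(det >= q10 - 1e-9) and np.all(det <= q90 + 1e-9), sp.name


class TestRecruitmentSdTotal:
    def test_zero_noise_gives_zero(self, blue_rockfish):
        assert recruitment_sd_total(blue_rockfish, 25, 0.0) == 0.0

    def test_single_term_at_t_zero(self, blue_rockfish):
        expected = 50.0 * np.exp(-blue_rockfish.M * (blue_rockfish.a_c - 1))
        assert recruitment_sd_total(blue_rockfish, 0, 50.0) == pytest.approx(expected)

    def test_monotone_and_convergent(self, blue_rockfish):
        vals = [recruitment_sd_total(blue_rockfish, t, 50.0) for t in range(0, 200)]
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] - vals[-50] < 1e-6
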