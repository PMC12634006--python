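"""qCSF engine: grid/prior construction, likelihood, Bayes updates,
entropy-minimizing stimulus selection, posterior metrics."""

import math

import numpy as np
import pytest

from etgcsf import (
    CSFParams,
    DegenerateUpdateError,
    EngineConfig,
    ParameterGrid,
    Posterior,
    PsychometricConfig,
    QcsfEngine,
    Stimulus,
    StimulusSpace,
    aulcsf,
    build,
    csf_acuity,
    estimate_metrics,
    expected_entropies,
    p_correct,
    posterior_entropy,
    select_stimulus,
    update,
)
from etgcsf.engine import _p_correct_grid


def entropy_bits(w):
    w = np.asarray(w, float)
    w = w[w > 0]
    return float(-(w * np.log2(w)).sum())


def naive_expected_entropy(mass, p_vec):
    """Enumerate both responses, renormalize, average entropies (oracle)."""
    a = float(mass @ p_vec)
    h_c = entropy_bits(mass * p_vec / a) if a > 0 else 0.0
    h_i = entropy_bits(mass * (1 - p_vec) / (1 - a)) if a < 1 else 0.0
    return a * h_c + (1 - a) * h_i


class TestBuild:
    def test_exp1_and_exp2_frequency_ranges(self):
        g1, s1, _ = build(EngineConfig(sf_range=(0.5, 32.0)))
        assert s1.sf_values.min() == pytest.approx(0.5)
        assert s1.sf_values.max() == pytest.approx(32.0)
        g2, s2, _ = build(EngineConfig(sf_range=(0.5, 15.0)))
        assert s2.sf_values.max() == pytest.approx(15.0)

    def test_prior_is_normalized_uniform(self, small_engine_config):
        grid, space, prior = build(small_engine_config)
        assert prior.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(prior.mass, prior.mass[0])
        assert grid.n_points == 5 * 4 * 3 * 2

    def test_every_grid_point_is_a_valid_csf(self, small_engine_config):
        grid, _, _ = build(small_engine_config)
        for i in range(grid.n_points):
            grid.params_at(i)  # raises if invariants are broken

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            EngineConfig(sf_range=(32.0, 0.5))
        with pytest.raises(ValueError):
            EngineConfig(n_sf=0)


class TestPCorrect:
    def test_asymptotes(self, worked_params):
        psych = PsychometricConfig()
        low = p_correct(worked_params, Stimulus(sf=2.0, contrast=1e-6), psych)
        assert low == pytest.approx(psych.guess, abs=1e-6)
        high = p_correct(worked_params, Stimulus(sf=2.0, contrast=1.0), psych)
        assert high == pytest.approx(1 - psych.lapse, abs=1e-6)

    def test_unit_drive_value(self, worked_params):
        # S(2 cpd) = 100, contrast 0.01 -> contrast * S = 1
        p = p_correct(worked_params, Stimulus(sf=2.0, contrast=0.01),
                      PsychometricConfig(guess=0.5, lapse=0.04, slope=3.0))
        assert p == pytest.approx(0.5 + 0.46 * (1 - math.exp(-1)), abs=1e-12)
        assert p == pytest.approx(0.7908, abs=1e-4)

    def test_increasing_in_contrast(self, worked_params):
        psych = PsychometricConfig()
        contrasts = np.geomspace(1e-3, 1.0, 25)
        ps = np.array(
            [p_correct(worked_params, Stimulus(sf=4.0, contrast=c), psych)
             for c in contrasts]
        )
        assert np.all(np.diff(ps) >= 0)
        # strictly increasing wherever the upper asymptote has not saturated
        unsat = ps[:-1] < 1 - psych.lapse - 1e-12
        assert np.all(np.diff(ps)[unsat] > 0)

    def test_grid_vectorization_matches_scalar(self, small_engine_config):
        grid, _, _ = build(small_engine_config)
        psych = PsychometricConfig()
        vec = _p_correct_grid(grid, 4.0, 0.1, psych)
        for i in [0, 17, grid.n_points - 1]:
            assert vec[i] == pytest.approx(
                p_correct(grid.params_at(i), Stimulus(sf=4.0, contrast=0.1), psych)
            )


class TestUpdate:
    def test_bayes_rule_against_manual_computation(self, small_engine_config):
        grid, _, _ = build(small_engine_config)
        rng = np.random.default_rng(0)
        psych = PsychometricConfig()
        stim = Stimulus(sf=2.0, contrast=0.05)
        p_vec = _p_correct_grid(grid, stim.sf, stim.contrast, psych)
        mass = rng.dirichlet(np.ones(grid.n_points))
        post = Posterior(grid=grid, mass=mass)
        up_c = update(post, stim, "correct", psych)
        assert np.allclose(up_c.mass, mass * p_vec / (mass @ p_vec), atol=1e-14)
        up_i = update(post, stim, "incorrect", psych)
        assert np.allclose(up_i.mass, mass * (1 - p_vec) / (mass @ (1 - p_vec)), atol=1e-14)

    def test_two_point_hand_example_arithmetic(self):
        # prior (0.5, 0.5), likelihood (0.8, 0.6): the same Bayes arithmetic
        # the update applies, frozen by hand
        prior = np.array([0.5, 0.5])
        like = np.array([0.8, 0.6])
        post_c = prior * like / (prior @ like)
        assert post_c == pytest.approx([0.5714, 0.4286], abs=1e-4)
        post_i = prior * (1 - like) / (prior @ (1 - like))
        assert post_i == pytest.approx([1 / 3, 2 / 3], abs=1e-4)

    def test_point_mass_prior_is_absorbing(self, small_engine_config):
        grid, _, _ = build(small_engine_config)
        mass = np.zeros(grid.n_points)
        mass[5] = 1.0
        post = Posterior(grid=grid, mass=mass)
        for resp in ("correct", "incorrect"):
            out = update(post, Stimulus(sf=1.0, contrast=0.5), resp)
            assert np.array_equal(out.mass, mass)

    def test_degenerate_update_raises(self, small_engine_config):
        grid, _, _ = build(small_engine_config)
        mass = np.zeros(grid.n_points)
        mass[3] = 1.0
        post = Posterior(grid=grid, mass=mass)
        # lapse=0 makes an easy stimulus certain: incorrect annihilates mass
        psych = PsychometricConfig(lapse=0.0)
        sure = Stimulus(sf=grid.f_max[3], contrast=1.0)
        if p_correct(grid.params_at(3), sure, psych) == 1.0:
            with pytest.raises(DegenerateUpdateError):
                update(post, sure, "incorrect", psych)

    def test_mass_normalized_after_every_update(self, small_engine_config):
        grid, space, post = build(small_engine_config)
        rng = np.random.default_rng(1)
        for _ in range(50):
            j = rng.integers(space.n_candidates)
            sf, c = space.candidate(int(j))
            post = update(post, Stimulus(sf=sf, contrast=c),
                          rng.choice(["correct", "incorrect"]))
            assert abs(post.mass.sum() - 1.0) < 1e-12


class TestEntropyAndSelection:
    def test_entropy_reference_values(self, small_engine_config):
        grid, _, _ = build(small_engine_config)
        n = grid.n_points

        def post_with(head):
            mass = np.zeros(n)
            mass[: len(head)] = head
            return Posterior(grid=grid, mass=mass)

        assert posterior_entropy(post_with([0.5, 0.5])) == pytest.approx(1.0)
        assert posterior_entropy(post_with([1.0])) == pytest.approx(0.0)
        assert posterior_entropy(post_with([0.25, 0.75])) == pytest.approx(0.8113, abs=1e-4)

    def test_two_theta_hand_example(self):
        # stimulus A p=(0.9, 0.5) beats B p=(0.7, 0.7) in expected entropy
        mass = np.array([0.5, 0.5])
        eh_a = naive_expected_entropy(mass, np.array([0.9, 0.5]))
        eh_b = naive_expected_entropy(mass, np.array([0.7, 0.7]))
        assert eh_a == pytest.approx(0.8532, abs=1e-4)
        assert eh_b == pytest.approx(1.0, abs=1e-12)
        assert eh_a < eh_b

    def test_expected_entropies_match_naive_enumeration(self, small_engine_config):
        grid, space, _ = build(small_engine_config)
        rng = np.random.default_rng(2)
        psych = PsychometricConfig()
        mass = rng.dirichlet(np.ones(grid.n_points) * 0.2)
        post = Posterior(grid=grid, mass=mass)
        eh = expected_entropies(post, space, psych)
        for j in range(space.n_candidates):
            sf, c = space.candidate(j)
            p_vec = _p_correct_grid(grid, sf, c, psych)
            assert eh[j] == pytest.approx(naive_expected_entropy(mass, p_vec), abs=1e-10)

    def test_selected_stimulus_attains_exhaustive_minimum(self, small_engine_config):
        grid, space, _ = build(small_engine_config)
        rng = np.random.default_rng(3)
        psych = PsychometricConfig()
        for _ in range(5):
            mass = rng.dirichlet(np.ones(grid.n_points) * 0.5)
            post = Posterior(grid=grid, mass=mass)
            stim = select_stimulus(post, space, psych)
            eh = expected_entropies(post, space, psych)
            j = space.index_of(stim.sf, stim.contrast)
            assert eh[j] <= eh.min() + 1e-12

    def test_selection_never_exceeds_current_entropy(self, small_engine_config):
        grid, space, _ = build(small_engine_config)
        rng = np.random.default_rng(4)
        mass = rng.dirichlet(np.ones(grid.n_points))
        post = Posterior(grid=grid, mass=mass)
        eh = expected_entropies(post, space)
        assert eh.min() <= posterior_entropy(post) + 1e-12

    def test_point_mass_posterior_ties_break_to_lowest_index(self, small_engine_config):
        grid, space, _ = build(small_engine_config)
        mass = np.zeros(grid.n_points)
        mass[7] = 1.0
        post = Posterior(grid=grid, mass=mass)
        eh = expected_entropies(post, space)
        assert np.allclose(eh, 0.0, atol=1e-12)
        stim = select_stimulus(post, space)
        assert space.index_of(stim.sf, stim.contrast) == 0

    def test_fast_engine_agrees_with_reference_path(self, small_engine_config):
        eng = QcsfEngine(small_engine_config)
        rng = np.random.default_rng(5)
        mass = rng.dirichlet(np.ones(eng.grid.n_points))
        post = Posterior(grid=eng.grid, mass=mass)
        stim_fast = eng.select_stimulus(post)
        stim_ref = select_stimulus(post, eng.space, eng.psych)
        assert (stim_fast.sf, stim_fast.contrast) == (stim_ref.sf, stim_ref.contrast)
        up_fast = eng.update(post, stim_fast, "correct")
        up_ref = update(post, stim_fast, "correct", eng.psych)
        assert np.allclose(up_fast.mass, up_ref.mass, atol=1e-12)

    def test_entropy_decreases_in_expectation_for_fixed_truth(self, small_engine_config):
        eng = QcsfEngine(small_engine_config)
        rng = np.random.default_rng(6)
        truth = eng.grid.params_at(37)
        post = eng.new_posterior()
        entropies = [posterior_entropy(post)]
        for _ in range(40):
            stim = eng.select_stimulus(post)
            p = p_correct(truth, stim, eng.psych)
            resp = "correct" if rng.random() < p else "incorrect"
            post = eng.update(post, stim, resp)
            entropies.append(posterior_entropy(post))
        assert entropies[-1] < entropies[0] - 1.0  # substantial net information gain


class TestEstimateMetrics:
    def test_point_mass_recovers_closed_forms(self, small_engine_config):
        grid, _, _ = build(small_engine_config)
        i = 41
        mass = np.zeros(grid.n_points)
        mass[i] = 1.0
        est = estimate_metrics(Posterior(grid=grid, mass=mass))
        params = grid.params_at(i)
        assert est.aulcsf == pytest.approx(aulcsf(params, n_grid=512), abs=1e-9)
        assert est.csf_acuity_logmar == pytest.approx(csf_acuity(params).logmar, abs=1e-9)
        assert est.param_means["gamma_max"] == pytest.approx(params.gamma_max)

    def test_linearity_of_the_posterior_mean(self, small_engine_config):
        grid, _, _ = build(small_engine_config)
        i, j = 3, 100
        mass = np.zeros(grid.n_points)
        mass[[i, j]] = 0.5
        est = estimate_metrics(Posterior(grid=grid, mass=mass))
        a_i = aulcsf(grid.params_at(i), n_grid=512)
        a_j = aulcsf(grid.params_at(j), n_grid=512)
        assert est.aulcsf == pytest.approx((a_i + a_j) / 2, abs=1e-9)

    def test_credible_interval_brackets_mean_for_unimodal_mass(self, small_engine_config):
        grid, _, _ = build(small_engine_config)
        rng = np.random.default_rng(7)
        mass = rng.dirichlet(np.ones(grid.n_points))
        est = estimate_metrics(Posterior(grid=grid, mass=mass))
        lo, hi = est.ci["aulcsf"]
        assert lo <= est.aulcsf <= hi
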