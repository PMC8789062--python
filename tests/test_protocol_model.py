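"""Stage-level behavior of the protocol simulation."""

import numpy as np
import pytest

from protocount import protocol_model as pm
from protocount._rng import stage_rngs


def profile_of(mu):
    mu = np.asarray(mu, dtype=float)
    return pm.GeneExpressionProfile([f"g{i}" for i in range(mu.size)], mu)


def make_params(mu, n_cells, reads=10_000, **kw):
    return pm.ProtocolParameters(profile=profile_of(mu), n_cells=n_cells,
                                 sequencing=pm.SequencingSpec(reads, kw.pop("protocol", pm.FULL_LENGTH)),
                                 **kw)


class TestCellDraws:
    def test_degenerate_distributions_give_constants(self):
        params = make_params([5.0], 8,
                             heterogeneity=pm.HeterogeneityModel(1.0, 1.0),
                             capture=pm.EfficiencyModel(0.95, 0.0))
        draws = pm.draw_cell_parameters(params, 0)
        assert np.all(draws.omega == 1.0)
        assert np.all(draws.lam == 0.95)

    def test_capture_draws_match_stated_distribution(self):
        params = make_params([5.0], 10_000, capture=pm.EfficiencyModel(0.1, 0.05))
        draws = pm.draw_cell_parameters(params, 1)
        se = 0.05 / np.sqrt(10_000)
        # clamping at 0 truncates a ~2.3% tail, shifting the mean up slightly
        assert abs(draws.lam.mean() - 0.1) < 3 * se + 0.003
        assert draws.lam.min() > 0 and draws.lam.max() <= 1.0

    def test_deterministic_given_seed(self):
        params = make_params([5.0], 20)
        d1 = pm.draw_cell_parameters(params, 7)
        d2 = pm.draw_cell_parameters(params, 7)
        assert np.array_equal(d1.omega, d2.omega) and np.array_equal(d1.rho2, d2.rho2)


class TestInitialMrna:
    def test_zero_mean_gene_stays_zero(self):
        state = pm.generate_initial_mrna(profile_of([0.0, 4.0]), np.ones(50), 0)
        assert np.all(state.counts[0] == 0)

    def test_poisson_mean(self):
        state = pm.generate_initial_mrna(profile_of([10.0]), np.ones(100_000), 0)
        se = np.sqrt(10 / 100_000)
        assert abs(state.counts.mean() - 10) < 3 * se

    def test_omega_scales_mean(self):
        state = pm.generate_initial_mrna(profile_of([5.0]), np.full(100_000, 2.0), 0)
        se = np.sqrt(10 / 100_000)
        assert abs(state.counts.mean() - 10) < 3 * se


class TestCapture:
    def test_full_capture_preserves_columns(self):
        m = pm.StageState(np.array([[3, 7], [5, 0]]), "initial")
        z = pm.capture_molecules(m, np.array([1.0, 1.0]), 0)
        assert np.array_equal(z.counts.sum(0), m.counts.sum(0))

    def test_half_capture_exact_total(self):
        m = pm.StageState(np.full((10, 1), 100), "initial")
        z = pm.capture_molecules(m, np.array([0.5]), 0)
        assert z.counts.sum() == 500

    def test_multinomial_moment(self):
        # 10^4 replicate cells, each with M = (900, 100), lambda = 0.1
        m = pm.StageState(np.tile([[900], [100]], (1, 10_000)), "initial")
        z = pm.capture_molecules(m, np.full(10_000, 0.1), 0)
        # Z1 ~ Binomial(100, 0.9): mean 90, var 9
        se = np.sqrt(9 / 10_000)
        assert abs(z.counts[0].mean() - 90) < 3 * se

    def test_empty_cell_warns_and_stays_empty(self):
        m = pm.StageState(np.array([[0, 5]]), "initial")
        with pytest.warns(UserWarning, match="zero molecules"):
            z = pm.capture_molecules(m, np.array([0.5, 1.0]), 0)
        assert z.counts[0, 0] == 0 and z.counts[0, 1] == 5


class TestAmplify:
    @pytest.mark.parametrize("z,rho,cycles,expected", [
        (10, 1.0, 3, 80),
        (7, 1.0, 0, 7),
        (7, 0.95, 18, round(7 * 1.95 ** 18)),
    ])
    def test_arithmetic(self, z, rho, cycles, expected):
        state = pm.StageState(np.array([[z]]), "captured")
        out = pm.amplify(state, np.array([rho]), cycles)
        assert out.counts[0, 0] == expected

    def test_unique_molecules_pass_through(self):
        state = pm.StageState(np.array([[4]]), "captured", unique_molecules=np.array([[4]]))
        out = pm.amplify(state, np.array([1.0]), 5)
        assert np.array_equal(out.unique_molecules, [[4]])


class TestEqualization:
    def test_concentration_is_column_total(self):
        state = pm.StageState(np.array([[3, 0], [7, 0]]), "preamplified")
        assert np.array_equal(pm.cdna_concentrations(state), [10.0, 0.0])

    def test_tau_rule_above_target(self):
        # q* = min(l) = 1; the cell at 2*q* gets tau = 0.5, at q* gets tau = 1
        spec = pm.EqualizationSpec(enabled=True, mode=pm.DILUTE_TO_MIN, noise_sd=0.0)
        s, qstar = pm.compute_dilution_factors(np.array([1.0, 2.0]), spec, 0)
        assert qstar == 1.0
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(0.5)

    def test_in_range_cells_keep_retained_fraction(self):
        # quantile_range puts q* above the smallest cells -> they get 0.95
        spec = pm.EqualizationSpec(enabled=True, mode=pm.QUANTILE_RANGE,
                                   quantile=1.0, noise_sd=0.0)
        s, qstar = pm.compute_dilution_factors(np.array([1.0, 10.0]), spec, 0)
        assert qstar == pytest.approx(5.5)
        assert s[0] == pytest.approx(0.95)
        assert s[1] == pytest.approx(0.55)

    def test_equal_concentrations_all_tau_one(self):
        spec = pm.EqualizationSpec(enabled=True, mode=pm.DILUTE_TO_MIN, noise_sd=0.0)
        s, _ = pm.compute_dilution_factors(np.full(5, 100.0), spec, 0)
        assert np.all(s == 1.0)

    def test_all_zero_concentrations_error(self):
        with pytest.raises(ValueError, match="zero cDNA"):
            pm.compute_dilution_factors(np.zeros(3), pm.EqualizationSpec(enabled=True), 0)

    def test_equalize_totals(self):
        state = pm.StageState(np.full((10, 2), 100), "preamplified")
        out = pm.equalize(state, np.array([1.0, 0.5]), 0)
        assert out.counts[:, 0].sum() == 1000
        assert out.counts[:, 1].sum() == 500

    def test_diluted_cells_land_on_target(self):
        # with no noise, every cell above q* ends up at round(q*) molecules
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(50, 6)) + 1
        state = pm.StageState(counts, "preamplified")
        l = pm.cdna_concentrations(state)
        spec = pm.EqualizationSpec(enabled=True, mode=pm.DILUTE_TO_MIN, noise_sd=0.0)
        s, qstar = pm.compute_dilution_factors(l, spec, 0)
        out = pm.equalize(state, s, 0)
        totals = out.counts.sum(0)
        assert np.all(np.abs(totals - qstar) <= 1)


class TestTagmentAndSequence:
    def test_tagment_totals(self):
        state = pm.StageState(np.full((20, 1), 100), "equalized")
        out = pm.tagment(state, np.array([0.95]), 0)
        assert out.counts.sum() == 1900

    def test_sequencing_conserves_reads(self):
        state = pm.StageState(np.arange(1, 21).reshape(4, 5), "amplified2")
        out = pm.sequence_reads(state, 12_345, 0)
        assert out.counts.sum() == 12_345

    def test_single_entry_receives_everything(self):
        b = np.zeros((3, 3), dtype=int)
        b[1, 2] = 10
        out = pm.sequence_reads(pm.StageState(b, "amplified2"), 500, 0)
        assert out.counts[1, 2] == 500

    def test_marginal_fractions(self):
        b = np.array([[75], [25]])
        out = pm.sequence_reads(pm.StageState(b, "amplified2"), 10_000, 0)
        se = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(out.counts[0, 0] / 10_000 - 0.75) < 3 * se

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pm.sequence_reads(pm.StageState(np.zeros((2, 2), dtype=int), "amplified2"), 10, 0)


class TestCollapseUmi:
    def test_no_reads_no_umis(self):
        state = pm.StageState(np.array([[0]]), "sequenced")
        out = pm.collapse_umi(state, np.array([[5]]), 0)
        assert out[0, 0] == 0

    def test_single_molecule_caps_at_one(self):
        state = pm.StageState(np.array([[7]]), "sequenced")
        out = pm.collapse_umi(state, np.array([[1]]), 0)
        assert out[0, 0] == 1

    def test_occupancy_expectation(self):
        # u=10 molecules, r=10 reads: E[distinct] = 10 * (1 - 0.9^10)
        reads = np.full((1, 10_000), 10)
        uniq = np.full((1, 10_000), 10)
        out = pm.collapse_umi(pm.StageState(reads, "sequenced"), uniq, 0)
        expected = 10 * (1 - (1 - 1 / 10) ** 10)
        se = out.std(ddof=1) / np.sqrt(out.size)
        assert abs(out.mean() - expected) < 3 * se


class TestSimulateExperiment:
    def test_grand_total_is_read_budget(self):
        params = make_params(np.full(50, 20.0), 10, reads=30_000)
        result = pm.simulate_experiment(params, 0)
        assert result.counts.sum() == 30_000

    def test_bit_identical_given_seed(self):
        params = make_params(np.full(50, 20.0), 10)
        r1 = pm.simulate_experiment(params, 11)
        r2 = pm.simulate_experiment(params, 11)
        assert np.array_equal(r1.counts, r2.counts)

    def test_droplet_rejects_equalization(self):
        with pytest.raises(ValueError, match="droplet"):
            make_params(np.full(10, 5.0), 4, protocol=pm.DROPLET,
                        equalization=pm.EqualizationSpec(enabled=True))

    def test_umi_counts_bounded_by_captured_molecules(self):
        params = make_params(np.full(100, 10.0), 20, reads=200_000, protocol=pm.UMI_PLATE)
        result = pm.simulate_experiment(params, 0, keep_stages=True)
        captured = next(s for s in result.stages if s.stage == "captured")
        assert np.all(result.counts <= captured.unique_molecules)

    def test_equalization_toggle_shares_other_streams(self):
        params = make_params(np.full(100, 10.0), 10, reads=50_000)
        from dataclasses import replace
        p_eq = replace(params, equalization=pm.EqualizationSpec(enabled=True))
        r_un = pm.simulate_experiment(params, 5, keep_stages=True)
        r_eq = pm.simulate_experiment(p_eq, 5, keep_stages=True)
        for stage in ("initial", "captured", "preamplified"):
            a = next(s for s in r_un.stages if s.stage == stage)
            b = next(s for s in r_eq.stages if s.stage == stage)
            assert np.array_equal(a.counts, b.counts)


class TestModelProperties:
    def test_thinning_composition(self):
        # capture at lambda then tagment at gamma ~ single thinning at lambda*gamma
        rng = np.random.default_rng(0)
        m = pm.StageState(rng.poisson(30, (50, 20)), "initial")
        lam, gam = 0.6, 0.5
        z = pm.capture_molecules(m, np.full(20, lam), 1)
        t = pm.tagment(pm.StageState(z.counts, "equalized"), np.full(20, gam), 2)
        expected = np.rint(gam * np.rint(lam * m.counts.sum(0)))
        assert np.all(np.abs(t.counts.sum(0) - expected) <= 1)
        single = np.rint(lam * gam * m.counts.sum(0))
        assert np.all(np.abs(t.counts.sum(0) - single) <= 1)

    @pytest.mark.parametrize("mu_probe", [0.5, 2.0, 10.0])
    def test_capture_zero_rate_closed_form(self, mu_probe):
        # many background genes make per-gene capture ~ independent thinning:
        # P(zero) -> exp(-lambda * omega * mu).  The fixed-total multinomial
        # samples with replacement, so the exact rate is exp(-mu(1-e^-lam));
        # the Poisson-thinning form holds in the small-lambda limit.
        lam_eff = 0.05
        mu = np.concatenate([[mu_probe], np.full(300, 5.0)])
        n = 10_000
        rngs = stage_rngs(0)
        state = pm.generate_initial_mrna(profile_of(mu), np.ones(n), rng=rngs["initial"])
        z = pm.capture_molecules(state, np.full(n, lam_eff), rng=rngs["capture"])
        frac_zero = np.mean(z.counts[0] == 0)
        p = np.exp(-lam_eff * mu_probe)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac_zero - p) < 3 * se

    def test_detection_monotone_in_read_budget(self):
        mu = np.full(200, 5.0)
        rates = []
        for reads in (5_000, 50_000):
            vals = []
            for rep in range(10):
                params = make_params(mu, 10, reads=reads)
                res = pm.simulate_experiment(params, 100 + rep)
                vals.append(np.count_nonzero(res.counts, axis=0).mean() / 200)
            rates.append(np.mean(vals))
        assert rates[1] >= rates[0]

    def test_equalization_lowers_depth_cv(self):
        from dataclasses import replace
        mu = np.random.default_rng(1).lognormal(1, 1.5, 300)
        params = make_params(mu, 30, reads=100_000)
        p_eq = replace(params, equalization=pm.EqualizationSpec(enabled=True))
        lower = 0
        for s in range(6):
            du = pm.simulate_experiment(params, 200 + s).counts.sum(0)
            de = pm.simulate_experiment(p_eq, 200 + s).counts.sum(0)
            lower += (de.std() / de.mean()) < (du.std() / du.mean())
        assert lower == 6
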