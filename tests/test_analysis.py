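import numpy as np
import pytest
from scipy import stats

from fluxprof.analysis import (
    constrained_scan,
    correlations,
    flux_sum,
    flux_sum_per_sample,
    histogram,
    normalize,
    summarize,
)
from fluxprof.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    stoichiometric_matrix,
)
from fluxprof.sampling import FluxSampleSet, SamplerConfig, sample
from fluxprof.synthetic import make_box_polytope


def _sample_set(arr, ids=None):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"R{j}" for j in range(arr.shape[1])]
    return FluxSampleSet(reaction_ids=list(ids), samples=arr)


class TestSummarize:
    def test_constant_samples_have_zero_sd(self):
        s = summarize(_sample_set(np.tile([1.0, -2.0], (5, 1))))
        np.testing.assert_array_equal(s.sd, [0.0, 0.0])

    def test_two_point_closed_form(self):
        s = summarize(_sample_set([[0.0], [10.0]]))
        assert s.mean[0] == pytest.approx(5.0)
        assert s.sd[0] == pytest.approx(7.0711, abs=1e-4)

    def test_matches_naive_loop(self, toy_model, quick_config):
        smp = sample(toy_model, quick_config)
        s = summarize(smp)
        for j in range(smp.samples.shape[1]):  # brute-force recomputation
            col = [smp.samples[i, j] for i in range(smp.n_samples)]
            assert s.mean[j] == pytest.approx(sum(col) / len(col), abs=1e-12)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            summarize(_sample_set([[1.0]]))


class TestNormalize:
    def test_reference_already_on_target_unchanged(self):
        s = summarize(_sample_set(np.tile([-10.0, 3.0], (4, 1)), ["EX_glc", "R1"]))
        n = normalize(s, "EX_glc", 10.0)
        np.testing.assert_allclose(n.mean, s.mean)

    def test_scale_doubles_when_reference_is_half(self):
        s = summarize(_sample_set(np.tile([-5.0, 3.0], (4, 1)), ["EX_glc", "R1"]))
        n = normalize(s, "EX_glc", 10.0)
        assert n.value("EX_glc") == pytest.approx(-10.0)
        assert n.value("R1") == pytest.approx(6.0)

    def test_reference_magnitude_exact_and_ratios_preserved(self, toy_model, quick_config):
        s = summarize(sample(toy_model, quick_config))
        n = normalize(s, "EX_glc_e", 10.0)
        assert abs(n.value("EX_glc_e")) == 10.0  # exact, not approximate
        nz = np.abs(s.mean) > 1e-9
        idx = np.flatnonzero(nz)
        ratios_before = s.mean[idx[0]] / s.mean[idx[1:]]
        ratios_after = n.mean[idx[0]] / n.mean[idx[1:]]
        np.testing.assert_allclose(ratios_after, ratios_before, rtol=1e-12)

    def test_zero_reference_rejected(self):
        s = summarize(_sample_set(np.zeros((3, 1)), ["EX_glc"]))
        with pytest.raises(ZeroDivisionError):
            normalize(s, "EX_glc", 10.0)


class TestFluxSum:
    def test_isolated_metabolite_zero(self):
        S = np.array([[0.0, 0.0], [-1.0, 1.0]])
        fs = flux_sum(S, np.array([2.0, 2.0]), ["orphan", "B"])
        assert fs.value("orphan") == 0.0

    def test_simple_conversion_closed_form(self):
        # steady-state chain: -> A -> B ->, all carrying flux 5; the
        # turnover of each metabolite equals the through-flux
        S = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        fs = flux_sum(S, np.array([5.0, 5.0, 5.0]), ["A", "B"])
        assert fs.value("A") == pytest.approx(5.0)
        assert fs.value("B") == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            m, n = rng.integers(1, 8), rng.integers(1, 8)
            S = rng.standard_normal((m, n)) * (rng.random((m, n)) < 0.5)
            v = rng.standard_normal(n) * 10
            expected = [
                0.5 * sum(abs(S[i, j] * v[j]) for j in range(n)) for i in range(m)
            ]
            np.testing.assert_allclose(flux_sum(S, v).phi, expected, atol=1e-12)

    def test_absolute_homogeneity(self, rng):
        S = rng.standard_normal((4, 6))
        v = rng.standard_normal(6)
        for c in (-3.0, 0.0, 0.25):
            np.testing.assert_allclose(
                flux_sum(S, c * v).phi, abs(c) * flux_sum(S, v).phi, atol=1e-12
            )

    def test_production_consumption_balance_at_steady_state(self, toy_model, quick_config):
        smp = sample(toy_model, quick_config)
        S = stoichiometric_matrix(toy_model)
        v = summarize(smp).mean
        contrib = S * v[None, :]
        production = np.maximum(contrib, 0).sum(axis=1)
        consumption = -np.minimum(contrib, 0).sum(axis=1)
        tol = len(toy_model.reactions) * quick_config.residual_tolerance
        np.testing.assert_allclose(production, consumption, atol=tol)
        np.testing.assert_allclose(
            flux_sum(S, v).phi, production, atol=tol
        )

    def test_per_sample_mode_differs_for_sign_varying_flux(self):
        S = np.array([[1.0, -1.0]])
        samples = _sample_set([[1.0, 1.0], [-1.0, -1.0]], ["R1", "R2"])
        model = MetabolicModel(
            id="m",
            metabolites=(Metabolite("A"),),
            reactions=(
                Reaction("R1", {"A": 1.0}, -10, 10),
                Reaction("R2", {"A": -1.0}, -10, 10),
            ),
        )
        on_mean = flux_sum(S, summarize(samples).mean, ["A"])
        per_sample = flux_sum_per_sample(samples, model)
        assert on_mean.value("A") == pytest.approx(0.0)
        assert per_sample.value("A") == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            flux_sum(np.zeros((2, 3)), np.zeros(4))


class TestCorrelations:
    def test_diagonal_is_one_and_symmetric(self, toy_model, quick_config):
        c = correlations(sample(toy_model, quick_config))
        defined = ~np.isnan(np.diag(c.r))
        np.testing.assert_allclose(np.diag(c.r)[defined], 1.0, atol=1e-12)
        np.testing.assert_allclose(c.r, c.r.T, equal_nan=True)
        assert np.nanmax(np.abs(c.r)) <= 1 + 1e-12

    def test_stoichiometrically_coupled_pair_fully_correlated(self):
        v1 = np.linspace(0, 5, 50)
        c = correlations(_sample_set(np.column_stack([v1, 2 * v1]), ["a", "b"]))
        assert c.value("a", "b") == pytest.approx(1.0)

    def test_zero_variance_reaction_flagged_nan(self):
        v1 = np.linspace(0, 5, 50)
        c = correlations(_sample_set(np.column_stack([v1, np.zeros(50)]), ["a", "z"]))
        assert np.isnan(c.value("a", "z"))
        assert np.isnan(c.value("z", "z"))
        assert c.value("a", "a") == pytest.approx(1.0)

    def test_nadh_dehydrogenase_opposes_ethanol_branch(self, toy_nzn):
        # in the double knockout the quinone route and the ethanol branch
        # compete for the same NADH pool
        smp = sample(toy_nzn, SamplerConfig(n_samples=500, steps_per_sample=30, seed=21))
        c = correlations(smp)
        assert c.value("NADH16", "ADHE") < 0


class TestHistogram:
    def test_constant_flux_single_occupied_bin(self):
        h = histogram(_sample_set(np.full((30, 1), 2.5), ["R0"]), "R0", n_bins=5)
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == 30

    def test_one_bin_holds_everything(self):
        h = histogram(_sample_set(np.linspace(0, 1, 40)[:, None], ["R0"]), "R0", n_bins=1)
        assert h.counts.tolist() == [40]

    def test_uniform_samples_flat_by_chisquare(self):
        box = make_box_polytope(1, [0.0], [10.0])
        smp = sample(box, SamplerConfig(n_samples=2000, seed=8))
        h = histogram(smp, "R1", n_bins=10)
        assert h.counts.sum() == 2000
        assert stats.chisquare(h.counts).pvalue > 0.01

    def test_unknown_reaction_rejected(self):
        with pytest.raises(KeyError):
            histogram(_sample_set(np.zeros((5, 1))), "missing", 3)


class TestConstrainedScan:
    def test_bins_partition_range_and_respect_bounds(self, toy_nzn):
        cfg = SamplerConfig(n_samples=80, steps_per_sample=10, seed=6)
        bins = constrained_scan(
            toy_nzn, "EX_succ_e", 2, cfg,
            normalize_reference="EX_glc_e", keep_samples=True,
        )
        assert len(bins) == 2
        assert bins[0].bounds[1] == pytest.approx(bins[1].bounds[0])
        for b in bins:
            succ = b.samples.column("EX_succ_e")
            assert (succ >= b.bounds[0] - 1e-9).all()
            assert (succ <= b.bounds[1] + 1e-9).all()
            assert abs(b.summary.value("EX_glc_e")) == 10.0

    def test_single_bin_covers_full_range(self, toy_nzn):
        from fluxprof.lp import optimize_reaction

        cfg = SamplerConfig(n_samples=40, steps_per_sample=5, seed=2)
        (b,) = constrained_scan(toy_nzn, "EX_succ_e", 1, cfg)
        v_max = optimize_reaction(toy_nzn, "EX_succ_e", "max").objective
        assert b.bounds == (0.0, pytest.approx(v_max))
        assert b.feasible

    def test_infeasible_bin_recorded_and_scan_continues(self):
        # v1 = v2 with v2 >= 4 makes the low bin of v1 empty
        m = MetabolicModel(
            id="gap",
            metabolites=(Metabolite("A"),),
            reactions=(
                Reaction("R1", {"A": 1.0}, 0.0, 10.0),
                Reaction("R2", {"A": -1.0}, 4.0, 10.0),
            ),
        )
        cfg = SamplerConfig(n_samples=30, steps_per_sample=5, seed=3)
        bins = constrained_scan(m, "R1", 4, cfg)
        # [0, 2.5] cannot reach v2 >= 4; [2.5, 5] is partially feasible
        assert [b.feasible for b in bins] == [False, True, True, True]
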