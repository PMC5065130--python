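"""Simulator: effect sampling, phenotypes, measurement noise, adaptive walks."""

import io
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from enzevo.effects import expected_total_change, observed_total_change
from enzevo.simgen import (
    SimConfig,
    SimulationError,
    genotype_phenotype,
    measure,
    run_walk,
    sample_effects,
    simulate_library,
)
from enzevo.variant_io import parse_genotype, write_activity_table


class TestSampleEffects:
    def test_degenerate_spread_gives_means(self):
        cfg = SimConfig(sigma_old=0.0, sigma_new=0.0, mu_old=-0.3, mu_new=0.4, seed=1)
        eff, _ = sample_effects(cfg)
        assert np.allclose(eff["true_log10_old"], -0.3)
        assert np.allclose(eff["true_log10_new"], 0.4)

    def test_perfect_correlation(self):
        cfg = SimConfig(rho=1.0, mu_old=-0.2, mu_new=-0.2, sigma_old=0.5,
                        sigma_new=0.5, seed=2)
        eff, _ = sample_effects(cfg)
        assert np.allclose(eff["true_log10_old"], eff["true_log10_new"])

    def test_sample_correlation_matches_rho(self):
        cfg = SimConfig(n_candidate_pool=100_000, rho=0.6, seed=3)
        eff, _ = sample_effects(cfg)
        r = np.corrcoef(eff["true_log10_old"], eff["true_log10_new"])[0, 1]
        assert r == pytest.approx(0.6, abs=0.01)

    def test_interaction_density(self):
        cfg = SimConfig(n_candidate_pool=40, m_per_round=10, n_rounds=5,
                        epistasis_density=0.1, epistasis_sigma=0.3, seed=4)
        _, inter = sample_effects(cfg)
        n_pairs = 40 * 39 // 2
        assert len(inter) == 2 * round(0.1 * n_pairs)  # one term per activity
        assert set(inter["activity"]) == {"native", "new"}

    def test_invalid_correlation_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(rho=1.5)

    def test_mutation_tokens_are_parseable(self):
        cfg = SimConfig(n_candidate_pool=45, m_per_round=10, n_rounds=5, seed=5)
        eff, _ = sample_effects(cfg)
        for tok in eff["mutation"]:
            (m,) = parse_genotype(tok)
            assert m.label == tok


class TestGenotypePhenotype:
    def _effects(self):
        return pd.DataFrame(
            {
                "mutation": ["A1C", "C2D", "D3E"],
                "true_log10_old": [-1.0, -1.0, 0.5],
                "true_log10_new": [2.0, 2.0, 0.0],
            }
        )

    def test_empty_genotype_is_wildtype(self):
        assert genotype_phenotype([], self._effects()) == (1.0, 1.0)

    def test_additivity(self):
        old, new = genotype_phenotype(["A1C", "C2D"], self._effects())
        assert old == pytest.approx(1e-2)
        assert new == pytest.approx(1e4)

    def test_interaction_term_added(self):
        inter = pd.DataFrame(
            [{"mut_a": "A1C", "mut_b": "C2D", "activity": "native", "term": 1.0}]
        )
        old, new = genotype_phenotype(["A1C", "C2D"], self._effects(), inter)
        assert old == pytest.approx(1e-1)
        assert new == pytest.approx(1e4)

    def test_unknown_mutation_rejected(self):
        with pytest.raises(SimulationError):
            genotype_phenotype(["Z9A"], self._effects())


class TestMeasure:
    def test_noise_free_measurement_is_exact(self):
        cfg = SimConfig(noise_cv=0.0, n_batches=2, n_replicates=3, seed=6)
        recs = measure(0.7, cfg, np.random.default_rng(0), "v")
        assert len(recs) == 6
        assert all(r.rate == 0.7 for r in recs)
        assert {r.batch for r in recs} == {"b1", "b2"}

    def test_below_detection_all_censored(self):
        cfg = SimConfig(noise_cv=0.0, detection_limit=0.01, seed=6)
        recs = measure(1e-4, cfg, np.random.default_rng(0), "v")
        assert all(r.censor == "below" for r in recs)
        assert all(r.rate <= r.detection_limit for r in recs)

    def test_empirical_cv_matches_config(self):
        cfg = SimConfig(noise_cv=0.2, n_batches=1, n_replicates=1, seed=6)
        rng = np.random.default_rng(8)
        vals = np.array(
            [measure(1.0, cfg, rng, "v")[0].rate for _ in range(100_000)]
        )
        cv = vals.std(ddof=1) / vals.mean()
        assert cv == pytest.approx(0.2, rel=0.05)
        assert np.median(vals) == pytest.approx(1.0, rel=0.02)


class TestRunWalk:
    def test_same_seed_byte_identical(self):
        def dump(res):
            buf = io.StringIO()
            write_activity_table(res.table, buf)
            return buf.getvalue()

        a = run_walk(SimConfig(seed=7))
        b = run_walk(SimConfig(seed=7))
        assert dump(a) == dump(b)
        assert a.trajectory.equals(b.trajectory)
        assert np.array_equal(a.truth.true_old, b.truth.true_old)

    def test_m_equal_one_regimes_coincide(self):
        base = SimConfig(seed=3, m_per_round=1, n_candidate_pool=15, n_rounds=5)
        g = run_walk(replace(base, regime="greedy_new_activity"))
        r = run_walk(replace(base, regime="random_accept"))
        assert g.truth.genotypes == r.truth.genotypes

    def test_noise_free_greedy_picks_true_argmax(self):
        cfg = SimConfig(seed=9, noise_cv=0.0, n_rounds=6)
        res = run_walk(cfg, emit_tables=False)
        eff = res.truth.effects.set_index("mutation")
        for rnd in range(1, 7):
            screened = res.truth.screened[rnd - 1]
            accepted = set(res.truth.genotypes[rnd]) - set(res.truth.genotypes[rnd - 1])
            (accepted,) = accepted
            best = max(screened, key=lambda m: eff.loc[m, "true_log10_new"])
            assert accepted == best

    def test_pool_exhaustion_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(n_candidate_pool=20, m_per_round=15, n_rounds=10, seed=1)
        # boundary: pool exactly m + rounds - 1 is feasible
        cfg = SimConfig(n_candidate_pool=24, m_per_round=15, n_rounds=10, seed=1)
        res = run_walk(cfg, emit_tables=False)
        assert len(res.truth.genotypes[-1]) == 10

    def test_emitted_tables_chain_and_validate(self):
        res = run_walk(SimConfig(seed=10, n_rounds=4))
        assert res.table.substrate_roles == {"native": "native", "new": "new"}
        assert list(res.trajectory["variant_id"]) == [f"R{i}" for i in range(5)]
        # parent chaining in the activity table matches the trajectory table
        frame = res.table.frame
        for row in res.trajectory.itertuples(index=False):
            parents = set(
                frame.loc[frame["variant_id"] == row.variant_id, "parent_id"]
            )
            assert parents == {row.parent_id}

    def test_truth_free_mode_matches_table_mode(self):
        a = run_walk(SimConfig(seed=11), emit_tables=False)
        b = run_walk(SimConfig(seed=11), emit_tables=True)
        assert a.table is None and b.table is not None
        assert np.array_equal(a.truth.true_new, b.truth.true_new)


class TestPipelineClosure:
    def test_additivity_closure_without_noise_or_epistasis(self):
        """With epistasis and noise off, the null-model prediction from
        single-mutant effects equals the observed end-to-start change."""
        res = run_walk(SimConfig(seed=12, noise_cv=0.0), emit_tables=False)
        eff = res.truth.effects.set_index("mutation")
        folds = [10.0 ** eff.loc[m, "true_log10_old"] for m in res.truth.genotypes[-1]]
        predicted = expected_total_change(folds).value
        observed = observed_total_change(res.truth.true_old[0], res.truth.true_old[-1])
        assert abs(predicted - observed) / observed < 1e-9

    def test_epistasis_breaks_additivity(self):
        cfg = SimConfig(seed=13, noise_cv=0.0, epistasis_density=0.5,
                        epistasis_sigma=0.5)
        res = run_walk(cfg, emit_tables=False)
        eff = res.truth.effects.set_index("mutation")
        folds = [10.0 ** eff.loc[m, "true_log10_old"] for m in res.truth.genotypes[-1]]
        predicted = expected_total_change(folds).value
        observed = observed_total_change(res.truth.true_old[0], res.truth.true_old[-1])
        assert abs(math.log10(predicted) - math.log10(observed)) > 0.1

    def test_estimated_effects_recover_truth(self):
        """Measured single-mutant libraries feed the effects pipeline and
        recover the generating log10 effects within noise."""
        from enzevo.effects import effects_vs_background

        cfg = SimConfig(seed=14, noise_cv=0.1)
        table, truth = simulate_library(cfg, n_variants=40)
        effs = effects_vs_background(table, "wt", substrate="native")
        truth_map = dict(zip(truth["mutation"], truth["true_log10_old"]))
        errors = [e.log10_effect - truth_map[e.mutation] for e in effs]
        assert np.max(np.abs(errors)) < 0.25
        assert abs(np.mean(errors)) < 0.03

    def test_censoring_flows_through_library(self):
        cfg = SimConfig(seed=15, noise_cv=0.0, detection_limit=0.05,
                        mu_old=-3.0, sigma_old=0.0)
        table, _ = simulate_library(cfg, n_variants=5)
        from enzevo.effects import effects_vs_background

        effs = effects_vs_background(table, "wt", substrate="native")
        assert all(e.censor_bound == "at_most" for e in effs)
        assert all(e.bound == pytest.approx(0.05) for e in effs)
        assert all(e.effect_class == "deleterious" for e in effs)
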