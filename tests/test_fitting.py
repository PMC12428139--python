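"""Least-squares fitting: recovery, identifiability guards, model selection."""

import numpy as np
import pytest

from conftest import (OXALATE_C, OXALATE_MT, TRUNC_HILL_PEP, WT_BIBI,
                      WT_MM_PEP)
from enzkin.errors import DesignError, UsageError
from enzkin.fitting import (TRUTH_KEY, VelocityDataset, fit_global_bisubstrate,
                            fit_inhibition, fit_single_substrate, predict,
                            select_model)
from enzkin.synthetic_data import (DesignSpec, NoiseModel, generate_velocities,
                                   paper_design)

NOISELESS = NoiseModel(cv=0.0, seed=0)


def _fit(dataset, model_id):
    if model_id in ("mm", "hill"):
        return fit_single_substrate(dataset, model_id)
    if model_id == "bibi":
        return fit_global_bisubstrate(dataset)
    return fit_inhibition(dataset, model_id)


SCENARIOS = [
    ("mm", "fig2_mg_pep", WT_MM_PEP),
    ("hill", "truncated_pep", TRUNC_HILL_PEP),
    ("bibi", "fig4_bisubstrate", WT_BIBI),
    ("C", "fig5a_oxalate", OXALATE_C),
    ("MT", "fig5b_oxalate_adp", OXALATE_MT),
]


class TestZeroNoiseRecovery:
    @pytest.mark.parametrize("model_id, figure, truth", SCENARIOS)
    def test_exact_recovery_on_own_design(self, model_id, figure, truth):
        dataset = generate_velocities(paper_design(figure), model_id, truth,
                                      NOISELESS)
        result = _fit(dataset, model_id)
        assert result.converged
        for name, value in truth.items():
            assert result.parameters[name] == pytest.approx(value, rel=1e-6)

    def test_fit_is_deterministic(self):
        dataset = generate_velocities(paper_design("fig2_mg_pep"), "mm",
                                      WT_MM_PEP, NoiseModel(cv=0.02, seed=3))
        r1 = fit_single_substrate(dataset, "mm")
        r2 = fit_single_substrate(dataset, "mm")
        assert r1.parameters == r2.parameters
        assert r1.n_starts_used == 8


class TestDesignGuards:
    def test_too_few_substrate_levels(self):
        design = DesignSpec(kind="single_substrate", a_levels=(0.1, 0.2, 0.4))
        dataset = generate_velocities(design, "mm", WT_MM_PEP, NOISELESS)
        with pytest.raises(DesignError):
            fit_single_substrate(dataset, "mm")

    def test_hill_needs_five_levels(self):
        design = DesignSpec(kind="single_substrate",
                            a_levels=(0.1, 0.2, 0.4, 0.8))
        dataset = generate_velocities(design, "hill", TRUNC_HILL_PEP, NOISELESS)
        with pytest.raises(DesignError):
            fit_single_substrate(dataset, "hill")

    def test_single_b_level_is_unidentifiable(self):
        design = DesignSpec(kind="bisubstrate_grid",
                            a_levels=(0.024, 0.048, 0.097, 0.48),
                            b_levels=(0.024,))
        dataset = generate_velocities(design, "bibi", WT_BIBI, NOISELESS)
        with pytest.raises(DesignError):
            fit_global_bisubstrate(dataset)

    def test_inhibition_needs_zero_level(self):
        design = DesignSpec(kind="inhibition_grid",
                            a_levels=(0.01, 0.05, 0.1, 0.5),
                            i_levels=(0.05, 0.1, 0.25))
        dataset = generate_velocities(design, "C", OXALATE_C, NOISELESS)
        with pytest.raises(DesignError):
            fit_inhibition(dataset, "C")

    def test_wrong_design_kind(self):
        dataset = generate_velocities(paper_design("fig2_mg_pep"), "mm",
                                      WT_MM_PEP, NOISELESS)
        with pytest.raises(DesignError):
            fit_global_bisubstrate(dataset)


class TestOptimality:
    def test_no_lattice_point_beats_optimum(self):
        """Brute-force oracle: the converged SSE is at most the minimum over a
        coarse 20x20x20 parameter lattice around the truth."""
        dataset = generate_velocities(paper_design("fig4_bisubstrate"), "bibi",
                                      WT_BIBI, NoiseModel(cv=0.02, seed=11))
        result = fit_global_bisubstrate(dataset)
        v = dataset.frame["v"].to_numpy()
        a = dataset.frame["a"].to_numpy()
        b = dataset.frame["b"].to_numpy()
        best_lattice = np.inf
        for vmax in np.geomspace(WT_BIBI["vmax"] / 2, WT_BIBI["vmax"] * 2, 20):
            for ka in np.geomspace(WT_BIBI["ka"] / 2, WT_BIBI["ka"] * 2, 20):
                for kb in np.geomspace(WT_BIBI["kb"] / 2, WT_BIBI["kb"] * 2, 20):
                    pred = predict("bibi", {"vmax": vmax, "ka": ka, "kb": kb},
                                   a, b)
                    best_lattice = min(best_lattice,
                                       float(np.sum((v - pred) ** 2)))
        assert result.sse <= best_lattice * (1 + 1e-8)

    def test_matches_independent_optimizer(self):
        """Cross-check against lmfit on the same objective."""
        lmfit = pytest.importorskip("lmfit")
        dataset = generate_velocities(paper_design("fig2_mg_pep"), "mm",
                                      WT_MM_PEP, NoiseModel(cv=0.02, seed=5))
        ours = fit_single_substrate(dataset, "mm")
        a = dataset.frame["a"].to_numpy()
        v = dataset.frame["v"].to_numpy()
        params = lmfit.Parameters()
        params.add("vmax", value=np.max(v), min=0)
        params.add("km", value=np.median(a), min=0)
        out = lmfit.minimize(
            lambda p: v - p["vmax"] * a / (p["km"] + a), params)
        assert ours.parameters["vmax"] == pytest.approx(
            out.params["vmax"].value, rel=1e-6)
        assert ours.parameters["km"] == pytest.approx(
            out.params["km"].value, rel=1e-6)

    def test_global_beats_per_curve_constraint(self):
        """The global bi-substrate SSE cannot exceed what any shared-parameter
        per-curve reconstruction would give on the same data."""
        dataset = generate_velocities(paper_design("fig4_bisubstrate"), "bibi",
                                      WT_BIBI, NoiseModel(cv=0.02, seed=2))
        result = fit_global_bisubstrate(dataset)
        pred = predict("bibi", WT_BIBI, dataset.frame["a"].to_numpy(),
                       dataset.frame["b"].to_numpy())
        sse_truth = float(np.sum((dataset.frame["v"].to_numpy() - pred) ** 2))
        assert result.sse <= sse_truth + 1e-12


class TestNoisyRecovery:
    def test_km_recovered_within_ten_percent(self):
        """2 % proportional noise, 3 replicates: Km lands within 10 % of
        truth in nearly every seeded draw (20-seed regression check)."""
        hits = 0
        for seed in range(20):
            dataset = generate_velocities(paper_design("fig2_mg_pep"), "mm",
                                          WT_MM_PEP,
                                          NoiseModel(cv=0.02, seed=seed))
            result = fit_single_substrate(dataset, "mm")
            hits += abs(result.parameters["km"] - WT_MM_PEP["km"]) \
                / WT_MM_PEP["km"] < 0.10
        assert hits >= 18

    def test_more_replicates_do_not_hurt(self):
        """Doubling replicates at fixed noise does not increase the median
        absolute Km error (fixed seed set)."""
        def median_err(replicates):
            errs = []
            for seed in range(30):
                dataset = generate_velocities(
                    paper_design("fig2_mg_pep", replicates=replicates), "mm",
                    WT_MM_PEP, NoiseModel(cv=0.02, seed=400 + seed))
                result = fit_single_substrate(dataset, "mm")
                errs.append(abs(result.parameters["km"] - WT_MM_PEP["km"]))
            return float(np.median(errs))

        assert median_err(6) <= median_err(3)

    def test_fitter_never_reads_truth_metadata(self):
        dataset = generate_velocities(paper_design("fig2_mg_pep"), "mm",
                                      WT_MM_PEP, NoiseModel(cv=0.02, seed=9))
        assert TRUTH_KEY in dataset.metadata
        stripped = VelocityDataset(dataset.frame, dataset.design_kind, {})
        r1 = fit_single_substrate(dataset, "mm")
        r2 = fit_single_substrate(stripped, "mm")
        assert r1.parameters == r2.parameters


class TestModelSelection:
    def test_single_candidate_returned(self):
        dataset = generate_velocities(paper_design("fig5a_oxalate"), "C",
                                      OXALATE_C, NOISELESS)
        fit = fit_inhibition(dataset, "C")
        selection = select_model([fit])
        assert selection.best is fit

    def test_nested_tie_break_prefers_competitive(self):
        """On noise-free competitive data the mixed fit matches the SSE, so
        the parsimony rule returns the competitive model."""
        dataset = generate_velocities(paper_design("fig5a_oxalate"), "C",
                                      OXALATE_C, NOISELESS)
        fits = [fit_inhibition(dataset, "MT"), fit_inhibition(dataset, "C")]
        assert select_model(fits).best.model_id == "C"

    def test_mixed_data_fitted_by_competitive_has_higher_sse(self):
        dataset = generate_velocities(paper_design("fig5b_oxalate_adp"), "MT",
                                      OXALATE_MT, NOISELESS)
        fit_mt = fit_inhibition(dataset, "MT")
        fit_c = fit_inhibition(dataset, "C")
        assert fit_c.sse > fit_mt.sse

    def test_mixed_model_selected_on_strong_mixed_data(self):
        truth = dict(OXALATE_MT, alpha=0.3)
        dataset = generate_velocities(paper_design("fig5b_oxalate_adp"), "MT",
                                      truth, NoiseModel(cv=0.01, seed=13))
        fits = [fit_inhibition(dataset, "C"), fit_inhibition(dataset, "MT")]
        assert select_model(fits).best.model_id == "MT"

    def test_mixed_datasets_rejected(self):
        d1 = generate_velocities(paper_design("fig5a_oxalate"), "C",
                                 OXALATE_C, NoiseModel(cv=0.02, seed=1))
        d2 = generate_velocities(paper_design("fig5a_oxalate"), "C",
                                 OXALATE_C, NoiseModel(cv=0.02, seed=2))
        with pytest.raises(UsageError):
            select_model([fit_inhibition(d1, "C"), fit_inhibition(d2, "MT")])
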