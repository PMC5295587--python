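import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from dfscreen.models import (
    adjusted_contrasts,
    build_model_frame,
    fit_cell_means_model,
    fit_factorial_model,
    paired_t_test,
    within_species_temperature_family,
)
from dfscreen.panel import ChromosomeArm, Deficiency, DeficiencyPanel

SPECIES = ("san", "sim")
TEMPS = ("18", "24")


def synth_frame(n_stocks=12, effects=None, noise=0.0, seed=0, chromosomes=("X", "2", "3")):
    """Balanced complete-case frame with additive cell effects."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for i in range(n_stocks):
        chrom = chromosomes[i % len(chromosomes)]
        for sp in SPECIES:
            for t in TEMPS:
                mu = 0.5 + effects.get((sp, t), 0.0)
                rows.append(
                    {
                        "stock_id": f"Df-{i}",
                        "species": sp,
                        "temperature": t,
                        "chromosome": chrom,
                        "response": mu + noise * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


def viability_like(stocks, drop=()):
    """Minimal viability table covering all 4 cells except `drop`."""
    rows = []
    for s in stocks:
        for sp in SPECIES:
            for t in TEMPS:
                if (s, sp, t) in drop:
                    continue
                rows.append(
                    {
                        "stock_id": s,
                        "species": sp,
                        "temperature": t,
                        "n_df": 40,
                        "n_bal": 60,
                        "v_hat": 0.4,
                        "testable": True,
                    }
                )
    cols = ["stock_id", "species", "temperature", "n_df", "n_bal", "v_hat", "testable"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def tiny_panel():
    arms = (ChromosomeArm("X", 100), ChromosomeArm("2L", 100))
    defs = (Deficiency("Df-A", "X", 0, 10), Deficiency("Df-B", "2L", 0, 10))
    return DeficiencyPanel(arms, defs)


class TestBuildModelFrame:
    def test_complete_stocks_give_four_rows_each(self, tiny_panel):
        frame = build_model_frame(viability_like(["Df-A", "Df-B"]), tiny_panel)
        assert len(frame) == 8
        assert set(frame["chromosome"]) == {"X", "2"}

    def test_stock_missing_one_cell_is_dropped_entirely(self, tiny_panel):
        viab = viability_like(["Df-A", "Df-B"], drop={("Df-B", "sim", "24")})
        frame = build_model_frame(viab, tiny_panel)
        assert set(frame["stock_id"]) == {"Df-A"}
        assert len(frame) == 4

    def test_empty_input_gives_empty_frame(self, tiny_panel):
        frame = build_model_frame(viability_like([]), tiny_panel)
        assert frame.empty


class TestPairedT:
    def test_hand_computed_example(self):
        # per-stock differences 0.1, 0.0, 0.2: mean 0.1, sd 0.1, t = sqrt(3)
        rows = []
        for i, d in enumerate((0.1, 0.0, 0.2)):
            rows.append({"stock_id": f"s{i}", "species": "san",
                         "temperature": "18", "response": 0.5 + d})
            rows.append({"stock_id": f"s{i}", "species": "san",
                         "temperature": "24", "response": 0.5})
        res = paired_t_test(pd.DataFrame(rows), "san")
        assert res.mean_difference == pytest.approx(0.1)
        assert res.t_statistic == pytest.approx(np.sqrt(3))
        assert res.dof == 2
        assert res.ci95[0] < 0.1 < res.ci95[1]

    def test_zero_variance_is_an_error(self):
        frame = synth_frame(n_stocks=4)
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test(frame, "san")

    def test_equals_intercept_model_on_differences(self):
        frame = synth_frame(n_stocks=20, noise=0.05, seed=3)
        res = paired_t_test(frame, "sim")
        wide = frame[frame["species"] == "sim"].pivot(
            index="stock_id", columns="temperature", values="response"
        )
        diffs = (wide["18"] - wide["24"]).to_frame("d")
        fit = smf.ols("d ~ 1", data=diffs).fit()
        # the paired t equals the intercept t of the model on differences,
        # i.e. t^2 is the F of testing that intercept
        f_intercept = float(np.squeeze(fit.t_test("Intercept = 0").tvalue)) ** 2
        assert res.t_statistic ** 2 == pytest.approx(f_intercept, rel=1e-9)
        assert res.p_value == pytest.approx(float(fit.pvalues["Intercept"]), rel=1e-9)


class TestFactorialAnova:
    def test_constant_response_has_zero_term_sums(self):
        frame = synth_frame(n_stocks=6)
        table = fit_factorial_model(
            frame, ["temperature", "species", "temperature:species"]
        )
        for _, dof, ss, *_ in table.rows:
            assert ss == pytest.approx(0.0, abs=1e-20)

    def test_pure_species_shift_lands_in_species_row(self):
        delta = 0.2
        frame = synth_frame(
            n_stocks=8, effects={("sim", "18"): delta, ("sim", "24"): delta}
        )
        table = fit_factorial_model(
            frame, ["temperature", "species", "temperature:species"]
        )
        n = len(frame)
        # balanced 2x2 closed form: SS(species) = n * delta^2 / 4
        assert table.term("species")[2] == pytest.approx(n * delta**2 / 4)
        assert table.term("temperature")[2] == pytest.approx(0.0, abs=1e-18)
        assert table.term("temperature:species")[2] == pytest.approx(0.0, abs=1e-18)

    def test_sequential_sums_conserve_total(self):
        frame = synth_frame(n_stocks=9, noise=0.1, seed=5)
        table = fit_factorial_model(
            frame, ["temperature", "species", "temperature:species"]
        )
        total = ((frame["response"] - frame["response"].mean()) ** 2).sum()
        parts = sum(r[2] for r in table.rows) + table.residual_sum_sq
        assert parts == pytest.approx(total, rel=1e-9)

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            fit_factorial_model(synth_frame(), ["temperature", "altitude"])

    def test_rank_deficient_design_rejected(self):
        frame = synth_frame(n_stocks=6)
        # chromosome perfectly confounded with species aliases the two terms
        frame["chromosome"] = np.where(frame["species"] == "san", "X", "2")
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_factorial_model(frame, ["species", "chromosome"])


class TestCellMeansModel:
    def test_four_cell_dof_on_full_sized_frame(self):
        frame = synth_frame(n_stocks=223, noise=0.05, seed=1)
        fit = fit_cell_means_model(frame, ["temperature", "species"])
        assert fit.f_dof == (3, 888)
        assert fit.n_obs == 892

    def test_twelve_cell_residual_dof_on_full_sized_frame(self):
        frame = synth_frame(n_stocks=223, noise=0.05, seed=1)
        fit = fit_cell_means_model(frame, ["chromosome", "species", "temperature"])
        assert fit.df_resid == 880
        assert len(fit.means) == 12

    def test_equal_cell_means_give_zero_f(self):
        fit = fit_cell_means_model(synth_frame(n_stocks=8), ["temperature", "species"])
        assert fit.f_statistic == 0.0

    def test_cell_mean_recovery_within_three_se(self):
        effects = {("sim", "24"): 0.15, ("san", "18"): -0.1}
        frame = synth_frame(n_stocks=100, effects=effects, noise=0.08, seed=9)
        fit = fit_cell_means_model(frame, ["species", "temperature"])
        for (sp, t), mean in fit.means.items():
            truth = 0.5 + effects.get((sp, t), 0.0)
            se = np.sqrt(fit.resid_var / fit.sizes[(sp, t)])
            assert abs(mean - truth) <= 3 * se

    def test_empty_cell_rejected(self):
        frame = synth_frame(n_stocks=6)
        frame = frame[~((frame["species"] == "sim") & (frame["temperature"] == "24"))]
        with pytest.raises(ValueError, match="empty cell"):
            fit_cell_means_model(frame, ["temperature", "species"])


class TestAdjustedContrasts:
    def test_self_contrast_is_null(self):
        frame = synth_frame(n_stocks=10, noise=0.05, seed=2)
        fit = fit_cell_means_model(frame, ["species", "temperature"])
        cell = ("san", "18")
        res = adjusted_contrasts(fit, [(cell, cell)], seed=0)[0]
        assert res.estimate == 0.0
        assert res.p_adjusted == 1.0

    def test_adjusted_p_never_below_marginal(self):
        frame = synth_frame(
            n_stocks=20, effects={("sim", "24"): 0.1}, noise=0.08, seed=4
        )
        fit = fit_cell_means_model(frame, ["species", "temperature"])
        family = [
            (("sim", "24"), ("sim", "18")),
            (("san", "24"), ("san", "18")),
            (("sim", "24"), ("san", "24")),
        ]
        results = adjusted_contrasts(fit, family, seed=1)
        from scipy import stats

        for r in results:
            marginal = 2 * stats.t.sf(abs(r.t_value), fit.df_resid)
            assert r.p_adjusted >= marginal - 1e-12
            assert r.estimate == pytest.approx(r.mean_1 - r.mean_2)

    def test_packaged_family_has_six_within_species_contrasts(self):
        family = within_species_temperature_family()
        assert len(family) == 6
        for (c1, c2) in family:
            assert c1[0] == c2[0] and c1[1] == c2[1]  # same chromosome, species
            assert {c1[2], c2[2]} == {"18", "24"}

    def test_unknown_cell_rejected(self):
        frame = synth_frame(n_stocks=6, noise=0.02, seed=0)
        fit = fit_cell_means_model(frame, ["species", "temperature"])
        with pytest.raises(ValueError, match="unknown"):
            adjusted_contrasts(fit, [(("sp9", "18"), ("san", "18"))])

    def test_agrees_with_r_multcomp_single_step(self, tmp_path):
        """Dual-route check of the max-|t| adjustment against multcomp::glht."""
        import shutil

        rscript = shutil.which("Rscript")
        if rscript is None:
            pytest.skip("Rscript not available")
        frame = synth_frame(
            n_stocks=15, effects={("sim", "24"): 0.12}, noise=0.1, seed=6
        )
        frame["cell"] = frame["species"] + "." + frame["temperature"]
        fit = fit_cell_means_model(frame, ["species", "temperature"])
        family = [
            (("sim", "24"), ("sim", "18")),
            (("san", "24"), ("san", "18")),
        ]
        ours = adjusted_contrasts(fit, family, draws=200_000, seed=3)

        csv = tmp_path / "frame.csv"
        frame[["cell", "response"]].to_csv(csv, index=False)
        script = tmp_path / "glht.R"
        script.write_text(
            f"""
            suppressMessages(library(multcomp))
            d <- read.csv("{csv}")
            d$cell <- factor(d$cell)
            m <- lm(response ~ cell - 1, data = d)
            K <- rbind("sim24-sim18" = (levels(d$cell) == "sim.24") - (levels(d$cell) == "sim.18"),
                       "san24-san18" = (levels(d$cell) == "san.24") - (levels(d$cell) == "san.18"))
            g <- summary(glht(m, linfct = K))
            cat(sprintf("%.10f %.10f %.6f\\n",
                        g$test$coefficients, g$test$tstat, g$test$pvalues))
            """
        )
        import subprocess

        out = subprocess.run(
            [rscript, str(script)], capture_output=True, text=True, check=True
        ).stdout.split()
        r_est, r_t, r_p = (float(x) for x in out[:3])
        assert ours[0].estimate == pytest.approx(r_est, abs=1e-9)
        assert ours[0].t_value == pytest.approx(r_t, rel=1e-6)
        assert ours[0].p_adjusted == pytest.approx(r_p, abs=0.02)
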