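import io

import numpy as np
import pytest

from dfscreen.panel import ChromosomeArm, intervals_overlap
from dfscreen.simulate import (
    HILocus,
    ScreenScenario,
    generate_panel,
    preset_scenario,
    simulate_screen,
    survival,
    write_counts,
)


def counts_bytes(counts):
    buf = io.StringIO()
    counts.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


class TestGeneratePanel:
    def test_same_seed_gives_identical_panel(self):
        sc = ScreenScenario(seed=11)
        p1, p2 = generate_panel(sc), generate_panel(sc)
        assert p1.deficiencies == p2.deficiencies

    def test_default_scenario_has_223_deficiencies_on_5_arms(self):
        panel = generate_panel(ScreenScenario(seed=0))
        assert len(panel.deficiencies) == 223
        assert {d.arm for d in panel.deficiencies} == {"X", "2L", "2R", "3L", "3R"}

    def test_zero_overlap_gives_pairwise_disjoint_tiles(self):
        panel = generate_panel(ScreenScenario(seed=3, overlap_fraction=0.0))
        by_arm = {}
        for d in panel.deficiencies:
            by_arm.setdefault(d.arm, []).append(d.interval)
        for ivs in by_arm.values():
            for i, a in enumerate(ivs):
                for b in ivs[i + 1 :]:
                    assert not intervals_overlap(a, b)

    def test_positive_overlap_links_neighbours(self):
        panel = generate_panel(
            ScreenScenario(seed=3, overlap_fraction=0.2, length_jitter=0.0)
        )
        x_ivs = sorted(d.interval for d in panel.deficiencies if d.arm == "X")
        shared = sum(
            intervals_overlap(a, b) for a, b in zip(x_ivs, x_ivs[1:])
        )
        assert shared == len(x_ivs) - 1

    def test_infeasible_tiling_rejected(self):
        arms = (ChromosomeArm("X", 10),)
        sc = ScreenScenario(n_deficiencies=1, arms=arms, overlap_fraction=50.0)
        with pytest.raises(ValueError, match="infeasible tiling"):
            generate_panel(sc)


class TestSimulateScreen:
    def test_same_seed_gives_identical_count_table(self):
        sc = ScreenScenario(seed=5, n_deficiencies=20)
        panel = generate_panel(sc)
        c1 = simulate_screen(panel, sc)
        c2 = simulate_screen(panel, sc)
        assert counts_bytes(c1) == counts_bytes(c2)

    def test_fully_penetrant_locus_kills_every_df_daughter(self):
        sc = ScreenScenario(seed=2, n_deficiencies=20)
        panel = generate_panel(sc)
        target = panel.deficiencies[0]
        pos = (target.start + target.end) // 2
        pen = {(sp, t): 1.0 for sp in ("san", "sim") for t in ("18", "24")}
        sc = ScreenScenario(
            seed=2, n_deficiencies=20, loci=(HILocus(target.arm, pos, pen),)
        )
        counts = simulate_screen(panel, sc)
        hit = counts[counts["stock_id"] == target.stock_id]
        assert (hit["n_df"] == 0).all()
        assert hit["n_bal"].sum() > 0

    def test_neutral_deficiency_segregates_one_to_one(self):
        # two-Poisson sampling: pooled df share ~ 0.5 within 3 SE
        sc = ScreenScenario(
            seed=9,
            n_deficiencies=5,
            overlap_fraction=0.0,
            mean_progeny_per_class=500.0,
            vials_per_cross=20,
            vial_failure_prob=0.0,
        )
        panel = generate_panel(sc)
        counts = simulate_screen(panel, sc)
        pooled = counts.groupby("stock_id")[["n_df", "n_bal"]].sum()
        frac = pooled["n_df"] / (pooled["n_df"] + pooled["n_bal"])
        total = (pooled["n_df"] + pooled["n_bal"]).to_numpy()
        se = np.sqrt(0.25 / total)
        assert (np.abs(frac - 0.5) < 3 * se).all()

    def test_multiplicative_survival_across_loci(self):
        arms = (ChromosomeArm("X", 100),)
        d = generate_panel(
            ScreenScenario(n_deficiencies=1, arms=arms, overlap_fraction=0.0, seed=0)
        ).deficiencies[0]
        loci = (
            HILocus("X", 10, {("san", "18"): 0.5}),
            HILocus("X", 20, {("san", "18"): 0.5}),
        )
        assert survival(d, loci, "san", "18") == pytest.approx(0.25)
        assert survival(d, loci, "san", "24") == 1.0

    def test_locus_off_panel_arm_rejected(self):
        sc = ScreenScenario(seed=0, n_deficiencies=10)
        panel = generate_panel(sc)
        bad = ScreenScenario(
            seed=0, n_deficiencies=10,
            loci=(HILocus("9Z", 5, {("san", "18"): 1.0}),),
        )
        with pytest.raises(ValueError, match="unknown arm"):
            simulate_screen(panel, bad)


class TestPresets:
    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="san_like"):
            preset_scenario("nope")

    def test_san_like_penetrance_mostly_shared_across_temperatures(self):
        sc = preset_scenario("san_like", seed=4)
        shared = [
            abs(l.pen("san", "18") - l.pen("san", "24")) < 0.1 for l in sc.loci
        ]
        assert len(sc.loci) == 70
        assert np.mean(shared) >= 0.8

    def test_sim_like_penetrance_mostly_temperature_restricted(self):
        sc = preset_scenario("sim_like", seed=4)
        restricted = [
            min(l.pen("sim", "18"), l.pen("sim", "24")) < 0.05
            and max(l.pen("sim", "18"), l.pen("sim", "24")) >= 0.8
            for l in sc.loci
        ]
        assert len(sc.loci) == 15
        assert np.mean(restricted) >= 0.8

    @pytest.mark.parametrize("name", ["san_like", "sim_like"])
    def test_presets_reproducible_under_fixed_seed(self, name):
        assert preset_scenario(name, seed=8).loci == preset_scenario(name, seed=8).loci
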