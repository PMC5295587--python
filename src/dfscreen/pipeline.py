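"""End-to-end orchestration: panel -> counts -> viability -> loci ->
cross-temperature comparison -> effect models -> report bundle.

A run is configured either with input files (panel, counts, optional
euchromatin) or with a named synthetic scenario; all randomness descends
from one integer seed, so a rerun with the same configuration reproduces
every artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import loci as loci_mod
from . import models as models_mod
from . import overlap as overlap_mod
from . import simulate as sim_mod
from . import viability as viab_mod
from .panel import DeficiencyPanel, parse_panel, write_panel

log = logging.getLogger("dfscreen")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "write_report",
    "validate_summary",
    "REPORT_FILES",
]

REPORT_FILES = (
    "viability.tsv",
    "hi_track.bed",
    "loci_clusters.tsv",
    "comparison.tsv",
    "anova.tsv",
    "contrasts.tsv",
    "summary.json",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``panel_path`` + ``counts_path``) or ``scenario`` must
    be supplied; the scenario route simulates its own panel and counts.
    """

    panel_path: str | None = None
    counts_path: str | None = None
    arm_table_path: str | None = None
    euchromatin_path: str | None = None
    scenario: str | None = None
    alpha: float = viab_mod.DEFAULT_ALPHA
    min_total: int = viab_mod.DEFAULT_MIN_TOTAL
    permutations: int = 100_000
    uniformity_replicates: int = 2000
    seed: int = 0
    out_dir: str = "dfscreen_out"

    def __post_init__(self) -> None:
        file_route = self.panel_path is not None and self.counts_path is not None
        if file_route == (self.scenario is not None):
            raise ValueError(
                "supply either panel_path+counts_path or a scenario, not both"
            )


@dataclass
class PipelineResult:
    config: RunConfig
    panel: DeficiencyPanel
    counts: pd.DataFrame
    viability: pd.DataFrame
    hi_sets: dict[tuple[str, str], viab_mod.HISet]
    locus_estimates: dict[tuple[str, str], loci_mod.LocusEstimate]
    uniformity: dict[tuple[str, str], loci_mod.UniformityResult]
    comparisons: dict[str, overlap_mod.OverlapResult]
    paired_t: dict[str, models_mod.PairedTestResult]
    anova_two_way: models_mod.AnovaTable | None
    cell_model_4: models_mod.CellMeansFit | None
    anova_three_way: models_mod.AnovaTable | None
    cell_model_12: models_mod.CellMeansFit | None
    contrasts: list[models_mod.ContrastResult]
    model_frame: pd.DataFrame


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage of the analysis and return the result bundle."""
    seeds = _child_seeds(config.seed, 4)

    # --- stage 1: panel and counts ---------------------------------------
    if config.scenario is not None:
        scenario = sim_mod.preset_scenario(config.scenario, seed=seeds[0])
        panel = sim_mod.generate_panel(scenario)
        counts = sim_mod.simulate_screen(panel, scenario)
        log.info(
            "simulate: scenario=%s stocks=%d loci=%d vial rows=%d",
            config.scenario, len(panel.deficiencies), len(scenario.loci), len(counts),
        )
    else:
        panel = parse_panel(
            config.panel_path, config.arm_table_path, config.euchromatin_path
        )
        counts = sim_mod.read_counts(config.counts_path)
        unknown = set(counts["stock_id"]) - set(panel.stock_ids)
        if unknown:
            raise ValueError(
                f"counts reference stock ids absent from the panel: "
                f"{sorted(unknown)[:5]}"
            )
        log.info(
            "load: stocks=%d vial rows=%d", len(panel.deficiencies), len(counts)
        )

    # --- stage 2: viability and HI calls ----------------------------------
    totals = viab_mod.aggregate_counts(counts)
    viability = viab_mod.viability_table(
        totals, alpha=config.alpha, min_total=config.min_total
    )
    hi_sets = viab_mod.classify_hi(viability, panel)
    log.info(
        "viability: groups=%d testable=%d hi_calls=%d",
        len(viability), int(viability["testable"].sum()),
        int(viability["hi_call"].sum()),
    )

    # --- stage 3: locus resolution ----------------------------------------
    locus_estimates: dict[tuple[str, str], loci_mod.LocusEstimate] = {}
    uniformity: dict[tuple[str, str], loci_mod.UniformityResult] = {}
    arm_names = [a.name for a in panel.arms]
    for cond, hi in sorted(hi_sets.items()):
        est = loci_mod.minimal_locus_count(hi)
        locus_estimates[cond] = est
        per_arm = {a: est.per_arm_minimal.get(a, 0) for a in arm_names}
        if sum(per_arm.values()) >= 1 and len(per_arm) >= 2:
            uniformity[cond] = loci_mod.arm_density_test(
                per_arm, replicates=config.uniformity_replicates, seed=seeds[1]
            )
    log.info("loci: conditions=%d", len(locus_estimates))

    # --- stage 4: cross-temperature comparison per species ----------------
    comparisons: dict[str, overlap_mod.OverlapResult] = {}
    species_list = sorted({sp for sp, _ in hi_sets})
    temps = sorted({t for _, t in hi_sets})
    if len(temps) == 2:
        t_a, t_b = temps
        for sp in species_list:
            a, b = hi_sets.get((sp, t_a)), hi_sets.get((sp, t_b))
            if a is None or b is None:
                continue
            testable = viability[viability["testable"]]
            by_temp = [
                set(testable[(testable["species"] == sp)
                             & (testable["temperature"] == t)]["stock_id"])
                for t in (t_a, t_b)
            ]
            universe = by_temp[0] & by_temp[1]
            # untestable-in-the-other-condition stocks drop out of the
            # comparison, mirroring the shared-universe rule
            a = viab_mod.HISet(a.species, a.temperature,
                               a.members & universe, a.intervals)
            b = viab_mod.HISet(b.species, b.temperature,
                               b.members & universe, b.intervals)
            part = overlap_mod.partition_hi_sets(a, b, universe)
            p_rand = overlap_mod.overlap_randomization_test(
                part.n_universe, part.n_a, part.n_b, part.n_both,
                permutations=config.permutations, seed=seeds[2],
            )
            p_hyper = overlap_mod.hypergeometric_tail(
                part.n_universe, part.n_a, part.n_b, part.n_both
            )
            comparisons[sp] = dataclasses.replace(
                part,
                p_randomization=p_rand,
                p_hypergeometric=p_hyper,
                permutations=config.permutations,
                seed=seeds[2],
            )
        log.info("compare: species=%d universe sizes=%s",
                 len(comparisons),
                 {k: v.n_universe for k, v in comparisons.items()})

    # --- stage 5: effect models -------------------------------------------
    frame = models_mod.build_model_frame(viability, panel)
    paired_t: dict[str, models_mod.PairedTestResult] = {}
    anova2 = cell4 = anova3 = cell12 = None
    contrasts: list[models_mod.ContrastResult] = []
    if not frame.empty and frame["species"].nunique() == 2 and frame["temperature"].nunique() == 2:
        for sp in sorted(frame["species"].unique()):
            try:
                paired_t[sp] = models_mod.paired_t_test(frame, sp)
            except ValueError as exc:
                log.warning("paired t-test skipped for %s: %s", sp, exc)
        anova2 = models_mod.fit_factorial_model(
            frame, ["temperature", "species", "temperature:species"]
        )
        cell4 = models_mod.fit_cell_means_model(frame, ["temperature", "species"])
        chrom_frame = frame[frame["chromosome"].isin(models_mod.MODEL_CHROMOSOMES)]
        if chrom_frame["chromosome"].nunique() >= 2:
            anova3 = models_mod.fit_factorial_model(
                frame,
                [
                    "chromosome", "temperature", "species",
                    "chromosome:temperature", "chromosome:species",
                    "temperature:species", "chromosome:temperature:species",
                ],
            )
            cell12 = models_mod.fit_cell_means_model(
                frame, ["chromosome", "species", "temperature"]
            )
            family = models_mod.within_species_temperature_family(
                chromosomes=sorted(chrom_frame["chromosome"].unique()),
                species=sorted(frame["species"].unique()),
                temperatures=(temps[1], temps[0]) if len(temps) == 2 else ("24", "18"),
            )
            contrasts = models_mod.adjusted_contrasts(cell12, family, seed=seeds[3])
    log.info("models: frame rows=%d complete stocks=%d",
             len(frame), frame["stock_id"].nunique() if not frame.empty else 0)

    return PipelineResult(
        config=config,
        panel=panel,
        counts=counts,
        viability=viability,
        hi_sets=hi_sets,
        locus_estimates=locus_estimates,
        uniformity=uniformity,
        comparisons=comparisons,
        paired_t=paired_t,
        anova_two_way=anova2,
        cell_model_4=cell4,
        anova_three_way=anova3,
        cell_model_12=cell12,
        contrasts=contrasts,
        model_frame=frame,
    )


# ---------------------------------------------------------------------------
# reporting


def _anova_frame(tables: dict[str, models_mod.AnovaTable]) -> pd.DataFrame:
    rows = []
    for name, tab in tables.items():
        if tab is None:
            continue
        df = tab.to_frame()
        df.insert(0, "model", name)
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["model", "term", "dof", "sum_sq", "mean_sq", "F", "p"]
        )
    return pd.concat(rows, ignore_index=True)


def summarize(result: PipelineResult) -> dict:
    """Machine-readable summary of every headline number of a run."""
    cfg = result.config
    conditions = []
    for (sp, temp), hi in sorted(result.hi_sets.items()):
        sub = result.viability[
            (result.viability["species"] == sp)
            & (result.viability["temperature"] == temp)
            & result.viability["testable"]
        ]
        est = result.locus_estimates.get((sp, temp))
        uni = result.uniformity.get((sp, temp))
        conditions.append(
            {
                "species": sp,
                "temperature": temp,
                "n_tested": int(len(sub)),
                "n_hi": int(len(hi.members)),
                "n_complete_lethal": int(sub["complete_lethal"].sum()),
                "minimal_locus_count": int(est.minimal_count) if est else 0,
                "component_count": int(est.component_count) if est else 0,
                "mean_v_hat": float(sub["v_hat"].mean()) if len(sub) else float("nan"),
                "sd_v_hat": float(sub["v_hat"].std(ddof=1)) if len(sub) > 1 else float("nan"),
                "uniformity": (
                    {
                        "per_arm_counts": dict(uni.per_arm_counts),
                        "statistic": uni.statistic,
                        "p_simulated": uni.p_simulated,
                        "replicates": uni.replicates,
                        "seed": uni.seed,
                    }
                    if uni
                    else {}
                ),
            }
        )
    comparisons = [
        {
            "species": sp,
            "n_universe": r.n_universe,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "n_both": r.n_both,
            "n_only_a": r.n_only_a,
            "n_only_b": r.n_only_b,
            "p_randomization": r.p_randomization,
            "p_hypergeometric": r.p_hypergeometric,
            "permutations": r.permutations,
            "seed": r.seed,
        }
        for sp, r in sorted(result.comparisons.items())
    ]
    models = {
        "paired_t": {
            sp: dataclasses.asdict(t) for sp, t in result.paired_t.items()
        },
        "anova_two_way": (
            result.anova_two_way.to_frame().to_dict("records")
            if result.anova_two_way
            else []
        ),
        "cell_model_4": _cell_fit_dict(result.cell_model_4),
        "anova_three_way": (
            result.anova_three_way.to_frame().to_dict("records")
            if result.anova_three_way
            else []
        ),
        "cell_model_12": _cell_fit_dict(result.cell_model_12),
        "contrasts": [dataclasses.asdict(c) for c in result.contrasts],
    }
    return {
        "seed": cfg.seed,
        "config": {
            "alpha": cfg.alpha,
            "min_total": cfg.min_total,
            "permutations": cfg.permutations,
            "uniformity_replicates": cfg.uniformity_replicates,
            "scenario": cfg.scenario,
            "panel_path": cfg.panel_path,
            "counts_path": cfg.counts_path,
        },
        "conditions": conditions,
        "comparisons": comparisons,
        "models": models,
    }


def _cell_fit_dict(fit: models_mod.CellMeansFit | None) -> dict:
    if fit is None:
        return {}
    return {
        "factors": list(fit.factors),
        "cell_means": {".".join(k): v for k, v in fit.means.items()},
        "cell_sizes": {".".join(k): v for k, v in fit.sizes.items()},
        "f_statistic": fit.f_statistic,
        "f_dof": list(fit.f_dof),
        "p_value": fit.p_value,
        "df_resid": fit.df_resid,
    }


def validate_summary(summary: dict, schema: dict | None = None) -> None:
    """Check a summary document against the packaged JSON schema.

    Supports the subset of JSON Schema the packaged schema uses (``type``,
    ``required``, ``properties``, ``items``); raises ``ValueError`` naming
    the first violation.
    """
    if schema is None:
        schema = load_summary_schema()
    _validate(summary, schema, "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _validate(value, schema: dict, path: str) -> None:
    typ = schema.get("type")
    if typ is not None and not isinstance(value, _TYPES[typ]):
        raise ValueError(f"{path}: expected {typ}, got {type(value).__name__}")
    if typ == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"{path}: missing required field {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate(value[key], sub, f"{path}.{key}")
    if typ == "array" and "items" in schema:
        for i, item in enumerate(value):
            _validate(item, schema["items"], f"{path}[{i}]")


def load_summary_schema() -> dict:
    with resources.files("dfscreen").joinpath("summary_schema.json").open() as fh:
        return json.load(fh)


def write_report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the full report bundle; returns the paths written.

    Artifacts: the per-stock viability table, a BED track of HI intervals
    (name column ``species.temperature.stock_id``), cluster and contrast
    tables, combined ANOVA tables, per-condition viability histograms, and
    a schema-validated JSON summary.  Histograms draw dashed lines at the
    mean and at mean +/- SD of the v_hat distribution.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    viab_mod.write_viability_table(result.viability, out / "viability.tsv")
    written.append(out / "viability.tsv")

    with open(out / "hi_track.bed", "w") as fh:
        for (sp, temp), hi in sorted(result.hi_sets.items()):
            for stock_id in sorted(hi.members):
                arm, s, e = hi.intervals[stock_id]
                fh.write(f"{arm}\t{s}\t{e}\t{sp}.{temp}.{stock_id}\n")
    written.append(out / "hi_track.bed")

    cluster_rows = []
    for (sp, temp), est in sorted(result.locus_estimates.items()):
        for cl in est.clusters:
            cluster_rows.append(
                {
                    "species": sp,
                    "temperature": temp,
                    "arm": cl.arm,
                    "span_start": cl.span_start,
                    "span_end": cl.span_end,
                    "member_ids": ",".join(cl.members),
                }
            )
    pd.DataFrame(
        cluster_rows,
        columns=["species", "temperature", "arm", "span_start", "span_end", "member_ids"],
    ).to_csv(out / "loci_clusters.tsv", sep="\t", index=False)
    written.append(out / "loci_clusters.tsv")

    comp_rows = []
    for sp, r in sorted(result.comparisons.items()):
        comp_rows.append(
            {
                "species": sp,
                "n_universe": r.n_universe,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "n_both": r.n_both,
                "n_only_a": r.n_only_a,
                "n_only_b": r.n_only_b,
                "p_randomization": r.p_randomization,
                "p_hypergeometric": r.p_hypergeometric,
            }
        )
    pd.DataFrame(
        comp_rows,
        columns=[
            "species", "n_universe", "n_a", "n_b", "n_both",
            "n_only_a", "n_only_b", "p_randomization", "p_hypergeometric",
        ],
    ).to_csv(out / "comparison.tsv", sep="\t", index=False, float_format="%.6g")
    written.append(out / "comparison.tsv")

    _anova_frame(
        {"two_way": result.anova_two_way, "three_way": result.anova_three_way}
    ).to_csv(out / "anova.tsv", sep="\t", index=False, float_format="%.6g")
    written.append(out / "anova.tsv")

    pd.DataFrame(
        [dataclasses.asdict(c) for c in result.contrasts],
        columns=["label", "mean_1", "mean_2", "estimate", "se", "t_value", "p_adjusted"],
    ).to_csv(out / "contrasts.tsv", sep="\t", index=False, float_format="%.6g")
    written.append(out / "contrasts.tsv")

    written.extend(_write_histograms(result, out))

    summary = summarize(result)
    validate_summary(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    written.append(out / "summary.json")
    log.info("report: wrote %d files to %s", len(written), out)
    return written


def _write_histograms(result: PipelineResult, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for (sp, temp), _ in sorted(result.hi_sets.items()):
        sub = result.viability[
            (result.viability["species"] == sp)
            & (result.viability["temperature"] == temp)
            & result.viability["testable"]
        ]
        fig, ax = plt.subplots(figsize=(5, 3.2))
        vals = sub["v_hat"].dropna()
        ax.hist(vals, bins=np.linspace(0, 1, 21), color="#6699cc", edgecolor="white")
        if len(vals):
            m, sd = vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0
            for x in (m, m - sd, m + sd):
                ax.axvline(x, color="black", linestyle="--", linewidth=1)
        ax.set_xlabel("relative viability of df-carrying daughters")
        ax.set_ylabel("stocks")
        ax.set_title(f"{sp} at {temp}\N{DEGREE SIGN}")
        fig.tight_layout()
        path = out / f"viability_hist_{sp}_{temp}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def text_report_checksums(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 checksums of the deterministic text artifacts of a run."""
    out = Path(out_dir)
    sums = {}
    for name in REPORT_FILES:
        path = out / name
        if path.exists():
            sums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return sums
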