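"""Temperature, genotype and chromosome effects on hybrid viability.

The response throughout is the pooled per-stock relative viability of
deficiency-carrying hybrid daughters, one value per stock x species x
temperature.  Analyses are restricted to complete cases — stocks measured
in all four species x temperature cells — so the factorial designs are
balanced and paired comparisons are well defined.

Three layers of inference:

* paired t-tests of per-stock viability between temperatures, one per
  hybrid genotype;
* factorial ANOVA (ordinary least squares, sequential Type I sums of
  squares in formula order) of viability on temperature, species,
  chromosome and their interactions;
* cell-means models on the crossed factor (4 cells for temperature x
  species; 12 for chromosome x temperature x species) with family-wise
  adjusted pairwise contrasts, using the single-step max-|t| adjustment
  that underlies Tukey-HSD-style simultaneous inference on a linear model
  (Monte-Carlo approximated with a fixed seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .panel import DeficiencyPanel, arm_to_chromosome

__all__ = [
    "PairedTestResult",
    "AnovaTable",
    "CellMeansFit",
    "ContrastResult",
    "build_model_frame",
    "paired_t_test",
    "fit_factorial_model",
    "fit_cell_means_model",
    "adjusted_contrasts",
    "within_species_temperature_family",
    "MODEL_CHROMOSOMES",
]

# Chromosome models use the three large chromosomes; anything else (e.g. a
# fourth-chromosome stock, if present in a panel) is excluded from them.
MODEL_CHROMOSOMES = ("X", "2", "3")


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test on per-stock differences."""

    n_pairs: int
    mean_difference: float
    ci95: tuple[float, float]
    t_statistic: float
    dof: int
    p_value: float


@dataclass(frozen=True)
class AnovaTable:
    """Sequential (Type I) ANOVA: rows of (term, dof, sum_sq, mean_sq, F, p)."""

    rows: tuple[tuple[str, int, float, float, float, float], ...]
    residual_dof: int
    residual_sum_sq: float
    n_obs: int

    def term(self, name: str) -> tuple[str, int, float, float, float, float]:
        for row in self.rows:
            if row[0] == name:
                return row
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "dof": d, "sum_sq": ss, "mean_sq": ms, "F": f, "p": p}
            for t, d, ss, ms, f, p in self.rows
        ]
        rows.append(
            {
                "term": "Residuals",
                "dof": self.residual_dof,
                "sum_sq": self.residual_sum_sq,
                "mean_sq": self.residual_sum_sq / self.residual_dof,
                "F": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CellMeansFit:
    """One-factor fit on the crossed-cells factor of a factorial design."""

    factors: tuple[str, ...]
    means: Mapping[tuple[str, ...], float]
    sizes: Mapping[tuple[str, ...], int]
    resid_var: float
    df_resid: int
    f_statistic: float
    f_dof: tuple[int, int]
    p_value: float
    n_obs: int


@dataclass(frozen=True)
class ContrastResult:
    """A pairwise cell contrast with a family-wise adjusted p-value."""

    label: str
    mean_1: float
    mean_2: float
    estimate: float
    se: float
    t_value: float
    p_adjusted: float


def build_model_frame(
    viability: pd.DataFrame,
    panel: DeficiencyPanel,
    species: Sequence[str] = ("san", "sim"),
    temperatures: Sequence[str] = ("18", "24"),
) -> pd.DataFrame:
    """Assemble the complete-case modeling frame.

    ``viability`` is a per stock x condition table carrying ``v_hat`` (from
    :func:`dfscreen.viability.viability_table`).  Stocks are kept only when
    a testable viability value exists in every species x temperature cell;
    a stock missing any cell is dropped entirely.  The chromosome factor is
    derived from each stock's arm.  Returns columns ``stock_id, species,
    temperature, chromosome, response`` with one row per stock x cell
    (a full panel of 223 complete stocks yields 892 rows).
    """
    arm_by_id = {d.stock_id: d.arm for d in panel.deficiencies}
    df = viability.copy()
    unknown = set(df["stock_id"]) - set(arm_by_id)
    if unknown:
        raise ValueError(f"stocks absent from panel: {sorted(unknown)[:5]}")
    df = df[df["testable"] & df["v_hat"].notna()]
    df = df[df["species"].isin(species) & df["temperature"].isin(temperatures)]

    n_cells = len(species) * len(temperatures)
    cell_counts = df.groupby("stock_id").size()
    complete = set(cell_counts[cell_counts == n_cells].index)
    df = df[df["stock_id"].isin(complete)].copy()
    df["chromosome"] = [arm_to_chromosome(arm_by_id[s]) for s in df["stock_id"]]
    frame = df[["stock_id", "species", "temperature", "chromosome"]].copy()
    frame["response"] = df["v_hat"].to_numpy()
    return frame.sort_values(
        ["stock_id", "species", "temperature"], ignore_index=True
    )


def paired_t_test(
    frame: pd.DataFrame,
    species: str,
    temperatures: tuple[str, str] = ("18", "24"),
) -> PairedTestResult:
    """Paired t-test of per-stock viability between the two temperatures.

    Differences are v_hat at the first temperature minus v_hat at the
    second (default 18 minus 24), paired by stock within one hybrid
    genotype; two-sided, with a symmetric 95% confidence interval.
    """
    sub = frame[frame["species"] == species]
    wide = sub.pivot(index="stock_id", columns="temperature", values="response")
    missing = [t for t in temperatures if t not in wide.columns]
    if missing:
        raise ValueError(f"no records at temperature(s) {missing} for {species!r}")
    wide = wide.dropna(subset=list(temperatures))
    diffs = (wide[temperatures[0]] - wide[temperatures[1]]).to_numpy()
    n = len(diffs)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("paired t-test undefined: zero variance of differences")
    mean = float(diffs.mean())
    se = sd / np.sqrt(n)
    t_stat = mean / se
    dof = n - 1
    p = 2 * float(stats.t.sf(abs(t_stat), dof))
    half = float(stats.t.ppf(0.975, dof)) * se
    return PairedTestResult(
        n_pairs=n,
        mean_difference=mean,
        ci95=(mean - half, mean + half),
        t_statistic=float(t_stat),
        dof=dof,
        p_value=p,
    )


_FACTOR_COLS = {"temperature", "species", "chromosome"}


def _term_to_patsy(term: str) -> str:
    parts = term.split(":")
    bad = [p for p in parts if p not in _FACTOR_COLS]
    if bad:
        raise ValueError(f"unknown factor(s) {bad} in term {term!r}")
    return ":".join(f"C({p})" for p in parts)


def fit_factorial_model(frame: pd.DataFrame, terms: Sequence[str]) -> AnovaTable:
    """OLS factorial ANOVA with sequential (Type I) sums of squares.

    ``terms`` are factor names and colon-joined interactions, e.g.
    ``["temperature", "species", "temperature:species"]``; sums of squares
    are attributed in the order given and F-ratios use the residual mean
    square.  Rows using the chromosome factor are restricted to
    chromosomes X, 2, 3.
    """
    if frame.empty:
        raise ValueError("empty model frame")
    data = frame
    if any("chromosome" in t for t in terms):
        data = frame[frame["chromosome"].isin(MODEL_CHROMOSOMES)]
    formula = "response ~ " + " + ".join(_term_to_patsy(t) for t in terms)
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(f"rank-deficient design for terms {list(terms)}")
    fit = model.fit()
    anova = sm.stats.anova_lm(fit, typ=1)

    rows = []
    for patsy_term, term in zip(anova.index, list(terms) + ["Residual"]):
        if patsy_term == "Residual":
            continue
        r = anova.loc[patsy_term]
        dof = int(r["df"])
        ss = float(r["sum_sq"])
        rows.append((term, dof, ss, ss / dof, float(r["F"]), float(r["PR(>F)"])))
    resid = anova.loc["Residual"]
    return AnovaTable(
        rows=tuple(rows),
        residual_dof=int(resid["df"]),
        residual_sum_sq=float(resid["sum_sq"]),
        n_obs=int(fit.nobs),
    )


def fit_cell_means_model(
    frame: pd.DataFrame, factors: Sequence[str]
) -> CellMeansFit:
    """One-factor model on the crossed cells of ``factors``.

    Every combination of observed factor levels must be populated.  Returns
    the cell means, the pooled residual variance, and the overall F-test of
    equal cell means with (cells - 1, n - cells) degrees of freedom.
    """
    bad = [f for f in factors if f not in _FACTOR_COLS]
    if bad:
        raise ValueError(f"unknown factor(s) {bad}")
    data = frame
    if "chromosome" in factors:
        data = frame[frame["chromosome"].isin(MODEL_CHROMOSOMES)]
    if data.empty:
        raise ValueError("empty model frame")

    groups = data.groupby(list(factors), sort=True)["response"]
    means = {k if isinstance(k, tuple) else (k,): float(v) for k, v in groups.mean().items()}
    sizes = {k if isinstance(k, tuple) else (k,): int(v) for k, v in groups.size().items()}
    n_expected = int(np.prod([data[f].nunique() for f in factors]))
    if len(means) != n_expected:
        raise ValueError("empty cell in the crossed design")

    y = data["response"].to_numpy()
    n = len(y)
    k = len(means)
    grand = y.mean()
    keys = list(means)
    ss_between = sum(sizes[c] * (means[c] - grand) ** 2 for c in keys)
    fitted = data.groupby(list(factors))["response"].transform("mean").to_numpy()
    ss_within = float(((y - fitted) ** 2).sum())
    df1, df2 = k - 1, n - k
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    resid_var = ss_within / df2
    if resid_var == 0:
        f_stat = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df1) / resid_var
        p = float(stats.f.sf(f_stat, df1, df2))
    return CellMeansFit(
        factors=tuple(factors),
        means=means,
        sizes=sizes,
        resid_var=resid_var,
        df_resid=df2,
        f_statistic=float(f_stat),
        f_dof=(df1, df2),
        p_value=p,
        n_obs=n,
    )


def within_species_temperature_family(
    chromosomes: Sequence[str] = MODEL_CHROMOSOMES,
    species: Sequence[str] = ("sim", "san"),
    temperatures: tuple[str, str] = ("24", "18"),
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """The packaged 6-contrast family: per chromosome and species, the
    24-degree cell minus the 18-degree cell of the 12-cell model."""
    return [
        ((c, sp, temperatures[0]), (c, sp, temperatures[1]))
        for sp in species
        for c in chromosomes
    ]


def adjusted_contrasts(
    fit: CellMeansFit,
    family: Sequence[tuple[tuple[str, ...], tuple[str, ...]]],
    draws: int = 20_000,
    seed: int = 0,
) -> list[ContrastResult]:
    """Pairwise cell contrasts with single-step max-|t| adjusted p-values.

    Each contrast is a pair of cell keys of ``fit``; its estimate is the
    difference of cell means and its SE uses the pooled residual variance.
    The family-wise adjustment is the single-step multivariate-t method:
    the adjusted p of contrast *i* is P(max_j |T_j| >= |t_i|) where T
    follows the joint null distribution of the family's t-statistics
    (correlation induced by shared cells, residual dof of the fit),
    approximated by Monte Carlo with a fixed seed.
    """
    for c1, c2 in family:
        for c in (c1, c2):
            if c not in fit.means:
                raise ValueError(f"contrast references unknown/empty cell {c}")

    m = len(family)
    cells = list(fit.means)
    cell_index = {c: i for i, c in enumerate(cells)}
    # contrast matrix on cell means; Cov(cell means) = resid_var * diag(1/n)
    C = np.zeros((m, len(cells)))
    for j, (c1, c2) in enumerate(family):
        C[j, cell_index[c1]] += 1.0
        C[j, cell_index[c2]] -= 1.0
    inv_n = np.array([1.0 / fit.sizes[c] for c in cells])
    cov = C @ np.diag(inv_n) @ C.T  # up to the resid_var factor
    se_unit = np.sqrt(np.diag(cov))
    se = np.sqrt(fit.resid_var) * se_unit
    # degenerate contrasts (a cell against itself) have zero SE; keep the
    # correlation matrix well defined so the rest of the family is usable
    safe = np.where(se_unit > 0, se_unit, 1.0)
    corr = cov / np.outer(safe, safe)
    np.fill_diagonal(corr, 1.0)

    estimates = np.array([fit.means[c1] - fit.means[c2] for c1, c2 in family])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(se > 0, estimates / np.where(se > 0, se, 1.0), 0.0)

    # Monte-Carlo null of max |t| over the family: Z ~ N(0, corr) scaled by
    # a shared chi-square draw for the residual variance estimate.
    rng = np.random.default_rng(seed)
    jitter = 1e-10 * np.eye(m)
    L = np.linalg.cholesky(corr + jitter)
    z = rng.standard_normal((draws, m)) @ L.T
    w = rng.chisquare(fit.df_resid, size=draws) / fit.df_resid
    max_abs_t = np.abs(z / np.sqrt(w)[:, None]).max(axis=1)

    results = []
    for j, (c1, c2) in enumerate(family):
        p_mc = float((max_abs_t >= abs(t_vals[j])).mean())
        # single-step adjusted p can never fall below the marginal p; the
        # floor removes Monte-Carlo undershoot of that bound
        p_marginal = 2 * float(stats.t.sf(abs(t_vals[j]), fit.df_resid))
        p_adj = min(1.0, max(p_mc, p_marginal))
        label = " - ".join(".".join(c) for c in (c1, c2))
        results.append(
            ContrastResult(
                label=label,
                mean_1=float(fit.means[c1]),
                mean_2=float(fit.means[c2]),
                estimate=float(estimates[j]),
                se=float(se[j]),
                t_value=float(t_vals[j]),
                p_adjusted=p_adj,
            )
        )
    return results
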