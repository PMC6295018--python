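"""Screen-level differential-circularity statistics.

Per-cell circularities are pooled per (gene, siRNA, experiment), divided
by the experiment's scrambled-control mean and log2-transformed.  The
differential circularity of a condition is the mean of these log2 ratios
across experiments; significance comes from a one-sample test against 0 —
either a plain Student t or a moderated t whose per-condition variance is
shrunk toward a prior fitted by moment matching on the log sample
variances:

    s2_tilde = (d0*s0^2 + dg*sg^2) / (d0 + dg)
    t_tilde  = mean / (s_tilde / sqrt(n)),   df = d0 + dg

P-values are adjusted with the Benjamini-Hochberg step-up procedure; a
condition is a positive hit when its differential circularity is > 0 with
FDR < alpha (rounder than control), negative symmetrically.  A gene is
validated when at least two of its single siRNAs are significant with the
same sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "StatsConfig",
    "VariancePrior",
    "aggregate_condition",
    "normalize_experiment",
    "fit_variance_prior",
    "differential_test",
    "adjust_fdr",
    "classify_hits",
    "validate_gene",
    "validate_genes",
    "run_screen_stats",
]


@dataclass
class StatsConfig:
    alpha: float = 0.05
    test: str = "moderated_t"
    prior_df: float | str = "estimate"
    fallback_prior_df: float = float("inf")
    control_label: str = "Scrambled"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("moderated_t", "student_t"):
            raise ValueError("test must be 'moderated_t' or 'student_t'")
        if isinstance(self.prior_df, str):
            if self.prior_df != "estimate":
                raise ValueError("prior_df must be 'estimate' or a number >= 0")
        elif self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")


@dataclass(frozen=True)
class VariancePrior:
    """Fitted empirical-Bayes variance prior (d0, s0^2)."""

    prior_df: float
    prior_var: float
    fallback_used: bool = False


def aggregate_condition(per_cell: pd.DataFrame,
                        control_label: str = "Scrambled") -> pd.DataFrame:
    """Pool cells over fields: one mean per (gene, siRNA, experiment).

    Input may be a per-cell table (``circularity`` column) or an already
    aggregated table (``mean_circularity`` column), which passes through
    unchanged.  Every experiment must contain the control condition.
    """
    required = {"gene", "sirna", "experiment"}
    missing = required - set(per_cell.columns)
    if missing:
        raise ValueError(f"input table lacks columns: {sorted(missing)}")

    if "mean_circularity" in per_cell.columns:
        agg = per_cell.loc[:, ["gene", "sirna", "experiment",
                               "mean_circularity"]].copy()
        if "n_cells" in per_cell.columns:
            agg["n_cells"] = per_cell["n_cells"].to_numpy()
    else:
        if "circularity" not in per_cell.columns:
            raise ValueError("input table needs a 'circularity' or "
                             "'mean_circularity' column")
        grouped = per_cell.groupby(["gene", "sirna", "experiment"],
                                   sort=False)["circularity"]
        agg = grouped.agg(mean_circularity="mean", n_cells="size").reset_index()

    experiments = set(agg["experiment"].unique())
    with_control = set(agg.loc[agg["gene"] == control_label, "experiment"])
    absent = [x.item() if hasattr(x, "item") else x
              for x in sorted(experiments - with_control)]
    if absent:
        raise ValueError(
            f"control {control_label!r} missing from experiment(s) {absent}")
    return agg


def normalize_experiment(aggregated: pd.DataFrame,
                         config: StatsConfig | None = None) -> pd.DataFrame:
    """Divide each mean by its experiment's control mean; log2 transform.

    Adds a ``log2_ratio`` column.  Any experiment-wide multiplicative
    factor cancels exactly, and control rows map to 0 whenever a single
    control well is present (to the mean of their own ratios otherwise).
    """
    config = config or StatsConfig()
    agg = aggregated.copy()
    if (agg["mean_circularity"] <= 0).any():
        bad = agg.loc[agg["mean_circularity"] <= 0]
        raise ValueError(
            f"non-positive mean circularity for {len(bad)} condition(s); "
            "cannot normalize")
    control = agg["gene"] == config.control_label
    ctrl_means = (agg.loc[control].groupby("experiment")["mean_circularity"]
                  .mean())
    missing = set(agg["experiment"].unique()) - set(ctrl_means.index)
    if missing:
        raise ValueError(f"control {config.control_label!r} missing from "
                         f"experiment(s) {sorted(missing)}")
    denom = agg["experiment"].map(ctrl_means).to_numpy(dtype=float)
    agg["log2_ratio"] = np.log2(agg["mean_circularity"].to_numpy(dtype=float)
                                / denom)
    return agg


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(200):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if abs(step) < 1e-14 * y:
            break
    return y


def fit_variance_prior(sample_vars: Iterable[float], residual_df: float,
                       fallback_prior_df: float = float("inf")
                       ) -> VariancePrior:
    """Moment-match (d0, s0^2) on log sample variances.

    Under the scaled-chi-square model, ``log(sg^2)`` has known digamma/
    trigamma moments; equating the empirical spread to
    ``trigamma(dg/2) + trigamma(d0/2)`` yields d0, and the mean yields
    s0^2.  When the spread is no larger than the chi-square noise alone,
    the system has no finite solution and ``fallback_prior_df`` is used
    (logged), with s0^2 still moment-matched.  The default fallback is an
    infinite prior df: a spread at or below the chi-square floor means
    the sample variances look homogeneous, i.e. complete shrinkage.
    """
    s2 = np.asarray(list(sample_vars), dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        raise ValueError("need at least two positive sample variances "
                         "to fit the variance prior")
    dg = float(residual_df)
    if dg <= 0:
        raise ValueError("residual_df must be > 0")
    e = np.log(s2) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    spread = e_var - float(special.polygamma(1, dg / 2.0))
    if spread > 0:
        d0 = 2.0 * _trigamma_inverse(spread)
        fallback = False
    else:
        d0 = float(fallback_prior_df)
        fallback = True
        logger.info("variance-prior moment system has no solution; "
                    "falling back to prior_df=%g", d0)
    if np.isinf(d0):
        s0_sq = float(np.exp(e_mean))  # lim digamma(x)-log(x) = 0
    else:
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    return VariancePrior(prior_df=d0, prior_var=s0_sq, fallback_used=fallback)


def differential_test(normalized: pd.DataFrame,
                      config: StatsConfig | None = None
                      ) -> tuple[pd.DataFrame, VariancePrior | None]:
    """One-sample test of each condition's mean log2 ratio against 0.

    Returns (results, fitted prior).  The control condition is a fixed
    point: differential circularity exactly 0, p-value 1, never tested.
    Requires >= 2 experiments per condition.
    """
    config = config or StatsConfig()
    grouped = normalized.groupby(["gene", "sirna"], sort=False)["log2_ratio"]
    table = grouped.agg(n="size", diff_circularity="mean",
                        sample_var=lambda v: v.var(ddof=1)).reset_index()

    is_control = table["gene"] == config.control_label
    tested = table.loc[~is_control]
    too_few = tested.loc[tested["n"] < 2]
    if len(too_few):
        cond = too_few.iloc[0]
        raise ValueError(
            f"condition ({cond['gene']}, {cond['sirna']}) has only "
            f"{cond['n']} experiment(s); at least 2 are required")

    n = tested["n"].to_numpy(dtype=float)
    means = tested["diff_circularity"].to_numpy(dtype=float)
    s2 = tested["sample_var"].to_numpy(dtype=float)
    dg = n - 1.0

    prior: VariancePrior | None = None
    if config.test == "student_t":
        if (s2 <= 0).any():
            raise ValueError(
                "zero sample variance encountered under student_t; "
                "use test='moderated_t' which shrinks variances")
        t_stat = means / np.sqrt(s2 / n)
        df = dg
    else:
        if config.prior_df == "estimate":
            prior = fit_variance_prior(s2, residual_df=float(dg[0]),
                                       fallback_prior_df=config.fallback_prior_df)
        else:
            d0 = float(config.prior_df)
            if d0 == 0:
                prior = VariancePrior(prior_df=0.0, prior_var=0.0)
            else:
                e = (np.log(s2[s2 > 0]) - special.digamma(dg[0] / 2.0)
                     + np.log(dg[0] / 2.0))
                s0 = float(np.exp(e.mean() + special.digamma(d0 / 2.0)
                                  - np.log(d0 / 2.0)))
                prior = VariancePrior(prior_df=d0, prior_var=s0)
        d0, s0_sq = prior.prior_df, prior.prior_var
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
        else:
            s2_tilde = (d0 * s0_sq + dg * s2) / (d0 + dg)
        if (s2_tilde <= 0).any():
            raise ValueError("moderated variance is zero; the screen has "
                             "no variance information at all")
        t_stat = means / np.sqrt(s2_tilde / n)
        df = d0 + dg

    p = 2.0 * stats.t.sf(np.abs(t_stat), df)

    results = tested.loc[:, ["gene", "sirna", "n", "diff_circularity"]].copy()
    results["t"] = t_stat
    results["df"] = df
    results["p_value"] = p

    ctrl = table.loc[is_control, ["gene", "sirna", "n"]].copy()
    ctrl["diff_circularity"] = 0.0
    ctrl["t"] = 0.0
    ctrl["df"] = np.nan
    ctrl["p_value"] = 1.0
    out = pd.concat([ctrl, results], ignore_index=True)
    return out, prior


def adjust_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(q, 1.0)
    return out


def classify_hits(results: pd.DataFrame,
                  config: StatsConfig | None = None) -> pd.DataFrame:
    """Add ``fdr`` (BH over tested conditions) and ``hit_class`` columns."""
    config = config or StatsConfig()
    out = results.copy()
    is_control = out["gene"] == config.control_label
    out["fdr"] = 1.0
    tested_idx = out.index[~is_control]
    out.loc[tested_idx, "fdr"] = adjust_fdr(out.loc[tested_idx, "p_value"])
    significant = out["fdr"] < config.alpha
    out["hit_class"] = "not_significant"
    out.loc[significant & (out["diff_circularity"] > 0), "hit_class"] = "positive"
    out.loc[significant & (out["diff_circularity"] < 0), "hit_class"] = "negative"
    return out


def validate_gene(gene_results: pd.DataFrame,
                  config: StatsConfig | None = None) -> str:
    """'validated' iff >= 2 siRNAs are significant with the same sign."""
    config = config or StatsConfig()
    sig = gene_results.loc[gene_results["hit_class"] != "not_significant"]
    n_pos = int((sig["hit_class"] == "positive").sum())
    n_neg = int((sig["hit_class"] == "negative").sum())
    return "validated" if max(n_pos, n_neg) >= 2 else "false_positive"


def validate_genes(results: pd.DataFrame,
                   config: StatsConfig | None = None) -> pd.DataFrame:
    """Gene-level validation over single-siRNA results (control excluded).

    Genes with fewer than two siRNA conditions cannot be validated and are
    reported with status ``insufficient_sirnas``.
    """
    config = config or StatsConfig()
    singles = results.loc[results["gene"] != config.control_label]
    rows = []
    for gene, sub in singles.groupby("gene", sort=False):
        n_pos = int((sub["hit_class"] == "positive").sum())
        n_neg = int((sub["hit_class"] == "negative").sum())
        if len(sub) < 2:
            status = "insufficient_sirnas"
        else:
            status = validate_gene(sub, config)
        rows.append({"gene": gene, "n_sirnas": len(sub),
                     "n_positive": n_pos, "n_negative": n_neg,
                     "status": status})
    return pd.DataFrame(rows)


def run_screen_stats(table: pd.DataFrame, config: StatsConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, VariancePrior | None]:
    """aggregate -> normalize -> test -> FDR -> classify -> validate."""
    config = config or StatsConfig()
    agg = aggregate_condition(table, control_label=config.control_label)
    norm = normalize_experiment(agg, config)
    results, prior = differential_test(norm, config)
    results = classify_hits(results, config)
    validation = validate_genes(results, config)
    return results, validation, prior
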