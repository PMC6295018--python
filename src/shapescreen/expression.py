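"""Relative expression quantification: ddCt and densitometry ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["delta_delta_ct", "densitometry_ratio"]


def delta_delta_ct(ct_table: pd.DataFrame, reference_gene: str = "GAPDH",
                   calibrator: str = "Scrambled",
                   efficiency: float | None = None) -> pd.DataFrame:
    """2^-ddCt fold changes relative to the calibrator sample.

    Replicate Ct values are averaged first (arithmetic mean), then per
    sample dCt = mean Ct(gene) - mean Ct(reference); ddCt subtracts the
    calibrator's dCt, and fold_change = 2**-ddCt.  Any additive per-sample
    Ct offset (loading differences) cancels in dCt.

    ``efficiency`` switches to the amplification-efficiency-adjusted form
    ``(1 + E)**-ddCt`` (E as a fraction, e.g. 1.007 for 100.7%); the
    default keeps the plain base-2 formula.
    """
    required = {"sample", "gene", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")

    mean_ct = (ct_table.groupby(["sample", "gene"])["ct"].mean().unstack())
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    if mean_ct[reference_gene].isna().any():
        bad = mean_ct.index[mean_ct[reference_gene].isna()].tolist()
        raise ValueError(f"reference gene {reference_gene!r} missing for "
                         f"sample(s) {bad}")
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")

    base = 2.0 if efficiency is None else 1.0 + float(efficiency)
    if base <= 1.0:
        raise ValueError("efficiency must be > 0")

    rows = []
    target_genes = [g for g in mean_ct.columns if g != reference_gene]
    for gene in target_genes:
        if np.isnan(mean_ct.at[calibrator, gene]):
            raise ValueError(f"calibrator {calibrator!r} lacks gene {gene!r}")
        calib_dct = mean_ct.at[calibrator, gene] - mean_ct.at[calibrator,
                                                              reference_gene]
        for sample in mean_ct.index:
            ct_gene = mean_ct.at[sample, gene]
            if np.isnan(ct_gene):
                continue
            dct = ct_gene - mean_ct.at[sample, reference_gene]
            ddct = dct - calib_dct
            rows.append({"sample": sample, "gene": gene, "delta_ct": dct,
                         "delta_delta_ct": ddct,
                         "fold_change": base ** (-ddct)})
    return pd.DataFrame(rows)


def densitometry_ratio(lanes: pd.DataFrame,
                       calibrator: str = "Scrambled") -> pd.DataFrame:
    """Loading-control-normalised band intensities relative to a calibrator.

    ``lanes`` needs columns lane, target, control (band intensities);
    ratio = target/control per lane, then divided by the calibrator
    lane's ratio, making the result invariant to per-lane scaling.
    """
    required = {"lane", "target", "control"}
    missing = required - set(lanes.columns)
    if missing:
        raise ValueError(f"lane table lacks columns: {sorted(missing)}")
    if (lanes["control"] <= 0).any():
        bad = lanes.loc[lanes["control"] <= 0, "lane"].tolist()
        raise ValueError(f"non-positive loading-control intensity in "
                         f"lane(s) {bad}")
    out = lanes.copy()
    out["ratio"] = out["target"].astype(float) / out["control"].astype(float)
    calib = out.loc[out["lane"] == calibrator, "ratio"]
    if calib.empty:
        raise ValueError(f"calibrator lane {calibrator!r} not found")
    out["normalized"] = out["ratio"] / float(calib.iloc[0])
    return out
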