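"""Downstream wet-lab statistics: ddCt relative quantification and the
caspase-assay analysis (log2 transform, Student t-tests vs untreated,
Bonferroni correction, back-transformed 95% CIs)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

PLATE_COLUMNS = ["gene", "sample", "ct", "tech_rep"]
CASPASE_COLUMNS = ["condition", "luminescence", "experiment"]


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"qPCR plate missing columns: {missing}")
    ct = plate["ct"].astype(float)
    if not np.isfinite(ct).all():
        raise ValueError("non-finite Ct values")
    if ((ct < 5) | (ct > 40)).any():
        warnings.warn("Ct values outside the typical 5-40 cycle range", stacklevel=2)
    return plate


def ddct(
    plate: pd.DataFrame,
    target: str,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression by the ddCt method, fold = 2^(-ddCt).

    Per sample, dCt = mean Ct(target) - mean Ct(reference gene) over
    technical replicates; ddCt = dCt(sample) - dCt(calibrator).  The
    technical-replicate SDs of both genes propagate in quadrature to a
    fold-change interval [2^(-ddCt - sd), 2^(-ddCt + sd)].
    """
    validate_plate(plate)
    rows = []
    samples = plate["sample"].unique()
    stats_by = {}
    for sample in samples:
        sub = plate[plate["sample"] == sample]
        t = sub.loc[sub["gene"] == target, "ct"].astype(float)
        r = sub.loc[sub["gene"] == reference_gene, "ct"].astype(float)
        if t.empty or r.empty:
            missing = target if t.empty else reference_gene
            raise ValueError(f"sample {sample!r}: no wells for gene {missing!r}")
        sd = float(np.sqrt(t.std(ddof=1) ** 2 / len(t) + r.std(ddof=1) ** 2 / len(r))
                   ) if len(t) > 1 and len(r) > 1 else np.nan
        stats_by[sample] = (float(t.mean() - r.mean()), sd)
    if calibrator_sample not in stats_by:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not on plate")
    dct_cal = stats_by[calibrator_sample][0]
    for sample in samples:
        dct, sd = stats_by[sample]
        dd = dct - dct_cal
        fold = 2.0 ** (-dd)
        lo = 2.0 ** (-dd - sd) if np.isfinite(sd) else np.nan
        hi = 2.0 ** (-dd + sd) if np.isfinite(sd) else np.nan
        rows.append(dict(sample=sample, dct=dct, ddct=dd, fold=fold,
                         fold_lo=min(lo, hi), fold_hi=max(lo, hi)))
    return pd.DataFrame(rows).set_index("sample")


def caspase_analysis(
    table: pd.DataFrame,
    baseline_condition: str,
    m_comparisons: int,
) -> pd.DataFrame:
    """Per-condition geometric-mean ratio to baseline with 95% CI and a
    Bonferroni-adjusted two-sided Student t-test.

    Within each independent experiment, luminescence is divided by the
    baseline median, then log2-transformed; technical replicates are
    averaged so independent experiments are the statistical units.  Means
    and CIs are back-transformed to the original (ratio) scale; p-values
    are multiplied by ``m_comparisons`` and capped at 1.
    """
    missing = [c for c in CASPASE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"caspase table missing columns: {missing}")
    if (table["luminescence"] <= 0).any():
        raise ValueError("luminescence must be positive")
    if baseline_condition not in set(table["condition"]):
        raise ValueError(f"baseline condition {baseline_condition!r} absent")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")

    norm = table.copy()
    for exp, sub in table.groupby("experiment"):
        base = sub.loc[sub["condition"] == baseline_condition, "luminescence"]
        if base.empty:
            raise ValueError(f"experiment {exp!r} has no baseline wells")
        norm.loc[sub.index, "luminescence"] = sub["luminescence"] / base.median()
    norm["log2_value"] = np.log2(norm["luminescence"].astype(float))
    # experiment means are the units of analysis
    means = (norm.groupby(["condition", "experiment"])["log2_value"]
             .mean().reset_index())

    base_vals = means.loc[means["condition"] == baseline_condition, "log2_value"]
    rows = []
    for cond, sub in means.groupby("condition"):
        vals = sub["log2_value"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"condition {cond!r} has a single observation")
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        tcrit = stats.t.ppf(0.975, len(vals) - 1)
        if cond == baseline_condition:
            p_adj = np.nan
        else:
            _, p = stats.ttest_ind(vals, base_vals, equal_var=True)
            p_adj = min(1.0, float(p) * m_comparisons)
        rows.append(dict(
            condition=cond, n=len(vals),
            ratio=2.0 ** mean,
            ci_low=2.0 ** (mean - tcrit * se),
            ci_high=2.0 ** (mean + tcrit * se),
            p_adjusted=p_adj,
            significant=bool(p_adj < 0.05) if np.isfinite(p_adj) else False,
        ))
    return pd.DataFrame(rows).set_index("condition")
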