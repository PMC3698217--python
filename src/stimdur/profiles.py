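"""Fold-induction profiles, temporal grouping and CHX-based regulation calls.

Fold induction is the per-gene ratio of treated to time-matched untreated
expression, averaged over biological replicates on the log2 scale and
exponentiated.  From the dense sustained series, genes are grouped by the
time of their peak fold induction: early (<2 h), delayed (2-4 h, inclusive)
and late (>4 h), each split into two subgroups (a-f).  The cycloheximide
(CHX) experiment separates primary genes (induced with translation blocked)
from secondary genes (induction abolished): with
F_gc(t) = fold of gastrin+CHX over CHX alone and
F_c(t) = fold of CHX alone over untreated, a gastrin-induced gene is

* ``uncertain``  if max F_c >= theta_chx and max F_gc < theta_up
  (the CHX-alone response dominates, gastrin's effect cannot be separated),
* ``primary``    if max F_gc >= theta_up,
* ``secondary``  if max F_gc < theta_low,
* ``uncertain``  otherwise.

The original analysis made these calls by manual curve inspection; here the
thresholds are explicit, versioned configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import pair_conditions, validate_matrix, validate_sheet

THETA_FOLD = 2.0   # sustained peak fold for "markedly upregulated"
THETA_UP = 1.5     # max F_gc at or above -> primary
THETA_LOW = 1.2    # max F_gc below -> secondary
THETA_CHX = 3.0    # max F_c at or above (with weak F_gc) -> uncertain

#: subgroup boundaries by peak time (h); majors are early/delayed/late
GROUP_EDGES = {
    "a": (0.0, 1.0), "b": (1.0, 2.0),   # early: peak < 2, split at 1
    "c": (2.0, 3.0), "d": (3.0, 4.0),   # delayed: 2 <= peak <= 4 (d includes 4)
    "e": (4.0, 8.0), "f": (8.0, 14.0),  # late: peak > 4, split at 8
}
GROUP_TO_MAJOR = {"a": "early", "b": "early", "c": "delayed", "d": "delayed",
                  "e": "late", "f": "late"}


@dataclass
class GeneTimeProfile:
    """Mean fold-induction curves for one condition: genes x time grid."""

    condition: str
    fold: pd.DataFrame          # genes x times, FI(t) > 0
    peak_time: pd.Series        # argmax time, ties -> earliest
    peak_fold: pd.Series


def fold_induction(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    condition: str,
    reference_condition: str = "untreated",
) -> GeneTimeProfile:
    """Mean fold induction vs time-matched reference, per gene and time.

    Computed as 2^(mean over replicates of treated - reference) on the
    (normalized) log2 scale.  Time points missing a replicate pair are
    dropped with a warning.
    """
    validate_matrix(matrix)
    validate_sheet(sheet, matrix)
    meta = sheet.set_index("sample_id")
    cond_times = sorted(meta.loc[meta["condition"] == condition, "time_h"]
                        .round(3).unique())
    try:
        pairs = pair_conditions(sheet, condition, reference_condition)
    except Exception:
        # retry per time point so only unmatched times are lost
        pairs = pd.Series(dtype=object)
        for t in list(cond_times):
            sub = sheet[(sheet["condition"] != condition)
                        | (sheet["time_h"].round(3) == t)]
            try:
                sub_pairs = pair_conditions(sub, condition, reference_condition)
            except Exception:
                warnings.warn(
                    f"condition {condition!r}: no replicate pairs at t={t} h; "
                    "time point dropped", stacklevel=2)
                cond_times.remove(t)
                continue
            pairs = pd.concat([pairs, sub_pairs])
        pairs = pairs[~pairs.index.duplicated()]
    if not len(pairs):
        raise ValueError(f"no paired samples for condition {condition!r}")

    log_ratio = {}
    for t in cond_times:
        cols = [s for s in pairs.index if round(float(meta.loc[s, "time_h"]), 3) == t]
        if not cols:
            continue
        diffs = np.column_stack([
            matrix[s].to_numpy() - matrix[pairs[s]].to_numpy() for s in cols
        ])
        log_ratio[t] = diffs.mean(axis=1)
    fold = pd.DataFrame(log_ratio, index=matrix.index)
    fold = 2.0 ** fold
    values = fold.to_numpy()
    times = np.asarray(fold.columns, dtype=float)
    peak_idx = values.argmax(axis=1)  # argmax -> first maximum -> earliest time
    return GeneTimeProfile(
        condition=condition,
        fold=fold,
        peak_time=pd.Series(times[peak_idx], index=fold.index, name="peak_time"),
        peak_fold=pd.Series(values[np.arange(len(fold)), peak_idx],
                            index=fold.index, name="peak_fold"),
    )


def select_subset(
    profile_sustained: GeneTimeProfile,
    de_results,
    theta_fold: float = THETA_FOLD,
) -> pd.Series:
    """Markedly upregulated, lower-in-transient genes.

    A gene is in the subset iff it is significant in the transient-vs-
    sustained comparison with direction lower-in-transient, and its
    sustained peak fold is at least ``theta_fold``.
    """
    sig = de_results.significant & (de_results.direction == "lower_in_transient")
    sig = sig.reindex(profile_sustained.fold.index, fill_value=False)
    return (sig & (profile_sustained.peak_fold >= theta_fold)).rename("in_subset")


def classify_temporal(peak_time) -> pd.DataFrame:
    """Map peak times to (temporal_major, temporal_group a-f).

    early: peak < 2 h (a: <1, b: [1,2)); delayed: 2-4 h inclusive
    (c: [2,3), d: [3,4]); late: peak > 4 h (e: (4,8], f: (8,14]).
    """
    pt = pd.Series(peak_time, dtype=float)
    if pt.empty or pt.isna().any():
        raise ValueError("empty or missing peak times")
    group = pd.Series("f", index=pt.index)
    group[pt < 1] = "a"
    group[(pt >= 1) & (pt < 2)] = "b"
    group[(pt >= 2) & (pt < 3)] = "c"
    group[(pt >= 3) & (pt <= 4)] = "d"
    group[(pt > 4) & (pt <= 8)] = "e"
    group[pt > 8] = "f"
    major = group.map(GROUP_TO_MAJOR)
    return pd.DataFrame({"peak_time": pt, "temporal_major": major,
                         "temporal_group": group})


def classify_regulation(
    chx_matrix: pd.DataFrame,
    chx_sheet: pd.DataFrame,
    theta_up: float = THETA_UP,
    theta_low: float = THETA_LOW,
    theta_chx: float = THETA_CHX,
) -> pd.DataFrame:
    """Primary/secondary/uncertain calls from the four-arm CHX experiment.

    Requires the untreated, sustained (gastrin), chx and gastrin_chx arms;
    a missing arm raises naming it.  Returns per-gene calls plus the
    decision statistics max F_gc and max F_c.
    """
    validate_sheet(chx_sheet, chx_matrix)
    present = set(chx_sheet["condition"])
    for arm in ("untreated", "sustained", "chx", "gastrin_chx"):
        if arm not in present:
            raise ValueError(f"CHX experiment is missing the {arm!r} arm")
    f_gc = fold_induction(chx_matrix, chx_sheet, "gastrin_chx", "chx")
    f_c = fold_induction(chx_matrix, chx_sheet, "chx", "untreated")
    max_gc, max_c = f_gc.peak_fold, f_c.peak_fold
    regulation = pd.Series("uncertain", index=chx_matrix.index, name="regulation")
    regulation[max_gc >= theta_up] = "primary"
    regulation[max_gc < theta_low] = "secondary"
    confounded = (max_c >= theta_chx) & (max_gc < theta_up)
    regulation[confounded] = "uncertain"
    return pd.DataFrame({
        "regulation": regulation,
        "max_fold_gastrin_chx_vs_chx": max_gc,
        "max_fold_chx_vs_untreated": max_c,
    })


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of temporal_group x regulation with row percentages.

    ``calls`` needs columns temporal_group and regulation.  Percentages are
    of classified (non-uncertain) genes within each group.
    """
    counts = pd.crosstab(calls["temporal_group"], calls["regulation"])
    counts = counts.reindex(index=sorted(GROUP_EDGES), fill_value=0)
    for col in ("primary", "secondary", "uncertain"):
        if col not in counts:
            counts[col] = 0
    classified = counts["primary"] + counts["secondary"]
    with np.errstate(invalid="ignore", divide="ignore"):
        counts["pct_primary"] = 100.0 * counts["primary"] / classified
        counts["pct_secondary"] = 100.0 * counts["secondary"] / classified
    return counts[["primary", "secondary", "uncertain",
                   "pct_primary", "pct_secondary"]]


def make_gene_calls(
    profile_sustained: GeneTimeProfile,
    de_results,
    chx_matrix: pd.DataFrame,
    chx_sheet: pd.DataFrame,
    theta_fold: float = THETA_FOLD,
    theta_up: float = THETA_UP,
    theta_low: float = THETA_LOW,
    theta_chx: float = THETA_CHX,
) -> pd.DataFrame:
    """Full per-gene call table: subset flag, temporal group, regulation."""
    in_subset = select_subset(profile_sustained, de_results, theta_fold)
    temporal = classify_temporal(profile_sustained.peak_time)
    regulation = classify_regulation(chx_matrix, chx_sheet,
                                     theta_up, theta_low, theta_chx)
    out = pd.concat([in_subset, profile_sustained.peak_fold, temporal,
                     regulation], axis=1)
    return out
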