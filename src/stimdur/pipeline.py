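"""End-to-end pipeline: simulate -> normalize -> test -> classify -> report.

One global seed is expanded into per-stage streams through
``numpy.random.SeedSequence(seed)`` (the simulator consumes them in a fixed
order), so identical configuration and seed give byte-identical outputs and
each stage can be re-run independently from the TSVs written to disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster, io, normalize, profiles
from .cascade import StudyConfig, generate_study
from .de import TimecourseDE

log = logging.getLogger(__name__)


def evaluate_detection(de_results, truth: pd.DataFrame) -> dict:
    """Sensitivity / false-positive rate of duration-sensitive detection."""
    sig = de_results.significant
    responsive = truth["true_class"].isin(["primary", "secondary"])
    responsive = responsive.reindex(sig.index, fill_value=False)
    tp = int((sig & responsive).sum())
    fp = int((sig & ~responsive).sum())
    n_pos, n_neg = int(responsive.sum()), int((~responsive).sum())
    return {
        "n_genes": int(len(sig)),
        "n_significant": int(sig.sum()),
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "false_positive_rate": fp / n_neg if n_neg else float("nan"),
    }


def evaluate_regulation(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Confusion matrix and balanced accuracy of primary/secondary recovery.

    Scored on genes whose true class is primary or secondary; a call of
    ``uncertain`` on such a gene counts against its class recall.
    """
    merged = calls.join(truth, how="inner")
    merged = merged[merged["true_class"].isin(["primary", "secondary"])]
    confusion = pd.crosstab(merged["true_class"], merged["regulation"])
    recalls = []
    for cls in ("primary", "secondary"):
        total = int((merged["true_class"] == cls).sum())
        hit = int(((merged["true_class"] == cls)
                   & (merged["regulation"] == cls)).sum())
        recalls.append(hit / total if total else np.nan)
    finite = [r for r in recalls if not np.isnan(r)]
    return {
        "confusion": confusion,
        "recall_primary": recalls[0],
        "recall_secondary": recalls[1],
        "balanced_accuracy": float(np.mean(finite)) if finite else float("nan"),
    }


def run_study(
    seed: int,
    config: StudyConfig | None = None,
    outdir: str | Path | None = None,
    alpha: float = 0.05,
    span: float = normalize.DEFAULT_SPAN,
    theta_fold: float = profiles.THETA_FOLD,
    theta_up: float = profiles.THETA_UP,
    theta_low: float = profiles.THETA_LOW,
    theta_chx: float = profiles.THETA_CHX,
    write_heatmap: bool = True,
) -> dict:
    """Run the full simulated-study pipeline and return a report dict.

    With ``outdir`` set, every intermediate (matrices, sheets, normalized
    matrices, DE table, calls, heat map, report JSON) is written to disk.
    """
    cfg = config or StudyConfig()
    study = generate_study(seed, cfg)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    normed = {}
    for exp in ("duration_series", "sustained_series", "chx_series"):
        bundle = study[exp]
        normed[exp] = normalize.normalize_pipeline(bundle["matrix"],
                                                   bundle["sheet"], span=span)
        if outdir is not None:
            io.write_matrix(bundle["matrix"], outdir / f"{exp}.raw.tsv")
            io.write_sample_sheet(bundle["sheet"], outdir / f"{exp}.sheet.tsv")
            io.write_matrix(normed[exp], outdir / f"{exp}.norm.tsv")
    truth = study["duration_series"]["truth"]
    if outdir is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t")

    # differential testing on the duration series
    de_results = TimecourseDE(normed["duration_series"],
                              study["duration_series"]["sheet"]).fit(alpha=alpha)
    detection = evaluate_detection(de_results, truth)
    log.info("differential genes: %d/%d", detection["n_significant"],
             detection["n_genes"])

    # temporal profiles from the dense sustained series
    prof_sust = profiles.fold_induction(normed["sustained_series"],
                                        study["sustained_series"]["sheet"],
                                        "sustained")
    calls = profiles.make_gene_calls(
        prof_sust, de_results, normed["chx_series"], study["chx_series"]["sheet"],
        theta_fold=theta_fold, theta_up=theta_up,
        theta_low=theta_low, theta_chx=theta_chx,
    )
    subset = calls[calls["in_subset"]]
    table = profiles.summarize_calls(subset) if len(subset) else None
    regulation = evaluate_regulation(calls[calls["in_subset"]], truth)

    if outdir is not None:
        de_results.to_frame().to_csv(outdir / "de.tsv", sep="\t")
        calls.to_csv(outdir / "calls.tsv", sep="\t")
        if table is not None:
            table.to_csv(outdir / "temporal_regulation_table.tsv", sep="\t")

    # heat map of differential genes: transient | sustained log2-ratio blocks
    if write_heatmap and outdir is not None and detection["n_significant"] >= 2:
        sig_genes = de_results.significant[de_results.significant].index
        prof_t = profiles.fold_induction(normed["duration_series"],
                                         study["duration_series"]["sheet"],
                                         "transient")
        prof_s = profiles.fold_induction(normed["duration_series"],
                                         study["duration_series"]["sheet"],
                                         "sustained")
        lt = np.log2(prof_t.fold.loc[sig_genes])
        ls = np.log2(prof_s.fold.loc[sig_genes])
        lt.columns = [f"T{t:g}h" for t in lt.columns]
        ls.columns = [f"S{t:g}h" for t in ls.columns]
        both = pd.concat([lt, ls], axis=1)
        _, leaves = cluster.ward_cluster(both.to_numpy())
        cluster.heatmap_export(
            both, leaves,
            {"transient": list(lt.columns), "sustained": list(ls.columns)},
            outdir / "heatmap.png",
        )

    n_lower = int((de_results.significant
                   & (de_results.direction == "lower_in_transient")).sum())
    report = {
        "seed": seed,
        "config": asdict(cfg),
        "alpha": alpha,
        "null_run": detection["n_significant"] == 0,
        "detection": detection,
        "n_lower_in_transient": n_lower,
        "n_higher_in_transient": detection["n_significant"] - n_lower,
        "subset_size": int(calls["in_subset"].sum()),
        "regulation_counts": subset["regulation"].value_counts().to_dict()
        if len(subset) else {},
        "temporal_counts": subset["temporal_major"].value_counts().to_dict()
        if len(subset) else {},
        "regulation_recovery": {
            k: v for k, v in regulation.items() if k != "confusion"
        },
        "regulation_confusion": regulation["confusion"].to_dict(),
    }
    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    """Strict-JSON copy: numpy scalars unboxed, NaN/inf mapped to None."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj) if np.isfinite(obj) else None
    return obj
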