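"""End-to-end pipeline: simulate -> segment -> extract -> cluster ->
associate, with a machine-readable summary of every number produced.

Recovered clusters are relabelled by median MTV in decreasing order so
that group 1 is the large-tumor phenotype, group 2 the medium intense
one, and group 3 the small homogeneous one, matching the phenotype
ordering used in the clinical summaries.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import association as assoc
from .cluster import (
    OUTLIER,
    cluster_feature_summary,
    correlogram,
    hierarchical_clusters,
    zscore_features,
)
from .config import RunConfig
from .phantom import make_cohort
from .registry import FEATURE_NAMES
from .segmentation import segment_fixed_threshold
from .texture import ExtractionSettings, extract_all_features
from .volume_io import SUVVolume

logger = logging.getLogger(__name__)

#: features shown in the per-cluster clinical summary table
SUMMARY_FEATURES = [
    "SUV_max", "SUV_mean", "MTV", "TLG", "CV",
    "NL_Entropy^GLCM", "NL_Homogeneity^GLCM", "ZP^GLSZM", "Skewness",
]


def extract_cohort_features(
    volumes: list[SUVVolume], config: RunConfig, patient_ids: list[str] | None = None
) -> pd.DataFrame:
    """Segment every volume and extract the full feature vector."""
    settings = ExtractionSettings(
        bin_width=config.quantization.bin_width,
        range_min=config.quantization.range_min,
        range_max=config.quantization.range_max,
        n_levels=config.quantization.n_levels,
    )
    if patient_ids is None:
        patient_ids = [f"P{i:03d}" for i in range(len(volumes))]
    rows = []
    for pid, vol in zip(patient_ids, volumes):
        seg = segment_fixed_threshold(vol, cutoff=config.segmentation.cutoff)
        feats = extract_all_features(vol, seg.mask, settings)
        feats["patient_id"] = pid
        rows.append(feats)
    df = pd.DataFrame(rows).set_index("patient_id")
    return df[list(FEATURE_NAMES)]


def relabel_by_mtv(features: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Map cluster labels to 1..k by decreasing median MTV (outliers keep 0)."""
    clusters = sorted(c for c in labels.unique() if c != OUTLIER)
    medians = {
        c: features.loc[labels[labels == c].index, "MTV"].median() for c in clusters
    }
    order = sorted(clusters, key=lambda c: -medians[c])
    mapping = {c: i + 1 for i, c in enumerate(order)}
    mapping[OUTLIER] = OUTLIER
    return labels.map(mapping)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic study; write report artifacts, return summary.

    Deterministic given the config seeds: the written ``summary.json``
    is byte-identical across reruns of the same configuration.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("simulate: n_per_archetype=%s seed=%d",
                config.simulation.n_per_archetype, config.simulation.seed)
    volumes, cohort = make_cohort(
        n_per_archetype=config.simulation.n_per_archetype,
        jitter_sd=config.simulation.jitter_sd,
        seed=config.simulation.seed,
    )

    features = extract_cohort_features(
        volumes, config, patient_ids=list(cohort["patient_id"])
    )
    features.to_csv(out_dir / "features.csv")
    logger.info("extract: %s feature matrix", features.shape)

    standardized = zscore_features(features)
    corr = correlogram(
        features,
        alpha=config.statistics.alpha,
        correction_denominator=config.statistics.correlogram_denominator,
    )
    corr.corr.to_csv(out_dir / "correlation_matrix.csv")

    assignment = hierarchical_clusters(
        standardized,
        k=config.clustering.k,
        linkage_method=config.clustering.linkage,
        min_cluster_size=config.clustering.min_cluster_size,
    )
    labels = relabel_by_mtv(features, assignment.labels)
    clusters_df = pd.DataFrame(
        {"patient_id": features.index, "cluster": labels.values}
    )
    clusters_df.to_csv(out_dir / "clusters.csv", index=False)

    cohort = cohort.set_index("patient_id")
    cohort["cluster"] = labels
    non_outlier = cohort[cohort["cluster"] != OUTLIER].copy()

    summary_tab = cluster_feature_summary(features, assignment, SUMMARY_FEATURES)
    # remap the per-cluster column names to the MTV ordering
    raw_to_new = {}
    for raw in sorted(c for c in assignment.labels.unique() if c != OUTLIER):
        idx = assignment.labels[assignment.labels == raw].index
        raw_to_new[raw] = int(labels[idx].iloc[0])
    renames = {}
    for raw, new in raw_to_new.items():
        for stat in ("median", "min", "max"):
            renames[f"{stat}_c{raw}"] = f"{stat}_tc{new}"
    summary_tab = summary_tab.rename(columns=renames)
    summary_tab.to_csv(out_dir / "cluster_feature_summary.csv")

    ari = float(
        adjusted_rand_score(non_outlier["archetype"], non_outlier["cluster"])
    )

    results: dict = {
        "n_patients": int(len(cohort)),
        "n_features": int(features.shape[1]),
        "n_clusters": int(len(set(non_outlier["cluster"]))),
        "n_outliers": int((cohort["cluster"] == OUTLIER).sum()),
        "cluster_sizes": {
            f"tc{c}": int((non_outlier["cluster"] == c).sum())
            for c in sorted(non_outlier["cluster"].unique())
        },
        "adjusted_rand_index_vs_planted": round(ari, 6),
        "n_significant_correlations": int(corr.significant.to_numpy().sum() // 2),
    }

    # --- pCR association -------------------------------------------------
    stats_block: dict = {}
    try:
        chi = assoc.proportions_test(non_outlier, group="cluster", trait="pcr")
        stats_block["pcr_chi2"] = round(chi.statistic, 6)
        stats_block["pcr_chi2_p"] = round(chi.p_value, 8)
    except ValueError as exc:
        stats_block["pcr_chi2_note"] = str(exc)
    stats_block["pcr_rate_per_cluster"] = {
        f"tc{c}": round(float(sub["pcr"].mean()), 6)
        for c, sub in non_outlier.groupby("cluster")
    }
    try:
        ct = pd.crosstab(non_outlier["cluster"] == 2, non_outlier["pcr"])
        table = assoc.ContingencyTable2x2(
            a=int(ct.loc[True, 1]), b=int(ct.loc[True, 0]),
            c=int(ct.loc[False, 1]), d=int(ct.loc[False, 0]),
        )
        orr = assoc.odds_ratio_2x2(table)
        stats_block["or_tc2_vs_others"] = {
            "odds_ratio": round(orr.odds_ratio, 6),
            "ci_low": round(orr.ci_low, 6),
            "ci_high": round(orr.ci_high, 6),
            "p": round(orr.p_value, 8),
            "method": orr.method,
        }
    except (KeyError, ValueError) as exc:
        stats_block["or_tc2_vs_others_note"] = str(exc)

    # --- recurrence ------------------------------------------------------
    surv = assoc.km_logrank(non_outlier, group="cluster")
    stats_block["n_recurrences"] = surv.n_events
    if surv.logrank_p is not None:
        stats_block["logrank_p_clusters"] = round(surv.logrank_p, 8)
    else:
        stats_block["logrank_note"] = surv.note
    non_outlier["tc1"] = (non_outlier["cluster"] == 1).astype(int)
    try:
        hr = assoc.cox_fit(non_outlier, ["tc1"], mode="univariate")[0]
        stats_block["cox_tc1"] = {
            "hazard_ratio": round(hr.hazard_ratio, 6),
            "p": round(hr.p_value, 8),
            "flagged": hr.flagged,
        }
    except assoc.DegenerateOutcomeError as exc:
        stats_block["cox_tc1_note"] = str(exc)

    results["statistics"] = stats_block
    summary = {"config": config.to_dict(), "results": results}
    (out_dir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n"
    )

    _write_plots(out_dir, standardized, assignment, corr)
    return summary


def _write_plots(out_dir: Path, standardized, assignment, corr) -> None:
    """Heat map and correlogram images (best effort)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    try:
        mat = standardized.loc[assignment.patient_order, assignment.feature_order]
        fig, ax = plt.subplots(figsize=(10, 6))
        im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdYlGn", vmin=-3, vmax=3)
        ax.set_xlabel("texture features")
        ax.set_ylabel("patients (dendrogram order)")
        fig.colorbar(im, ax=ax, label="z-score")
        fig.savefig(out_dir / "heatmap.png", dpi=100)
        plt.close(fig)

        order = corr.feature_order
        cm = corr.corr.loc[order, order]
        fig, ax = plt.subplots(figsize=(8, 8))
        im = ax.imshow(cm.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_title("feature correlogram (hierarchical order)")
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.savefig(out_dir / "correlogram.png", dpi=100)
        plt.close(fig)
    except Exception as exc:  # plotting must never sink the run
        logger.warning("plot rendering failed: %s", exc)
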