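"""Reproducible validation experiments built on the pipeline.

These are the computations behind the package's headline numbers: the
odds ratios reconstructed from the published cluster sizes and pCR
rates, planted-archetype recovery by unsupervised clustering, and the
calibration of the survival statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import adjusted_rand_score

from .association import ContingencyTable2x2, ORResult, odds_ratio_2x2
from .cluster import OUTLIER, hierarchical_clusters, zscore_features
from .config import RunConfig
from .phantom import make_cohort
from .pipeline import extract_cohort_features

#: published cluster sizes and per-cluster pCR rates
CLUSTER_SIZES = (10, 25, 37)
PCR_RATES = (0.200, 0.480, 0.054)


def reconstructed_pcr_tables(
    sizes: tuple[int, ...] = CLUSTER_SIZES, rates: tuple[float, ...] = PCR_RATES
) -> dict[str, ContingencyTable2x2]:
    """2x2 pCR tables implied by the cluster sizes and pCR rates.

    Rounding rate x size gives the integer pCR counts (2, 12, 2).
    """
    pcr = [round(r * n) for r, n in zip(rates, sizes)]
    non = [n - e for n, e in zip(sizes, pcr)]
    return {
        "tc2_vs_others": ContingencyTable2x2(
            a=pcr[1], b=non[1], c=pcr[0] + pcr[2], d=non[0] + non[2]
        ),
        "tc2_vs_tc3": ContingencyTable2x2(a=pcr[1], b=non[1], c=pcr[2], d=non[2]),
        "tc1_vs_tc3": ContingencyTable2x2(a=pcr[0], b=non[0], c=pcr[2], d=non[2]),
    }


def reconstructed_pcr_odds_ratios() -> dict[str, ORResult]:
    """Univariate pCR odds ratios from the reconstructed tables."""
    return {name: odds_ratio_2x2(t) for name, t in reconstructed_pcr_tables().items()}


def cluster_recovery_ari(seed: int, config: RunConfig | None = None) -> float:
    """ARI between planted archetypes and recovered clusters for one cohort."""
    if config is None:
        config = RunConfig()
    volumes, cohort = make_cohort(
        n_per_archetype=config.simulation.n_per_archetype,
        jitter_sd=config.simulation.jitter_sd,
        seed=seed,
    )
    features = extract_cohort_features(
        volumes, config, patient_ids=list(cohort["patient_id"])
    )
    assignment = hierarchical_clusters(
        zscore_features(features),
        k=config.clustering.k,
        linkage_method=config.clustering.linkage,
        min_cluster_size=config.clustering.min_cluster_size,
    )
    keep = assignment.labels != OUTLIER
    planted = cohort.set_index("patient_id")["archetype"][keep]
    return float(adjusted_rand_score(planted, assignment.labels[keep]))


def logrank_null_rejection_rate(
    n_sims: int = 1000,
    n: int = 100,
    alpha: float = 0.05,
    hazard: float = 0.02,
    seed: int = 0,
) -> float:
    """Type-I error of the two-group log-rank test under the null.

    Both groups draw exponential event times with the same hazard,
    censored uniformly; the rejection rate at ``alpha`` should sit near
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    group = np.repeat([0, 1], n // 2)
    for _ in range(n_sims):
        t_event = rng.exponential(1.0 / hazard, size=n)
        t_cens = rng.uniform(16.0, 57.0, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        res = multivariate_logrank_test(time, group, event)
        rejections += res.p_value < alpha
    return rejections / n_sims


def cox_hr_recovery(
    n_cohorts: int = 200,
    n: int = 300,
    hr: float = 3.0,
    baseline_hazard: float = 0.01,
    seed: int = 0,
) -> float:
    """Mean Cox hazard-ratio estimate over simulated two-group cohorts.

    Each cohort has a Bernoulli(0.5) binary covariate multiplying the
    exponential hazard by ``hr``; uniform censoring leaves roughly 40%
    events.  Returns the mean fitted HR.
    """
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_cohorts):
        x = rng.integers(0, 2, size=n)
        lam = baseline_hazard * np.where(x == 1, hr, 1.0)
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.uniform(16.0, 57.0, size=n)
        df = pd.DataFrame(
            {
                "time": np.minimum(t_event, t_cens),
                "event": (t_event <= t_cens).astype(int),
                "x": x,
            }
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        estimates.append(float(np.exp(cph.params_["x"])))
    return float(np.mean(estimates))
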