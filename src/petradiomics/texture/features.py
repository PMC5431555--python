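"""Scalar texture features per matrix family and the full 109-feature
extraction.

Conventions shared by every family:

* features prefixed ``NL_`` are computed from the probability-normalized
  matrix (counts / total), never from a range-rescaled one;
* logarithms are base 2 (entropies in bits);
* zero-variance constructs (correlation-type features, skewness,
  kurtosis) are defined as 0 on constant input so the feature vector is
  always total and finite;
* neighborhoods are truncated at the mask boundary: only in-mask
  neighbors are ever counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..quantize import QuantizedROI, quantize_fixed_bin_width
from ..registry import FAMILIES, FEATURE_NAMES
from ..segmentation import compute_mtv_from_count
from ..volume_io import ROIMask, SUVVolume
from .coding import (
    TFCCM,
    MAX_TFC_CODE,
    TextureSpectrum,
    TFCVolume,
    complement_unit,
    compute_texture_spectrum,
    compute_tfc,
    compute_tfccm,
    invert_unit,
    spectrum_overlap_deficit,
)
from .matrices import (
    GLCM,
    GLRLM,
    GLSZM,
    NGLDM,
    NGTDM,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    compute_ngldm,
    compute_ngtdm,
)

#: epsilon guard for NGTDM coarseness/strength denominators
NGTDM_EPS = 1e-6


@dataclass(frozen=True)
class ExtractionSettings:
    """Quantization and matrix parameters of a feature extraction run."""

    bin_width: float = 0.4
    range_min: float = 0.0
    range_max: float = 25.0
    n_levels: int = 64
    glcm_distance: int = 1
    ngldm_tolerance: int = 0
    #: base of every entropy logarithm (2.0 = bits, e for nats)
    log_base: float = 2.0


def _entropy(p: np.ndarray, base: float = 2.0) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


# ---------------------------------------------------------------- GLCM


def glcm_features(m: GLCM, log_base: float = 2.0) -> dict[str, float]:
    p = m.p
    Ng = p.shape[0]
    i = np.arange(1, Ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)

    px = p.sum(axis=1)
    mu = float((i * px).sum())  # symmetric: mu_x = mu_y
    var = float(((i - mu) ** 2 * px).sum())

    # diagonal-band (sum / difference) distributions
    ksum = np.arange(2, 2 * Ng + 1, dtype=np.float64)
    p_sum = np.zeros(ksum.size)
    kdiff = np.arange(0, Ng, dtype=np.float64)
    p_diff = np.zeros(kdiff.size)
    for a in range(Ng):
        for b in range(Ng):
            if p[a, b] > 0:
                p_sum[a + b] += p[a, b]
                p_diff[abs(a - b)] += p[a, b]
    sum_avg = float((ksum * p_sum).sum())
    diff_avg = float((kdiff * p_diff).sum())

    hxy = _entropy(p.ravel(), log_base)
    hx = _entropy(px, log_base)
    pxy = np.outer(px, px)
    nz = pxy > 0
    hxy1 = float(-(p[nz] * np.log(pxy[nz])).sum() / np.log(log_base))
    hxy2 = _entropy(pxy.ravel(), log_base)
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0  # HX = HY by symmetry
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = diff > 0
    corr = (
        float((((ii - mu) * (jj - mu) * p).sum()) / var) if var > 0 else 0.0
    )

    return {
        "NL_Energy^GLCM": float((p**2).sum()),
        "NL_MaximumProbability^GLCM": float(p.max()),
        "NL_Contrast^GLCM": float((p * diff**2).sum()),
        "NL_Entropy^GLCM": hxy,
        "NL_Homogeneity^GLCM": float((p / (1.0 + diff)).sum()),
        "NL_Dissimilarity^GLCM": float((p * diff).sum()),
        "NL_InverseDifferenceMoment^GLCM": float((p / (1.0 + diff**2)).sum()),
        "NL_InverseVariance^GLCM": float((p[off] / diff[off] ** 2).sum()),
        "NL_Correlation^GLCM": corr,
        "NL_Autocorrelation^GLCM": float((ii * jj * p).sum()),
        "NL_JointAverage^GLCM": mu,
        "NL_JointVariance^GLCM": var,
        "NL_ClusterTendency^GLCM": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "NL_ClusterShade^GLCM": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "NL_ClusterProminence^GLCM": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "NL_SumAverage^GLCM": sum_avg,
        "NL_SumVariance^GLCM": float(((ksum - sum_avg) ** 2 * p_sum).sum()),
        "NL_SumEntropy^GLCM": _entropy(p_sum, log_base),
        "NL_DifferenceAverage^GLCM": diff_avg,
        "NL_DifferenceVariance^GLCM": float(((kdiff - diff_avg) ** 2 * p_diff).sum()),
        "NL_DifferenceEntropy^GLCM": _entropy(p_diff, log_base),
        "NL_IMC1^GLCM": float(imc1),
        "NL_IMC2^GLCM": imc2,
    }


# --------------------------------------------------------------- GLRLM


def glrlm_features(m: GLRLM, log_base: float = 2.0) -> dict[str, float]:
    r = m.r.astype(np.float64)
    n_runs = r.sum()
    i = np.arange(1, r.shape[0] + 1, dtype=np.float64)
    ell = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    ii, ll = np.meshgrid(i, ell, indexing="ij")
    pr = r / n_runs
    mu_i = float((ii * pr).sum())
    mu_l = float((ll * pr).sum())
    return {
        "SRE^GLRLM": float((r / ll**2).sum() / n_runs),
        "LRE^GLRLM": float((r * ll**2).sum() / n_runs),
        "LGRE^GLRLM": float((r / ii**2).sum() / n_runs),
        "HGRE^GLRLM": float((r * ii**2).sum() / n_runs),
        "SRLGE^GLRLM": float((r / (ii**2 * ll**2)).sum() / n_runs),
        "SRHGE^GLRLM": float((r * ii**2 / ll**2).sum() / n_runs),
        "LRLGE^GLRLM": float((r * ll**2 / ii**2).sum() / n_runs),
        "LRHGE^GLRLM": float((r * ii**2 * ll**2).sum() / n_runs),
        "GLN^GLRLM": float((r.sum(axis=1) ** 2).sum() / n_runs),
        "GLNN^GLRLM": float((r.sum(axis=1) ** 2).sum() / n_runs**2),
        "RLN^GLRLM": float((r.sum(axis=0) ** 2).sum() / n_runs),
        "RLNN^GLRLM": float((r.sum(axis=0) ** 2).sum() / n_runs**2),
        "RP^GLRLM": float(n_runs / (m.n_voxels * m.n_directions)),
        "GLV^GLRLM": float(((ii - mu_i) ** 2 * pr).sum()),
        "RLV^GLRLM": float(((ll - mu_l) ** 2 * pr).sum()),
        "RE^GLRLM": _entropy(pr.ravel(), log_base),
    }


# --------------------------------------------------------------- GLSZM


def glszm_features(m: GLSZM, log_base: float = 2.0) -> dict[str, float]:
    z = m.z.astype(np.float64)
    n_zones = float(m.n_zones)
    i = np.arange(1, z.shape[0] + 1, dtype=np.float64)
    s = np.arange(1, z.shape[1] + 1, dtype=np.float64)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    pz = z / n_zones
    mu_i = float((ii * pz).sum())
    mu_s = float((ss * pz).sum())
    return {
        "SZE^GLSZM": float((z / ss**2).sum() / n_zones),
        "LZE^GLSZM": float((z * ss**2).sum() / n_zones),
        "LIZE^GLSZM": float((z / ii**2).sum() / n_zones),
        "HIZE^GLSZM": float((z * ii**2).sum() / n_zones),
        "LISZE^GLSZM": float((z / (ii**2 * ss**2)).sum() / n_zones),
        "HISZE^GLSZM": float((z * ii**2 / ss**2).sum() / n_zones),
        "LILZE^GLSZM": float((z * ss**2 / ii**2).sum() / n_zones),
        "HILZE^GLSZM": float((z * ii**2 * ss**2).sum() / n_zones),
        "IN^GLSZM": float((z.sum(axis=1) ** 2).sum() / n_zones),
        "INN^GLSZM": float((z.sum(axis=1) ** 2).sum() / n_zones**2),
        "ZSN^GLSZM": float((z.sum(axis=0) ** 2).sum() / n_zones),
        "ZSNN^GLSZM": float((z.sum(axis=0) ** 2).sum() / n_zones**2),
        "ZP^GLSZM": float(n_zones / m.n_voxels),
        "IV^GLSZM": float(((ii - mu_i) ** 2 * pz).sum()),
        "ZSV^GLSZM": float(((ss - mu_s) ** 2 * pz).sum()),
        "ZE^GLSZM": _entropy(pz.ravel(), log_base),
    }


# --------------------------------------------------------------- NGTDM


def ngtdm_features(m: NGTDM) -> dict[str, float]:
    p, s = m.p, m.s
    occ = p > 0
    i = np.arange(1, m.Ng + 1, dtype=np.float64)
    n_gp = int(occ.sum())
    ps = float((p * s).sum())

    coarseness = 1.0 / (NGTDM_EPS + ps)
    if n_gp > 1:
        pi, pj = np.meshgrid(p[occ], p[occ], indexing="ij")
        li, lj = np.meshgrid(i[occ], i[occ], indexing="ij")
        si, sj = np.meshgrid(s[occ], s[occ], indexing="ij")
        contrast = float(
            (pi * pj * (li - lj) ** 2).sum()
            / (n_gp * (n_gp - 1))
            * s.sum()
            / m.n_valid
        )
        denom_b = float(np.abs(li * pi - lj * pj).sum())
        busyness = ps / denom_b if denom_b > 0 else 0.0
        complexity = float(
            (np.abs(li - lj) * (pi * si + pj * sj) / (pi + pj)).sum() / m.n_valid
        )
        strength = float(((pi + pj) * (li - lj) ** 2).sum() / (NGTDM_EPS + s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness^NGTDM": coarseness,
        "Contrast^NGTDM": contrast,
        "Busyness^NGTDM": busyness,
        "Complexity^NGTDM": complexity,
        "Strength^NGTDM": strength,
    }


# --------------------------------------------------------------- NGLDM


def ngldm_features(m: NGLDM, log_base: float = 2.0) -> dict[str, float]:
    d = m.d.astype(np.float64)
    ns = float(d.sum())
    i = np.arange(1, d.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, d.shape[1] + 1, dtype=np.float64)  # dependence count k+1
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pd = d / ns
    mu_i = float((ii * pd).sum())
    mu_j = float((jj * pd).sum())
    return {
        "SNE^NGLDM": float((d / jj**2).sum() / ns),
        "LNE^NGLDM": float((d * jj**2).sum() / ns),
        "LGCE^NGLDM": float((d / ii**2).sum() / ns),
        "HGCE^NGLDM": float((d * ii**2).sum() / ns),
        "SNLGE^NGLDM": float((d / (ii**2 * jj**2)).sum() / ns),
        "SNHGE^NGLDM": float((d * ii**2 / jj**2).sum() / ns),
        "LNLGE^NGLDM": float((d * jj**2 / ii**2).sum() / ns),
        "LNHGE^NGLDM": float((d * ii**2 * jj**2).sum() / ns),
        "GLN^NGLDM": float((d.sum(axis=1) ** 2).sum() / ns),
        "GLNN^NGLDM": float((d.sum(axis=1) ** 2).sum() / ns**2),
        "DCN^NGLDM": float((d.sum(axis=0) ** 2).sum() / ns),
        "DCNN^NGLDM": float((d.sum(axis=0) ** 2).sum() / ns**2),
        "SecondMoment^NGLDM": float((pd**2).sum()),
        "Entropy^NGLDM": _entropy(pd.ravel(), log_base),
    }


# ----------------------------------------------------- TS / TFC / TFCCM


def ts_features(ts: TextureSpectrum, log_base: float = 2.0) -> dict[str, float]:
    p = ts.counts / ts.n
    return {
        "MaxSpectrum^TS": float(p.max()),
        "Entropy^TS": _entropy(p, log_base),
        "BWS^TS": 1.0 - spectrum_overlap_deficit(ts, complement_unit),
        "GS^TS": 1.0 - spectrum_overlap_deficit(ts, invert_unit),
    }


def tfc_features(tfc: TFCVolume, log_base: float = 2.0) -> dict[str, float]:
    codes = tfc.codes[tfc.valid].astype(np.float64)
    hist = np.bincount(codes.astype(np.int64), minlength=MAX_TFC_CODE + 1)
    p = hist / hist.sum()
    mean_code = float(codes.mean())
    n_pairs = float(tfc.class_counts.sum())
    return {
        "Coarseness^TFC": 1.0 / (1.0 + mean_code),
        "Homogeneity^TFC": float(tfc.class_counts[0] / n_pairs),
        "MeanConvergence^TFC": mean_code / MAX_TFC_CODE,
        "Variance^TFC": float(codes.var()),
        "CodeEntropy^TFC": _entropy(p, log_base),
        "MaxCodeProbability^TFC": float(p.max()),
    }


def tfccm_features(m: TFCCM, log_base: float = 2.0) -> dict[str, float]:
    p = m.p
    n = p.shape[0]
    c = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(c, c, indexing="ij")
    diff = np.abs(ii - jj)
    px = p.sum(axis=1)
    mu = float((c * px).sum())
    var = float(((c - mu) ** 2 * px).sum())
    corr = float((((ii - mu) * (jj - mu) * p).sum()) / var) if var > 0 else 0.0
    return {
        "SecondAngularMoment^TFCCM": float((p**2).sum()),
        "Contrast^TFCCM": float((p * diff**2).sum()),
        "Entropy^TFCCM": _entropy(p.ravel(), log_base),
        "Homogeneity^TFCCM": float((p / (1.0 + diff)).sum()),
        "InverseDifferenceMoment^TFCCM": float((p / (1.0 + diff**2)).sum()),
        "Dissimilarity^TFCCM": float((p * diff).sum()),
        "Correlation^TFCCM": corr,
        "MaximumProbability^TFCCM": float(p.max()),
        "Variance^TFCCM": var,
    }


# ------------------------------------------------- first-order statistics


def suv_statistics(volume: SUVVolume, mask: ROIMask) -> dict[str, float]:
    """First-order SUV statistics and volumetric indices on raw SUVs.

    CV = population SD / mean; TLG = SUV_mean x MTV; skewness and
    kurtosis (Pearson) are 0 by convention on constant input.
    """
    if not mask.flags.any():
        raise ValueError("empty mask")
    suv = volume.values[mask.flags]
    n = suv.size
    mean = float(suv.mean())
    sd = float(suv.std())  # population convention
    mtv = compute_mtv_from_count(n, volume.spacing)
    if sd > 0:
        skew = float(((suv - mean) ** 3).mean() / sd**3)
        kurt = float(((suv - mean) ** 4).mean() / sd**4)
    else:
        skew = kurt = 0.0
    q25, q75 = np.percentile(suv, [25, 75])
    return {
        "SUV_max": float(suv.max()),
        "SUV_mean": mean,
        "SUV_min": float(suv.min()),
        "SUV_median": float(np.median(suv)),
        "SUV_IQR": float(q75 - q25),
        "SUV_SD": sd,
        "SUV_Variance": sd**2,
        "SUV_Range": float(suv.max() - suv.min()),
        "SUV_RMS": float(np.sqrt((suv**2).mean())),
        "CV": sd / mean if mean > 0 else 0.0,
        "Skewness": skew,
        "Kurtosis": kurt,
        "MTV": mtv,
        "TLG": mean * mtv,
    }


def histogram_features(q: QuantizedROI, log_base: float = 2.0) -> dict[str, float]:
    """Entropy and uniformity of the quantized gray-level histogram."""
    counts = np.bincount(q.levels[q.mask], minlength=q.Ng + 1)[1:]
    p = counts / counts.sum()
    return {
        "Entropy^Histogram": _entropy(p, log_base),
        "Uniformity^Histogram": float((p[p > 0] ** 2).sum()),
    }


# --------------------------------------------------------- full vector


def extract_all_features(
    volume: SUVVolume,
    mask: ROIMask,
    settings: ExtractionSettings | None = None,
) -> dict[str, float]:
    """Compute the complete 109-feature vector of a segmented tumor.

    Returns a dict keyed exactly by the registry names, in registry
    order.  Raises ``ValueError`` naming the feature if any value is
    non-finite.
    """
    if settings is None:
        settings = ExtractionSettings()
    q = quantize_fixed_bin_width(
        volume,
        mask,
        bin_width=settings.bin_width,
        range_min=settings.range_min,
        range_max=settings.range_max,
        n_levels=settings.n_levels,
    )
    out: dict[str, float] = {}
    lb = settings.log_base
    out.update(suv_statistics(volume, mask))
    out.update(histogram_features(q, lb))
    out.update(glcm_features(compute_glcm(q, distance=settings.glcm_distance), lb))
    out.update(glrlm_features(compute_glrlm(q), lb))
    out.update(glszm_features(compute_glszm(q), lb))
    out.update(ngtdm_features(compute_ngtdm(q)))
    out.update(ngldm_features(compute_ngldm(q, tolerance=settings.ngldm_tolerance), lb))
    out.update(ts_features(compute_texture_spectrum(q), lb))
    tfc = compute_tfc(q)
    out.update(tfc_features(tfc, lb))
    out.update(tfccm_features(compute_tfccm(tfc), lb))

    missing = [n for n in FEATURE_NAMES if n not in out]
    extra = [n for n in out if n not in FEATURE_NAMES]
    if missing or extra:
        raise ValueError(f"feature set mismatch: missing={missing} extra={extra}")
    for name, value in out.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite feature {name!r} = {value}")
    return {name: out[name] for name in FEATURE_NAMES}


__all__ = [
    "ExtractionSettings",
    "extract_all_features",
    "suv_statistics",
    "histogram_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "ngldm_features",
    "ts_features",
    "tfc_features",
    "tfccm_features",
    "FAMILIES",
]
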