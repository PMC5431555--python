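"""Declarative registry of the 109 texture features.

The feature vector computed per tumor contains exactly the names listed
here, one scalar per name.  Matrix-derived features carry the matrix name
as a ``^`` suffix (``NL_Entropy^GLCM``); first-order SUV statistics and
the conventional volumetric indices (SUV_max, MTV, TLG, ...) are plain
names.  The registry is validated at import time: 109 unique names,
partitioned over the nine matrix families, and containing every feature
referenced individually in downstream summaries.

The exact membership of the original 109-feature panel is not published
in full; this registry follows the standard 3D radiomics feature lists
per family and is the package's single source of truth.
"""

from __future__ import annotations

from types import MappingProxyType

#: family name -> tuple of feature names belonging to it
FAMILIES: MappingProxyType[str, tuple[str, ...]] = MappingProxyType(
    {
        # first-order statistics on raw SUVs + histogram statistics on the
        # quantized levels + volumetric indices
        "SUVstats": (
            "SUV_max",
            "SUV_mean",
            "SUV_min",
            "SUV_median",
            "SUV_IQR",
            "SUV_SD",
            "SUV_Variance",
            "SUV_Range",
            "SUV_RMS",
            "CV",
            "Skewness",
            "Kurtosis",
            "MTV",
            "TLG",
            "Entropy^Histogram",
            "Uniformity^Histogram",
        ),
        # gray level co-occurrence matrix; NL_ = computed from the
        # probability-normalized matrix
        "GLCM": (
            "NL_Energy^GLCM",
            "NL_MaximumProbability^GLCM",
            "NL_Contrast^GLCM",
            "NL_Entropy^GLCM",
            "NL_Homogeneity^GLCM",
            "NL_Dissimilarity^GLCM",
            "NL_InverseDifferenceMoment^GLCM",
            "NL_InverseVariance^GLCM",
            "NL_Correlation^GLCM",
            "NL_Autocorrelation^GLCM",
            "NL_JointAverage^GLCM",
            "NL_JointVariance^GLCM",
            "NL_ClusterTendency^GLCM",
            "NL_ClusterShade^GLCM",
            "NL_ClusterProminence^GLCM",
            "NL_SumAverage^GLCM",
            "NL_SumVariance^GLCM",
            "NL_SumEntropy^GLCM",
            "NL_DifferenceAverage^GLCM",
            "NL_DifferenceVariance^GLCM",
            "NL_DifferenceEntropy^GLCM",
            "NL_IMC1^GLCM",
            "NL_IMC2^GLCM",
        ),
        # gray level run-length matrix (13 directions, summed)
        "GLRLM": (
            "SRE^GLRLM",
            "LRE^GLRLM",
            "LGRE^GLRLM",
            "HGRE^GLRLM",
            "SRLGE^GLRLM",
            "SRHGE^GLRLM",
            "LRLGE^GLRLM",
            "LRHGE^GLRLM",
            "GLN^GLRLM",
            "GLNN^GLRLM",
            "RLN^GLRLM",
            "RLNN^GLRLM",
            "RP^GLRLM",
            "GLV^GLRLM",
            "RLV^GLRLM",
            "RE^GLRLM",
        ),
        # gray level size zone matrix (26-connected zones)
        "GLSZM": (
            "SZE^GLSZM",
            "LZE^GLSZM",
            "LIZE^GLSZM",
            "HIZE^GLSZM",
            "LISZE^GLSZM",
            "HISZE^GLSZM",
            "LILZE^GLSZM",
            "HILZE^GLSZM",
            "IN^GLSZM",
            "INN^GLSZM",
            "ZSN^GLSZM",
            "ZSNN^GLSZM",
            "ZP^GLSZM",
            "IV^GLSZM",
            "ZSV^GLSZM",
            "ZE^GLSZM",
        ),
        # neighborhood gray tone difference matrix
        "NGTDM": (
            "Coarseness^NGTDM",
            "Contrast^NGTDM",
            "Busyness^NGTDM",
            "Complexity^NGTDM",
            "Strength^NGTDM",
        ),
        # neighboring gray level dependence matrix
        "NGLDM": (
            "SNE^NGLDM",
            "LNE^NGLDM",
            "LGCE^NGLDM",
            "HGCE^NGLDM",
            "SNLGE^NGLDM",
            "SNHGE^NGLDM",
            "LNLGE^NGLDM",
            "LNHGE^NGLDM",
            "GLN^NGLDM",
            "GLNN^NGLDM",
            "DCN^NGLDM",
            "DCNN^NGLDM",
            "SecondMoment^NGLDM",
            "Entropy^NGLDM",
        ),
        # texture spectrum over 26-neighbor ternary texture units
        "TS": (
            "MaxSpectrum^TS",
            "Entropy^TS",
            "BWS^TS",
            "GS^TS",
        ),
        # texture feature coding (per-voxel gradient-class code)
        "TFC": (
            "Coarseness^TFC",
            "Homogeneity^TFC",
            "MeanConvergence^TFC",
            "Variance^TFC",
            "CodeEntropy^TFC",
            "MaxCodeProbability^TFC",
        ),
        # co-occurrence matrix over TFC codes
        "TFCCM": (
            "SecondAngularMoment^TFCCM",
            "Contrast^TFCCM",
            "Entropy^TFCCM",
            "Homogeneity^TFCCM",
            "InverseDifferenceMoment^TFCCM",
            "Dissimilarity^TFCCM",
            "Correlation^TFCCM",
            "MaximumProbability^TFCCM",
            "Variance^TFCCM",
        ),
    }
)

#: flat ordered tuple of all registry feature names
FEATURE_NAMES: tuple[str, ...] = tuple(
    name for family in FAMILIES.values() for name in family
)

N_FEATURES = 109

# features referenced individually in the clinical summaries; their
# presence is a registry invariant
_REQUIRED = (
    "SUV_max",
    "SUV_mean",
    "MTV",
    "TLG",
    "CV",
    "Skewness",
    "NL_Entropy^GLCM",
    "NL_Homogeneity^GLCM",
    "NL_Dissimilarity^GLCM",
    "ZP^GLSZM",
    "HILZE^GLSZM",
)


def validate_registry() -> None:
    """Check registry invariants; raise ``ValueError`` on violation."""
    if len(FEATURE_NAMES) != N_FEATURES:
        raise ValueError(
            f"registry lists {len(FEATURE_NAMES)} features, expected {N_FEATURES}"
        )
    if len(set(FEATURE_NAMES)) != len(FEATURE_NAMES):
        seen: set[str] = set()
        dup = [n for n in FEATURE_NAMES if n in seen or seen.add(n)]
        raise ValueError(f"duplicate feature names in registry: {dup}")
    missing = [n for n in _REQUIRED if n not in FEATURE_NAMES]
    if missing:
        raise ValueError(f"registry is missing required features: {missing}")


validate_registry()
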