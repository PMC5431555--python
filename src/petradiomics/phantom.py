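"""Synthetic SUV tumor phantoms and cohorts.

The generator emulates the three tumor phenotypes seen in FDG-PET of
locally advanced breast cancer:

* archetype I  — large, intense, heterogeneous (MTV ~63 cm^3, CV ~0.42),
* archetype II — medium size, intense, heterogeneous (MTV ~18 cm^3, CV ~0.45),
* archetype III — small, mildly avid, homogeneous (MTV ~3 cm^3, CV ~0.21),

with archetype-conditional pathologic-complete-response probabilities
(0.200 / 0.480 / 0.054) and recurrence hazards.  A tumor is an ellipsoid
of elevated uptake whose interior is modulated by a log-normal random
field: Gaussian white noise smoothed with an isotropic kernel of width
``correlation_length`` (mm), standardized, and exponentiated so the
multiplicative field has mean 1 and standard deviation
``heterogeneity_sd`` exactly.  Background parenchyma sits at a low SUV
level with small additive noise.

All randomness flows from explicit integer seeds; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume_io import ROIMask, SUVVolume, write_mask, write_volume

#: default scanner geometry (mm), a typical whole-body PET voxel size
DEFAULT_SPACING = (3.91, 3.91, 3.27)

#: additive Gaussian noise SD on the background (SUV units)
BACKGROUND_NOISE_SD = 0.05


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single ellipsoidal tumor phantom.

    Lengths are in mm, uptake in SUV units.  ``heterogeneity_sd`` is the
    standard deviation of the multiplicative intensity field (0 gives a
    constant-uptake tumor).
    """

    semi_axes: tuple[float, float, float]
    base_suv: float
    heterogeneity_sd: float = 0.0
    correlation_length: float = 8.0
    background_suv: float = 0.5
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    grid_shape: tuple[int, int, int] = (28, 28, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise PhantomError(f"semi_axes must be positive, got {self.semi_axes}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if any(int(n) < 1 or n != int(n) for n in self.grid_shape):
            raise PhantomError(f"grid_shape must be positive integers, got {self.grid_shape}")
        if self.background_suv < 0 or self.base_suv <= self.background_suv:
            raise PhantomError(
                f"need base_suv > background_suv >= 0, got {self.base_suv} / {self.background_suv}"
            )
        if self.heterogeneity_sd < 0:
            raise PhantomError("heterogeneity_sd must be >= 0")
        if self.correlation_length <= 0:
            raise PhantomError("correlation_length must be > 0")


@dataclass(frozen=True)
class OutcomeModel:
    """Archetype-conditional outcome generator.

    pCR is Bernoulli per archetype; recurrence times are exponential with
    the per-archetype hazard (events/month) right-censored by a uniform
    draw over ``censor_time_range`` (months).  Default pCR probabilities
    are the observed per-cluster rates 20.0% / 48.0% / 5.4%; default
    hazards reproduce the observed recurrence pattern (3/10 in group I,
    0 in group II, 1/35 in group III over ~4 years of follow-up).
    """

    pcr_prob_per_cluster: tuple[float, ...] = (0.200, 0.480, 0.054)
    recurrence_hazard_per_cluster: tuple[float, ...] = (0.008, 0.0, 0.0007)
    censor_time_range: tuple[float, float] = (16.0, 57.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.pcr_prob_per_cluster):
            raise PhantomError("pCR probabilities must lie in [0, 1]")
        if any(h < 0 for h in self.recurrence_hazard_per_cluster):
            raise PhantomError("hazards must be >= 0")
        lo, hi = self.censor_time_range
        if not (0 < lo <= hi):
            raise PhantomError("censor_time_range must be positive and ordered")


def _ellipsoid_radius_mm(volume_cm3: float) -> float:
    """Radius of the sphere with the given volume."""
    return float((3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def _sphere_spec(volume_cm3: float, base_suv: float, cv: float, seed: int) -> PhantomSpec:
    r = _ellipsoid_radius_mm(volume_cm3)
    return PhantomSpec(
        semi_axes=(r, r, r), base_suv=base_suv, heterogeneity_sd=cv, seed=seed
    )


#: archetype templates calibrated to the published per-cluster medians
#: (MTV in cm^3, SUV_mean, CV); SUV_max is emergent from the field
DEFAULT_ARCHETYPES: tuple[PhantomSpec, PhantomSpec, PhantomSpec] = (
    _sphere_spec(62.9, 4.9, 0.42, seed=101),
    _sphere_spec(18.4, 6.1, 0.45, seed=102),
    _sphere_spec(2.9, 3.6, 0.21, seed=103),
)

# archetype-conditional marker prevalences used to populate the clinical
# table (ER+, PgR+, HER2+, Ki67-high), matching the published per-cluster
# proportions
_MARKER_PROBS = {
    "er": (0.30, 0.32, 0.65),
    "pgr": (0.20, 0.16, 0.49),
    "her2": (0.33, 0.21, 0.29),
    "ki67_high": (0.80, 0.64, 0.32),
}
_STAGE3_PROB = 35.0 / 73.0  # cohort-level stage III fraction


def make_tumor_phantom(spec: PhantomSpec) -> tuple[SUVVolume, ROIMask]:
    """Generate one tumor phantom; returns the volume and ground-truth mask.

    Deterministic for a fixed ``spec.seed``.  Raises :class:`PhantomError`
    when the ellipsoid does not fit in the grid with a 2-voxel margin.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    semi = np.asarray(spec.semi_axes, dtype=float)

    # grid must contain the ellipsoid with >= 2 voxels margin per side
    needed = 2.0 * semi / spacing + 4.0
    if np.any(needed > np.asarray(shape)):
        raise PhantomError(
            f"ellipsoid with semi-axes {spec.semi_axes} mm exceeds grid "
            f"{shape} at spacing {spec.voxel_spacing} (needs {np.ceil(needed).astype(int)})"
        )

    center = (np.asarray(shape) - 1) / 2.0 * spacing
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    inside = (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    ) <= 1.0

    rng = np.random.default_rng(spec.seed)
    if spec.heterogeneity_sd > 0:
        white = rng.standard_normal(shape)
        sigma_vox = spec.correlation_length / spacing
        smooth = gaussian_filter(white, sigma=sigma_vox, mode="nearest")
        # standardize over the tumor voxels so the within-tumor field SD
        # equals heterogeneity_sd regardless of smoothing or grid edges
        sd = smooth[inside].std()
        g = (smooth - smooth[inside].mean()) / sd if sd > 0 else np.zeros(shape)
        # log-normal field with mean exactly 1 and SD exactly heterogeneity_sd
        s_log = np.sqrt(np.log1p(spec.heterogeneity_sd**2))
        fld = np.exp(s_log * g - 0.5 * s_log**2)
    else:
        fld = np.ones(shape)

    values = np.empty(shape, dtype=np.float64)
    values[inside] = spec.base_suv * fld[inside]
    noise = rng.normal(0.0, BACKGROUND_NOISE_SD, size=shape)
    values[~inside] = np.clip(spec.background_suv + noise[~inside], 0.0, None)

    vol = SUVVolume(values=values, spacing=tuple(spacing))
    mask = ROIMask(flags=inside.astype(np.uint8), spacing=tuple(spacing))
    return vol, mask


def make_cohort(
    n_per_archetype: tuple[int, ...] = (10, 25, 37),
    archetypes: tuple[PhantomSpec, ...] = DEFAULT_ARCHETYPES,
    outcomes: OutcomeModel | None = None,
    jitter_sd: float = 0.15,
    seed: int = 0,
) -> tuple[list[SUVVolume], pd.DataFrame]:
    """Simulate a cohort of tumor phantoms with clinical outcomes.

    Each patient draws phantom parameters around its archetype template
    (log-normal multiplicative jitter of ``jitter_sd`` on semi-axes and
    base uptake), a Bernoulli pCR given its archetype, and an exponential
    recurrence time truncated by uniform censoring.  Returns the volumes
    and a cohort table with the planted archetype labels retained.
    """
    if len(archetypes) == 0:
        raise PhantomError("archetypes must be non-empty")
    if len(n_per_archetype) != len(archetypes):
        raise PhantomError("n_per_archetype and archetypes must have the same length")
    if any(int(n) < 1 for n in n_per_archetype):
        raise PhantomError("each archetype needs at least one patient")
    if outcomes is None:
        outcomes = OutcomeModel()
    if len(outcomes.pcr_prob_per_cluster) < len(archetypes):
        raise PhantomError("outcome model covers fewer archetypes than requested")

    ss = np.random.SeedSequence(seed)
    n_total = int(sum(n_per_archetype))
    patient_seeds = ss.generate_state(n_total) % (2**31)
    out_rng = np.random.default_rng(outcomes.seed)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])

    volumes: list[SUVVolume] = []
    rows: list[dict] = []
    pid = 0
    for k, (n_k, template) in enumerate(zip(n_per_archetype, archetypes)):
        for _ in range(int(n_k)):
            jit = jitter_rng.lognormal(mean=0.0, sigma=jitter_sd, size=4)
            semi = tuple(a * j for a, j in zip(template.semi_axes, jit[:3]))
            base = template.base_suv * jit[3]
            spec = replace(
                template,
                semi_axes=semi,
                base_suv=max(base, template.background_suv + 0.5),
                seed=int(patient_seeds[pid]),
            )
            vol, _ = make_tumor_phantom(spec)
            volumes.append(vol)

            pcr = int(out_rng.random() < outcomes.pcr_prob_per_cluster[k])
            hazard = outcomes.recurrence_hazard_per_cluster[k]
            t_event = out_rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
            t_censor = out_rng.uniform(*outcomes.censor_time_range)
            event = int(t_event <= t_censor)
            dfs = float(min(t_event, t_censor))
            row = {
                "patient_id": f"P{pid:03d}",
                "archetype": k + 1,
                "stage": 3 if out_rng.random() < _STAGE3_PROB else 2,
                "pcr": pcr,
                "dfs_months": dfs,
                "event": event,
            }
            for marker, probs in _MARKER_PROBS.items():
                row[marker] = int(out_rng.random() < probs[k])
            rows.append(row)
            pid += 1

    cols = ["patient_id", "archetype", "er", "pgr", "her2", "ki67_high",
            "stage", "pcr", "dfs_months", "event"]
    table = pd.DataFrame(rows)[cols]
    return volumes, table


def write_cohort(
    volumes: list[SUVVolume], table: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write cohort volumes as NIfTI plus the clinical table as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pid, vol in zip(table["patient_id"], volumes):
        write_volume(vol, out_dir / f"{pid}.nii.gz")
    table.to_csv(out_dir / "cohort.csv", index=False)
    return out_dir
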