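"""ROI projection onto PET grids and regional uptake quantification.

The template's label volume lives on a fine MR grid (~0.0013 mm^3 voxels); PET
voxels are ~1390x larger. Projection therefore estimates, for every PET voxel,
the fraction of its volume inside each region by k^3 subvoxel sampling mapped
through the inverse registration transform. Two inclusion rules are offered:

* ``threshold`` (default): a voxel belongs to the region when at least
  ``inclusion_fraction`` of it is inside (binary weights);
* ``fractional``: the coverage fractions are used directly as weights.

Regional uptake is expressed as percent injected dose per gram:

    %ID/g = C / (D * rho) * 100

with C the regional mean concentration (kBq/mL), D the injected dose (kBq) and
rho the brain tissue density (g/mL, default 1.045).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DynamicImage, ImageVolume, RigidTransform, VoxelGrid
from .template import LabelVolume, RegionInfo

logger = logging.getLogger("ratpet")

__all__ = [
    "QuantConfig",
    "ROIStatistics",
    "project_rois",
    "roi_statistics",
    "percent_id_per_g",
    "extract_tac",
    "timepoint_uptake",
    "statistics_table",
]

DEFAULT_TISSUE_DENSITY_G_PER_ML = 1.045


@dataclass(frozen=True)
class QuantConfig:
    """Quantification settings (dose in kBq, density in g/mL)."""

    injected_dose_kbq: float = 9900.0
    tissue_density_g_per_ml: float = DEFAULT_TISSUE_DENSITY_G_PER_ML
    inclusion_mode: str = "threshold"
    inclusion_fraction: float = 0.5
    supersampling: int = 4

    def __post_init__(self) -> None:
        if self.injected_dose_kbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.tissue_density_g_per_ml <= 0:
            raise ValueError("tissue density must be positive")
        if self.inclusion_mode not in ("threshold", "fractional"):
            raise ValueError("inclusion_mode must be 'threshold' or 'fractional'")
        if not 0 < self.inclusion_fraction <= 1:
            raise ValueError("inclusion fraction must be in (0, 1]")
        if int(self.supersampling) < 1:
            raise ValueError("supersampling must be >= 1")
        object.__setattr__(self, "supersampling", int(self.supersampling))


@dataclass
class ROIStatistics:
    """Per-region statistics: the row type of the volume/activity tables."""

    code: int
    name: str
    volume_mm3: float
    mean_kbq_per_ml: float
    total_bq: float
    voxel_count: float  # sum of inclusion weights (integer in threshold mode)
    defined: bool = True


def _region_codes(labels: LabelVolume, regions=None):
    if regions:
        return sorted(int(c) for c in regions)
    return labels.codes()


def project_rois(
    labels: LabelVolume,
    target: VoxelGrid,
    t: RigidTransform | None = None,
    cfg: QuantConfig | None = None,
    regions=None,
) -> dict:
    """Per-region voxel weights of the template ROIs on ``target``.

    ``t`` maps target world coordinates into the label volume's world space
    (the registration transform for PET data in scanner space; identity when
    both live in template space). Returns ``{code: weight array}``; threshold
    mode yields boolean arrays, fractional mode float32 coverage fractions.
    """
    t = t or RigidTransform.identity()
    cfg = cfg or QuantConfig()
    codes = _region_codes(labels, regions)

    if t.is_identity() and target == labels.grid:
        # Same-grid identity projection is exact: the labels are the weights.
        return {code: labels.labels == code for code in codes}

    k = cfg.supersampling
    offsets = (np.arange(k) + 0.5) / k - 0.5  # symmetric subcell centres, voxel units
    vs_tgt = np.asarray(target.voxel_size)
    counts = {code: np.zeros(target.shape, dtype=np.int32) for code in codes}

    idx = np.indices(target.shape, dtype=float)  # (3, *shape)
    base_world = idx * vs_tgt[:, None, None, None] + np.asarray(target.origin)[:, None, None, None]
    # t maps target world -> label world (i.e. the registration transform for
    # scanner-space PET data); subvoxel points are formed in target space and
    # pushed through it.
    lin = t.rotation_matrix @ np.diag(t.scale)
    vs_lab = np.asarray(labels.grid.voxel_size)
    origin_lab = np.asarray(labels.grid.origin)
    label_arr = labels.labels

    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                shift = np.array([ox, oy, oz]) * vs_tgt
                world = base_world + shift[:, None, None, None]
                mapped = np.einsum("ij,j...->i...", lin, world) + np.asarray(t.translation_mm)[
                    :, None, None, None
                ]
                coords = (mapped - origin_lab[:, None, None, None]) / vs_lab[:, None, None, None]
                sampled = ndimage.map_coordinates(
                    label_arr, coords, order=0, mode="constant", cval=0, prefilter=False
                )
                for code in codes:
                    counts[code] += sampled == code

    total = float(k**3)
    weights = {}
    for code in codes:
        frac = counts[code] / total
        if cfg.inclusion_mode == "threshold":
            w = frac >= cfg.inclusion_fraction
        else:
            w = frac.astype(np.float32)
        if not np.any(w):
            warnings.warn(
                f"region {code} covers no target voxels after projection", stacklevel=2
            )
        weights[code] = w
    return weights


def roi_statistics(img: ImageVolume, weights: dict, regions=None) -> list:
    """Weighted per-region volume, mean concentration and total activity.

    total activity [Bq] = mean [kBq/mL] x volume [mm^3], because
    1 kBq/mL = 1 Bq/mm^3 (volume/1000 -> mL, x mean -> kBq, x1000 -> Bq).
    """
    regions = regions or {}
    out = []
    voxvol = img.grid.voxel_volume
    values = np.asarray(img.values, dtype=float)
    for code, w in sorted(weights.items()):
        w = np.asarray(w, dtype=float)
        wsum = float(w.sum())
        info = regions.get(code)
        name = info.name if isinstance(info, RegionInfo) else (info or f"region_{code}")
        if wsum == 0:
            out.append(ROIStatistics(code, name, 0.0, float("nan"), float("nan"), 0.0, defined=False))
            continue
        mean = float((w * values).sum() / wsum)
        volume = wsum * voxvol
        out.append(ROIStatistics(code, name, volume, mean, mean * volume, wsum))
    return out


def statistics_table(stats) -> pd.DataFrame:
    """Tabular view of :func:`roi_statistics` output."""
    return pd.DataFrame(
        {
            "code": [s.code for s in stats],
            "region": [s.name for s in stats],
            "volume_mm3": [s.volume_mm3 for s in stats],
            "mean_kbq_per_ml": [s.mean_kbq_per_ml for s in stats],
            "total_bq": [s.total_bq for s in stats],
            "voxel_count": [s.voxel_count for s in stats],
        }
    )


def percent_id_per_g(mean_concentration_kbq_per_ml, cfg: QuantConfig):
    """%ID/g = concentration / (injected dose x tissue density) x 100."""
    conc = np.asarray(mean_concentration_kbq_per_ml, dtype=float)
    result = conc / (cfg.injected_dose_kbq * cfg.tissue_density_g_per_ml) * 100.0
    return float(result) if result.ndim == 0 else result


def extract_tac(dyn: DynamicImage, weights: dict, regions=None) -> pd.DataFrame:
    """Per-region time-activity curve: one row per frame, one column per region.

    Columns ``start_s``, ``duration_s``, ``midpoint_s`` carry the schedule;
    remaining columns are region mean concentrations (kBq/mL).
    """
    rows = {
        "start_s": [s for s, _ in dyn.schedule],
        "duration_s": [d for _, d in dyn.schedule],
        "midpoint_s": [s + d / 2 for s, d in dyn.schedule],
    }
    names = {}
    for code in weights:
        info = (regions or {}).get(code)
        names[code] = info.name if isinstance(info, RegionInfo) else (info or f"region_{code}")
    series = {names[code]: [] for code in weights}
    for frame in dyn.frames:
        stats = {s.code: s for s in roi_statistics(frame, weights, regions)}
        for code in weights:
            series[names[code]].append(stats[code].mean_kbq_per_ml)
    rows.update(series)
    return pd.DataFrame(rows)


def _frame_for_minute(tac: pd.DataFrame, minute: float) -> int:
    seconds = minute * 60.0
    last_end = float(tac["start_s"].iloc[-1] + tac["duration_s"].iloc[-1])
    # Grace of half the final frame so a nominal scan-length time point
    # (e.g. "45 min" on a 44.5 min schedule) still maps to the last frame.
    if seconds > last_end + float(tac["duration_s"].iloc[-1]) / 2 or seconds < 0:
        raise ValueError(f"time point {minute} min is outside the scan span")
    return int((tac["midpoint_s"] - seconds).abs().idxmin())


def timepoint_uptake(tac: pd.DataFrame, minutes, cfg: QuantConfig) -> pd.DataFrame:
    """%ID/g per region at the frames nearest the requested minutes.

    Each requested minute maps to the single frame whose midpoint is nearest;
    frames are not averaged. Returns long-format rows
    ``(region, time_min, frame_index, mean_kbq_per_ml, percent_id_per_g)``.
    """
    region_cols = [c for c in tac.columns if c not in ("start_s", "duration_s", "midpoint_s")]
    records = []
    for minute in minutes:
        i = _frame_for_minute(tac, minute)
        for region in region_cols:
            conc = float(tac.loc[i, region])
            records.append(
                {
                    "region": region,
                    "time_min": float(minute),
                    "frame_index": i,
                    "mean_kbq_per_ml": conc,
                    "percent_id_per_g": percent_id_per_g(conc, cfg),
                }
            )
    return pd.DataFrame.from_records(records)
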