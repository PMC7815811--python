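"""Post-denoising preprocessing and quality control.

Covers the steps applied after ICA-based denoising: discarding initial
volumes, motion-based subject exclusion via framewise displacement,
nuisance regression (white matter / CSF signals), discrete-cosine high-pass
filtering, and atlas-masked extraction of region time series from a 4D
image with robust-range voxel exclusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import MotionTrace, RegionTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "discard_initial_volumes",
    "framewise_displacement",
    "motion_exclusion",
    "regress_nuisance",
    "highpass_filter",
    "extract_region_timeseries",
    "ExtractionResult",
]


def discard_initial_volumes(ts: RegionTimeSeries, n_discard: int) -> RegionTimeSeries:
    """Drop the first ``n_discard`` volumes (scanner equilibration period)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_volumes} volumes"
        )
    return ts.copy_with(values=ts.values[:, n_discard:])


def framewise_displacement(
    motion: MotionTrace, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Framewise displacement (mm) per frame-to-frame transition.

    FD_t = sum of absolute translation deltas plus absolute rotation deltas
    converted to arc length on a sphere of ``head_radius_mm``. A single
    volume yields an empty sequence.
    """
    if head_radius_mm <= 0:
        raise ValueError("head radius must be positive")
    if motion.n_volumes < 2:
        return np.empty(0)
    d = np.diff(motion.params, axis=0)
    trans = np.abs(d[:, :3]).sum(axis=1)
    rot = np.abs(d[:, 3:]).sum(axis=1) * head_radius_mm
    return trans + rot


def motion_exclusion(
    fd: np.ndarray, threshold_mm: float = 0.5, max_fraction: float = 0.20
) -> str:
    """Decide subject retention from the framewise-displacement sequence.

    Returns ``"exclude"`` iff the fraction of transitions with
    FD > ``threshold_mm`` reaches ``max_fraction`` (inclusive boundary),
    else ``"retain"``.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty framewise-displacement sequence")
    frac = float(np.mean(fd > threshold_mm))
    return "exclude" if frac >= max_fraction else "retain"


def regress_nuisance(ts: RegionTimeSeries, nuisance: np.ndarray) -> RegionTimeSeries:
    """Regress nuisance signals (plus intercept) out of every region series.

    ``nuisance`` is a signals x volumes matrix (e.g. mean white-matter and
    CSF series). Each region series is replaced by its ordinary
    least-squares residual.
    """
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[1] != ts.n_volumes:
        raise ValueError("nuisance volume count does not match the series")
    design = np.column_stack([np.ones(ts.n_volumes), nuisance.T])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient nuisance design (collinear signals)")
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    residuals = ts.values - (design @ beta).T
    return ts.copy_with(values=residuals)


def _dct_drift_basis(n_volumes: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine basis spanning drifts with period > 1/cutoff."""
    total = n_volumes * tr
    k_max = int(np.floor(2.0 * total * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes))
        for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def highpass_filter(ts: RegionTimeSeries, cutoff_hz: float = 0.01) -> RegionTimeSeries:
    """Remove slow drift below ``cutoff_hz`` by discrete-cosine regression.

    A DCT basis covering all periods longer than 1/cutoff (plus the mean)
    is regressed out of every region, leaving a mean-centred, drift-free
    series. Deterministic and free of filter edge transients.
    """
    nyquist = 0.5 / ts.tr
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above Nyquist {nyquist} Hz")
    basis = _dct_drift_basis(ts.n_volumes, ts.tr, cutoff_hz)
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    if basis.shape[1]:
        q, _ = np.linalg.qr(basis)
        x = x - (x @ q) @ q.T
    return ts.copy_with(values=x)


@dataclass
class ExtractionResult:
    """Region series from a labelled 4D image plus extraction QC."""

    timeseries: RegionTimeSeries
    dropped_regions: list[str]
    voxel_counts: dict[str, int]
    surviving_voxel_counts: dict[str, int]


def extract_region_timeseries(
    image,
    labels,
    tr: float,
    robust_fraction: float = 0.25,
    min_coverage: float = 0.5,
    subject_id: str = "",
) -> ExtractionResult:
    """Average voxel series per atlas region, excluding low-intensity voxels.

    ``image`` is a 4D nibabel image (or x,y,z,t array) and ``labels`` an
    integer label volume on the same grid. The robust intensity range is
    the [2nd, 98th] percentile of the temporal-mean intensity over the
    whole image (so background/dropout anchors the low end); voxels whose
    mean intensity falls below ``robust_min + robust_fraction *
    (robust_max - robust_min)`` are excluded (e.g. signal dropout).
    Regions retaining fewer than ``min_coverage`` of their voxels are
    dropped with a warning.
    """
    data = np.asarray(image.get_fdata() if hasattr(image, "get_fdata") else image, dtype=float)
    lab = np.asarray(
        labels.get_fdata() if hasattr(labels, "get_fdata") else labels
    ).astype(int)
    if data.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, t)")
    if lab.shape != data.shape[:3]:
        raise ValueError(
            f"label grid {lab.shape} does not match image grid {data.shape[:3]}"
        )
    mean_img = data.mean(axis=3)
    in_atlas = lab > 0
    if not in_atlas.any():
        raise ValueError("label volume contains no labelled voxels")
    lo, hi = np.percentile(mean_img, [2, 98])
    threshold = lo + robust_fraction * (hi - lo)
    mask = in_atlas & (mean_img >= threshold)

    region_ids = np.unique(lab[in_atlas])
    series, kept_labels, dropped = [], [], []
    voxel_counts, surviving = {}, {}
    for rid in region_ids:
        name = f"region_{rid:03d}"
        region = lab == rid
        total = int(region.sum())
        surv = region & mask
        n_surv = int(surv.sum())
        voxel_counts[name] = total
        surviving[name] = n_surv
        if n_surv < min_coverage * total or n_surv == 0:
            dropped.append(name)
            continue
        series.append(data[surv].mean(axis=0))
        kept_labels.append(name)
    if dropped:
        logger.warning("regions dropped for insufficient coverage: %s", dropped)
        warnings.warn(
            f"regions dropped for insufficient coverage: {dropped}", stacklevel=2
        )
    if not kept_labels:
        raise ValueError("no region retained sufficient coverage")
    ts = RegionTimeSeries(
        values=np.vstack(series),
        tr=tr,
        region_labels=kept_labels,
        subject_id=subject_id,
    )
    return ExtractionResult(
        timeseries=ts,
        dropped_regions=dropped,
        voxel_counts=voxel_counts,
        surviving_voxel_counts=surviving,
    )
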