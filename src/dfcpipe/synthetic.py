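"""Synthetic multi-region BOLD-like cohorts with known connectivity dynamics.

Emulates the study conditions the pipeline targets: ~224 regions scanned
for 202 volumes at TR 2.2 s, a patient group with stronger time-varying
inter-region correlation than controls, realistic motion traces with
occasional spikes, and clinical records in which fatigue is linked to a
known subnetwork-dynamics ground truth.

The generative model is multivariate Gaussian with an instantaneous
correlation target that is either constant (stationary) or follows a
sinusoid / piecewise-constant state sequence around a base profile. No
haemodynamic convolution is applied by default; an optional low-pass flag
smooths the draws to give BOLD-like autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (
    SubnetworkSpec,
    WindowSpec,
    dfc_coefficient_of_variation,
    subnetwork_value,
    windowed_fc,
)
from .core import MotionTrace, RegionTimeSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortSubject",
    "NAMED_SUBNETWORK_REGIONS",
    "default_subnetwork",
    "make_region_labels",
    "make_correlation_profile",
    "simulate_stationary_series",
    "simulate_modulated_series",
    "simulate_motion_trace",
    "simulate_cohort",
    "clinical_table",
    "make_image_fixture",
]

# Bilateral basal ganglia and default-mode-network regions carried by every
# simulated atlas; the remaining regions get generic cortical labels.
BASAL_GANGLIA_LABELS = (
    "caudate_l", "caudate_r", "putamen_l", "putamen_r", "pallidum_l", "pallidum_r",
)
DMN_LABELS = (
    "mpfc_l", "mpfc_r", "pcc_l", "pcc_r", "precuneus_l", "precuneus_r",
)
NAMED_SUBNETWORK_REGIONS = BASAL_GANGLIA_LABELS + DMN_LABELS


def default_subnetwork(mode: str = "between-sets-plus-within") -> SubnetworkSpec:
    """Basal ganglia vs. default-mode-network subnetwork of the simulated atlas."""
    return SubnetworkSpec(set_a=BASAL_GANGLIA_LABELS, set_b=DMN_LABELS, mode=mode)


def make_region_labels(n_regions: int) -> list[str]:
    """Generic cortical labels plus the named subnetwork regions (last 12)."""
    if n_regions < len(NAMED_SUBNETWORK_REGIONS):
        return [f"region_{i:03d}" for i in range(1, n_regions + 1)]
    n_generic = n_regions - len(NAMED_SUBNETWORK_REGIONS)
    labels = [f"cortical_{i:03d}" for i in range(1, n_generic + 1)]
    return labels + list(NAMED_SUBNETWORK_REGIONS)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Defaults emulate the target protocol: 224 regions, 202 acquired volumes
    (197 usable after discarding 5) at TR 2.2 s, 35 patients and 19
    controls. Patients carry stronger global correlation modulation than
    controls; each patient additionally receives a random subnetwork
    modulation whose realized dynamic-connectivity value drives fatigue.
    Fatigue effect sizes are chosen so the dFC and EDSS contributions are
    each clearly detectable at the emulated sample size.
    """

    n_regions: int = 224
    n_volumes: int = 202
    tr_seconds: float = 2.2
    n_patients: int = 35
    n_controls: int = 19
    n_discard: int = 5
    base_correlation: float = 0.3
    modulation_amplitude: float = 0.15
    subnetwork_amplitude_max: float = 0.3
    modulation_period_seconds: float = 120.0
    fatigue_intercept: float = 46.0
    fatigue_effect_slope: float = 240.0
    fatigue_driver_reference: float = 1.0
    edss_effect_slope: float = 9.0
    control_fatigue_mean: float = 45.0
    noise_sd: float = 14.0
    motion_baseline_fd_mm: float = 0.1
    motion_spike_prob: float = 0.02
    motion_spike_fd_mm: float = 0.8
    female_fraction: float = 0.57
    bold_lowpass: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.base_correlation < 1:
            raise ValueError("base_correlation must be in [0, 1)")
        if self.modulation_amplitude < 0 or self.subnetwork_amplitude_max < 0:
            raise ValueError("modulation amplitudes must be non-negative")
        hi = self.base_correlation + self.modulation_amplitude + self.subnetwork_amplitude_max
        lo = self.base_correlation - self.modulation_amplitude - self.subnetwork_amplitude_max
        if not (-1 < lo and hi < 1):
            raise ValueError("implied correlation targets leave (-1, 1)")


@dataclass
class GroundTruth:
    """What the generator actually injected for one subject."""

    target_correlation_trajectory: np.ndarray  # per-volume mean target of modulated pairs
    group_label: str  # "low-dynamics" (control) or "high-dynamics" (patient)
    true_fatigue_driver: float = float("nan")  # realized subnetwork dFC-cv (normalized)
    modulation_amplitude: float = 0.0
    subnetwork_amplitude: float = 0.0


@dataclass
class CohortSubject:
    timeseries: RegionTimeSeries
    motion: MotionTrace
    clinical: dict
    ground_truth: GroundTruth


def _nearest_psd(mat: np.ndarray, min_eig: float = 1e-10) -> np.ndarray:
    """Eigenvalue clipping followed by unit-diagonal rescaling."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= 0:
        return sym
    vals = np.clip(vals, min_eig, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def make_correlation_profile(
    n_regions: int,
    base_correlation: float,
    seed: int | np.random.Generator,
    jitter_sd: float | None = None,
) -> np.ndarray:
    """Random PSD correlation matrix with off-diagonals near ``base_correlation``.

    Off-diagonal entries are jittered around the base value and the matrix
    is projected to the nearest positive semi-definite correlation matrix
    by eigenvalue clipping when needed. The default jitter scales as
    ``0.1 / sqrt(n_regions)`` so the jitter's spectral radius stays well
    below ``1 - base_correlation`` and the profile keeps a comfortable
    smallest eigenvalue even when modulation is added downstream.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0 <= base_correlation < 1:
        raise ValueError("base_correlation must be in [0, 1)")
    if jitter_sd is None:
        jitter_sd = 0.1 / np.sqrt(n_regions)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    jit = rng.normal(0.0, jitter_sd, size=(n_regions, n_regions))
    jit = (jit + jit.T) / 2.0
    mat = np.full((n_regions, n_regions), base_correlation) + jit
    np.clip(mat, -0.99, 0.99, out=mat)
    np.fill_diagonal(mat, 1.0)
    mat = _nearest_psd(mat)
    if np.linalg.eigvalsh(mat).min() < -1e-8:
        raise ValueError("correlation profile not PSD after projection")
    return mat


def _cholesky_psd(mat: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(
            _nearest_psd(mat) + 1e-10 * np.eye(mat.shape[0])
        )


def _bold_smooth(x: np.ndarray) -> np.ndarray:
    """Optional mild temporal smoothing giving BOLD-like autocorrelation."""
    kernel = np.array([0.25, 0.5, 0.25])
    pad = np.pad(x, ((0, 0), (1, 1)), mode="edge")
    return (
        kernel[0] * pad[:, :-2] + kernel[1] * pad[:, 1:-1] + kernel[2] * pad[:, 2:]
    )


def _sample_with_offsets(
    profile: np.ndarray,
    offsets: np.ndarray,
    pair_mask: np.ndarray,
    rng: np.random.Generator,
    lowpass: bool = False,
) -> np.ndarray:
    """Draw columns x_t = L_t z_t with per-volume target profile + o_t * mask."""
    n = profile.shape[0]
    t_total = offsets.shape[0]
    z = rng.standard_normal((n, t_total))
    x = np.empty_like(z)
    uniq, inv = np.unique(np.round(offsets, 12), return_inverse=True)
    for k, off in enumerate(uniq):
        cols = inv == k
        target = profile + off * pair_mask
        chol = _cholesky_psd(target)
        x[:, cols] = chol @ z[:, cols]
    if lowpass:
        x = _bold_smooth(x)
    return x


def _offdiag_mask(n: int) -> np.ndarray:
    mask = np.ones((n, n)) - np.eye(n)
    return mask


def simulate_stationary_series(
    profile: np.ndarray,
    n_volumes: int,
    tr: float,
    seed: int | np.random.Generator,
    region_labels: list[str] | None = None,
    subject_id: str = "",
    lowpass: bool = False,
) -> RegionTimeSeries:
    """Zero-mean Gaussian draws with fixed instantaneous correlation."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = profile.shape[0]
    x = _sample_with_offsets(profile, np.zeros(n_volumes), _offdiag_mask(n), rng, lowpass)
    labels = region_labels or make_region_labels(n)
    return RegionTimeSeries(values=x, tr=tr, region_labels=labels, subject_id=subject_id)


def simulate_modulated_series(
    profile: np.ndarray,
    modulation_amplitude: float,
    modulation_period: float,
    n_volumes: int,
    tr: float,
    seed: int | np.random.Generator,
    pair_mask: np.ndarray | None = None,
    phase: float = 0.0,
    state_sequence: np.ndarray | None = None,
    region_labels: list[str] | None = None,
    subject_id: str = "",
    lowpass: bool = False,
    offset_resolution: float | None = None,
) -> tuple[RegionTimeSeries, GroundTruth]:
    """Gaussian draws whose instantaneous correlation varies over time.

    The per-volume target is ``profile + o_t * pair_mask`` with
    ``o_t = amplitude * sin(2 pi t TR / period + phase)``, or, if
    ``state_sequence`` is given, ``o_t`` taken directly from it (a
    piecewise-constant offset sequence). Targets must stay inside (-1, 1).
    ``offset_resolution`` optionally discretizes the offsets to that step
    size so Cholesky factors of repeated targets are reused.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = profile.shape[0]
    mask = _offdiag_mask(n) if pair_mask is None else np.asarray(pair_mask, dtype=float)
    if state_sequence is not None:
        offsets = np.asarray(state_sequence, dtype=float)
        if offsets.shape[0] != n_volumes:
            raise ValueError("state sequence length must equal n_volumes")
    else:
        t = np.arange(n_volumes)
        offsets = modulation_amplitude * np.sin(
            2 * np.pi * t * tr / modulation_period + phase
        )
    if offset_resolution:
        offsets = np.round(offsets / offset_resolution) * offset_resolution
    off = profile[mask > 0]
    if off.size:
        lo = off.min() + offsets.min() * mask.max()
        hi = off.max() + offsets.max() * mask.max()
        if not (-1 < lo and hi < 1):
            raise ValueError("modulation pushes a correlation target outside (-1, 1)")
    x = _sample_with_offsets(profile, offsets, mask, rng, lowpass)
    labels = region_labels or make_region_labels(n)
    ts = RegionTimeSeries(values=x, tr=tr, region_labels=labels, subject_id=subject_id)
    base_mean = float(off.mean()) if off.size else 0.0
    gt = GroundTruth(
        target_correlation_trajectory=base_mean + offsets,
        group_label="high-dynamics" if np.any(offsets != 0) else "low-dynamics",
        modulation_amplitude=float(modulation_amplitude),
    )
    return ts, gt


def simulate_motion_trace(
    n_volumes: int,
    baseline_fd_mm: float = 0.1,
    spike_prob: float = 0.02,
    spike_fd_mm: float = 0.8,
    seed: int | np.random.Generator = 0,
    head_radius_mm: float = 50.0,
    subject_id: str = "",
) -> MotionTrace:
    """Six-parameter motion with controlled framewise-displacement behaviour.

    Each frame-to-frame total displacement is drawn around
    ``baseline_fd_mm`` and, with probability ``spike_prob``, augmented by
    ``spike_fd_mm``. The displacement is split across the six rigid-body
    channels so the implied FD (sum of absolute deltas, rotations scaled by
    ``head_radius_mm``) reproduces the drawn values exactly.
    """
    if not 0 <= spike_prob <= 1:
        raise ValueError("spike_prob must be a probability")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_volumes < 1:
        raise ValueError("need at least one volume")
    n_trans = n_volumes - 1
    params = np.zeros((n_volumes, 6))
    if n_trans == 0:
        return MotionTrace(params=params, subject_id=subject_id)
    fd = baseline_fd_mm * np.abs(rng.normal(1.0, 0.3, size=n_trans))
    spikes = rng.random(n_trans) < spike_prob
    fd[spikes] += spike_fd_mm
    shares = rng.dirichlet(np.ones(6), size=n_trans)
    signs = rng.choice([-1.0, 1.0], size=(n_trans, 6))
    deltas = shares * fd[:, None] * signs
    deltas[:, 3:] /= head_radius_mm  # rotations stored in radians
    params[1:] = np.cumsum(deltas, axis=0)
    return MotionTrace(params=params, subject_id=subject_id)


def _subnetwork_pair_mask(labels: list[str], spec: SubnetworkSpec) -> np.ndarray:
    mask = np.zeros((len(labels), len(labels)))
    for i, j in spec.pair_indices(labels):
        mask[i, j] = mask[j, i] = 1.0
    return mask


def _cis20r_items(total: int, rng: np.random.Generator) -> list[int]:
    """20 item responses in [1, 7] summing exactly to ``total``."""
    total = int(np.clip(total, 20, 140))
    base, rem = divmod(total, 20)
    items = np.full(20, base, dtype=int)
    items[rng.permutation(20)[:rem]] += 1
    for _ in range(40):  # random transfers keep the sum, add item-level spread
        i, j = rng.integers(0, 20, size=2)
        if items[i] > 1 and items[j] < 7:
            items[i] -= 1
            items[j] += 1
    return items.tolist()


def _realized_driver(
    ts_usable: RegionTimeSeries, window: WindowSpec, subnet: SubnetworkSpec
) -> float:
    wc = windowed_fc(ts_usable, window)
    cv = dfc_coefficient_of_variation(wc)
    return subnetwork_value(cv, subnet, normalize_by_global=True)


def simulate_cohort(
    config: SimulationConfig, window: WindowSpec | None = None
) -> list[CohortSubject]:
    """Simulate a two-group cohort with a known fatigue-dynamics link.

    Patients ("high-dynamics") receive the full global modulation amplitude
    plus a per-subject uniform subnetwork amplitude; controls get half the
    global amplitude and no subnetwork boost. Patient fatigue totals are
    generated as ``intercept + edss_slope * EDSS - fatigue_slope * (driver -
    reference) + noise`` where the driver is the realized (normalized)
    subnetwork dFC coefficient of variation computed from the usable
    volumes (normalized values sit near the reference of 1); controls
    get fatigue around ``control_fatigue_mean``. Totals are clipped to the
    CIS-20r range [20, 140] and expanded into consistent item responses.

    One master seed expands into independent per-subject substreams, so
    cohorts are bit-reproducible and subjects statistically independent.
    """
    window = window or WindowSpec()
    usable = config.n_volumes - config.n_discard
    if usable < window.length_volumes:
        raise ValueError("too few usable volumes for the window length")
    labels = make_region_labels(config.n_regions)
    if config.n_regions < len(NAMED_SUBNETWORK_REGIONS):
        raise ValueError("cohort simulation needs the 12 named subnetwork regions")
    subnet = default_subnetwork()
    sub_mask = _subnetwork_pair_mask(labels, subnet)
    master = np.random.SeedSequence(config.seed)
    profile_rng = np.random.default_rng(master.spawn(1)[0])
    profile = make_correlation_profile(
        config.n_regions, config.base_correlation, profile_rng
    )
    n_total = config.n_patients + config.n_controls
    streams = master.spawn(n_total + 1)[1:]
    cohort: list[CohortSubject] = []
    for idx in range(n_total):
        rng = np.random.default_rng(streams[idx])
        is_patient = idx < config.n_patients
        sid = f"{'ms' if is_patient else 'hc'}_{idx:03d}"
        glob_amp = config.modulation_amplitude * (1.0 if is_patient else 0.5)
        sub_amp = (
            rng.uniform(0.0, config.subnetwork_amplitude_max) if is_patient else 0.0
        )
        # per-pair amplitudes live in the mask; the sinusoid has unit amplitude
        mask = glob_amp * _offdiag_mask(config.n_regions) + sub_amp * sub_mask
        ts, gt = simulate_modulated_series(
            profile,
            modulation_amplitude=1.0,
            modulation_period=config.modulation_period_seconds,
            n_volumes=config.n_volumes,
            tr=config.tr_seconds,
            seed=rng,
            pair_mask=mask,
            phase=rng.uniform(0, 2 * np.pi),
            offset_resolution=0.05,
            region_labels=labels,
            subject_id=sid,
            lowpass=config.bold_lowpass,
        )
        gt.group_label = "high-dynamics" if is_patient else "low-dynamics"
        gt.modulation_amplitude = glob_amp
        gt.subnetwork_amplitude = sub_amp
        usable_ts = ts.copy_with(values=ts.values[:, config.n_discard :])
        driver = _realized_driver(usable_ts, window, subnet)
        gt.true_fatigue_driver = driver
        motion = simulate_motion_trace(
            config.n_volumes,
            baseline_fd_mm=config.motion_baseline_fd_mm,
            spike_prob=config.motion_spike_prob,
            spike_fd_mm=config.motion_spike_fd_mm,
            seed=rng,
            subject_id=sid,
        )
        age = float(np.clip(rng.normal(42.0, 10.0), 18.0, 65.0))
        sex = "female" if rng.random() < config.female_fraction else "male"
        education = int(rng.integers(3, 8))
        clinical: dict = {
            "subject_id": sid,
            "group": "patient" if is_patient else "control",
            "age": age,
            "sex": sex,
            "education": education,
            "timepoint": "T0",
        }
        # head-size-normalized volumetrics (ml): noise covariates for the
        # regression's second block, with a mild patient atrophy shift
        clinical["norm_wm_volume"] = float(rng.normal(680.0 if is_patient else 697.0, 42.0))
        clinical["norm_gm_volume"] = float(rng.normal(745.0 if is_patient else 810.0, 70.0))
        if is_patient:
            edss = float(rng.choice(np.arange(1.0, 6.5, 0.5)))
            disease_duration = float(np.clip(rng.normal(11.0, 7.0), 0.5, 40.0))
            medication = "second-line" if rng.random() < 0.5 else "first-line"
            clinical["log_lesion_volume"] = float(np.log(rng.lognormal(3.0, 0.7)))
            total = (
                config.fatigue_intercept
                + config.edss_effect_slope * edss
                - config.fatigue_effect_slope
                * (driver - config.fatigue_driver_reference)
                + rng.normal(0.0, config.noise_sd)
            )
            clinical.update(
                edss=edss,
                disease_duration=disease_duration,
                medication=medication,
            )
        else:
            total = config.control_fatigue_mean + rng.normal(0.0, config.noise_sd)
            clinical.update(
                edss=np.nan, disease_duration=np.nan, medication="",
                log_lesion_volume=np.nan,
            )
        total = float(np.clip(total, 20.0, 140.0))
        items = _cis20r_items(int(round(total)), rng)
        clinical["cis20r_items"] = items
        clinical["cis20r_total"] = int(sum(items))
        clinical["hads_anxiety"] = int(rng.integers(0, 14))
        clinical["hads_depression"] = int(rng.integers(0, 12))
        cohort.append(
            CohortSubject(timeseries=ts, motion=motion, clinical=clinical, ground_truth=gt)
        )
    return cohort


def clinical_table(cohort: list[CohortSubject]) -> pd.DataFrame:
    """One clinical row per subject, with item responses in wide columns."""
    rows = []
    for subj in cohort:
        row = dict(subj.clinical)
        items = row.pop("cis20r_items")
        for i, v in enumerate(items, start=1):
            row[f"cis20r_item_{i:02d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def make_image_fixture(
    grid_shape: tuple[int, int, int],
    n_regions: int,
    n_volumes: int,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.0,
    nearzero_fraction: float = 0.0,
    nearzero_region: int | None = None,
    tr: float = 2.2,
):
    """4D image + integer label volume with known injected region series.

    Regions are painted as disjoint slabs along the first axis inside the
    grid, leaving a one-voxel near-zero background shell that anchors the
    low end of the robust intensity range (as air/dropout does in real
    images); each in-region voxel carries its region's time series
    (baseline 1000, signal sd 10) plus optional voxel noise.
    ``nearzero_fraction`` of the voxels of ``nearzero_region`` (or of
    every region if None) are set near zero to exercise the robust-range
    voxel exclusion. Returns ``(image, label_image, injected_series)`` as
    nibabel images and an (n_regions, n_volumes) array.
    """
    import nibabel as nib

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nx, ny, nz = grid_shape
    if nx < n_regions + 2:
        raise ValueError("grid too small for the requested number of regions")
    labels = np.zeros(grid_shape, dtype=np.int16)
    bounds = np.linspace(1, nx - 1, n_regions + 1).astype(int)
    profile = make_correlation_profile(max(n_regions, 2), 0.2, rng)[:n_regions, :n_regions]
    np.fill_diagonal(profile, 1.0)
    series = 1000.0 + 10.0 * _sample_with_offsets(
        profile, np.zeros(n_volumes), _offdiag_mask(n_regions), rng
    )
    data = np.zeros((*grid_shape, n_volumes))
    for rid in range(n_regions):
        sl = slice(bounds[rid], bounds[rid + 1])
        labels[sl] = rid + 1
        data[sl] = series[rid]
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    if nearzero_fraction > 0:
        for rid in range(n_regions):
            if nearzero_region is not None and rid + 1 != nearzero_region:
                continue
            vox = np.argwhere(labels == rid + 1)
            n_kill = int(round(nearzero_fraction * len(vox)))
            kill = vox[rng.permutation(len(vox))[:n_kill]]
            data[kill[:, 0], kill[:, 1], kill[:, 2], :] = rng.uniform(
                0.0, 1.0, size=(n_kill, 1)
            )
    affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    lab_img = nib.Nifti1Image(labels, affine)
    return img, lab_img, series
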