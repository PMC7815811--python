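"""Static and dynamic functional connectivity.

Static functional connectivity (sFC) between two regions is the absolute
Pearson correlation of their full time series. Dynamic functional
connectivity (dFC) is estimated with a tapered sliding window: the series
is cut into overlapping windows (default 27 volumes, advanced in steps of
5), each window is weighted by a rectangular window convolved with a
Gaussian kernel (sd 9 volumes), and a weighted Pearson correlation matrix
is computed per window. Two per-connection variability statistics summarise
the window stack:

* summed difference (dFC-diff): the sum over consecutive window pairs of
  the absolute change in (signed) windowed correlation;
* coefficient of variation (dFC-cv): standard deviation divided by mean of
  the absolutized windowed correlations across windows.

Global values average the unique off-diagonal cells; subnetwork values
average a named subset of connections (e.g. basal ganglia with the default
mode network) and may be normalized by the subject's global value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import RegionTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "SubnetworkSpec",
    "ConnectivityMatrix",
    "WindowedConnectivity",
    "DfcResult",
    "static_fc",
    "tapered_window_weights",
    "window_start_indices",
    "weighted_correlation",
    "windowed_fc",
    "dfc_summed_difference",
    "dfc_coefficient_of_variation",
    "global_mean",
    "subnetwork_value",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window scheme: length, step and Gaussian taper width (volumes).

    Defaults are 27-volume windows advanced by 5 volumes with a 9-volume
    taper sd; at TR 2.2 s this gives 59.4 s windows shifted by 11 s.
    """

    length_volumes: int = 27
    step_volumes: int = 5
    taper_sd_volumes: float = 9.0

    def __post_init__(self) -> None:
        if self.length_volumes < 2:
            raise ValueError("window length must be at least 2 volumes")
        if not 1 <= self.step_volumes <= self.length_volumes:
            raise ValueError("step must be in [1, window length]")
        if self.taper_sd_volumes <= 0:
            raise ValueError("taper sd must be positive")

    def length_seconds(self, tr: float) -> float:
        return self.length_volumes * tr

    def step_seconds(self, tr: float) -> float:
        return self.step_volumes * tr


@dataclass(frozen=True)
class SubnetworkSpec:
    """Two disjoint region-label sets defining a subnetwork of connections.

    ``mode`` selects which pairs enter the subnetwork average:
    ``between-sets-plus-within`` takes every pair among the union of the two
    sets (between-set and within-set connections alike); ``between-sets-only``
    restricts to pairs with one region in each set.
    """

    set_a: tuple[str, ...]
    set_b: tuple[str, ...]
    mode: str = "between-sets-plus-within"

    def __post_init__(self) -> None:
        object.__setattr__(self, "set_a", tuple(str(x) for x in self.set_a))
        object.__setattr__(self, "set_b", tuple(str(x) for x in self.set_b))
        if not self.set_a or not self.set_b:
            raise ValueError("both region sets must be non-empty")
        if set(self.set_a) & set(self.set_b):
            raise ValueError("region sets must be disjoint")
        if self.mode not in ("between-sets-plus-within", "between-sets-only"):
            raise ValueError(f"unknown subnetwork mode: {self.mode!r}")

    def pair_indices(self, labels: list[str]) -> list[tuple[int, int]]:
        """Resolve the connection list as index pairs into ``labels``."""
        pos = {lab: i for i, lab in enumerate(labels)}
        missing = [x for x in self.set_a + self.set_b if x not in pos]
        if missing:
            raise KeyError(f"subnetwork labels not found: {missing}")
        ia = [pos[x] for x in self.set_a]
        ib = [pos[x] for x in self.set_b]
        pairs = set()
        if self.mode == "between-sets-plus-within":
            sel = sorted(ia + ib)
            for k, i in enumerate(sel):
                for j in sel[k + 1 :]:
                    pairs.add((i, j))
        else:
            for i in ia:
                for j in ib:
                    pairs.add((min(i, j), max(i, j)))
        return sorted(pairs)


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region connectivity values; diagonal is NaN."""

    values: np.ndarray
    measure: str
    region_labels: list[str]


@dataclass
class WindowedConnectivity:
    """Stack of per-window weighted correlation matrices (signed)."""

    stack: np.ndarray  # windows x regions x regions
    window_starts: np.ndarray
    spec: WindowSpec
    region_labels: list[str]
    tr: float

    @property
    def n_windows(self) -> int:
        return self.stack.shape[0]


@dataclass
class DfcResult:
    """Per-connection variability matrix for one dFC measure."""

    matrix: np.ndarray
    measure: str  # "summed-difference" or "coefficient-of-variation"
    region_labels: list[str]
    n_undefined: int = 0
    subnetwork_values: dict = field(default_factory=dict)

    @property
    def global_value(self) -> float:
        return global_mean(self)


def static_fc(ts: RegionTimeSeries) -> ConnectivityMatrix:
    """Absolute Pearson correlation over the entire series per region pair.

    Regions with zero variance yield NaN entries and a logged warning;
    the diagonal is set to NaN and excluded from all summaries.
    """
    if ts.n_volumes < 3:
        raise ValueError("static FC requires at least 3 volumes")
    x = ts.values
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        bad = [ts.region_labels[i] for i in np.flatnonzero(degenerate)]
        logger.warning("zero-variance regions in static FC: %s", bad)
        warnings.warn(f"zero-variance regions set to NaN: {bad}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    vals = np.abs(r)
    vals[degenerate, :] = np.nan
    vals[:, degenerate] = np.nan
    np.fill_diagonal(vals, np.nan)
    return ConnectivityMatrix(
        values=vals, measure="sFC", region_labels=list(ts.region_labels)
    )


def tapered_window_weights(spec: WindowSpec) -> np.ndarray:
    """Taper weights: rectangular window convolved with a Gaussian kernel.

    The kernel is a discretized Gaussian with sd ``taper_sd_volumes``
    truncated at +/-3 sd; the full convolution of a length-L window of ones
    with that kernel is evaluated at the L central (in-window) positions and
    renormalized to sum to one. Weights are symmetric, strictly positive and
    maximal at the window centre.
    """
    L = spec.length_volumes
    sd = spec.taper_sd_volumes
    radius = int(np.ceil(3 * sd))
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sd) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(L), kernel, mode="full")
    w = full[radius : radius + L]
    return w / w.sum()


def window_start_indices(n_volumes: int, spec: WindowSpec) -> np.ndarray:
    """0-based half-open window starts: 0, step, ... while a full window fits."""
    if n_volumes < spec.length_volumes:
        raise ValueError(
            f"series of {n_volumes} volumes is shorter than the "
            f"{spec.length_volumes}-volume window"
        )
    return np.arange(0, n_volumes - spec.length_volumes + 1, spec.step_volumes)


def weighted_correlation(segment: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of a regions x length segment.

    With weights w summing to one: m_x = sum(w x), c_xy = sum(w (x-m_x)(y-m_y)),
    r_xy = c_xy / sqrt(c_xx c_yy). Zero weighted variance gives NaN entries.
    """
    segment = np.asarray(segment, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if segment.ndim != 2 or segment.shape[1] != weights.shape[0]:
        raise ValueError("segment columns must match weight length")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    w = weights / weights.sum()
    m = segment @ w
    c = segment - m[:, None]
    cov = (c * w) @ c.T
    var = np.diag(cov).copy()
    degenerate = var <= 0
    if degenerate.any():
        warnings.warn("zero weighted variance: correlation undefined", stacklevel=2)
        var[degenerate] = np.nan
    sd = np.sqrt(var)
    r = cov / np.outer(sd, sd)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, np.where(degenerate, np.nan, 1.0))
    return r


def _windowed_corr_stack(
    values: np.ndarray, starts: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted window correlations for a (..., regions, volumes) array.

    Returns (..., n_windows, regions, regions); leading axes are treated as
    independent batches (e.g. surrogate replicates).
    """
    L = weights.shape[0]
    views = sliding_window_view(values, L, axis=-1)  # (..., R, T-L+1, L)
    seg = np.swapaxes(views[..., starts, :], -3, -2)  # (..., W, R, L)
    m = seg @ weights
    c = seg - m[..., None]
    cov = (c * weights) @ c.swapaxes(-1, -2)
    var = np.diagonal(cov, axis1=-2, axis2=-1).copy()
    degenerate = var <= 0
    if degenerate.any():
        warnings.warn("zero weighted variance in some windows", stacklevel=3)
        var[degenerate] = np.nan
    sd = np.sqrt(var)
    stack = cov / (sd[..., :, None] * sd[..., None, :])
    np.clip(stack, -1.0, 1.0, out=stack)
    idx = np.arange(values.shape[-2])
    stack[..., idx, idx] = np.where(degenerate, np.nan, 1.0)
    return stack


def windowed_fc(ts: RegionTimeSeries, spec: WindowSpec | None = None) -> WindowedConnectivity:
    """Tapered sliding-window weighted correlations for every window."""
    spec = spec or WindowSpec()
    starts = window_start_indices(ts.n_volumes, spec)
    w = tapered_window_weights(spec)
    stack = _windowed_corr_stack(ts.values, starts, w)
    return WindowedConnectivity(
        stack=stack,
        window_starts=starts,
        spec=spec,
        region_labels=list(ts.region_labels),
        tr=ts.tr,
    )


def _require_windows(wc: WindowedConnectivity) -> None:
    if wc.n_windows < 2:
        raise ValueError("dFC requires at least 2 windows")


def dfc_summed_difference(
    wc: WindowedConnectivity, absolutize_windows: bool = False
) -> DfcResult:
    """Summed absolute window-to-window change per connection.

    Differences are taken on signed window correlations by default; only the
    differences themselves are absolutized before summing. Set
    ``absolutize_windows`` to difference absolutized matrices instead.
    """
    _require_windows(wc)
    stack = np.abs(wc.stack) if absolutize_windows else wc.stack
    mat = np.sum(np.abs(np.diff(stack, axis=0)), axis=0)
    np.fill_diagonal(mat, np.nan)
    n_undef = int(np.isnan(mat[np.triu_indices_from(mat, k=1)]).sum())
    if n_undef:
        logger.warning("summed-difference: %d undefined connections", n_undef)
    return DfcResult(
        matrix=mat,
        measure="summed-difference",
        region_labels=list(wc.region_labels),
        n_undefined=n_undef,
    )


def dfc_coefficient_of_variation(wc: WindowedConnectivity, ddof: int = 1) -> DfcResult:
    """Coefficient of variation of absolutized windowed correlations.

    Per connection: sd / mean across windows of |r_w|. The sd uses the sample
    convention (``ddof=1``) by default; connections with zero mean strength
    are marked NaN and excluded from summaries.
    """
    _require_windows(wc)
    a = np.abs(wc.stack)
    mu = a.mean(axis=0)
    sigma = a.std(axis=0, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(mu > 0, sigma / mu, np.nan)
    np.fill_diagonal(mat, np.nan)
    n_undef = int(np.isnan(mat[np.triu_indices_from(mat, k=1)]).sum())
    if n_undef:
        warnings.warn(
            f"coefficient of variation undefined for {n_undef} connections",
            stacklevel=2,
        )
    return DfcResult(
        matrix=mat,
        measure="coefficient-of-variation",
        region_labels=list(wc.region_labels),
        n_undefined=n_undef,
    )


def _matrix_of(result: DfcResult | ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(result, DfcResult):
        return result.matrix
    if isinstance(result, ConnectivityMatrix):
        return result.values
    return np.asarray(result, dtype=float)


def _labels_of(result) -> list[str]:
    return list(result.region_labels)


def global_mean(result: DfcResult | ConnectivityMatrix | np.ndarray) -> float:
    """Mean over unique off-diagonal cells, skipping undefined (NaN) cells."""
    mat = _matrix_of(result)
    vals = mat[np.triu_indices_from(mat, k=1)]
    n_undef = int(np.isnan(vals).sum())
    if n_undef == vals.size:
        raise ValueError("all off-diagonal cells are undefined")
    if n_undef:
        logger.info("global mean skipped %d undefined cells", n_undef)
    return float(np.nanmean(vals))


def subnetwork_value(
    result: DfcResult | ConnectivityMatrix,
    spec: SubnetworkSpec,
    normalize_by_global: bool = False,
) -> float:
    """Mean connectivity over a subnetwork's connections.

    With ``normalize_by_global``, the subnetwork mean is divided by the
    global mean of the same matrix, correcting for between-subject
    differences in overall connectivity strength.
    """
    mat = _matrix_of(result)
    pairs = spec.pair_indices(_labels_of(result))
    if not pairs:
        raise ValueError("subnetwork pair set is empty")
    vals = np.array([mat[i, j] for i, j in pairs])
    if np.isnan(vals).all():
        raise ValueError("all subnetwork cells are undefined")
    value = float(np.nanmean(vals))
    if normalize_by_global:
        value /= global_mean(result)
    return value
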