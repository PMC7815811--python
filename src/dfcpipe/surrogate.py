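"""Phase-randomization surrogate null model for dynamic connectivity.

Sliding-window variability can register purely sampling-driven
fluctuations as dynamics. The null model asks: how much dFC would a
stationary process with the same static connectivity and autocorrelation
produce? Surrogates are built by randomizing the phases of the discrete
Fourier transform while keeping amplitudes; crucially, one random phase
sequence is added identically to every region's spectrum, so full-series
cross-correlations (and hence sFC) are preserved exactly along with each
region's power spectrum. A paired t-test then compares each subject's real
dFC against the mean over their surrogate ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from numpy.lib.stride_tricks import sliding_window_view

from .connectivity import (
    SubnetworkSpec,
    WindowSpec,
    tapered_window_weights,
    window_start_indices,
)
from .core import RegionTimeSeries

__all__ = [
    "SurrogateEnsemble",
    "phase_randomized_surrogate",
    "surrogate_dfc",
    "surrogate_dfc_ensembles",
    "surrogate_dfc_full",
    "real_vs_surrogate_test",
]

MEASURES = ("summed-difference", "coefficient-of-variation")


@dataclass
class SurrogateEnsemble:
    """Real vs. surrogate dFC values for one subject and one measure."""

    subject_id: str
    measure: str
    real_value: float
    surrogate_values: np.ndarray
    seed: int | None = None

    @property
    def surrogate_mean(self) -> float:
        return float(np.mean(self.surrogate_values))


def _phase_rotations(
    n_volumes: int, n_bins: int, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Common-phase rotation factors, one row per surrogate.

    Bin 0 (DC) and, for even-length series, the Nyquist bin stay real so
    the inverse transform is real-valued; every other positive-frequency
    bin gets a uniform random phase.
    """
    last = n_bins - 1 if n_volumes % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(size, last - 1))
    rot = np.ones((size, n_bins), dtype=complex)
    rot[:, 1:last] = np.exp(1j * phases)
    return rot


def phase_randomized_surrogate(
    ts: RegionTimeSeries, seed: int | np.random.Generator
) -> RegionTimeSeries:
    """One common-phase surrogate of a multi-region series.

    A single uniform phase per positive frequency is added to every
    region's spectrum (DC and Nyquist bins untouched so the inverse
    transform is real), amplitudes are unchanged, and the inverse DFT gives
    the surrogate. Per-region spectra, means, autocovariances and the
    full-series correlation matrix are preserved by construction; only
    time-localized co-fluctuation structure is destroyed.
    """
    if ts.n_volumes < 4:
        raise ValueError("phase randomization requires at least 4 volumes")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spec = np.fft.rfft(ts.values, axis=1)
    rot = _phase_rotations(ts.n_volumes, spec.shape[1], rng, size=1)[0]
    surrogate = np.fft.irfft(spec * rot, n=ts.n_volumes, axis=1)
    return ts.copy_with(values=surrogate)


def _windowed_sums(values: np.ndarray, step: int, n_windows: int, w: np.ndarray) -> np.ndarray:
    """Weighted window sums of (..., T) series at regular window starts."""
    views = sliding_window_view(values, w.shape[0], axis=-1)
    return views[..., ::step, :][..., :n_windows, :] @ w


def _pair_window_correlations(
    values: np.ndarray,
    step: int,
    n_windows: int,
    w: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
) -> np.ndarray:
    """Weighted window correlations for region pairs (ii, jj).

    ``values`` is (..., R, T); the result is (..., P, W). Equivalent to the
    full-matrix window stack restricted to the listed pairs, but computed
    as sliding weighted sums of pair products, which vectorizes cleanly
    over surrogate batches.
    """
    # centring per series keeps the moment arithmetic well-conditioned;
    # weighted correlation itself is shift-invariant
    values = values - values.mean(axis=-1, keepdims=True)
    m = _windowed_sums(values, step, n_windows, w)
    var = _windowed_sums(values * values, step, n_windows, w) - m * m
    prod = values[..., ii, :] * values[..., jj, :]
    cov = _windowed_sums(prod, step, n_windows, w) - m[..., ii, :] * m[..., jj, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var[..., ii, :] * var[..., jj, :])
    return np.clip(r, -1.0, 1.0)


def _pair_measure_values(
    pair_corr: np.ndarray,
    measures: tuple[str, ...],
    scopes: dict[str, np.ndarray],
    ddof: int = 1,
) -> dict[str, np.ndarray]:
    """dFC values per batch element for each (scope, measure) key.

    ``pair_corr`` is (..., P, W); ``scopes`` maps scope name to indices
    into the pair axis.
    """
    per_pair: dict[str, np.ndarray] = {}
    for m in measures:
        if m == "summed-difference":
            per_pair[m] = np.abs(np.diff(pair_corr, axis=-1)).sum(axis=-1)
        elif m == "coefficient-of-variation":
            a = np.abs(pair_corr)
            mu = a.mean(axis=-1)
            sd = a.std(axis=-1, ddof=ddof)
            with np.errstate(invalid="ignore", divide="ignore"):
                per_pair[m] = np.where(mu > 0, sd / mu, np.nan)
        else:
            raise ValueError(f"unknown dFC measure: {m!r}")
    out = {}
    for scope, sel in scopes.items():
        for m in measures:
            out[f"{scope}:{m}"] = np.nanmean(per_pair[m][..., sel], axis=-1)
    return out


def _ensemble_values(
    ts: RegionTimeSeries,
    spec: WindowSpec,
    measures: tuple[str, ...],
    subnetwork: SubnetworkSpec | None,
    n_surrogates: int,
    rng: np.random.Generator,
    chunk: int = 16,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Real values and surrogate value arrays for every (scope, measure) key."""
    starts = window_start_indices(ts.n_volumes, spec)
    w = tapered_window_weights(spec)
    step, n_win = spec.step_volumes, len(starts)
    iu = np.triu_indices(ts.n_regions, k=1)
    ii, jj = iu
    scopes: dict[str, np.ndarray] = {"global": np.arange(ii.size)}
    if subnetwork is not None:
        pair_pos = {(a, b): k for k, (a, b) in enumerate(zip(ii, jj))}
        scopes["subnetwork"] = np.array(
            [pair_pos[p] for p in subnetwork.pair_indices(ts.region_labels)]
        )

    real_corr = _pair_window_correlations(ts.values, step, n_win, w, ii, jj)
    real = {
        k: float(v)
        for k, v in _pair_measure_values(real_corr, measures, scopes).items()
    }
    fourier = np.fft.rfft(ts.values, axis=1)
    surr: dict[str, list[np.ndarray]] = {k: [] for k in real}
    done = 0
    while done < n_surrogates:
        size = min(chunk, n_surrogates - done)
        rot = _phase_rotations(ts.n_volumes, fourier.shape[1], rng, size)
        batch = np.fft.irfft(
            fourier[None, :, :] * rot[:, None, :], n=ts.n_volumes, axis=-1
        )
        corr = _pair_window_correlations(batch, step, n_win, w, ii, jj)
        vals = _pair_measure_values(corr, measures, scopes)
        for k in surr:
            surr[k].append(vals[k])
        done += size
    return real, {k: np.concatenate(v) for k, v in surr.items()}


def surrogate_dfc_full(
    ts: RegionTimeSeries,
    spec: WindowSpec | None = None,
    subnetwork: SubnetworkSpec | None = None,
    measures: tuple[str, ...] = MEASURES,
    n_surrogates: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, SurrogateEnsemble]:
    """Global and (optionally) subnetwork ensembles sharing one surrogate set.

    Returns a dict keyed ``"global:<measure>"`` and, when a subnetwork is
    given, ``"subnetwork:<measure>"``; the same surrogates feed every key,
    so scopes are directly comparable. Subnetwork values are reported
    without global normalization, matching how the null comparison is
    defined. The real value and every surrogate value use the identical
    window scheme.
    """
    spec = spec or WindowSpec()
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    real, surr = _ensemble_values(ts, spec, measures, subnetwork, n_surrogates, rng)
    return {
        k: SurrogateEnsemble(
            subject_id=ts.subject_id,
            measure=k,
            real_value=real[k],
            surrogate_values=surr[k],
        )
        for k in real
    }


def surrogate_dfc_ensembles(
    ts: RegionTimeSeries,
    spec: WindowSpec | None = None,
    measures: tuple[str, ...] = MEASURES,
    subnetwork: SubnetworkSpec | None = None,
    n_surrogates: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, SurrogateEnsemble]:
    """Surrogate ensembles for several dFC measures, one scope.

    The scope is the subnetwork (un-normalized) when ``subnetwork`` is
    given, otherwise global; keys are the measure names.
    """
    scope = "global" if subnetwork is None else "subnetwork"
    full = surrogate_dfc_full(ts, spec, subnetwork, measures, n_surrogates, seed)
    out = {}
    for m in measures:
        e = full[f"{scope}:{m}"]
        e.measure = m
        out[m] = e
    return out


def surrogate_dfc(
    ts: RegionTimeSeries,
    spec: WindowSpec | None = None,
    measure: str = "coefficient-of-variation",
    subnetwork: SubnetworkSpec | None = None,
    n_surrogates: int = 100,
    seed: int | np.random.Generator = 0,
) -> SurrogateEnsemble:
    """Surrogate ensemble for a single dFC measure (global or subnetwork)."""
    return surrogate_dfc_ensembles(
        ts, spec, (measure,), subnetwork, n_surrogates, seed
    )[measure]


def real_vs_surrogate_test(
    ensembles: list[SurrogateEnsemble],
) -> tuple[float, float, float]:
    """Paired t-test of per-subject real dFC vs. mean surrogate dFC.

    Returns ``(t, p, mean_difference)`` where the difference is
    real minus surrogate mean, averaged over subjects.
    """
    if len(ensembles) < 2:
        raise ValueError("paired test requires at least 2 subjects")
    measures = {e.measure for e in ensembles}
    if len(measures) != 1:
        raise ValueError("ensembles mix dFC measures; test one measure at a time")
    real = np.array([e.real_value for e in ensembles])
    surr = np.array([e.surrogate_mean for e in ensembles])
    diff = real - surr
    if np.allclose(diff, 0.0):
        return 0.0, 1.0, 0.0
    t, p = sps.ttest_rel(real, surr)
    return float(t), float(p), float(diff.mean())
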