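"""Spike-train, membrane-potential and LFP statistics, plus the
subsampled Kolmogorov-Smirnov comparison harness.

All single-train statistics are restricted to trains with at least 10
spikes; with the standard 30 s observation window this matches a rate
criterion of > 0.33 Hz for "spiking" neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as sstats

MIN_SPIKES = 10


# ---------------------------------------------------------------------------
# single-train statistics


@dataclass
class SpikeTrainStats:
    n_spikes: int
    mean_isi: float | None
    cv: float | None
    isis: np.ndarray
    included: bool


def isi_statistics(spike_times, min_spikes: int = MIN_SPIKES) -> SpikeTrainStats:
    """Mean and coefficient of variation of the inter-spike intervals.

    Trains with fewer than ``min_spikes`` spikes are flagged as excluded
    (no statistics), not errored.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    isis = np.diff(t)
    if len(t) < min_spikes:
        return SpikeTrainStats(len(t), None, None, isis, included=False)
    m = isis.mean()
    cv = isis.std(ddof=0) / m if m > 0 else 0.0
    return SpikeTrainStats(len(t), float(m), float(cv), isis, included=True)


def isi_autocorrelation(isis, max_lag: int, local_window: int | None = None):
    """Normalized autocorrelation of an ISI sequence by lag (in intervals).

    ``local_window`` (odd number of intervals) subtracts a moving-average
    local mean before correlating, the stationarity correction appropriate
    for slowly drifting rates; None subtracts the global mean (sufficient
    for stationary simulated trains).  Lag 0 is normalized to one.
    """
    x = np.asarray(isis, dtype=float)
    if len(x) <= max_lag:
        raise ValueError("series shorter than max_lag")
    if local_window is not None:
        if local_window % 2 == 0:
            raise ValueError("local_window must be odd")
        ones = np.ones(local_window)
        loc = np.convolve(x, ones, mode="same") / \
            np.convolve(np.ones(len(x)), ones, mode="same")
        z = x - loc
    else:
        z = x - x.mean()
    denom = np.dot(z, z)
    if denom == 0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    return np.array([np.dot(z[:len(z) - l], z[l:]) / denom
                     for l in range(max_lag + 1)])


def pooled_autocorrelation_halfwidth(trains, max_lag: int = 20,
                                     min_spikes: int = MIN_SPIKES):
    """Half-width at half maximum of the pooled ISI autocorrelation, in ms.

    Lags (in intervals) are mapped to time through the pooled mean ISI;
    the pooled autocorrelation is the spike-count-weighted average across
    trains long enough for the requested lag.
    """
    acs, weights, mean_isis = [], [], []
    for t in trains:
        st = isi_statistics(t, min_spikes)
        if not st.included or len(st.isis) <= max_lag:
            continue
        acs.append(isi_autocorrelation(st.isis, max_lag))
        weights.append(st.n_spikes)
        mean_isis.append(st.mean_isi)
    if not acs:
        return None
    ac = np.average(acs, axis=0, weights=weights)
    mean_isi = float(np.average(mean_isis, weights=weights))
    below = np.flatnonzero(ac <= 0.5)
    if len(below) == 0:
        return max_lag * mean_isi
    k = below[0]
    if k == 0:
        return 0.0
    # linear interpolation between lags k-1 and k
    frac = (ac[k - 1] - 0.5) / (ac[k - 1] - ac[k])
    return (k - 1 + frac) * mean_isi


# ---------------------------------------------------------------------------
# pairwise correlation


def _isi_signal(train, grid):
    """ISI-interpolated process: value at t is the current interval length."""
    t = np.sort(np.asarray(train, dtype=float))
    idx = np.searchsorted(t, grid, side="right")
    valid = (idx > 0) & (idx < len(t))
    out = np.full(len(grid), np.nan)
    ok = np.flatnonzero(valid)
    out[ok] = t[idx[ok]] - t[idx[ok] - 1]
    return out


def zero_lag_cc(train_a, train_b, bin_ms: float = 200.0,
                t_range: tuple[float, float] | None = None,
                method: str = "isi") -> float:
    """Zero-lag Pearson correlation between two units' activity processes.

    ``method='isi'`` correlates the ISI-interpolated series (the interval
    containing each bin center), ``method='counts'`` the binned spike
    counts.  Only jointly valid bins enter the correlation.
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if t_range is None:
        if len(a) == 0 or len(b) == 0:
            return 0.0
        t_range = (min(a.min(), b.min()), max(a.max(), b.max()))
    lo, hi = t_range
    if hi <= lo:
        raise ValueError("empty overlap window")
    grid = np.arange(lo + bin_ms / 2, hi, bin_ms)
    if method == "isi":
        xa, xb = _isi_signal(a, grid), _isi_signal(b, grid)
        ok = ~(np.isnan(xa) | np.isnan(xb))
        xa, xb = xa[ok], xb[ok]
    elif method == "counts":
        edges = np.arange(lo, hi + bin_ms, bin_ms)
        xa = np.histogram(a, edges)[0].astype(float)
        xb = np.histogram(b, edges)[0].astype(float)
    else:
        raise ValueError("method must be 'isi' or 'counts'")
    if len(xa) < 3 or xa.std() == 0 or xb.std() == 0:
        return 0.0
    return float(np.corrcoef(xa, xb)[0, 1])


def population_cc0(trains, n_pairs: int = 500, bin_ms: float = 200.0,
                   t_range=None, min_spikes: int = MIN_SPIKES,
                   seed: int = 0, method: str = "isi") -> np.ndarray:
    """CC(0) samples over random pairs of sufficiently active trains."""
    rng = np.random.default_rng(seed)
    eligible = [np.asarray(t) for t in trains if len(t) >= min_spikes]
    n = len(eligible)
    if n < 2:
        return np.empty(0)
    out = []
    for _ in range(n_pairs):
        i, j = rng.choice(n, size=2, replace=False)
        out.append(zero_lag_cc(eligible[i], eligible[j], bin_ms,
                               t_range, method))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# KS comparison harness


@dataclass
class ComparisonReport:
    """Subsampled two-sample KS comparison over several statistics."""

    per_statistic: dict[str, tuple[float, float]]  # name -> (mean D, mean p)

    @property
    def max_d(self) -> float:
        return max(v[0] for v in self.per_statistic.values())

    @property
    def min_p(self) -> float:
        return min(v[1] for v in self.per_statistic.values())


def ks_compare(sample_a, sample_b, n_sub: int = 30, reps: int = 100,
               seed: int = 0) -> tuple[float, float]:
    """Average two-sample KS statistic and p over repeated subsamples.

    Each repetition draws ``n_sub`` points without replacement from both
    samples, which decouples the test from unequal sample sizes.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < n_sub or len(b) < n_sub:
        raise ValueError(f"both samples need at least n_sub={n_sub} points")
    rng = np.random.default_rng(seed)
    ds, ps = np.empty(reps), np.empty(reps)
    for r in range(reps):
        sa = rng.choice(a, size=n_sub, replace=False)
        sb = rng.choice(b, size=n_sub, replace=False)
        res = sstats.ks_2samp(sa, sb)
        ds[r], ps[r] = res.statistic, res.pvalue
    return float(ds.mean()), float(ps.mean())


def compare_samples(samples_a: dict, samples_b: dict, n_sub: int = 30,
                    reps: int = 100, seed: int = 0) -> ComparisonReport:
    """ks_compare per shared statistic name; summary = worst case."""
    common = sorted(set(samples_a) & set(samples_b))
    out = {}
    for k, name in enumerate(common):
        out[name] = ks_compare(samples_a[name], samples_b[name],
                               n_sub=n_sub, reps=reps, seed=seed + k)
    return ComparisonReport(per_statistic=out)


# ---------------------------------------------------------------------------
# LFP spectrum


@dataclass
class LFPSpectrum:
    freq: np.ndarray
    psd: np.ndarray
    slope_low: float   # log-log slope on [1, 60] Hz
    slope_high: float  # log-log slope on [60, 200] Hz


def lfp_psd(trace, fs: float = 1000.0, nperseg: int = 4096) -> LFPSpectrum:
    """Welch power spectrum of the summed-synaptic-current LFP proxy."""
    x = np.asarray(trace, dtype=float)
    nperseg = min(nperseg, len(x))
    freq, psd = sps.welch(x - x.mean(), fs=fs, nperseg=nperseg)

    def _slope(f_lo, f_hi):
        sel = (freq >= f_lo) & (freq <= f_hi) & (psd > 0)
        if sel.sum() < 3:
            return np.nan
        return float(np.polyfit(np.log10(freq[sel]), np.log10(psd[sel]), 1)[0])

    return LFPSpectrum(freq=freq, psd=psd,
                       slope_low=_slope(1.0, 60.0),
                       slope_high=_slope(60.0, 200.0))


# ---------------------------------------------------------------------------
# membrane potential


def vm_fluctuation_sd(v_trace, t_grid, spike_times,
                      spike_removal_window: tuple[float, float] = (-2.0, 10.0)
                      ) -> float:
    """SD of the membrane potential with spike events excised.

    Samples within ``spike_removal_window`` (ms, relative to each
    threshold crossing) are dropped and the remaining trace concatenated.
    """
    v = np.asarray(v_trace, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    keep = np.ones(len(v), dtype=bool)
    lo, hi = spike_removal_window
    for ts in np.asarray(spike_times, dtype=float):
        keep &= ~((t >= ts + lo) & (t <= ts + hi))
    if keep.sum() < 2:
        return 0.0
    return float(v[keep].std(ddof=0))


# ---------------------------------------------------------------------------
# population summaries


@dataclass
class SpikingReport:
    fraction: float
    spiking_ids: np.ndarray
    nonspiking_ids: np.ndarray
    rheobase_spiking: float | None = None
    rheobase_nonspiking: float | None = None


def spiking_fraction(rec, n_neurons: int, min_spikes: int = MIN_SPIKES,
                     graph=None) -> SpikingReport:
    """Fraction of cells with more than ``min_spikes`` spikes in the run.

    With ``graph`` given, also reports the mean rheobase of the spiking
    (rate above min_spikes/duration) versus non-spiking group.
    """
    counts = rec.spike_counts(n_neurons)
    spiking = np.flatnonzero(counts > min_spikes)
    silent = np.flatnonzero(counts <= min_spikes)
    report = SpikingReport(
        fraction=len(spiking) / n_neurons,
        spiking_ids=spiking,
        nonspiking_ids=silent,
    )
    if graph is not None:
        from .neuron import rheobase

        rheo = np.asarray([rheobase(nrn) for nrn in graph.neurons])
        report.rheobase_spiking = float(rheo[spiking].mean()) if len(spiking) else None
        report.rheobase_nonspiking = float(rheo[silent].mean()) if len(silent) else None
    return report


def subthreshold_distance(rec, graph, ids=None) -> np.ndarray:
    """Time-averaged membrane potential minus firing threshold V_up per cell.

    Computed from the recorded voltage traces; negative values mean the
    cell sits below threshold on average (fluctuation-driven firing).
    """
    if len(rec.v_ids) == 0:
        raise ValueError("recording carries no voltage traces")
    vup = graph.neuron_array("V_up")
    sel = np.arange(len(rec.v_ids)) if ids is None else \
        np.flatnonzero(np.isin(rec.v_ids, ids))
    return rec.V[sel].mean(axis=1) - vup[rec.v_ids[sel]]


def network_summary(rec, graph, min_spikes: int = MIN_SPIKES,
                    cc_pairs: int = 500, cc_bin_ms: float = 200.0,
                    seed: int = 0) -> dict:
    """Per-neuron statistic samples of one recording.

    Returns {"cv": ..., "mean_isi": ..., "cc0": ...} arrays (spiking
    neurons only) plus the spiking fraction, ready for the KS harness.
    """
    n = graph.n_neurons
    trains = rec.spike_trains(n)
    cvs, mean_isis = [], []
    for t in trains:
        st = isi_statistics(t, min_spikes)
        if st.included:
            cvs.append(st.cv)
            mean_isis.append(st.mean_isi)
    cc0 = population_cc0(trains, n_pairs=cc_pairs, bin_ms=cc_bin_ms,
                         t_range=(0.0, rec.duration), min_spikes=min_spikes,
                         seed=seed)
    report = spiking_fraction(rec, n, min_spikes, graph=graph)
    return {
        "cv": np.asarray(cvs),
        "mean_isi": np.asarray(mean_isis),
        "cc0": cc0,
        "spiking_fraction": report.fraction,
    }


# ---------------------------------------------------------------------------
# stimulus-response measures


def evoked_latency(spike_times, t0: float, window: float = 50.0,
                   bin_ms: float = 0.5, smooth_sigma_ms: float = 1.5):
    """Latency (ms) from stimulus onset to the evoked population-rate peak.

    The PSTH of the supplied (population-restricted) spike times is
    smoothed with a Gaussian kernel and the time of its maximum within
    ``window`` after ``t0`` is returned; None when no spikes follow the
    stimulus.
    """
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= t0) & (t <= t0 + window)]
    if len(t) == 0:
        return None
    edges = np.arange(t0, t0 + window + bin_ms, bin_ms)
    counts = np.histogram(t, edges)[0].astype(float)
    sig = smooth_sigma_ms / bin_ms
    half = int(np.ceil(4 * sig))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sig) ** 2)
    kern /= kern.sum()
    smooth = np.convolve(counts, kern, mode="same")
    return float((np.argmax(smooth) + 0.5) * bin_ms)


def evoked_spike_count(rec, t0: float, window: float = 200.0,
                       baseline: tuple[float, float] | None = None) -> float:
    """Number of network spikes attributable to a stimulus.

    Counts spikes in [t0, t0 + window]; when a ``baseline`` interval is
    given, the expected baseline count for the same window length is
    subtracted (clipped at zero).
    """
    t = rec.spike_t
    n_evoked = float(np.sum((t >= t0) & (t < t0 + window)))
    if baseline is not None:
        b0, b1 = baseline
        if b1 <= b0:
            raise ValueError("empty baseline interval")
        rate = np.sum((t >= b0) & (t < b1)) / (b1 - b0)
        n_evoked = max(n_evoked - rate * window, 0.0)
    return n_evoked


# ---------------------------------------------------------------------------
# surrogate reference distributions


def make_surrogate_invivo(seed: int = 0, n: int = 381) -> dict:
    """Synthetic stand-in for unavailable awake-rodent reference samples.

    Draws match the published summary statistics of the recordings the
    model is normally compared against: CV ~ N(1.04, 0.33) truncated
    positive, mean ISI log-normal with mean 570 ms / SD 610 ms, CC(0)
    ~ N(2.4e-4, 0.025).  For harness testing only; clearly a surrogate,
    not data.
    """
    rng = np.random.default_rng(seed)
    cv = rng.normal(1.04, 0.33, 2 * n)
    cv = cv[cv > 0][:n]
    while len(cv) < n:
        extra = rng.normal(1.04, 0.33, n)
        cv = np.concatenate([cv, extra[extra > 0]])[:n]
    mean, sd = 570.0, 610.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    mean_isi = rng.lognormal(mu, np.sqrt(sigma2), n)
    cc0 = rng.normal(2.4e-4, 0.025, n)
    return {"cv": cv, "mean_isi": mean_isi, "cc0": cc0}
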