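"""Extracellular recording metrics.

Implements the signal chain from raw multi-channel voltage traces to the
two recording outcomes of a chronic IME study:

1. percent of the kept channels detecting single units, and
2. number of detectable single units per (active) channel,

via zero-phase 300-3000 Hz band-pass filtering, common average
referencing, a robust MAD-based noise estimate, downward threshold
crossing at 3.5 robust SD below the mean, waveform clustering, and the
two unit-inclusion filters (>= 20 spikes, SNR strictly greater than 3,
with SNR = peak-to-peak of the unit mean waveform divided by the channel
noise, noise being twice the robust SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

DEFAULT_BAND_HZ = (300.0, 3000.0)
THRESHOLD_K = 3.5          # robust SDs below the mean
NOISE_FACTOR = 2.0         # noise = 2 * sigma_bg (SNR denominator)
WINDOW_MS = 1.6            # extracted waveform window
REFRACTORY_MS = 1.0        # minimum separation of detected events
MIN_SPIKES = 20
MIN_SNR = 3.0
SILHOUETTE_FLOOR = 0.25    # below this, one candidate unit per channel


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseEstimate:
    """Robust background-noise summary of one processed trace."""

    sigma_bg: float      # MAD / 0.6745
    noise: float         # 2 * sigma_bg
    threshold: float     # mean - 3.5 * sigma_bg
    mean: float


@dataclass
class SpikeEvents:
    """Detected threshold crossings with their extracted windows."""

    times: np.ndarray        # sample index of each event's local minimum
    windows: np.ndarray      # (n_events, window_samples) waveforms
    fs: float


@dataclass
class SpikeUnit:
    """One candidate single unit after clustering."""

    channel_id: int
    spike_times: np.ndarray
    mean_waveform: np.ndarray
    amplitude: float         # peak-to-peak of the mean waveform
    snr: float               # amplitude / channel noise


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(traces: np.ndarray, fs: float,
               band: tuple[float, float] = DEFAULT_BAND_HZ,
               car: bool = True) -> np.ndarray:
    """Zero-phase band-pass filter, then common average reference.

    ``traces`` is (n_channels, n_samples). The filter is a 4th-order
    Butterworth applied forward-backward; CAR subtracts the per-sample
    mean across channels. With a single channel CAR is skipped with a
    warning (the average would annihilate the signal).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz is below Nyquist for the "
            f"{band[0]}-{band[1]} Hz band")
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, traces, axis=-1)
    if car:
        if out.shape[0] < 2:
            warnings.warn("single channel: common average reference skipped")
        else:
            out = out - out.mean(axis=0, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Noise estimate and detection
# ---------------------------------------------------------------------------


def estimate_background_noise(trace: np.ndarray) -> NoiseEstimate:
    """MAD-based robust noise estimate: sigma_bg = median(|v - med|)/0.6745."""
    v = np.asarray(trace, dtype=float)
    if v.size == 0:
        raise ValueError("cannot estimate noise of an empty trace")
    sigma = float(np.median(np.abs(v - np.median(v))) / 0.6745)
    mean = float(v.mean())
    return NoiseEstimate(sigma_bg=sigma, noise=NOISE_FACTOR * sigma,
                         threshold=mean - THRESHOLD_K * sigma, mean=mean)


def detect_spikes(trace: np.ndarray, noise_est: NoiseEstimate, fs: float,
                  window_ms: float = WINDOW_MS,
                  refractory_ms: float = REFRACTORY_MS) -> SpikeEvents:
    """Detect downward threshold crossings and extract waveform windows.

    An event occurs where the trace steps from above to at-or-below the
    threshold; the window (``window_ms``, default 1.6 ms) is centered on
    the local minimum found within one refractory period after the
    crossing. Events closer than ``refractory_ms`` to the previous kept
    event are suppressed; events whose window would leave the trace are
    dropped.
    """
    v = np.asarray(trace, dtype=float)
    thr = noise_est.threshold
    cross = np.flatnonzero((v[1:] <= thr) & (v[:-1] > thr)) + 1
    refr = max(int(round(refractory_ms * 1e-3 * fs)), 1)
    half = max(int(round(window_ms * 1e-3 * fs / 2)), 1)
    wlen = 2 * half + 1
    times, windows = [], []
    last = -refr
    for c in cross:
        if c - last < refr:
            continue
        seg_end = min(c + refr, v.size)
        peak = c + int(np.argmin(v[c:seg_end]))
        if peak - half < 0 or peak + half + 1 > v.size:
            last = c
            continue
        times.append(peak)
        windows.append(v[peak - half: peak + half + 1])
        last = c
    return SpikeEvents(
        times=np.asarray(times, dtype=int),
        windows=(np.asarray(windows, dtype=float)
                 if windows else np.empty((0, wlen))),
        fs=fs)


# ---------------------------------------------------------------------------
# Candidate units and the inclusion filters
# ---------------------------------------------------------------------------


def cluster_and_filter(events: SpikeEvents, noise_est: NoiseEstimate,
                       channel_id: int = 0, min_spikes: int = MIN_SPIKES,
                       min_snr: float = MIN_SNR, max_k: int = 4,
                       random_state: int = 0) -> list[SpikeUnit]:
    """Group detected waveforms into candidate units and apply the filters.

    Candidate units come from k-means on the waveform windows with k
    chosen by silhouette score over k = 2..max_k (k = 1 when the best
    silhouette is below a floor or there are too few events). A candidate
    is kept iff it has at least ``min_spikes`` events and SNR strictly
    greater than ``min_snr``.
    """
    n = len(events.times)
    if n == 0:
        return []
    X = events.windows
    labels = np.zeros(n, dtype=int)
    if n >= 4:
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        best_score, best_labels = -1.0, None
        for k in range(2, min(max_k, n - 1) + 1):
            km = KMeans(n_clusters=k, n_init=4, random_state=random_state)
            lab = km.fit_predict(X)
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(X, lab)
            if score > best_score:
                best_score, best_labels = score, lab
        if best_labels is not None and best_score >= SILHOUETTE_FLOOR:
            labels = best_labels
    units = []
    for lab in np.unique(labels):
        sel = labels == lab
        mean_wf = X[sel].mean(axis=0)
        amp = float(mean_wf.max() - mean_wf.min())
        snr = amp / noise_est.noise if noise_est.noise > 0 else np.inf
        if int(sel.sum()) >= min_spikes and snr > min_snr:
            units.append(SpikeUnit(
                channel_id=channel_id, spike_times=events.times[sel],
                mean_waveform=mean_wf, amplitude=amp, snr=float(snr)))
    return units


def process_channel(trace: np.ndarray, fs: float, channel_id: int = 0,
                    random_state: int = 0) -> list[SpikeUnit]:
    """Noise estimate -> detection -> clustering -> filters for one trace.

    The trace is assumed already filtered/referenced (see
    :func:`preprocess`); mean and MAD are computed on this same trace.
    """
    est = estimate_background_noise(trace)
    events = detect_spikes(trace, est, fs)
    return cluster_and_filter(events, est, channel_id=channel_id,
                              random_state=random_state)


# ---------------------------------------------------------------------------
# Channel selection and weekly outcomes
# ---------------------------------------------------------------------------


def select_best_window(units_matrix: np.ndarray, n_keep: int = 10) -> int:
    """Start index (0-based) of the best ``n_keep``-consecutive-channel block.

    The score of a block is the sum over its channels of each channel's
    mean unit count across weeks (missing weeks ignored); ties break
    toward the lowest start index.
    """
    M = np.asarray(units_matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("units_matrix must be channels x weeks")
    n_channels = M.shape[0]
    if n_channels < n_keep:
        raise ValueError(f"need at least {n_keep} channels, got {n_channels}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ch_mean = np.nanmean(M, axis=1)
    ch_mean = np.nan_to_num(ch_mean, nan=0.0)
    scores = np.array([ch_mean[s:s + n_keep].sum()
                       for s in range(n_channels - n_keep + 1)])
    return int(np.argmax(scores))  # argmax takes the first (lowest) maximum


def weekly_outcomes(channel_week: pd.DataFrame, n_keep: int = 10) -> pd.DataFrame:
    """Recording outcomes per animal/week from kept channels' unit counts.

    Expects columns ``animal_id, channel_id, week, n_units`` and optional
    ``session`` / ``missing``. Outcomes are computed per session, then
    averaged to one weekly value: ``pct_active`` = 100 x (channels with
    at least one unit) / n_keep; ``units_per_channel`` = mean unit count
    over active channels only (missing, i.e. NaN, when no channel is
    active). Missing channels are excluded, never imputed.
    """
    df = channel_week.copy()
    if "session" not in df.columns:
        df["session"] = 1
    if "missing" in df.columns:
        df = df[~df.missing.astype(bool)]
    df = df.dropna(subset=["n_units"])
    rows = []
    for (a, w, _s), grp in df.groupby(["animal_id", "week", "session"]):
        if grp.empty:
            continue
        active = grp.n_units >= 1
        pct = 100.0 * active.sum() / n_keep
        upc = float(grp.n_units[active].mean()) if active.any() else np.nan
        rows.append((a, w, pct, upc))
    per_session = pd.DataFrame(
        rows, columns=["animal_id", "week", "pct_active", "units_per_channel"])
    out = (per_session.groupby(["animal_id", "week"], as_index=False)
           .agg(pct_active=("pct_active", "mean"),
                units_per_channel=("units_per_channel",
                                   lambda s: s.mean(skipna=True))))
    return out


def recording_metrics(channel_units: pd.DataFrame, n_channels: int = 16,
                      n_keep: int = 10) -> tuple[pd.DataFrame, pd.DataFrame,
                                                 dict[str, int]]:
    """Full metric stage on a channel-unit-count table.

    Input columns: ``animal_id, channel_id, week, session, n_units``
    (+ optional ``missing``). Per animal: average sessions to a
    channels-x-weeks unit matrix, pick the best consecutive block, keep
    those channels, and compute weekly outcomes.

    Returns ``(channel_metrics, outcomes, best_start)`` where
    ``channel_metrics`` has one row per animal/kept-channel/week with the
    weekly mean unit count.
    """
    df = channel_units.copy()
    if "missing" in df.columns:
        df.loc[df.missing.astype(bool), "n_units"] = np.nan
    kept_rows, best_start = [], {}
    for a, grp in df.groupby("animal_id"):
        weekly = (grp.groupby(["channel_id", "week"])["n_units"]
                  .mean().unstack("week"))
        weekly = weekly.reindex(index=np.arange(1, n_channels + 1))
        start = select_best_window(weekly.to_numpy(), n_keep=n_keep)
        best_start[a] = start
        kept = np.arange(start + 1, start + 1 + n_keep)
        sub = grp[grp.channel_id.isin(kept)]
        kept_rows.append(sub)
    kept_df = pd.concat(kept_rows, ignore_index=True)
    outcomes = weekly_outcomes(kept_df, n_keep=n_keep)
    channel_metrics = (kept_df.dropna(subset=["n_units"])
                       .groupby(["animal_id", "channel_id", "week"],
                                as_index=False)["n_units"].mean())
    return channel_metrics, outcomes, best_start
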