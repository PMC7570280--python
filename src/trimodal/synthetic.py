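"""Synthetic IME study generator.

Generates every input the analysis pipeline consumes — multi-channel
extracellular voltage traces, stained-section images, behavior trial
scores — together with the ground truth behind them (latent variable
values, true spike times, planted neuron points), so every downstream
stage is testable without animal data.

Cross-modal structure is planted through a Gaussian copula: one latent
standard-normal vector per animal-week, correlated across the sixteen
analysis variables by ``StudyConfig.latent_correlation``, then pushed
through monotone links into each modality's observable. The links and
noise scales are chosen so the Pearson correlation of the observables
tracks the planted latent correlation closely (attenuation by
observation noise kept small); they are module constants, not per-run
knobs.

Voltage traces and histology images are synthesized lazily
(deterministically, on demand) because a full default study is 768
traces of 30 s at 24.4 kHz and 144 section images — eager generation
would not fit in memory. The eager outputs are the ground-truth tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    BEHAVIOR_VARS,
    DISTANCE_BINS,
    HISTOLOGY_VAR_OF,
    MARKERS,
    StudyConfig,
    VARIABLES,
    variable_index,
)

# ---------------------------------------------------------------------------
# Link / noise constants (study conditions; see docs/methods.md)
# ---------------------------------------------------------------------------

REFRACTORY_S = 1e-3            # minimum separation of two events of one unit
TEMPLATE_WIDTH_S = 1.2e-3      # biphasic template support

TRACE_NOISE_UV = 10.0          # Gaussian background scale per channel
UNIT_P2P_RANGE_UV = (120.0, 200.0)   # per-unit peak-to-peak (SNR 6-10)
UNIT_RATE_RANGE_HZ = (4.0, 8.0)

# per-channel activity: P(channel records >=1 unit) = lo + span * Phi(z);
# the probit link keeps the probability responsive over the whole latent
# range, so binomial noise over 16 channels attenuates the planted
# correlation only mildly
ACTIVITY_PROBIT = dict(lo=0.10, span=0.85)
# units on an active channel: 1 + Poisson(lambda - 1), lambda = exp(a + b*z)
UNIT_RATE_LOG = (1.05, 0.4)

# behavior weekly "true" scores: base * exp(scale * z) (times/velocity/
# distance), base + scale*z (grip). Slips are Poisson totals over the 5
# ladder crossings of a session, rate per crossing exp(a + b*z).
BEHAVIOR_LINKS = {
    "ladder_time": dict(base=6.0, scale=0.25, trial_sigma=0.08),
    "grid_distance": dict(base=2000.0, scale=0.20, trial_sigma=0.05),
    "grid_max_velocity": dict(base=50.0, scale=0.20, trial_sigma=0.05),
    "grip_force": dict(base=900.0, scale=120.0, trial_sigma=40.0),
    "ladder_left_slips": dict(log_rate=(1.1, 0.45), baseline_rate=0.1,
                              crossings=5),
    "ladder_right_slips": dict(log_rate=(1.1, 0.45), baseline_rate=0.1,
                               crossings=5),
}
ANIMAL_BASELINE_SIGMA = 0.05   # lognormal animal-to-animal baseline spread

# histology links: target normalized ring-band means (intensity markers)
# and percent-of-background (NeuN), per distance bin
INTENSITY_BAND_MEAN = {          # band mean = 1 + amp * exp(scale * z)
    "0-50": dict(amp=0.9, scale=0.35),
    "50-100": dict(amp=0.35, scale=0.35),
}
NEUN_PERCENT = {                 # percent = lo + (hi - lo) * sigmoid(0.9*z)
    "0-50": dict(lo=15.0, hi=85.0),
    "50-100": dict(lo=55.0, hi=115.0),
}
SLICE_JITTER_SIGMA = 0.03        # section-to-section lognormal jitter
SLICES_PER_ANIMAL = 6            # 2 slides x 3 sections

IMAGE_UM_PER_PIXEL = 2.0
IMAGE_HALF_WIDTH_UM = 1100.0     # implant-centered square half-width
IMAGE_BACKGROUND = 500.0         # expected photon counts per background px
NEURON_BG_PER_MM2 = 2000.0       # background neuron density (20 um sections)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTrace:
    """One channel-session voltage trace with its ground truth."""

    animal_id: str
    channel_id: int
    week: int
    session: int
    fs: float
    samples: np.ndarray                  # microvolts, float32
    true_spike_times: np.ndarray         # sample indices, strictly increasing
    true_unit_labels: np.ndarray         # per-spike unit id

    def __post_init__(self) -> None:
        t = np.asarray(self.true_spike_times)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0
                       or t[-1] >= len(self.samples)):
            raise ValueError("true_spike_times must be strictly increasing "
                             "and lie inside the trace")


@dataclass
class SyntheticImage:
    """Stand-in for one stitched fluorescence section image (synthetic)."""

    pixels: np.ndarray                   # nonnegative intensities
    implant_center: tuple[float, float]  # (x, y) in pixel coordinates
    um_per_pixel: float
    marker: str = ""
    neuron_points: np.ndarray | None = None   # (n, 2) pixel coords, NeuN only

    def __post_init__(self) -> None:
        ny, nx = self.pixels.shape
        x, y = self.implant_center
        if not (0 <= x < nx and 0 <= y < ny):
            raise ValueError("implant_center must lie inside the pixel grid")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")


@dataclass
class StudyBundle:
    """Everything one synthetic study produces.

    Ground-truth tables are eager; traces and images are rendered on
    demand (deterministically) via :meth:`trace` and
    :meth:`histology_image`.
    """

    config: StudyConfig
    latent: pd.DataFrame            # animal_id, week, one column per variable
    channel_units: pd.DataFrame     # animal_id, channel_id, week, session,
                                    # n_units, missing
    behavior_trials: pd.DataFrame   # animal_id, test, week, session,
                                    # trial_index, value
    histology_params: pd.DataFrame  # animal_id, marker, distance_bin, target
    histology_table: pd.DataFrame   # analytic analysis values
                                    # (animal_id, marker, distance_bin, value)

    # -- lazy heavy outputs -------------------------------------------------

    def trace(self, animal_id: str, channel_id: int, week: int,
              session: int = 1) -> SyntheticTrace:
        """Render the voltage trace for one channel-session."""
        row = self.channel_units[
            (self.channel_units.animal_id == animal_id)
            & (self.channel_units.channel_id == channel_id)
            & (self.channel_units.week == week)
            & (self.channel_units.session == session)]
        if row.empty:
            raise KeyError(
                f"no such recording: {animal_id}/ch{channel_id}/wk{week}/"
                f"s{session}")
        n_units = int(row.n_units.iloc[0])
        rng = self.config.rng("trace", animal_id, channel_id, week, session)
        templates = [
            biphasic_template(rng.uniform(*UNIT_P2P_RANGE_UV),
                              self.config.sampling_rate)
            for _ in range(n_units)]
        rates = rng.uniform(*UNIT_RATE_RANGE_HZ, size=n_units)
        tr = inject_spikes(
            TRACE_NOISE_UV, templates, rates,
            self.config.trace_duration_s,
            rng=rng, fs=self.config.sampling_rate)
        tr.animal_id, tr.channel_id, tr.week, tr.session = (
            animal_id, channel_id, week, session)
        return tr

    def iter_traces(self, weeks=None):
        cu = self.channel_units
        if weeks is not None:
            cu = cu[cu.week.isin(weeks)]
        for r in cu.itertuples():
            if not r.missing:
                yield self.trace(r.animal_id, r.channel_id, r.week, r.session)

    def histology_image(self, animal_id: str, marker: str,
                        slice_index: int = 0) -> SyntheticImage:
        """Render one section image for an animal/marker (deterministic)."""
        if marker not in MARKERS:
            raise KeyError(f"unknown marker {marker!r}")
        if not 0 <= slice_index < SLICES_PER_ANIMAL:
            raise IndexError("slice_index out of range")
        rng = self.config.rng("histo", animal_id, marker, slice_index)
        hp = self.histology_params
        tgt = {
            b: float(hp[(hp.animal_id == animal_id) & (hp.marker == marker)
                        & (hp.distance_bin == b)].target.iloc[0])
            for b in DISTANCE_BINS}
        jit = np.exp(rng.normal(0.0, SLICE_JITTER_SIGMA, size=2))
        if marker == "NeuN":
            p0 = float(np.clip(tgt["0-50"] * jit[0], 1.0, 120.0))
            p1 = float(np.clip(tgt["50-100"] * jit[1], 1.0, 130.0))
            profile = _piecewise_band_profile(p0 / 100.0, p1 / 100.0)
            return render_histology_image(
                neuron_density_profile=profile, marker=marker, rng=rng)
        m0 = 1.0 + (tgt["0-50"] - 1.0) * jit[0]
        m1 = 1.0 + (tgt["50-100"] - 1.0) * jit[1]
        profile = _piecewise_band_profile(m0, m1)
        return render_histology_image(
            intensity_profile=profile, marker=marker, rng=rng)


# ---------------------------------------------------------------------------
# Gaussian copula
# ---------------------------------------------------------------------------


def gaussian_copula(rng: np.random.Generator, corr: np.ndarray, n: int,
                    ar1: float = 0.0, n_weeks: int | None = None) -> np.ndarray:
    """Draw ``n`` latent rows with cross-variable correlation ``corr``.

    Marginals are standard normal (their probit transforms are uniform —
    the copula property tested in the suite). With ``ar1 > 0`` the rows
    of each consecutive block of ``n_weeks`` get an AR(1) dependence in
    time while preserving the cross-sectional correlation.
    """
    w, V = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    z = rng.standard_normal((n, corr.shape[0]))
    x = z @ L.T
    if ar1 > 0:
        if n_weeks is None or n % n_weeks:
            raise ValueError("ar1 requires n to be a multiple of n_weeks")
        x = x.reshape(n // n_weeks, n_weeks, -1)
        out = np.empty_like(x)
        out[:, 0] = x[:, 0]
        c = np.sqrt(1 - ar1 ** 2)
        for t in range(1, n_weeks):
            out[:, t] = ar1 * out[:, t - 1] + c * x[:, t]
        x = out.reshape(n, -1)
    return x


# ---------------------------------------------------------------------------
# Spike-train traces
# ---------------------------------------------------------------------------


def biphasic_template(p2p_uv: float, fs: float,
                      width_s: float = TEMPLATE_WIDTH_S) -> np.ndarray:
    """Fixed biphasic action-potential template, negative peak leading.

    A single-cycle sine under a Gaussian envelope, scaled to the requested
    peak-to-peak amplitude. The negative phase leads so detection on the
    lower threshold sees the larger deflection first.
    """
    if p2p_uv <= 0:
        raise ValueError("template peak-to-peak amplitude must be positive")
    n = max(int(round(width_s * fs)), 8)
    t = np.arange(n) / fs
    shape = -np.sin(2 * np.pi * t / width_s) * np.exp(
        -((t - width_s / 3) / (width_s / 3)) ** 2)
    return shape / (shape.max() - shape.min()) * p2p_uv


def inject_spikes(noise_sigma: float, templates: list[np.ndarray],
                  rate, duration: float, *, seed: int | None = None,
                  rng: np.random.Generator | None = None,
                  fs: float = 24414.0) -> SyntheticTrace:
    """Gaussian background plus spike templates at Poisson event times.

    ``rate`` may be a scalar (events/s for every unit) or one rate per
    template. Events of one unit are never closer than 1 ms; event rates
    that cannot be packed at that refractory separation are rejected.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = np.broadcast_to(np.asarray(rate, dtype=float),
                            (len(templates),)).copy()
    feasible = 1.0 / REFRACTORY_S
    if np.any(rates > 0.5 * feasible):
        raise ValueError(
            "event rate exceeds refractory packing; feasible maximum is "
            f"{0.5 * feasible:.0f} events/s per unit")
    n = int(round(duration * fs))
    samples = rng.normal(0.0, noise_sigma, size=n) if noise_sigma > 0 \
        else np.zeros(n)
    refr = int(round(REFRACTORY_S * fs))
    times, labels = [], []
    for u, (tpl, r) in enumerate(zip(templates, rates)):
        tpl = np.asarray(tpl, dtype=float)
        if tpl.size < 2 or tpl.max() <= tpl.min():
            raise ValueError("templates must be biphasic with a defined "
                             "peak-to-peak amplitude")
        k = rng.poisson(r * duration)
        ev = np.sort(rng.integers(0, max(n - tpl.size, 1), size=k))
        kept = []
        last = -refr
        for e in ev:
            if e - last >= refr:
                kept.append(e)
                last = e
        for e in kept:
            samples[e:e + tpl.size] += tpl[: n - e]
        times.extend(kept)
        labels.extend([u] * len(kept))
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=int)[order]
    labels = np.asarray(labels, dtype=int)[order]
    # keep ground truth strictly increasing: coincident events of distinct
    # units are jittered apart by one sample for bookkeeping only
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + 1
    return SyntheticTrace(
        animal_id="", channel_id=-1, week=0, session=1, fs=fs,
        samples=samples.astype(np.float32),
        true_spike_times=times, true_unit_labels=labels)


# ---------------------------------------------------------------------------
# Histology images
# ---------------------------------------------------------------------------


def _piecewise_band_profile(m0: float, m1: float):
    """Radial multiplier with prescribed means over [0,50) and [50,100) um.

    Piecewise linear through knots at 0/50/100 um, relaxing linearly to the
    background level 1 at 300 um and flat beyond — so the 700-750 um
    intensity background and the 450-500 um neuron-count background are
    exactly at level 1.
    """
    n50 = 0.5 * (m0 + m1)
    n0 = 2.0 * m0 - n50
    n100 = 2.0 * m1 - n50
    r_knots = np.array([0.0, 50.0, 100.0, 300.0])
    v_knots = np.array([n0, n50, n100, 1.0])

    def profile(r):
        return np.interp(np.asarray(r, dtype=float), r_knots, v_knots,
                         right=1.0)

    return profile


def exponential_profile(amplitude: float, decay_um: float):
    """Radial multiplier 1 + a*exp(-r/lambda) (classic glial-scar shape)."""

    def profile(r):
        return 1.0 + amplitude * np.exp(-np.asarray(r, dtype=float) / decay_um)

    return profile


def depletion_profile(b: float, decay_um: float):
    """Neuron-density multiplier 1 - b*exp(-r/lambda): near-implant loss."""

    def profile(r):
        return 1.0 - b * np.exp(-np.asarray(r, dtype=float) / decay_um)

    return profile


def render_histology_image(
    intensity_profile=None,
    neuron_density_profile=None,
    *,
    background: float = IMAGE_BACKGROUND,
    neuron_bg_per_mm2: float = NEURON_BG_PER_MM2,
    um_per_pixel: float = IMAGE_UM_PER_PIXEL,
    half_width_um: float = IMAGE_HALF_WIDTH_UM,
    marker: str = "",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticImage:
    """Render one synthetic stained-section image around an implant center.

    Pixel intensities are Poisson draws around ``background *
    intensity_profile(r)``; when a ``neuron_density_profile`` is given
    (NeuN), point neurons are planted by thinning a homogeneous Poisson
    process of density ``neuron_bg_per_mm2``.
    """
    if half_width_um < 1000.0:
        raise ValueError(
            "image too small: need >= 1 mm of tissue around the implant "
            "center so the 700-750 um background annulus fits "
            f"(got half-width {half_width_um} um)")
    if rng is None:
        rng = np.random.default_rng(seed)
    npx = int(round(2 * half_width_um / um_per_pixel)) + 1
    cx = cy = (npx - 1) / 2.0
    xs = (np.arange(npx) - cx) * um_per_pixel
    r = np.sqrt(xs[None, :] ** 2 + xs[:, None] ** 2)
    prof = intensity_profile(r) if intensity_profile is not None \
        else np.ones_like(r)
    pixels = rng.poisson(np.clip(background * prof, 0.0, None)).astype(float)

    points = None
    if neuron_density_profile is not None:
        area_mm2 = (2 * half_width_um / 1000.0) ** 2
        # thinning bound: densities are piecewise profiles <= their max
        probe = np.linspace(0.0, 2 * half_width_um * np.sqrt(2), 2048)
        dmax = float(np.max(neuron_density_profile(probe)))
        dmax = max(dmax, 1e-9)
        n_cand = rng.poisson(neuron_bg_per_mm2 * dmax * area_mm2)
        pts = rng.uniform(0, npx - 1, size=(n_cand, 2))  # (x, y) pixel coords
        d_um = np.sqrt(((pts[:, 0] - cx) * um_per_pixel) ** 2
                       + ((pts[:, 1] - cy) * um_per_pixel) ** 2)
        keep = rng.uniform(0, dmax, size=n_cand) < neuron_density_profile(d_um)
        points = pts[keep]

    return SyntheticImage(pixels=pixels, implant_center=(cx, cy),
                          um_per_pixel=um_per_pixel, marker=marker,
                          neuron_points=points)


# ---------------------------------------------------------------------------
# Full-study generation
# ---------------------------------------------------------------------------


def _analytic_histology_value(marker: str, distance_bin: str,
                              target: float) -> float:
    """Analysis value implied by a planted target (noise-free limit).

    Intensity markers: the 50-um AUC increment of the normalized profile,
    i.e. 50 * band mean. NeuN: percent of background, the target itself.
    """
    if marker == "NeuN":
        return target
    return 50.0 * target


def generate_study(config: StudyConfig) -> StudyBundle:
    """Generate one full synthetic study (deterministic given the seed)."""
    p = len(VARIABLES)
    n_aw = config.n_animals * config.n_weeks
    rng = config.rng("latent")
    z = gaussian_copula(rng, config.latent_correlation, n_aw,
                        ar1=config.behavior_ar1, n_weeks=config.n_weeks)
    animals = np.repeat(config.animals, config.n_weeks)
    weeks = np.tile(config.weeks, config.n_animals)
    latent = pd.DataFrame(z, columns=list(VARIABLES))
    latent.insert(0, "week", weeks)
    latent.insert(0, "animal_id", animals)

    channel_units = _generate_channel_units(config, latent)
    behavior_trials = _generate_behavior_trials(config, latent)
    histology_params, histology_table = _generate_histology(config, latent)

    return StudyBundle(config=config, latent=latent,
                       channel_units=channel_units,
                       behavior_trials=behavior_trials,
                       histology_params=histology_params,
                       histology_table=histology_table)


def _generate_channel_units(config: StudyConfig,
                            latent: pd.DataFrame) -> pd.DataFrame:
    from scipy.special import ndtr

    rng = config.rng("channels")
    u0, u1 = UNIT_RATE_LOG
    rows = []
    for r in latent.itertuples():
        z_pct = getattr(r, "pct_channels_active")
        z_upc = getattr(r, "units_per_channel")
        pi = ACTIVITY_PROBIT["lo"] + ACTIVITY_PROBIT["span"] * float(
            ndtr(z_pct))
        lam = max(float(np.exp(u0 + u1 * z_upc)), 1.0)
        for s in range(1, config.tests_per_week + 1):
            # the number of active contacts tracks the animal-week state
            # (activity across a shank is spatially structured, not an
            # iid coin flip per contact); which contacts are active is
            # random
            k = int(np.clip(round(config.n_channels * pi
                                  + rng.normal(0.0, 0.4)),
                            0, config.n_channels))
            active = np.zeros(config.n_channels, dtype=bool)
            active[rng.choice(config.n_channels, size=k, replace=False)] = True
            extra = rng.poisson(lam - 1.0, size=config.n_channels)
            n_units = np.where(active, 1 + extra, 0)
            miss_day = rng.random() < config.missing_day_rate
            miss_ch = rng.random(config.n_channels) < config.missing_channel_rate
            for c in range(config.n_channels):
                rows.append((r.animal_id, c + 1, r.week, s,
                             int(n_units[c]), bool(miss_day or miss_ch[c])))
    return pd.DataFrame(rows, columns=[
        "animal_id", "channel_id", "week", "session", "n_units", "missing"])


def _generate_behavior_trials(config: StudyConfig,
                              latent: pd.DataFrame) -> pd.DataFrame:
    rng = config.rng("behavior")
    rows = []
    lat = latent.set_index(["animal_id", "week"])
    base_factor = {
        (a, t): float(np.exp(rng.normal(0.0, ANIMAL_BASELINE_SIGMA)))
        for a in config.animals for t in BEHAVIOR_VARS}

    def add(a, test, week, session, values):
        for i, v in enumerate(values, start=1):
            rows.append((a, test, week, session, i, v))

    for a in config.animals:
        for week in range(0, config.n_weeks + 1):
            for s in range(1, config.tests_per_week + 1):
                for test in BEHAVIOR_VARS:
                    link = BEHAVIOR_LINKS[test]
                    z = 0.0 if week == 0 else float(lat.loc[(a, week), test])
                    if test in ("ladder_left_slips", "ladder_right_slips"):
                        la, lb = link["log_rate"]
                        lam = link["baseline_rate"] if week == 0 \
                            else float(np.exp(la + lb * z))
                        total = int(rng.poisson(link["crossings"] * lam))
                        add(a, test, week, s, [total])
                    elif test == "grip_force":
                        mu = base_factor[(a, test)] * link["base"] \
                            + link["scale"] * z
                        pulls = np.maximum(
                            rng.normal(mu, link["trial_sigma"], size=3), 1.0)
                        add(a, test, week, s, pulls)
                    elif test == "ladder_time":
                        mu = base_factor[(a, test)] * link["base"] \
                            * np.exp(link["scale"] * z)
                        t5 = mu * np.exp(
                            rng.normal(0.0, link["trial_sigma"], size=5))
                        add(a, test, week, s, t5)
                    else:  # grid metrics, one value per session
                        mu = base_factor[(a, test)] * link["base"] \
                            * np.exp(link["scale"] * z)
                        v = mu * np.exp(rng.normal(0.0, link["trial_sigma"]))
                        add(a, test, week, s, [v])
    return pd.DataFrame(rows, columns=[
        "animal_id", "test", "week", "session", "trial_index", "value"])


def _generate_histology(config: StudyConfig, latent: pd.DataFrame):
    """Per-animal planted targets and their analytic analysis values.

    The endpoint latent of a histology variable is the per-animal mean of
    its weekly copula column, rescaled back to unit variance, so the
    animal-level correlation with the longitudinal modalities matches the
    planted entry.
    """
    params, table = [], []
    g = latent.groupby("animal_id", sort=False)
    for marker in MARKERS:
        for dbin in DISTANCE_BINS:
            var = HISTOLOGY_VAR_OF[(marker, dbin)]
            z_a = g[var].mean() * np.sqrt(config.n_weeks)
            for a in config.animals:
                z = float(z_a.loc[a])
                if marker == "NeuN":
                    lk = NEUN_PERCENT[dbin]
                    target = lk["lo"] + (lk["hi"] - lk["lo"]) / (
                        1.0 + np.exp(-0.9 * z))
                else:
                    lk = INTENSITY_BAND_MEAN[dbin]
                    target = 1.0 + lk["amp"] * np.exp(lk["scale"] * z)
                params.append((a, marker, dbin, float(target)))
                table.append((a, marker, dbin,
                              _analytic_histology_value(marker, dbin, target)))
    return (
        pd.DataFrame(params, columns=["animal_id", "marker", "distance_bin",
                                      "target"]),
        pd.DataFrame(table, columns=["animal_id", "marker", "distance_bin",
                                     "value"]),
    )


# ---------------------------------------------------------------------------
# Writers (flat binary traces + JSON sidecar, TIFF images, tidy CSV)
# ---------------------------------------------------------------------------


def write_trace(trace: SyntheticTrace, path: str | Path) -> None:
    """float32 little-endian samples + JSON sidecar with the metadata."""
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    meta = dict(animal_id=trace.animal_id, channel_id=trace.channel_id,
                week=trace.week, session=trace.session, fs=trace.fs,
                n_samples=int(len(trace.samples)), dtype="<f4",
                true_spike_times=trace.true_spike_times.tolist(),
                true_unit_labels=trace.true_unit_labels.tolist())
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_trace(path: str | Path) -> SyntheticTrace:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = np.fromfile(path, dtype="<f4")
    return SyntheticTrace(
        animal_id=meta["animal_id"], channel_id=meta["channel_id"],
        week=meta["week"], session=meta["session"], fs=meta["fs"],
        samples=samples,
        true_spike_times=np.asarray(meta["true_spike_times"], dtype=int),
        true_unit_labels=np.asarray(meta["true_unit_labels"], dtype=int))


def write_image(image: SyntheticImage, path: str | Path) -> None:
    """Single-channel TIFF plus JSON sidecar (implant center, scale)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    meta = dict(implant_center=list(image.implant_center),
                um_per_pixel=image.um_per_pixel, marker=image.marker)
    if image.neuron_points is not None:
        meta["neuron_points"] = image.neuron_points.tolist()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_image(path: str | Path) -> SyntheticImage:
    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pts = meta.get("neuron_points")
    return SyntheticImage(
        pixels=tifffile.imread(path).astype(float),
        implant_center=tuple(meta["implant_center"]),
        um_per_pixel=meta["um_per_pixel"], marker=meta.get("marker", ""),
        neuron_points=None if pts is None else np.asarray(pts, dtype=float))
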