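"""Study design configuration and the frozen analysis-variable registry.

A chronic intracortical-microelectrode (IME) study in this package has a
fixed tri-modal design: weekly multi-channel extracellular recordings,
weekly motor-behavior testing (plus a presurgery baseline week), and
endpoint immunohistology quantified at radial distance bins around the
implant. All design parameters live in :class:`StudyConfig`; the sixteen
analysis variables that enter the correlation network are enumerated in
:data:`VARIABLES` in a canonical, string-stable order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Variable registry (canonical order, frozen for string-stable outputs)
# ---------------------------------------------------------------------------

RECORDING_VARS = (
    "pct_channels_active",   # % of kept channels recording single units (Y2)
    "units_per_channel",     # mean detectable single units per active channel (Y1)
)

BEHAVIOR_VARS = (
    "grid_distance",         # open-field grid: total distance traveled
    "grid_max_velocity",     # open-field grid: maximum velocity
    "ladder_time",           # ladder crossing time (fastest 3 of 5)
    "ladder_left_slips",     # left front-paw slips per crossing day
    "ladder_right_slips",    # right front-paw slips per crossing day
    "grip_force",            # maximum grip strength (mean of 3 pulls)
)

MARKERS = ("NeuN", "GFAP", "CD68", "IgG")
DISTANCE_BINS = ("0-50", "50-100")

HISTOLOGY_VARS = (
    "neun_0_50", "neun_50_100",
    "gfap_0_50", "gfap_50_100",
    "cd68_0_50", "cd68_50_100",
    "igg_0_50", "igg_50_100",
)

VARIABLES = RECORDING_VARS + BEHAVIOR_VARS + HISTOLOGY_VARS

#: marker/bin pair -> registry name
HISTOLOGY_VAR_OF = {
    ("NeuN", "0-50"): "neun_0_50", ("NeuN", "50-100"): "neun_50_100",
    ("GFAP", "0-50"): "gfap_0_50", ("GFAP", "50-100"): "gfap_50_100",
    ("CD68", "0-50"): "cd68_0_50", ("CD68", "50-100"): "cd68_50_100",
    ("IgG", "0-50"): "igg_0_50", ("IgG", "50-100"): "igg_50_100",
}

#: behavior tests normalized to baseline by the percent-change rule;
#: slip counts are analyzed raw because baseline slips are near zero.
EQ1_NORMALIZED_TESTS = (
    "grid_distance", "grid_max_velocity", "ladder_time", "grip_force",
)
RAW_COUNT_TESTS = ("ladder_left_slips", "ladder_right_slips")


def variable_index(name: str) -> int:
    try:
        return VARIABLES.index(name)
    except ValueError:
        raise KeyError(f"unknown analysis variable {name!r}") from None


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """All design parameters of one (synthetic or real) IME study.

    Parameters
    ----------
    n_animals
        Number of implanted animals (default 6).
    n_channels
        Contacts on the single-shank array (default 16).
    n_keep
        Consecutive channels retained for analysis, chosen by spiking
        activity (default 10, the contacts spanning cortical layers III-V).
    n_weeks
        Post-implant weekly time points (default 8).
    tests_per_week
        Recording/behavior sessions per week, aggregated to one weekly
        value before analysis (default 2).
    sampling_rate
        Voltage-trace sampling rate in Hz (default 24414).
    rng_seed
        Root seed; every stochastic stage derives its stream from it.
    latent_correlation
        Symmetric positive semi-definite matrix with unit diagonal over
        the 16 registry variables; the Gaussian-copula correlation that
        links the three modalities. ``None`` means identity.
    trace_duration_s
        Duration of each synthesized voltage trace. 30 s keeps a full
        study at desk scale; real sessions are longer.
    behavior_ar1
        Week-to-week AR(1) coefficient of the within-animal latent
        series (default 0: weeks exchangeable).
    missing_day_rate, missing_channel_rate
        Fractions of recording days / individual channels flagged
        missing (excluded, never zero-filled). Defaults 0.
    """

    n_animals: int = 6
    n_channels: int = 16
    n_keep: int = 10
    n_weeks: int = 8
    tests_per_week: int = 2
    sampling_rate: float = 24414.0
    rng_seed: int = 0
    latent_correlation: np.ndarray | None = None
    trace_duration_s: float = 30.0
    behavior_ar1: float = 0.0
    missing_day_rate: float = 0.0
    missing_channel_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_animals", "n_channels", "n_keep", "n_weeks",
                     "tests_per_week"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if self.n_keep > self.n_channels:
            raise ValueError(
                f"n_keep ({self.n_keep}) must not exceed n_channels "
                f"({self.n_channels})")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.behavior_ar1 < 1:
            raise ValueError("behavior_ar1 must be in [0, 1)")
        p = len(VARIABLES)
        if self.latent_correlation is None:
            self.latent_correlation = np.eye(p)
        else:
            C = np.asarray(self.latent_correlation, dtype=float)
            if C.shape != (p, p):
                raise ValueError(
                    f"latent_correlation must be {p}x{p}, got {C.shape}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("latent_correlation must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ValueError("latent_correlation must have unit diagonal")
            if np.any(np.abs(C) > 1 + 1e-12):
                raise ValueError("latent_correlation entries must be in [-1, 1]")
            w = np.linalg.eigvalsh(C)
            if w[0] < -1e-8:
                raise ValueError(
                    "latent_correlation is not positive semi-definite "
                    f"(smallest eigenvalue {w[0]:.3g})")
            self.latent_correlation = C

    # -- reproducible substreams --------------------------------------------

    def rng(self, *tags) -> np.random.Generator:
        """Independent, reproducible generator for a named pipeline stage.

        The stream is keyed on ``rng_seed`` plus a CRC of the tags, so
        adding a stage never perturbs the draws of existing stages.
        """
        key = zlib.crc32("/".join(str(t) for t in tags).encode())
        return np.random.default_rng([int(self.rng_seed) & 0x7FFFFFFF, key])

    @property
    def animals(self) -> list[str]:
        return [f"A{i + 1}" for i in range(self.n_animals)]

    @property
    def weeks(self) -> np.ndarray:
        """Post-implant analysis weeks, 1..n_weeks."""
        return np.arange(1, self.n_weeks + 1)


def block_correlation(blocks: list[list[str]], rho: float = 0.9) -> np.ndarray:
    """Latent correlation with ``rho`` inside each named block, 0 between.

    Convenience for planted-structure studies; variables not listed in any
    block stay uncorrelated with everything.
    """
    p = len(VARIABLES)
    C = np.eye(p)
    for block in blocks:
        idx = [variable_index(v) for v in block]
        for i in idx:
            for j in idx:
                if i != j:
                    C[i, j] = rho
    w = np.linalg.eigvalsh(C)
    if w[0] < -1e-8:
        raise ValueError(f"block correlation not PSD (eigenvalue {w[0]:.3g})")
    return C
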