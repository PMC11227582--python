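"""Seeded generators for synthetic photometry, spot-field, uptake and score data.

Every generator takes an explicit ``seed`` (no global RNG state) and returns
both the simulated dataset and, where meaningful, the ground truth needed for
parameter-recovery tests. Randomness is split into independent substreams
(one per noise component) via :class:`numpy.random.SeedSequence` spawning, so
that sweeping one parameter — e.g. the transient rate — at a fixed seed keeps
all other noise realizations identical. That keeps parameter sweeps low
variance without any post-hoc pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from striakit.exceptions import ConfigError
from striakit.photometry import PhotometryRecording

__all__ = [
    "PhotometrySimConfig",
    "SpotFieldSimConfig",
    "UptakeSimConfig",
    "BehaviorSimConfig",
    "simulate_photometry",
    "simulate_spot_field",
    "simulate_uptake",
    "simulate_behavior_scores",
    "transient_kernel",
    "PAPER_UPTAKE_GLUTAMATE",
    "PAPER_UPTAKE_ACH",
]


# ---------------------------------------------------------------------------
# photometry


@dataclass(frozen=True)
class PhotometrySimConfig:
    """Generative model of a two-channel fiber-photometry recording.

    The signal channel (465 nm) is built as::

        autofluorescence + baseline + bleach_amp * exp(-t / bleach_tau_s)
        + sum of transients + shared artifact + independent noise

    and the control channel (405 nm) is identical minus the transients, with
    its own independent noise draw. Transient onsets follow a homogeneous
    Poisson process of ``event_rate_per_min``; overlapping transients add
    linearly. The shared artifact emulates slow motion/hemodynamic
    fluctuations common to both channels: Gaussian noise low-pass smoothed to
    ``artifact_cutoff_hz`` and rescaled to ``artifact_sd``.

    Units: times in s, rates in Hz or events/min, fluorescence in arbitrary
    detector units (a.u.).
    """

    duration_s: float = 1200.0
    rate_hz: float = 600.0
    baseline_f: float = 100.0
    bleach_amp: float = 30.0
    bleach_tau_s: float = 600.0
    event_rate_per_min: float = 2.0
    event_amp: float = 5.0
    event_rise_s: float = 0.3
    event_decay_s: float = 1.5
    artifact_sd: float = 1.0
    artifact_cutoff_hz: float = 0.5
    noise_sd: float = 1.0
    autofluorescence_signal: float = 10.0
    autofluorescence_control: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ConfigError("duration_s and rate_hz must be positive")
        for name in ("bleach_tau_s", "event_rise_s", "event_decay_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.event_rate_per_min < 0:
            raise ConfigError("event_rate_per_min must be non-negative")
        if self.artifact_sd < 0 or self.noise_sd < 0:
            raise ConfigError("noise scales must be non-negative")
        n = self.duration_s * self.rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("duration_s * rate_hz must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


def transient_kernel(rise_s: float, decay_s: float, rate_hz: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel on the sample grid.

    ``k(t) = (1 - exp(-t/rise)) * exp(-t/decay)`` normalized so its analytic
    maximum (at ``t* = rise * log(1 + decay/rise)``) equals 1. The kernel is
    truncated at 8 decay constants.
    """
    t = np.arange(0.0, 8.0 * decay_s, 1.0 / rate_hz)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    t_peak = rise_s * np.log1p(decay_s / rise_s)
    peak = (1.0 - np.exp(-t_peak / rise_s)) * np.exp(-t_peak / decay_s)
    return k / peak


def _smoothed_noise(rng: np.random.Generator, n: int, rate_hz: float,
                    cutoff_hz: float, sd: float) -> np.ndarray:
    """Gaussian noise low-passed with a moving average to ~cutoff_hz, unit-sd
    rescaled to ``sd``."""
    if sd == 0:
        return np.zeros(n)
    w = max(int(round(rate_hz / (2.0 * cutoff_hz))), 1)
    x = rng.standard_normal(n + w - 1)
    sm = np.convolve(x, np.ones(w) / w, mode="valid")
    return sd * sm / np.sqrt(1.0 / w)


def simulate_photometry(cfg: PhotometrySimConfig) -> tuple[PhotometryRecording, np.ndarray]:
    """Simulate a two-channel recording; return it with ground-truth event times."""
    n = cfg.n_samples
    t = np.arange(n) / cfg.rate_hz
    ss = np.random.SeedSequence(cfg.seed)
    rng_events, rng_artifact, rng_sig, rng_ctl = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    lam = cfg.event_rate_per_min / 60.0 * cfg.duration_s
    n_events = rng_events.poisson(lam) if lam > 0 else 0
    event_times = np.sort(rng_events.uniform(0.0, cfg.duration_s, size=n_events))

    transients = np.zeros(n)
    if n_events:
        spikes = np.zeros(n)
        idx = np.minimum((event_times * cfg.rate_hz).astype(int), n - 1)
        np.add.at(spikes, idx, cfg.event_amp)
        kernel = transient_kernel(cfg.event_rise_s, cfg.event_decay_s, cfg.rate_hz)
        transients = np.convolve(spikes, kernel)[:n]

    bleach = cfg.bleach_amp * np.exp(-t / cfg.bleach_tau_s)
    artifact = _smoothed_noise(rng_artifact, n, cfg.rate_hz,
                               cfg.artifact_cutoff_hz, cfg.artifact_sd)
    common = cfg.baseline_f + bleach + artifact
    f_signal = (cfg.autofluorescence_signal + common + transients
                + cfg.noise_sd * rng_sig.standard_normal(n))
    f_control = (cfg.autofluorescence_control + common
                 + cfg.noise_sd * rng_ctl.standard_normal(n))

    rec = PhotometryRecording(
        time_s=t,
        f_signal=f_signal,
        f_control=f_control,
        rate_hz=cfg.rate_hz,
        autofluorescence_signal=cfg.autofluorescence_signal,
        autofluorescence_control=cfg.autofluorescence_control,
    )
    return rec, event_times


# ---------------------------------------------------------------------------
# spot fields


@dataclass(frozen=True)
class SpotFieldSimConfig:
    """Two-channel spot field: a fraction of channel-A spots carry a channel-B
    partner displaced by a Rayleigh-distributed distance at uniform angle,
    plus unpaired channel-B spots, all in a rectangular field (nm).

    Defaults emulate vesicle preparations where ~40% of vesicles carry both
    transporters and paired-spot displacements peak around tens of nm.
    """

    field_w_nm: float = 10_000.0
    field_h_nm: float = 10_000.0
    n_primary: int = 200
    paired_fraction: float = 0.40
    pair_sigma_nm: float = 40.0
    n_singleton_b: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ConfigError("paired_fraction must be in [0, 1]")
        if self.n_primary < 0 or self.n_singleton_b < 0:
            raise ConfigError("spot counts must be non-negative")
        if self.field_w_nm <= 0 or self.field_h_nm <= 0:
            raise ConfigError("field dimensions must be positive")
        if self.pair_sigma_nm < 0:
            raise ConfigError("pair_sigma_nm must be non-negative")


def simulate_spot_field(cfg: SpotFieldSimConfig):
    """Simulate a two-channel spot field.

    Returns a :class:`striakit.colocalization.SpotField` whose ``truth_pair_id``
    columns link each paired A spot to its B partner (exactly
    ``round(paired_fraction * n_primary)`` pairs); singletons carry id -1.
    """
    from striakit.colocalization import SpotField

    rng = np.random.default_rng(cfg.seed)
    ax = rng.uniform(0.0, cfg.field_w_nm, cfg.n_primary)
    ay = rng.uniform(0.0, cfg.field_h_nm, cfg.n_primary)
    n_paired = int(round(cfg.paired_fraction * cfg.n_primary))

    pair_r = rng.rayleigh(cfg.pair_sigma_nm, n_paired) if cfg.pair_sigma_nm > 0 \
        else np.zeros(n_paired)
    pair_theta = rng.uniform(0.0, 2.0 * np.pi, n_paired)
    bx_paired = ax[:n_paired] + pair_r * np.cos(pair_theta)
    by_paired = ay[:n_paired] + pair_r * np.sin(pair_theta)

    bx_single = rng.uniform(0.0, cfg.field_w_nm, cfg.n_singleton_b)
    by_single = rng.uniform(0.0, cfg.field_h_nm, cfg.n_singleton_b)

    a_pair_id = np.concatenate([np.arange(n_paired),
                                -np.ones(cfg.n_primary - n_paired, dtype=int)])
    b_pair_id = np.concatenate([np.arange(n_paired),
                                -np.ones(cfg.n_singleton_b, dtype=int)])

    spots_a = pd.DataFrame({"x_nm": ax, "y_nm": ay, "truth_pair_id": a_pair_id})
    spots_b = pd.DataFrame({
        "x_nm": np.concatenate([bx_paired, bx_single]),
        "y_nm": np.concatenate([by_paired, by_single]),
        "truth_pair_id": b_pair_id,
    })
    return SpotField(spots_a=spots_a, spots_b=spots_b,
                     field_w_nm=cfg.field_w_nm, field_h_nm=cfg.field_h_nm)


# ---------------------------------------------------------------------------
# uptake replicates

# Printed group summaries (mean, SEM, n) from radiolabeled uptake assays in
# striatal synaptic vesicles, used as default generative parameters.
# Values in pmol per mg protein per 10 min.
PAPER_UPTAKE_GLUTAMATE: dict[tuple[str, str], tuple[float, float, int]] = {
    ("WT", "glutamate"): (330.3, 50.0, 6),
    ("T8I", "glutamate"): (350.7, 38.7, 6),
    ("KO", "glutamate"): (187.7, 34.7, 6),
}
PAPER_UPTAKE_ACH: dict[tuple[str, str], tuple[float, float, int]] = {
    ("WT", "basal"): (11.9, 1.2, 8),
    ("WT", "glutamate"): (25.3, 2.5, 7),
    ("T8I", "basal"): (9.27, 1.15, 8),
    ("T8I", "glutamate"): (16.21, 0.68, 7),
}


def _cells_from_summaries(
    summaries: dict[tuple[str, str], tuple[float, float, int]],
) -> dict[tuple[str, str], tuple[float, float, int]]:
    # (mean, SEM, n) -> (mean, sd, n)
    return {k: (m, sem * np.sqrt(n), n) for k, (m, sem, n) in summaries.items()}


@dataclass(frozen=True)
class UptakeSimConfig:
    """Replicate tables for vesicular-uptake assays.

    ``cells`` maps (genotype, condition) to (mean, sd, n_replicates); values
    are drawn from a normal truncated at zero (uptake is a non-negative
    count-derived quantity). Defaults reproduce the printed acetylcholine
    synergy experiment (basal vs 1 mM glutamate) group summaries.
    """

    cells: dict[tuple[str, str], tuple[float, float, int]] = field(
        default_factory=lambda: _cells_from_summaries(PAPER_UPTAKE_ACH))
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (mean, sd, n) in self.cells.items():
            if mean < 0:
                raise ConfigError(f"negative mean for cell {key}")
            if sd < 0:
                raise ConfigError(f"negative sd for cell {key}")
            if n < 2:
                raise ConfigError(f"cell {key} needs >= 2 replicates")


def simulate_uptake(cfg: UptakeSimConfig) -> pd.DataFrame:
    """Draw replicate values; returns tidy (genotype, condition, value) rows."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for (genotype, condition), (mean, sd, n) in cfg.cells.items():
        if sd == 0:
            values = np.full(n, mean)
        else:
            a = (0.0 - mean) / sd  # truncate at zero
            values = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                         size=n, random_state=rng)
        for v in values:
            rows.append({"genotype": genotype, "condition": condition,
                         "value": float(v)})
    return pd.DataFrame(rows, columns=["genotype", "condition", "value"])


# ---------------------------------------------------------------------------
# behavioral scores

_CRITERIA = ("persistence", "motivation", "compulsivity")

# Operant-score scales: persistence = non-reinforced active responses in the
# pellet-free period, motivation = progressive-ratio breaking point,
# compulsivity = shocks endured. Means/covariance are plausible for mice on a
# long fixed-ratio-5 schedule; both genotypes share the distribution by
# default (no genotype effect on the raw criterion scores).
_DEFAULT_SCORE_MEAN = (30.0, 35.0, 10.0)
_DEFAULT_SCORE_COV = (
    (100.0, 30.0, 10.0),
    (30.0, 144.0, 12.0),
    (10.0, 12.0, 16.0),
)


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Per-animal (persistence, motivation, compulsivity) scores drawn from a
    genotype-specific multivariate normal, floored at zero."""

    n_per_genotype: int = 14
    mean_by_genotype: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"WT": _DEFAULT_SCORE_MEAN,
                                 "T8I": _DEFAULT_SCORE_MEAN})
    cov_by_genotype: dict[str, tuple] = field(
        default_factory=lambda: {"WT": _DEFAULT_SCORE_COV,
                                 "T8I": _DEFAULT_SCORE_COV})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_genotype < 0:
            raise ConfigError("n_per_genotype must be non-negative")
        if set(self.mean_by_genotype) != set(self.cov_by_genotype):
            raise ConfigError("mean and covariance genotype sets differ")
        for g, cov in self.cov_by_genotype.items():
            c = np.asarray(cov, dtype=float)
            if c.shape != (3, 3) or not np.allclose(c, c.T):
                raise ConfigError(f"covariance for {g!r} must be symmetric 3x3")
            if np.min(np.linalg.eigvalsh(c)) < -1e-9:
                raise ConfigError(f"covariance for {g!r} must be PSD")


def simulate_behavior_scores(cfg: BehaviorSimConfig) -> pd.DataFrame:
    """Per-animal score table: (animal, genotype, persistence, motivation,
    compulsivity)."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for genotype in cfg.mean_by_genotype:
        mean = np.asarray(cfg.mean_by_genotype[genotype], dtype=float)
        cov = np.asarray(cfg.cov_by_genotype[genotype], dtype=float)
        scores = rng.multivariate_normal(mean, cov, size=cfg.n_per_genotype,
                                         method="cholesky" if
                                         np.min(np.linalg.eigvalsh(cov)) > 0
                                         else "eigh")
        scores = np.maximum(scores, 0.0)
        for i, row in enumerate(scores):
            rows.append({"animal": f"{genotype}-{i + 1:03d}", "genotype": genotype,
                         **dict(zip(_CRITERIA, map(float, row)))})
    return pd.DataFrame(rows, columns=["animal", "genotype", *_CRITERIA])
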