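"""Seeded synthetic droplet trains, fluorescence evolution, spectrometer
frame streams, and hyphal-exit outcomes.

This module is the stand-in for the physical screening platform: a
T-junction droplet generator emitting ~1 nL water-in-oil droplets at a few
hertz, single fungal spores encapsulated at a Poisson mean occupancy
(lambda = spore concentration x droplet volume, 0.35 by default), multi-day
incubation during which glycoside-hydrolase activity linearly accumulates
fluorescein from a fluorogenic substrate, and a fibre-coupled
mini-spectrometer that sees each droplet transit as a Gaussian emission
band near 515 nm riding on excitation bleed-through near 470 nm.

Reproducibility contract: every stochastic draw is keyed on the top-level
seed; per-droplet attributes use a substream keyed on ``(seed, droplet id,
purpose)`` so that results do not depend on evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .sigproc import SpectralStream

__all__ = [
    "Media",
    "Substrate",
    "SimConfig",
    "DropletRecord",
    "DetectorModel",
    "MEDIA_EXIT_PARAMS",
    "occupancy_from_concentration",
    "generate_droplet_train",
    "generate_calibration_train",
    "mark_true_positives",
    "incubation_fluorescence",
    "synthesize_stream",
    "hyphal_exit_process",
]


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


class Media(str, Enum):
    """Incubation media for solid-state droplet fermentation."""

    MM = "MM"  # minimal media, no carbon source
    G1 = "G1"  # 1% glucose
    CC1_G1 = "CC1_G1"  # 1% colloidal chitin + 1% glucose
    CC1_G01 = "CC1_G01"  # 1% colloidal chitin + 0.1% glucose
    CCMM = "CCMM"  # colloidal chitin minimal media


class Substrate(str, Enum):
    """Fluorogenic substrates releasing fluorescein on cleavage."""

    FL_GLCNAC = "FL_GlcNAc"  # exo-chitinase reporter
    FL_GALNAC = "FL_GalNAc"  # N-acetylgalactosaminidase reporter
    FD_GLC = "FD_Glc"  # beta-glucanase / glucosidase reporter


#: Media-dependent hyphal-exit kinetics: (onset delay [h], exponential
#: rate after onset [1/h]).  Glucose-only media shows exits from 24 h on;
#: colloidal chitin acts as structural support and delays first exits to
#: ~96 h when little glucose is present.
MEDIA_EXIT_PARAMS: dict[Media, tuple[float, float]] = {
    Media.G1: (24.0, 0.05),
    Media.CC1_G1: (36.0, 0.02),
    Media.CC1_G01: (96.0, 0.01),
    Media.MM: (96.0, 0.01),
    Media.CCMM: (96.0, 0.008),
}

# substream purpose keys for per-droplet generators
_KEY_ATTRS = 0
_KEY_EXIT = 1
_KEY_ROUTE = 2


def occupancy_from_concentration(concentration_per_ml: float, volume_nl: float) -> float:
    """Poisson mean occupancy: spores/mL x droplet volume (1 nL = 1e-6 mL)."""
    if concentration_per_ml < 0 or volume_nl < 0:
        raise ConfigurationError("concentration and volume must be >= 0")
    return concentration_per_ml * volume_nl * 1e-6


@dataclass
class SimConfig:
    """Study conditions for one simulated screening session.

    Defaults reproduce the platform's operating point: 7 droplets/s, 1 nL
    droplets, Poisson occupancy lambda = 0.35, 5% volume CV at generation
    growing with incubation, chitin-based media.  If ``spore_concentration``
    (spores/mL) is given, ``occupancy_lambda`` is derived from it and the
    mean droplet volume.
    """

    session_length: float  # s
    droplet_rate: float = 7.0  # droplets / s
    occupancy_lambda: float = 0.35
    spore_concentration: float | None = None  # spores / mL
    droplet_volume_mean: float = 1.0  # nL
    volume_cv: float = 0.05
    cv_growth_per_day: float = 0.08  # extra volume CV per day of incubation
    incubation_time: float = 0.0  # h
    media: Media = Media.CCMM
    substrate: Substrate = Substrate.FL_GLCNAC
    mutant_fraction: float = 1.0
    substrate_background_uM: float = 0.5
    substrate_ceiling_uM: float = 100.0  # in-droplet substrate concentration
    wt_activity_median: float = 0.3  # uM fluorescein / h for a wild-type clone
    wt_activity_sigma: float = 0.5  # lognormal sigma of clone-to-clone activity
    mutant_sigma: float = 1.0  # lognormal sigma of the mutant multiplier
    arrival_process: str = "jittered"  # 'regular' | 'jittered' | 'poisson'
    arrival_jitter_frac: float = 0.1  # sd of arrival jitter / mean spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.media, str):
            self.media = Media(self.media)
        if isinstance(self.substrate, str):
            self.substrate = Substrate(self.substrate)
        if self.session_length <= 0 or self.droplet_rate <= 0:
            raise ConfigurationError("session length and droplet rate must be > 0")
        if self.droplet_volume_mean <= 0 or self.volume_cv < 0:
            raise ConfigurationError("volumes must be > 0 and CV >= 0")
        if self.spore_concentration is not None:
            self.occupancy_lambda = occupancy_from_concentration(
                self.spore_concentration, self.droplet_volume_mean
            )
        if self.occupancy_lambda < 0:
            raise ConfigurationError("occupancy_lambda must be >= 0")
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ConfigurationError("mutant_fraction must lie in [0, 1]")
        if self.incubation_time < 0:
            raise ConfigurationError("incubation_time must be >= 0")
        if self.arrival_process not in ("regular", "jittered", "poisson"):
            raise ConfigurationError(
                "arrival_process must be 'regular', 'jittered' or 'poisson'"
            )

    @property
    def effective_volume_cv(self) -> float:
        """Volume CV after incubation-driven polydispersity growth."""
        return self.volume_cv + self.cv_growth_per_day * self.incubation_time / 24.0


@dataclass
class DropletRecord:
    """Ground truth for one droplet, from generation through routing."""

    id: int
    arrival_time: float  # s, at the detection point
    volume: float  # nL
    n_spores: int
    activity_rate: float  # uM fluorescein / h
    fluorescein_conc: float  # uM at reinjection
    true_positive: bool = False
    hyphal_exit_time: float | None = None  # h post-incubation start
    routed_channel: str = "unrouted"  # main|disfavored|merged|burst|unrouted
    failure_mode: str = "none"  # none|E1|E2|E3

    def __post_init__(self) -> None:
        if self.n_spores < 0:
            raise ValueError("n_spores must be >= 0")
        if self.fluorescein_conc < 0:
            raise ValueError("fluorescein_conc must be >= 0")


@dataclass
class DetectorModel:
    """Optical model of the fibre-coupled spectrometer.

    The grid spans 450-650 nm at 0.5 nm, covering the 500-600 nm recording
    band plus the 470 nm excitation bleed-through.  Fluorescein emission is
    a Gaussian band at 515 nm (sd 15 nm) with amplitude ``rfu_per_uM`` x
    concentration; every droplet transit additionally scatters excitation
    light into a bleed-through band at 470 nm, which is what makes empty
    droplets countable.
    """

    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(450.0, 650.0 + 0.25, 0.5)
    )
    frame_period: float = 0.010  # s (integration time per frame)
    dark_spectrum: np.ndarray | None = None  # defaults to flat dark_level
    dark_level: float = 100.0  # RFU
    noise_sd: float = 5.0  # RFU
    emission_center: float = 515.0  # nm
    emission_width_sd: float = 15.0  # nm
    bleedthrough_center: float = 470.0  # nm
    bleedthrough_amplitude: float = 60.0  # RFU
    bleedthrough_width_sd: float = 8.0  # nm
    rfu_per_uM: float = 20.0
    transit_fraction: float = 0.4  # transit duration / mean droplet spacing

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        if np.any(np.diff(self.wavelength_grid) <= 0):
            raise ConfigurationError("wavelength grid must be strictly increasing")
        if self.frame_period <= 0:
            raise ConfigurationError("frame_period must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.dark_spectrum is None:
            self.dark_spectrum = np.full(self.wavelength_grid.size, self.dark_level)
        else:
            self.dark_spectrum = np.asarray(self.dark_spectrum, dtype=float)
            if self.dark_spectrum.size != self.wavelength_grid.size:
                raise ConfigurationError("dark spectrum is on a different grid")


def _droplet_rng(seed: int, droplet_id: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, droplet_id, purpose)))


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _arrival_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spacing = 1.0 / config.droplet_rate
    n = int(math.floor(config.session_length * config.droplet_rate))
    if config.arrival_process == "poisson":
        gaps = rng.exponential(spacing, size=4 * n + 16)
        times = np.cumsum(gaps)
        return times[times < config.session_length]
    base = (np.arange(n) + 0.5) * spacing
    if config.arrival_process == "regular":
        return base
    sd = config.arrival_jitter_frac * spacing
    jitter = np.clip(rng.normal(0.0, sd, size=n), -3.5 * sd, 3.5 * sd)
    return base + jitter


def generate_droplet_train(config: SimConfig) -> list[DropletRecord]:
    """Generate one seeded droplet train with ground-truth attributes.

    Arrivals follow the configured process (quasi-regular with timing
    jitter by default, matching the near-periodic output of a T-junction;
    a homogeneous Poisson mode is available but allows physically
    overlapping transits at high rates).  Occupancy is Poisson, volumes
    lognormal, and occupied droplets draw a lognormal activity rate; a
    ``mutant_fraction`` of clones additionally draws a heavy-tailed
    (lognormal) activity multiplier, producing the right-skewed intensity
    populations characteristic of UV-mutagenised libraries.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA221)))
    arrivals = _arrival_times(config, rng)
    mu_v, sd_v = _lognormal_params(config.droplet_volume_mean, max(config.effective_volume_cv, 1e-12))
    # clone activity is lognormal with the configured median and sigma
    mu_a = math.log(config.wt_activity_median)
    sd_a = config.wt_activity_sigma
    train: list[DropletRecord] = []
    for i, t in enumerate(arrivals):
        r = _droplet_rng(config.seed, i, _KEY_ATTRS)
        n_spores = int(r.poisson(config.occupancy_lambda))
        volume = float(r.lognormal(mu_v, sd_v))
        if n_spores > 0:
            activity = float(r.lognormal(mu_a, sd_a))
            if r.random() < config.mutant_fraction:
                activity *= float(r.lognormal(0.0, config.mutant_sigma))
        else:
            activity = 0.0
        rec = DropletRecord(
            id=i,
            arrival_time=float(t),
            volume=volume,
            n_spores=n_spores,
            activity_rate=activity,
            fluorescein_conc=0.0,
        )
        rec.fluorescein_conc = incubation_fluorescence(rec, config)
        train.append(rec)
    return train


def generate_calibration_train(
    n_droplets: int,
    droplet_rate: float = 2.0,
    positive_conc_uM: float = 5.0,
    negative_conc_uM: float = 0.0,
    positive_fraction: float = 0.5,
    seed: int = 0,
    arrival_process: str = "regular",
) -> list[DropletRecord]:
    """Mixed standards train: fluorescein droplets vs dye-only droplets.

    Emulates sorter-calibration experiments in which droplets of a known
    fluorescein concentration are mixed with 0 uM (blue-dyed) droplets, so
    the true class of every droplet is known by construction.
    """
    if n_droplets < 1 or droplet_rate <= 0:
        raise ConfigurationError("need n_droplets >= 1 and droplet_rate > 0")
    cfg = SimConfig(
        session_length=n_droplets / droplet_rate,
        droplet_rate=droplet_rate,
        occupancy_lambda=0.0,
        arrival_process=arrival_process,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA11)))
    arrivals = _arrival_times(cfg, rng)[:n_droplets]
    train = []
    for i, t in enumerate(arrivals):
        r = _droplet_rng(seed, i, _KEY_ATTRS)
        positive = bool(r.random() < positive_fraction)
        conc = positive_conc_uM if positive else negative_conc_uM
        train.append(
            DropletRecord(
                id=i,
                arrival_time=float(t),
                volume=float(r.lognormal(*_lognormal_params(1.0, 0.05))),
                n_spores=0,
                activity_rate=0.0,
                fluorescein_conc=conc,
                true_positive=positive,
            )
        )
    return train


def mark_true_positives(train: Sequence[DropletRecord], threshold_uM: float) -> None:
    """Label droplets whose fluorescein concentration exceeds a threshold."""
    for rec in train:
        rec.true_positive = rec.fluorescein_conc > threshold_uM


def incubation_fluorescence(record: DropletRecord, config: SimConfig) -> float:
    """Fluorescein concentration (uM) after incubation.

    Enzymatic cleavage accumulates fluorescein linearly at the clone's
    activity rate, on top of the substrate's intrinsic background, and
    saturates at the in-droplet substrate concentration.  Empty droplets
    return background only.
    """
    if config.incubation_time < 0:
        raise ConfigurationError("incubation_time must be >= 0")
    conc = config.substrate_background_uM + record.activity_rate * config.incubation_time
    return float(min(conc, config.substrate_ceiling_uM))


def synthesize_stream(
    train: Sequence[DropletRecord],
    detector: DetectorModel,
    session_length: float | None = None,
    transit_time: float | None = None,
    droplet_rate: float | None = None,
    seed: int = 0,
) -> SpectralStream:
    """Render a droplet train into a spectrometer frame stream.

    Baseline frames contain the dark spectrum plus Gaussian read noise.
    During each droplet's transit (a rectangular pulse of duration
    ``transit_time``, default ``transit_fraction`` x the mean droplet
    spacing) frames additionally carry the droplet's emission band and the
    excitation bleed-through band.  The same seed reproduces the stream
    bit for bit.
    """
    arrivals = np.array([rec.arrival_time for rec in train], dtype=float)
    if arrivals.size > 1 and np.any(np.diff(arrivals) <= 0):
        raise ValueError("train must be sorted by arrival time")
    if droplet_rate is None:
        if arrivals.size > 1:
            droplet_rate = 1.0 / float(np.mean(np.diff(arrivals)))
        else:
            droplet_rate = 7.0
    if transit_time is None:
        transit_time = detector.transit_fraction / droplet_rate
    if session_length is None:
        session_length = (float(arrivals[-1]) if arrivals.size else 0.0) + 2 * transit_time
    n_frames = int(math.ceil(session_length / detector.frame_period))
    if n_frames < 1:
        n_frames = 1
    grid = detector.wavelength_grid
    times = np.arange(n_frames) * detector.frame_period
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x57E4)))
    frames = rng.standard_normal((n_frames, grid.size))
    frames *= detector.noise_sd
    frames += detector.dark_spectrum[None, :]
    emission_shape = np.exp(
        -((grid - detector.emission_center) ** 2) / (2.0 * detector.emission_width_sd**2)
    )
    bleed = detector.bleedthrough_amplitude * np.exp(
        -((grid - detector.bleedthrough_center) ** 2)
        / (2.0 * detector.bleedthrough_width_sd**2)
    )
    for rec in train:
        first = int(math.ceil(rec.arrival_time / detector.frame_period))
        last = int(math.floor((rec.arrival_time + transit_time) / detector.frame_period))
        if last >= n_frames:
            last = n_frames - 1
        if first > last:
            continue
        band = bleed + (detector.rfu_per_uM * rec.fluorescein_conc) * emission_shape
        frames[first : last + 1] += band[None, :]
    return SpectralStream(times=times, intensities=frames, wavelengths=grid)


def hyphal_exit_process(
    train: Sequence[DropletRecord],
    config: SimConfig,
) -> list[float | None]:
    """Assign a time-to-hyphal-exit (h) to each occupied droplet.

    Exit times are onset-delayed exponentials with media-dependent
    parameters (``MEDIA_EXIT_PARAMS``): no droplet exits before the
    media's onset delay, and empty droplets never exit.  The assigned
    times are also stored on the records.
    """
    try:
        onset, rate = MEDIA_EXIT_PARAMS[config.media]
    except KeyError:
        raise ConfigurationError(f"unknown media {config.media!r}") from None
    out: list[float | None] = []
    for rec in train:
        if rec.n_spores == 0:
            rec.hyphal_exit_time = None
        else:
            r = _droplet_rng(config.seed, rec.id, _KEY_EXIT)
            rec.hyphal_exit_time = onset + float(r.exponential(1.0 / rate))
        out.append(rec.hyphal_exit_time)
    return out
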