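"""Synthetic simulated-strike trials with the statistical structure of field data.

The generator emulates one strike-simulator trial per individual: the animal
either jumps or scrambles (Bernoulli on a species-specific jump propensity),
with reaction and take-off times drawn from truncated normal distributions
whose moments are the per-species field estimates (SD recovered from the
printed standard error as ``se * sqrt(n)``). For jumps, a latent take-off
speed and angle are drawn and projected through the level-ground ballistic
model to give airborne time and horizontal displacement, so every generated
jump satisfies the reconstruction equations exactly before measurement noise.

Measurement noise mimics the field protocol: displacement is rounded to the
nearest centimetre (tape measure), and all timed quantities are snapped to
the species' video frame grid with a uniform +/-2-frame digitization jitter.
Censoring flags (hit by the cork, premature reaction, landed off-screen,
poor video) null the fields the corresponding field failure would lose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .kinematics import forward_ballistics

__all__ = [
    "KNOWN_SPECIES",
    "TRIAL_COLUMNS",
    "SpeciesProfile",
    "CensoringRates",
    "default_profiles",
    "default_censoring",
    "generate_trials",
]

#: Species codes the study covers (three kangaroo rats, a pocket mouse,
#: a woodrat and a ground squirrel).
KNOWN_SPECIES = ("DIME", "DIDE", "DISP", "CHPE", "NEAL", "OTBE")

#: Fixed CSV header of a trial table.
TRIAL_COLUMNS = [
    "species",
    "individual_id",
    "mass_g",
    "fps",
    "mode",
    "reaction_ms",
    "takeoff_ms",
    "displacement_m",
    "airborne_s",
    "hit_by_cork",
    "premature",
    "offscreen",
    "poor_video",
]

#: Reaction times below this are physiologically implausible; the truncation
#: floor for the reaction-time distribution (ms).
REACTION_FLOOR_MS = 4.0

_VALID_FPS = (120, 240, 250)


@dataclass(frozen=True)
class SpeciesProfile:
    """Generative parameters for one species.

    Moments are mean and standard error; ``n_reference`` holds the per-metric
    sample sizes those moments were estimated from, so the generator can
    recover per-animal SDs as ``se * sqrt(n)``. Jump-performance moments
    (speed, angle) are ``None`` for species that effectively never jump.
    Optional mode-specific take-off means let jump and scramble maneuvers
    differ in speed, as observed for Merriam's kangaroo rats.
    """

    species_code: str
    mass_mean_g: float
    mass_se_g: float
    jump_propensity: float
    reaction_mean_ms: float
    reaction_se_ms: float
    takeoff_mean_ms: float
    takeoff_se_ms: float
    fps: int
    n_reference: dict = field(default_factory=dict)
    takeoff_speed_mean_ms1: float | None = None
    takeoff_speed_se_ms1: float | None = None
    angle_mean_deg: float | None = None
    angle_se_deg: float | None = None
    takeoff_jump_mean_ms: float | None = None
    takeoff_scramble_mean_ms: float | None = None

    def __post_init__(self) -> None:
        if self.species_code not in KNOWN_SPECIES:
            raise ValueError(
                f"unknown species_code {self.species_code!r}; "
                f"expected one of {KNOWN_SPECIES}"
            )
        if not 0.0 <= self.jump_propensity <= 1.0:
            raise ValueError(
                f"jump_propensity must be in [0, 1], got {self.jump_propensity!r}"
            )
        if self.fps not in _VALID_FPS:
            raise ValueError(f"fps must be one of {_VALID_FPS}, got {self.fps!r}")
        for name in (
            "mass_mean_g",
            "mass_se_g",
            "reaction_mean_ms",
            "reaction_se_ms",
            "takeoff_mean_ms",
            "takeoff_se_ms",
            "takeoff_speed_mean_ms1",
            "takeoff_speed_se_ms1",
            "angle_mean_deg",
            "angle_se_deg",
        ):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise ValueError(f"{name} must be > 0 when present, got {val!r}")

    def sd(self, metric: str, se: float) -> float:
        """Per-animal SD for ``metric``: se * sqrt(n_reference[metric])."""
        n = self.n_reference.get(metric, 1)
        return se * float(np.sqrt(n))

    @property
    def has_jump_performance(self) -> bool:
        return (
            self.takeoff_speed_mean_ms1 is not None and self.angle_mean_deg is not None
        )


@dataclass(frozen=True)
class CensoringRates:
    """Per-trial probabilities of the four field data-loss events."""

    p_hit_by_cork: float = 0.0
    p_premature_react: float = 0.0
    p_offscreen: float = 0.0
    p_poor_video: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_hit_by_cork",
            "p_premature_react",
            "p_offscreen",
            "p_poor_video",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val!r}")


def _load_default_config() -> dict:
    text = (
        resources.files("escapekin").joinpath("data/default_profiles.yaml").read_text()
    )
    return yaml.safe_load(text)


def default_profiles() -> list[SpeciesProfile]:
    """The packaged six-species profile set estimated from the field study."""
    cfg = _load_default_config()
    return [SpeciesProfile(**entry) for entry in cfg["species"]]


def default_censoring() -> CensoringRates:
    """The packaged field-realistic censoring rates."""
    return CensoringRates(**_load_default_config()["censoring"])


def profiles_from_yaml(path) -> tuple[list[SpeciesProfile], CensoringRates]:
    """Load profiles (and censoring rates, if present) from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    profiles = [SpeciesProfile(**entry) for entry in cfg["species"]]
    censoring = CensoringRates(**cfg.get("censoring", {}))
    return profiles, censoring


def _truncnorm(rng, mean, sd, lower=-np.inf, upper=np.inf, size=None):
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _quantize_ms(rng, value_ms: float, fps: int, min_frames: int = 0) -> float:
    """Snap a time to the frame grid and add the +/-2-frame digitization jitter."""
    period = 1000.0 / fps
    frames = round(value_ms / period) + rng.integers(-2, 3)
    return max(frames, min_frames) * period


def generate_trials(
    profiles: list[SpeciesProfile],
    n_per_species: int,
    censoring: CensoringRates | None = None,
    seed: int = 0,
    measurement_noise: bool = True,
) -> pd.DataFrame:
    """Simulate ``n_per_species`` strike trials for each species profile.

    Each row is one individual (animals are tested once). With
    ``measurement_noise=False`` the rows carry the latent, un-digitized
    values, so every jump's (displacement, airborne time) pair inverts
    exactly to its latent (speed, angle) under the ballistic model.

    Deterministic: identical inputs and seed give a byte-identical table.
    """
    if n_per_species < 1:
        raise ValueError(f"n_per_species must be >= 1, got {n_per_species}")
    censoring = censoring or CensoringRates()
    # one independent substream per trial: the latent draws of a trial do not
    # depend on how many random variates other trials consumed (so e.g. the
    # same seed with noise on/off yields the same latent animals)
    children = np.random.SeedSequence(seed).spawn(len(profiles) * n_per_species)
    rows = []
    for p_idx, prof in enumerate(profiles):
        for i in range(n_per_species):
            rng = np.random.default_rng(children[p_idx * n_per_species + i])
            rows.append(_one_trial(rng, prof, i, censoring, measurement_noise))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _one_trial(rng, prof, index, censoring, noise):
    jumped = rng.random() < prof.jump_propensity
    mode = "jump" if jumped else "scramble"

    mass = _truncnorm(rng, prof.mass_mean_g, prof.sd("mass", prof.mass_se_g), lower=0.0)
    reaction = _truncnorm(
        rng,
        prof.reaction_mean_ms,
        prof.sd("reaction", prof.reaction_se_ms),
        lower=REACTION_FLOOR_MS,
    )
    if jumped and prof.takeoff_jump_mean_ms is not None:
        takeoff_mean = prof.takeoff_jump_mean_ms
    elif not jumped and prof.takeoff_scramble_mean_ms is not None:
        takeoff_mean = prof.takeoff_scramble_mean_ms
    else:
        takeoff_mean = prof.takeoff_mean_ms
    takeoff = _truncnorm(
        rng, takeoff_mean, prof.sd("takeoff", prof.takeoff_se_ms), lower=0.0
    )

    displacement = airborne = None
    if jumped and prof.has_jump_performance:
        speed = _truncnorm(
            rng,
            prof.takeoff_speed_mean_ms1,
            prof.sd("speed", prof.takeoff_speed_se_ms1),
            lower=0.0,
        )
        angle = _truncnorm(
            rng,
            prof.angle_mean_deg,
            prof.sd("angle", prof.angle_se_deg),
            lower=0.0,
            upper=90.0,
        )
        obs = forward_ballistics(speed, angle)
        displacement = obs.horizontal_displacement_m
        airborne = obs.airborne_time_s

    if noise:
        reaction = _quantize_ms(rng, reaction, prof.fps)
        # movement to toe-off always spans at least one visible frame
        takeoff = _quantize_ms(rng, takeoff, prof.fps, min_frames=1)
        if displacement is not None:
            displacement = round(displacement, 2)
            # a scoreable jump spans at least one airborne frame
            airborne = _quantize_ms(rng, airborne * 1000.0, prof.fps, min_frames=1) / 1000.0

    hit = rng.random() < censoring.p_hit_by_cork
    premature = rng.random() < censoring.p_premature_react
    poor = rng.random() < censoring.p_poor_video
    # only an airborne animal can leave the frame
    offscreen = jumped and rng.random() < censoring.p_offscreen

    if hit or premature or poor:
        # first visible movement (or its timing) is unusable
        reaction = takeoff = None
    if offscreen:
        displacement = airborne = None

    return {
        "species": prof.species_code,
        "individual_id": f"{prof.species_code}-{index:04d}",
        "mass_g": mass,
        "fps": prof.fps,
        "mode": mode,
        "reaction_ms": reaction,
        "takeoff_ms": takeoff,
        "displacement_m": displacement,
        "airborne_s": airborne,
        "hit_by_cork": hit,
        "premature": premature,
        "offscreen": offscreen,
        "poor_video": poor,
    }
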