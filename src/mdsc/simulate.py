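"""Synthetic cerebral-palsy cohort generation.

The generator reproduces the joint structure the downstream analysis
assumes: an ordinal GMFCS severity level drives the GMFM-66 motor score,
and the motor score in turn drives which assistive devices a patient uses.

Model
-----
* GMFCS level ~ categorical with the study-population proportions
  (118/289/592/470/112 of 1581 for levels I-V).
* GMFM-66 | level ~ Normal(mean_level, sd) truncated to [0, 100], with
  strictly decreasing level means so severity maps onto motor ability.
* CP subtype | level ~ categorical per level (bilateral spastic dominant,
  unilateral spastic concentrated at level I, dyskinetic at level V).
* Device d | score s: independent Bernoulli with a Gaussian "usage bump"

      P(use d | s) = base_rate_d * exp(-(s - center_d)^2 / (2 width_d^2)),

  i.e. every device has a motor-ability niche.  Devices for the severely
  affected (passive wheelchair, seating shell) peak at low scores; devices
  requiring residual walking ability (therapy bike, shoe inserts) peak high.
* Age ~ Normal(8.1, 4.3) truncated to [2.2, 25.5] years, independent of
  level; sex ~ Bernoulli(female share of the study population).

The shipped default catalog is calibrated so the *realized* device-user
mean scores reproduce the published anchors (therapy bike 71.19, shoe
inserts 61.06, roller board 30.29, passive wheelchair 26.20 GMFM-66
points) and every base rate is solved numerically so the marginal usage
frequency hits its target under the score mixture, preserving the
published frequency ordering (transtibial orthoses first, active
wheelchair second, ...).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
import numpy as np
import yaml
from scipy.stats import truncnorm

from mdsc._rng import substream
from mdsc.cohort import SUBTYPES, Cohort, PatientRecord
from mdsc.errors import ConfigurationError

_PROB_TOL = 1e-9

#: Study-population GMFCS counts for levels I-V (total 1581).
GMFCS_COUNTS = (118, 289, 592, 470, 112)

#: Subtype percentages per GMFCS level, columns in SUBTYPES order
#: (bilateral, unilateral, dyskinetic, ataxic, mixed).  Rows are
#: renormalized at config build time (printed percentages round to 99.9
#: for level I).
_SUBTYPE_PCT_BY_LEVEL = (
    (50.0, 39.8, 2.5, 2.5, 5.1),
    (75.8, 12.1, 1.7, 4.2, 6.2),
    (82.1, 3.5, 3.7, 1.7, 9.0),
    (77.4, 1.5, 7.7, 1.1, 12.3),
    (60.7, 0.0, 22.3, 0.9, 16.1),
)

#: Default device catalog: (code, label, score_center, score_width,
#: target marginal usage frequency).  ``score_center`` is the ability level
#: at which usage peaks; because the score mixture pulls device-user means
#: toward the population center, the four anchored devices' peaks sit beyond
#: their published user means so the *realized* user means land on the
#: published values (therapy bike 71.19, shoe inserts 61.06, roller board
#: 30.29, passive wheelchair 26.20).  Target frequencies are the published
#: device-record shares scaled to patient-level rates (x2, ~1.8 devices per
#: patient) with the published frequency ordering preserved.
DEFAULT_DEVICE_TARGETS = (
    ("transtibial_orthosis", "Transtibial orthoses", 55.0, 22.0, 0.264),
    ("active_wheelchair", "Active wheelchair", 38.0, 14.0, 0.256),
    ("posterior_walker", "Posterior walker", 45.0, 12.0, 0.190),
    ("standing_frame", "Standing frame", 30.0, 14.0, 0.152),
    ("night_splint", "Night splints", 52.0, 18.0, 0.132),
    ("shoe_insert", "Shoe inserts", 71.0, 16.0, 0.125),
    ("passive_wheelchair", "Passive wheelchair", 18.0, 10.0, 0.125),
    ("hand_orthosis", "Hand orthoses", 47.0, 20.0, 0.116),
    ("roller_board", "Roller board", 25.0, 10.0, 0.115),
    ("therapy_bike", "Therapy bike with training wheels", 84.0, 14.0, 0.115),
    ("seating_shell", "Seating shell", 22.0, 9.0, 0.110),
    ("walking_frame", "Walking frame", 42.0, 12.0, 0.090),
)


@dataclass(frozen=True)
class DeviceProfile:
    """Usage model of one assistive device.

    ``score_center`` is the GMFM-66 value at which usage probability peaks,
    ``score_width`` the spread of the bump, and ``base_rate`` the peak
    usage probability.
    """

    code: str
    label: str
    base_rate: float
    score_center: float
    score_width: float

    def validate(self) -> None:
        if not (0.0 < self.base_rate <= 1.0):
            raise ConfigurationError(
                f"device {self.code!r}: base_rate must be in (0, 1], got {self.base_rate}"
            )
        if not (0.0 <= self.score_center <= 100.0):
            raise ConfigurationError(
                f"device {self.code!r}: score_center must be in [0, 100]"
            )
        if not self.score_width > 0:
            raise ConfigurationError(f"device {self.code!r}: score_width must be > 0")


@dataclass
class SimConfig:
    """Full parameterization of the cohort generator."""

    n_patients: int
    seed: int
    gmfcs_probs: tuple[float, ...]
    gmfm_level_means: tuple[float, ...]
    gmfm_level_sd: float
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    device_profiles: list[DeviceProfile]
    subtype_probs_by_level: tuple[tuple[float, ...], ...]
    female_prob: float = 656 / 1581

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        probs = np.asarray(self.gmfcs_probs, dtype=float)
        if probs.shape != (5,) or np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError("gmfcs_probs must be 5 probabilities in [0, 1]")
        if abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ConfigurationError(
                f"gmfcs_probs must sum to 1, got {probs.sum():.12f}"
            )
        means = np.asarray(self.gmfm_level_means, dtype=float)
        if means.shape != (5,):
            raise ConfigurationError("gmfm_level_means must have 5 entries")
        if not np.all(np.diff(means) < 0):
            raise ConfigurationError(
                "gmfm_level_means must be strictly decreasing from level I to V"
            )
        if self.gmfm_level_sd < 0:
            raise ConfigurationError("gmfm_level_sd must be >= 0")
        rows = np.asarray(self.subtype_probs_by_level, dtype=float)
        if rows.shape != (5, len(SUBTYPES)):
            raise ConfigurationError("subtype_probs_by_level must be a 5x5 matrix")
        if np.any(rows < 0) or np.any(rows > 1):
            raise ConfigurationError("subtype probabilities must be in [0, 1]")
        bad = np.abs(rows.sum(axis=1) - 1.0) > _PROB_TOL
        if np.any(bad):
            raise ConfigurationError(
                f"subtype rows for level(s) {np.flatnonzero(bad) + 1} do not sum to 1"
            )
        if not (0.0 <= self.female_prob <= 1.0):
            raise ConfigurationError("female_prob must be in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy min < max")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be > 0")
        for profile in self.device_profiles:
            profile.validate()
        codes = [p.code for p in self.device_profiles]
        if len(set(codes)) != len(codes):
            raise ConfigurationError("device codes must be unique")


def usage_probability(score, profile: DeviceProfile):
    """P(device used | GMFM-66 score): the Gaussian usage bump."""
    score = np.asarray(score, dtype=float)
    z = (score - profile.score_center) / profile.score_width
    return profile.base_rate * np.exp(-0.5 * z * z)


def _score_mixture_pdf(grid: np.ndarray, probs, means, sd: float) -> np.ndarray:
    dens = np.zeros_like(grid)
    for p, m in zip(probs, means):
        a, b = (0.0 - m) / sd, (100.0 - m) / sd
        dens += p * truncnorm.pdf(grid, a, b, loc=m, scale=sd)
    return dens


def expected_usage_frequency(profile: DeviceProfile, probs, means, sd: float) -> float:
    """Marginal P(device used) under the truncated-normal score mixture."""
    if sd == 0:
        return float(
            sum(p * usage_probability(m, profile) for p, m in zip(probs, means))
        )
    grid = np.linspace(0.0, 100.0, 2001)
    dens = _score_mixture_pdf(grid, probs, means, sd)
    return float(np.trapezoid(dens * usage_probability(grid, profile), grid))


def calibrated_device_profiles(
    probs, means, sd: float, targets=DEFAULT_DEVICE_TARGETS
) -> list[DeviceProfile]:
    """Solve each base rate so the marginal usage frequency hits its target.

    The bump shape is fixed; only the peak height is scaled, so the
    device-user score distribution (and hence the user-mean ordering) is
    unaffected by the calibration.
    """
    profiles = []
    for code, label, center, width, freq in targets:
        shape = DeviceProfile(code, label, 1.0, center, width)
        achievable = expected_usage_frequency(shape, probs, means, sd)
        base = min(1.0, freq / achievable)
        profiles.append(replace(shape, base_rate=base))
    return profiles


def default_config(n_patients: int = 1581, seed: int = 0) -> SimConfig:
    """The shipped default configuration, calibrated to the study
    population's printed marginals."""
    total = sum(GMFCS_COUNTS)
    probs = tuple(c / total for c in GMFCS_COUNTS)
    means = (85.0, 65.0, 50.0, 35.0, 15.0)
    sd = 8.0
    rows = tuple(
        tuple(v / sum(row) for v in row) for row in _SUBTYPE_PCT_BY_LEVEL
    )
    cfg = SimConfig(
        n_patients=n_patients,
        seed=seed,
        gmfcs_probs=probs,
        gmfm_level_means=means,
        gmfm_level_sd=sd,
        age_mean=8.1,
        age_sd=4.3,
        age_range=(2.2, 25.5),
        device_profiles=calibrated_device_profiles(probs, means, sd),
        subtype_probs_by_level=rows,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Samplers.  Each takes an explicit Generator so callers control the stream.
# ---------------------------------------------------------------------------

def sample_gmfcs(config: SimConfig, rng: np.random.Generator, size=None):
    """Draw GMFCS level(s) 1-5 with the configured probabilities."""
    probs = np.asarray(config.gmfcs_probs, dtype=float)
    if abs(probs.sum() - 1.0) > _PROB_TOL or np.any(probs < 0):
        raise ConfigurationError("invalid gmfcs probability vector")
    out = rng.choice(np.arange(1, 6), p=probs, size=size)
    return out if size is not None else int(out)


def sample_gmfm_given_gmfcs(
    level: int, config: SimConfig, rng: np.random.Generator, size=None
):
    """Draw GMFM-66 score(s) from the level's truncated normal."""
    if level not in (1, 2, 3, 4, 5):
        raise ConfigurationError(f"level must be in 1..5, got {level}")
    m = float(config.gmfm_level_means[level - 1])
    sd = float(config.gmfm_level_sd)
    if sd == 0:
        return np.full(size, m) if size is not None else m
    a, b = (0.0 - m) / sd, (100.0 - m) / sd
    out = truncnorm.rvs(a, b, loc=m, scale=sd, size=size, random_state=rng)
    return out if size is not None else float(out)


def sample_subtype_given_gmfcs(
    level: int, config: SimConfig, rng: np.random.Generator, size=None
):
    """Draw CP subtype(s) with the level-conditional probabilities."""
    if level not in (1, 2, 3, 4, 5):
        raise ConfigurationError(f"level must be in 1..5, got {level}")
    row = np.asarray(config.subtype_probs_by_level[level - 1], dtype=float)
    if abs(row.sum() - 1.0) > _PROB_TOL or np.any(row < 0):
        raise ConfigurationError(f"subtype row for level {level} does not sum to 1")
    idx = rng.choice(len(SUBTYPES), p=row, size=size)
    if size is None:
        return SUBTYPES[int(idx)]
    return np.array(SUBTYPES, dtype=object)[idx]


def sample_devices(
    score: float, config: SimConfig, rng: np.random.Generator
) -> frozenset[str]:
    """Draw the device set for one patient: independent Bernoulli per
    profile with the Gaussian-bump probability.  May be empty."""
    if not (0.0 <= score <= 100.0):
        raise ConfigurationError(f"score must be in [0, 100], got {score}")
    u = rng.random(len(config.device_profiles))
    return frozenset(
        p.code
        for p, x in zip(config.device_profiles, u)
        if x < usage_probability(score, p)
    )


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a full cohort.  Deterministic given ``config.seed``.

    Per-stage sub-streams (level, score, subtype, devices, age, sex) are
    derived from the single seed with fixed offsets, so stages never
    perturb each other's draws.
    """
    config.validate()
    n = config.n_patients

    levels = sample_gmfcs(config, substream(config.seed, 0), size=n)

    scores = np.empty(n, dtype=float)
    rng_score = substream(config.seed, 1)
    subtypes = np.empty(n, dtype=object)
    rng_sub = substream(config.seed, 2)
    for level in (1, 2, 3, 4, 5):
        mask = levels == level
        k = int(mask.sum())
        if k:
            scores[mask] = np.atleast_1d(
                sample_gmfm_given_gmfcs(level, config, rng_score, size=k)
            )
            subtypes[mask] = sample_subtype_given_gmfcs(level, config, rng_sub, size=k)

    profiles = config.device_profiles
    prob = np.column_stack([usage_probability(scores, p) for p in profiles])
    used = substream(config.seed, 3).random((n, len(profiles))) < prob

    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    ages = truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n,
        random_state=substream(config.seed, 4),
    )
    female = substream(config.seed, 5).random(n) < config.female_prob

    codes = [p.code for p in profiles]
    records = [
        PatientRecord(
            patient_id=f"P{i:05d}",
            age=float(ages[i]),
            sex="female" if female[i] else "male",
            cp_subtype=str(subtypes[i]),
            gmfcs=int(levels[i]),
            gmfm66=float(scores[i]),
            devices=frozenset(c for c, u in zip(codes, used[i]) if u),
        )
        for i in range(n)
    ]
    labels = {p.code: p.label for p in profiles}
    return Cohort.from_records(records, labels=labels)


# ---------------------------------------------------------------------------
# YAML configuration round-trip.
# ---------------------------------------------------------------------------

def config_to_dict(config: SimConfig) -> dict:
    return {
        "n_patients": config.n_patients,
        "seed": config.seed,
        "gmfcs_probs": [float(p) for p in config.gmfcs_probs],
        "gmfm_level_means": [float(m) for m in config.gmfm_level_means],
        "gmfm_level_sd": float(config.gmfm_level_sd),
        "age_mean": float(config.age_mean),
        "age_sd": float(config.age_sd),
        "age_range": [float(config.age_range[0]), float(config.age_range[1])],
        "female_prob": float(config.female_prob),
        "subtype_probs_by_level": [
            [float(v) for v in row] for row in config.subtype_probs_by_level
        ],
        "device_profiles": [
            {
                "code": p.code,
                "label": p.label,
                "base_rate": float(p.base_rate),
                "score_center": float(p.score_center),
                "score_width": float(p.score_width),
            }
            for p in config.device_profiles
        ],
    }


def config_from_dict(data: dict) -> SimConfig:
    try:
        cfg = SimConfig(
            n_patients=int(data["n_patients"]),
            seed=int(data["seed"]),
            gmfcs_probs=tuple(data["gmfcs_probs"]),
            gmfm_level_means=tuple(data["gmfm_level_means"]),
            gmfm_level_sd=float(data["gmfm_level_sd"]),
            age_mean=float(data["age_mean"]),
            age_sd=float(data["age_sd"]),
            age_range=(float(data["age_range"][0]), float(data["age_range"][1])),
            device_profiles=[DeviceProfile(**p) for p in data["device_profiles"]],
            subtype_probs_by_level=tuple(
                tuple(row) for row in data["subtype_probs_by_level"]
            ),
            female_prob=float(data.get("female_prob", 656 / 1581)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed simulation config: {exc}") from exc
    cfg.validate()
    return cfg


def save_config(config: SimConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    return config_from_dict(data)


def packaged_default_config() -> SimConfig:
    """Load the default configuration shipped inside the package."""
    ref = importlib.resources.files("mdsc").joinpath("data/default_config.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return config_from_dict(data)
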