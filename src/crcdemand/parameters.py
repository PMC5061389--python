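"""Model probabilities, their priors, and per-run sampling.

Every screening-chain probability (exclusion, opportunistic screening,
participation, FIT positivity, colonoscopy refusal) is a *probabilistic
parameter*: before each simulation run one value per stratum is drawn from a
prior distribution, and individuals then face Bernoulli trials at that value.
Strata combine gender with the age groups 50-54, 55-59, 60-64 and 65-69.
Adherence to successive surveillance colonoscopies is drawn once per run from
a uniform prior and held constant within the run.

Colonoscopy result distributions are empirical and held fixed (point masses):
the model does not represent the natural history of colorectal neoplasia, so
test results come from observed category shares, not from sensitivity and
specificity on latent disease.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

log = logging.getLogger(__name__)

GENDERS = ("male", "female")
AGE_GROUPS = ("50-54", "55-59", "60-64", "65-69")
N_STRATA = len(GENDERS) * len(AGE_GROUPS)

#: index colonoscopy outcome categories (European-guideline classification)
RESULT_CATEGORIES = ("negative", "low_risk", "intermediate_risk", "high_risk", "cancer")
#: surveillance outcome categories (intermediate and high risk merged)
SURV_CATEGORIES = ("negative", "low_risk", "intermediate_high_risk", "cancer")

#: default re-invitation intervals in years, by reason
DEFAULT_REINVITE = {
    "non_participation": 2,
    "negative_fit": 2,
    "refusal": 2,
    "low_risk_adenoma": 2,
    "opportunistic_3_5y": 2,
    "opportunistic_le_3y": 4,
    "negative_index_colonoscopy": 10,
}


def stratum_of(gender: np.ndarray, age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map gender codes (0 male, 1 female) and ages to (gender, age-group) indices."""
    grp = np.clip(((np.asarray(age) - 50.0) // 5).astype(np.intp), 0, 3)
    return np.asarray(gender, dtype=np.intp), grp


# ---------------------------------------------------------------------------
# priors


class Prior:
    """A prior over a probability; samples always lie inside its support."""

    def sample(self, rng: np.random.Generator):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def mean(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class PointMass(Prior):
    value: float

    def sample(self, rng):
        return float(self.value)

    @property
    def mean(self):
        return float(self.value)


@dataclass(frozen=True)
class BetaPrior(Prior):
    """Beta prior parametrized by mean and effective sample size (alpha+beta).

    ``ess`` controls the run-to-run spread: sd ~= sqrt(m(1-m)/(ess+1)).
    ``ess=None`` degenerates to a point mass at the mean.
    """

    mean_: float
    ess: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.mean_ <= 1.0:
            raise ValueError(f"Beta prior mean {self.mean_} outside [0, 1]")
        if self.ess is not None and self.ess <= 0:
            raise ValueError("Beta prior ess must be positive")

    def sample(self, rng):
        if self.ess is None or self.mean_ in (0.0, 1.0):
            return float(self.mean_)
        a = self.mean_ * self.ess
        b = (1.0 - self.mean_) * self.ess
        return float(rng.beta(a, b))

    @property
    def mean(self):
        return float(self.mean_)


@dataclass(frozen=True)
class UniformPrior(Prior):
    lo: float
    hi: float

    def __post_init__(self):
        if not 0.0 <= self.lo <= self.hi <= 1.0:
            raise ValueError(f"Uniform prior [{self.lo}, {self.hi}] invalid")

    def sample(self, rng):
        if self.lo == self.hi:
            return float(self.lo)
        return float(rng.uniform(self.lo, self.hi))

    @property
    def mean(self):
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class StratifiedPrior:
    """One prior per (gender, age-group) stratum; shape (2, 4)."""

    priors: tuple  # tuple of 2 tuples of 4 Prior

    @classmethod
    def shared(cls, prior: Prior) -> "StratifiedPrior":
        return cls(tuple(tuple(prior for _ in AGE_GROUPS) for _ in GENDERS))

    def sample(self, rng) -> np.ndarray:
        return np.array(
            [[p.sample(rng) for p in row] for row in self.priors], dtype=float
        )

    @property
    def means(self) -> np.ndarray:
        return np.array([[p.mean for p in row] for row in self.priors], dtype=float)


# ---------------------------------------------------------------------------
# per-run realization


@dataclass
class ParameterSet:
    """One run's complete realization of all probabilities.

    Stratified fields are (2, 4) arrays indexed by (gender, age group); the
    successive-round fields are scalars because the source program's
    successive-screening inputs were not stratified.
    """

    exclusion_initial: np.ndarray
    exclusion_successive: float
    opportunistic: np.ndarray
    opportunistic_recent_fraction: float
    participation_initial: np.ndarray
    participation_successive_prev_participant: float
    participation_successive_prev_nonparticipant: float
    positivity_initial: np.ndarray
    positivity_successive: float
    refusal: np.ndarray
    second_look_rate: float
    second_look_mode: str  # "chain" | "single"
    result_dist_initial: np.ndarray  # 5 categories
    result_dist_successive: np.ndarray  # 5 categories
    surveillance_result_dist: np.ndarray  # 4 categories
    adherence_successive_surveillance: float
    reinvite_intervals: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_REINVITE))

    def validate(self) -> None:
        for name in (
            "exclusion_initial", "opportunistic", "participation_initial",
            "positivity_initial", "refusal",
        ):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        for name in (
            "exclusion_successive", "opportunistic_recent_fraction",
            "participation_successive_prev_participant",
            "participation_successive_prev_nonparticipant",
            "positivity_successive", "second_look_rate",
            "adherence_successive_surveillance",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name, k in (
            ("result_dist_initial", 5),
            ("result_dist_successive", 5),
            ("surveillance_result_dist", 4),
        ):
            d = getattr(self, name)
            if len(d) != k or np.any(d < 0) or abs(d.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} is not a length-{k} distribution summing to 1")


@dataclass
class PriorLibrary:
    """Priors for every ParameterSet field, plus the fixed structural settings."""

    exclusion_initial: StratifiedPrior
    exclusion_successive: Prior
    opportunistic: StratifiedPrior
    opportunistic_recent_fraction: Prior
    participation_initial: StratifiedPrior
    participation_successive_prev_participant: Prior
    participation_successive_prev_nonparticipant: Prior
    positivity_initial: StratifiedPrior
    positivity_successive: Prior
    refusal: StratifiedPrior
    second_look_rate: Prior
    second_look_mode: str
    result_dist_initial: np.ndarray
    result_dist_successive: np.ndarray
    surveillance_result_dist: np.ndarray
    adherence_successive_surveillance: UniformPrior
    reinvite_intervals: Mapping[str, int]

    def with_overrides(self, **kw) -> "PriorLibrary":
        return replace(self, **kw)


def sample_parameters(priors: PriorLibrary, rng: np.random.Generator) -> ParameterSet:
    """Draw one ParameterSet: one value per field, per stratum where stratified.

    Adherence is drawn once and is constant for the whole run. The draw order
    is fixed, so the same seeded generator state yields an identical set.
    """
    ps = ParameterSet(
        exclusion_initial=priors.exclusion_initial.sample(rng),
        exclusion_successive=priors.exclusion_successive.sample(rng),
        opportunistic=priors.opportunistic.sample(rng),
        opportunistic_recent_fraction=priors.opportunistic_recent_fraction.sample(rng),
        participation_initial=priors.participation_initial.sample(rng),
        participation_successive_prev_participant=(
            priors.participation_successive_prev_participant.sample(rng)
        ),
        participation_successive_prev_nonparticipant=(
            priors.participation_successive_prev_nonparticipant.sample(rng)
        ),
        positivity_initial=priors.positivity_initial.sample(rng),
        positivity_successive=priors.positivity_successive.sample(rng),
        refusal=priors.refusal.sample(rng),
        second_look_rate=priors.second_look_rate.sample(rng),
        second_look_mode=priors.second_look_mode,
        result_dist_initial=np.asarray(priors.result_dist_initial, dtype=float),
        result_dist_successive=np.asarray(priors.result_dist_successive, dtype=float),
        surveillance_result_dist=np.asarray(priors.surveillance_result_dist, dtype=float),
        adherence_successive_surveillance=(
            priors.adherence_successive_surveillance.sample(rng)
        ),
        reinvite_intervals=dict(priors.reinvite_intervals),
    )
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# configuration file


class ConfigError(ValueError):
    pass


def _default_config_text() -> str:
    return (
        importlib.resources.files("crcdemand.data")
        .joinpath("default_config.yaml")
        .read_text()
    )


def default_config() -> dict:
    """The packaged default configuration, calibrated to the source program."""
    return yaml.safe_load(_default_config_text())


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        here = f"{path}.{k}" if path else k
        if k not in base:
            out[k] = v
        elif isinstance(base[k], dict) and isinstance(v, dict):
            out[k] = _deep_merge(base[k], v, here)
        else:
            out[k] = v
    return out


def read_config(path: str | None = None) -> dict:
    """Read a YAML config, overlaying it on the packaged defaults.

    Any omitted field falls back to the packaged calibrated default; fallbacks
    are logged at debug level, full-section fallbacks at info level.
    """
    cfg = default_config()
    if path is None:
        return cfg
    try:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    except FileNotFoundError as e:
        raise ConfigError(f"config file not found: {path}") from e
    except yaml.YAMLError as e:
        raise ConfigError(f"config file {path} does not parse as YAML: {e}") from e
    if not isinstance(user, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    for section in cfg:
        if section not in user:
            log.info("config section [%s] not given; using packaged defaults", section)
    return _deep_merge(cfg, user)


def _prob_prior(spec, name: str) -> Prior:
    """Parse a scalar probability prior: either a bare number (point mass) or
    a mapping {mean, ess} / {low, high} / {value}."""
    if isinstance(spec, (int, float)):
        v = float(spec)
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name}: probability {v} outside [0, 1]")
        return PointMass(v)
    if not isinstance(spec, dict):
        raise ConfigError(f"{name}: cannot parse prior from {spec!r}")
    if "value" in spec:
        return _prob_prior(spec["value"], name)
    if "low" in spec or "high" in spec:
        try:
            return UniformPrior(float(spec["low"]), float(spec["high"]))
        except ValueError as e:
            raise ConfigError(f"{name}: {e}") from e
    if "mean" in spec:
        m = float(spec["mean"])
        if not 0.0 <= m <= 1.0:
            raise ConfigError(f"{name}: probability {m} outside [0, 1]")
        ess = spec.get("ess")
        try:
            return BetaPrior(m, None if ess is None else float(ess))
        except ValueError as e:
            raise ConfigError(f"{name}: {e}") from e
    raise ConfigError(f"{name}: cannot parse prior from {spec!r}")


def _stratified_prior(spec, name: str) -> StratifiedPrior:
    """Parse a stratified prior.  A plain prior is shared across the 8 strata;
    a ``strata:`` block with per-gender lists of 4 means differentiates them."""
    if isinstance(spec, dict) and "strata" in spec:
        ess = spec.get("ess")
        rows = []
        for g in GENDERS:
            means = spec["strata"].get(g)
            if means is None or len(means) != len(AGE_GROUPS):
                raise ConfigError(
                    f"{name}.strata.{g}: expected {len(AGE_GROUPS)} values"
                )
            rows.append(
                tuple(_prob_prior({"mean": m, "ess": ess}, f"{name}.strata.{g}") for m in means)
            )
        return StratifiedPrior(tuple(rows))
    return StratifiedPrior.shared(_prob_prior(spec, name))


def _distribution(spec: Sequence[float], name: str, k: int) -> np.ndarray:
    d = np.asarray(spec, dtype=float)
    if d.shape != (k,):
        raise ConfigError(f"{name}: expected {k} category probabilities")
    if np.any(d < 0) or np.any(d > 1):
        raise ConfigError(f"{name}: probability outside [0, 1]")
    if abs(d.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{name}: distribution sums to {d.sum():.6g}, not 1")
    return d


def priors_from_config(cfg: dict) -> PriorLibrary:
    s = cfg["screening"]
    surv = cfg["surveillance"]
    psa = cfg["psa"]
    adher = psa["adherence"]
    adherence = UniformPrior(float(adher["low"]), float(adher["high"]))
    reinvite = dict(DEFAULT_REINVITE)
    reinvite.update({k: int(v) for k, v in s.get("reinvite_intervals", {}).items()})
    mode = s.get("second_look_mode", "chain")
    if mode not in ("chain", "single"):
        raise ConfigError(f"screening.second_look_mode: unknown mode {mode!r}")
    return PriorLibrary(
        exclusion_initial=_stratified_prior(s["exclusion_initial"], "screening.exclusion_initial"),
        exclusion_successive=_prob_prior(s["exclusion_successive"], "screening.exclusion_successive"),
        opportunistic=_stratified_prior(s["opportunistic"], "screening.opportunistic"),
        opportunistic_recent_fraction=_prob_prior(
            s["opportunistic_recent_fraction"], "screening.opportunistic_recent_fraction"
        ),
        participation_initial=_stratified_prior(
            s["participation_initial"], "screening.participation_initial"
        ),
        participation_successive_prev_participant=_prob_prior(
            s["participation_successive_prev_participant"],
            "screening.participation_successive_prev_participant",
        ),
        participation_successive_prev_nonparticipant=_prob_prior(
            s["participation_successive_prev_nonparticipant"],
            "screening.participation_successive_prev_nonparticipant",
        ),
        positivity_initial=_stratified_prior(
            s["positivity_initial"], "screening.positivity_initial"
        ),
        positivity_successive=_prob_prior(
            s["positivity_successive"], "screening.positivity_successive"
        ),
        refusal=_stratified_prior(s["refusal"], "screening.refusal"),
        second_look_rate=_prob_prior(s["second_look_rate"], "screening.second_look_rate"),
        second_look_mode=mode,
        result_dist_initial=_distribution(
            s["result_dist_initial"], "screening.result_dist_initial", 5
        ),
        result_dist_successive=_distribution(
            s["result_dist_successive"], "screening.result_dist_successive", 5
        ),
        surveillance_result_dist=_distribution(
            surv["result_dist"], "surveillance.result_dist", 4
        ),
        adherence_successive_surveillance=adherence,
        reinvite_intervals=reinvite,
    )


def load_config(path: str | None = None) -> PriorLibrary:
    """Load a config file (or the packaged default) into a PriorLibrary."""
    return priors_from_config(read_config(path))
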