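"""Simulated population: initial cohort, annual entrants, and mortality.

The target population starts at 100,000 persons aged 50-69 under biennial
screening (half the cohort invited each calendar year, alternating waves).
From the second simulation year on, a cohort of 50-year-olds enters every
year; its size follows a configurable per-year series.  Time to death is
drawn from a gender-specific piecewise-constant hazard table (by default a
Gompertz law approximating Spanish period life tables).

Time is continuous in years from the start of the horizon (t=0 is the start
of the first calendar year); calendar years are floor(t) offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# person status codes
ROUTINE, EXCLUDED, SURVEILLANCE, EXITED = 0, 1, 2, 3

#: sentinel death time meaning "never dies within any horizon"
NEVER = np.inf


@dataclass
class MortalityTable:
    """Piecewise-constant hazard by integer age and gender.

    ``hazard[g, i]`` applies on age interval [ages[i], ages[i]+1) for gender
    g (0 male, 1 female); the last hazard extends beyond the table.
    """

    ages: np.ndarray  # (k,) integer ages, consecutive from age_min
    hazard: np.ndarray  # (2, k) non-negative hazards per year

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.hazard = np.atleast_2d(np.asarray(self.hazard, dtype=float))
        if np.any(self.hazard < 0):
            raise ValueError("mortality hazards must be non-negative")

    @classmethod
    def gompertz(cls, male: tuple[float, float], female: tuple[float, float],
                 age_min: int = 50, age_max: int = 110) -> "MortalityTable":
        """h(x) = a * exp(b * (x - age_min)), evaluated at integer ages."""
        ages = np.arange(age_min, age_max, dtype=float)
        rows = []
        for a, b in (male, female):
            rows.append(a * np.exp(b * (ages - age_min)))
        return cls(ages, np.array(rows))

    @classmethod
    def from_frame(cls, df) -> "MortalityTable":
        """Build from a (age, hazard_male, hazard_female) data frame/CSV dump."""
        ages = np.asarray(df["age"], dtype=float)
        return cls(ages, np.array([df["hazard_male"], df["hazard_female"]], dtype=float))


def draw_time_to_death(age, gender, table: MortalityTable,
                       rng: np.random.Generator) -> np.ndarray:
    """Sample remaining years of life for persons of given age and gender.

    Inverse-hazard sampling: draw E ~ Exp(1) and invert the cumulative hazard
    of the piecewise-constant table from the person's current age.  A table of
    all-zero hazards yields the +infinity sentinel (immortal limit).
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    gender = np.atleast_1d(np.asarray(gender, dtype=np.intp))
    if np.any(age < table.ages[0]):
        raise ValueError(f"age below table start {table.ages[0]}")
    n = age.shape[0]
    out = np.empty(n, dtype=float)
    e = rng.exponential(1.0, size=n)
    edges = np.append(table.ages, np.inf)
    for g in (0, 1):
        m = gender == g
        if not m.any():
            continue
        h = table.hazard[g]
        # cumulative hazard at bin edges from the table start
        cumh = np.concatenate([[0.0], np.cumsum(h)])
        a = age[m]
        # cumulative hazard already accrued at current age
        i0 = np.minimum(np.searchsorted(table.ages, a, side="right") - 1, len(h) - 1)
        acc = cumh[i0] + h[i0] * (a - table.ages[i0])
        target = acc + e[m]
        j = np.searchsorted(cumh, target, side="right") - 1
        j = np.minimum(j, len(h) - 1)
        hz = h[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_abs = np.where(
                hz > 0, table.ages[j] + (target - cumh[j]) / hz, np.inf
            )
        # beyond the last bin the last hazard extends; exhausted hazard -> inf
        last_h = h[-1]
        over = target > cumh[-1]
        if last_h > 0:
            t_abs = np.where(over, edges[-2] + 1 + (target - cumh[-1]) / last_h, t_abs)
        else:
            t_abs = np.where(over, np.inf, t_abs)
        out[m] = np.maximum(t_abs - a, np.finfo(float).tiny)
    return out


@dataclass
class Demography:
    """Population inputs: initial cohort, entrant series, mortality."""

    initial_size: int = 100_000
    age_low: float = 50.0
    age_high: float = 70.0
    female_fraction: float = 0.5
    start_year: int = 2015
    #: entrants per calendar year (start_year+1 ... start_year+horizon-1)
    entrants: dict[int, int] = field(default_factory=dict)
    mortality: MortalityTable = field(
        default_factory=lambda: MortalityTable.gompertz((0.0033, 0.095), (0.0015, 0.105))
    )

    def __post_init__(self):
        if self.initial_size < 0:
            raise ValueError("initial_size must be >= 0")
        if any(v < 0 for v in self.entrants.values()):
            raise ValueError("entrant counts must be >= 0")

    def entrant_count(self, year: int) -> int:
        return int(self.entrants.get(year, 0))


def demography_from_config(cfg: dict) -> Demography:
    d = cfg["demography"]
    run = cfg.get("run", {})
    start_year = int(run.get("start_year", 2015))
    horizon = int(run.get("horizon", 20))
    if "entrants" in d and d["entrants"]:
        entrants = {int(y): int(n) for y, n in d["entrants"].items()}
    else:
        # linear series between the two calibrated endpoints
        y0, y1 = start_year + 1, start_year + horizon - 1
        e0, e1 = float(d["entrants_first"]), float(d["entrants_last"])
        entrants = {
            y: int(round(e0 + (e1 - e0) * (y - y0) / max(y1 - y0, 1)))
            for y in range(y0, y1 + 1)
        }
    g = d.get("gompertz")
    if g:
        mort = MortalityTable.gompertz(
            (float(g["male"]["a"]), float(g["male"]["b"])),
            (float(g["female"]["a"]), float(g["female"]["b"])),
        )
    else:
        mort = Demography().mortality
    return Demography(
        initial_size=int(d.get("initial_size", 100_000)),
        age_low=float(d.get("age_low", 50.0)),
        age_high=float(d.get("age_high", 70.0)),
        female_fraction=float(d.get("female_fraction", 0.5)),
        start_year=start_year,
        entrants=entrants,
        mortality=mort,
    )


class Population:
    """Struct-of-arrays container for all simulated persons.

    Attributes are flat numpy arrays indexed by person id.  ``age0`` is the
    age at simulation time 0, so age at time t is ``age0 + t``; entrants born
    later have age0 < 50.
    """

    __slots__ = (
        "gender", "age0", "death", "status", "next_invite", "ever_screen_invited",
        "prev_participant", "screen_count", "surv_next", "surv_consec_neg",
        "surv_exams",
    )

    def __init__(self, n: int = 0):
        self.gender = np.zeros(n, dtype=np.int8)
        self.age0 = np.zeros(n, dtype=float)
        self.death = np.full(n, NEVER)
        self.status = np.full(n, ROUTINE, dtype=np.int8)
        self.next_invite = np.full(n, np.inf)
        # has this person ever reached a participation decision before?
        self.ever_screen_invited = np.zeros(n, dtype=bool)
        self.prev_participant = np.zeros(n, dtype=bool)
        self.screen_count = np.zeros(n, dtype=np.int16)
        self.surv_next = np.full(n, np.inf)
        self.surv_consec_neg = np.zeros(n, dtype=np.int8)
        self.surv_exams = np.zeros(n, dtype=np.int16)

    def __len__(self):
        return self.gender.shape[0]

    def append(self, other: "Population") -> None:
        for name in self.__slots__:
            setattr(self, name, np.concatenate([getattr(self, name), getattr(other, name)]))

    def age_at(self, t) -> np.ndarray:
        return self.age0 + t

    def status_counts(self) -> dict[str, int]:
        names = {ROUTINE: "routine", EXCLUDED: "excluded",
                 SURVEILLANCE: "surveillance", EXITED: "exited"}
        return {names[k]: int((self.status == k).sum()) for k in names}


def init_population(demog: Demography, rng: np.random.Generator) -> Population:
    """Create the initial cohort.

    Ages are uniform over [age_low, age_high); invitation waves alternate so
    that each wave holds half the cohort (biennial program: wave 0 is invited
    during the first calendar year, wave 1 during the second), with the
    invitation instant uniform within the wave's year.
    """
    n = demog.initial_size
    pop = Population(n)
    if n == 0:
        return pop
    pop.gender = (rng.random(n) < demog.female_fraction).astype(np.int8)
    pop.age0 = rng.uniform(demog.age_low, demog.age_high, size=n)
    pop.death = draw_time_to_death(pop.age0, pop.gender, demog.mortality, rng)
    wave = np.arange(n, dtype=np.int64) % 2
    pop.next_invite = wave + rng.random(n)
    return pop


def annual_entrants(demog: Demography, year: int, rng: np.random.Generator,
                    horizon: int = 20) -> Population:
    """Create the cohort of 50-year-olds entering in a given calendar year.

    Each entrant is aged exactly 50 at entry, with the entry (= first
    invitation) instant uniform within the year.
    """
    first, last = demog.start_year + 1, demog.start_year + horizon - 1
    if not first <= year <= last:
        raise ValueError(f"entrant year {year} outside horizon [{first}, {last}]")
    n = demog.entrant_count(year)
    pop = Population(n)
    if n == 0:
        return pop
    t_entry = (year - demog.start_year) + rng.random(n)
    pop.gender = (rng.random(n) < demog.female_fraction).astype(np.int8)
    pop.age0 = 50.0 - t_entry
    pop.death = t_entry + draw_time_to_death(
        np.full(n, 50.0), pop.gender, demog.mortality, rng
    )
    pop.next_invite = t_entry
    return pop
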