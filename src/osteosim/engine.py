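"""Per-woman discrete event simulation, one year per interval.

This is the reference implementation of the model flow: each woman is
preloaded with her start characteristics, then stepped through yearly
intervals — osteoporosis onset, the six fracture draws, hospitalization and
rehabilitation, nursing-home entry (fracture-related or background), the
parallel counterfactual background-NH track, and the survival draw — until
death or the end of the age-100 interval.  Every decision consumes the
keyed uniform of its (age, slot) stream at the woman's person index, so a
cohort of these women is draw-for-draw identical to the vectorized engine
in :mod:`osteosim.cohort` (which is what the large experiments run).

Within-year order: onset → fractures → hospitalization/rehab → NH entry →
counterfactual background entry → survival.  Fractures from earlier
intervals set the previous-fracture flag; same-interval fractures do not
count as "previous" for each other.  Nursing-home residence and
osteoporosis are absorbing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import rng
from .parameters import (
    AGE_MAX,
    FractureType,
    N_TYPES,
    ParameterSet,
    age_class_index,
)

COMMUNITY = "community"
NURSING_HOME = "nursing_home"

RESIDENCES = ("C", "N")
DISEASE_STATUSES = ("O", "avO", "nO")
HISTORIES = ("P", "nP", "avP")
START_AGES = (50, 75)


@dataclass(frozen=True)
class ScenarioSpec:
    """Start characteristics of one simulated cohort.

    ``residence``: C (community) or N (nursing home; start age >= 65 only).
    ``disease``: O (osteoporosis at start), avO (average risk: prevalence
    preload plus incidence), nO (never develops osteoporosis).
    ``history``: P (prevalent fracture at start), nP (none), avP
    (prevalence-drawn flag; the base case).
    """

    start_age: int = 50
    residence: str = "C"
    disease: str = "avO"
    history: str = "avP"

    def __post_init__(self):
        if self.start_age not in START_AGES:
            raise ValueError(f"start_age must be one of {START_AGES}")
        if self.residence not in RESIDENCES:
            raise ValueError(f"residence must be one of {RESIDENCES}")
        if self.disease not in DISEASE_STATUSES:
            raise ValueError(f"disease must be one of {DISEASE_STATUSES}")
        if self.history not in HISTORIES:
            raise ValueError(f"history must be one of {HISTORIES}")
        if self.residence == "N" and self.start_age < 65:
            raise ValueError("nursing-home start requires start age >= 65")

    @property
    def label(self) -> str:
        return f"{self.start_age}_{self.residence}_{self.disease}_{self.history}"

    @classmethod
    def from_label(cls, label: str) -> "ScenarioSpec":
        age, res, dis, hist = label.split("_")
        return cls(int(age), res, dis, hist)

    @property
    def n_years(self) -> int:
        """Number of fracture-bearing intervals (ages start .. 99)."""
        return 100 - self.start_age


#: the base case: 50 year old community-dwelling woman at average
#: osteoporosis risk with prevalence-drawn previous-fracture status
BASE_CASE = ScenarioSpec(50, "C", "avO", "avP")
#: its paired counterfactual: the same woman never developing osteoporosis
BASE_CASE_NEVER = ScenarioSpec(50, "C", "nO", "avP")


def enumerate_scenarios() -> list[ScenarioSpec]:
    """The 18 valid start-characteristic combinations (no NH start at 50)."""
    out = []
    for age, res, dis, hist in itertools.product(START_AGES, RESIDENCES,
                                                 DISEASE_STATUSES, ("P", "nP")):
        if res == "N" and age < 65:
            continue
        out.append(ScenarioSpec(age, res, dis, hist))
    assert len(out) == 18
    return out


@dataclass
class WomanState:
    """One woman's dynamic attribute profile."""

    person_index: int
    age: int
    year: int = 0                       # model year index (0 = start interval)
    alive: bool = True
    osteoporotic: bool = False          # absorbing
    can_develop_osteoporosis: bool = True
    prevalent_fracture: bool = False    # preloaded, type-free; risk only
    fracture_history: list = field(default_factory=list)  # (FractureType, year, hospitalized)
    residence: str = COMMUNITY          # absorbing once NURSING_HOME
    residence_cause: str = "none"       # none | fracture | background
    background_nh_entered: bool = False  # counterfactual parallel track
    background_nh_year: int | None = None

    @property
    def has_previous_fracture(self) -> bool:
        """True once any fracture predates the current interval (or was preloaded)."""
        return self.prevalent_fracture or any(y < self.year for _, y, _ in self.fracture_history)

    @property
    def in_nh(self) -> bool:
        return self.residence == NURSING_HOME


@dataclass
class YearRecord:
    """Event ledger of one yearly interval."""

    year: int
    model_year: int
    age: int
    fractures: list = field(default_factory=list)  # (FractureType, hospitalized, rehab)
    osteoporosis_onset: bool = False
    nh_entry: str = "none"              # none | fracture | background
    background_nh_entry: bool = False   # counterfactual track fired this year
    died: bool = False
    fracture_related_death: bool = False


@dataclass
class PersonHistory:
    """Complete simulated life of one woman."""

    person_index: int
    scenario: ScenarioSpec
    osteo_preloaded: bool
    prevfx_preloaded: bool
    records: list[YearRecord] = field(default_factory=list)

    @property
    def death_year(self) -> int | None:
        for r in self.records:
            if r.died:
                return r.year
        return None

    @property
    def fracture_count(self) -> int:
        return sum(len(r.fractures) for r in self.records)

    def fracture_counts_by_type(self) -> np.ndarray:
        out = np.zeros(N_TYPES, dtype=int)
        for r in self.records:
            for f, _, _ in r.fractures:
                out[f] += 1
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def preload_state(scenario: ScenarioSpec, params: ParameterSet, seed: int,
                  person_index: int) -> WomanState:
    """Initialize a woman's risk-factor attributes from the scenario.

    Average-risk women draw osteoporosis from the age-specific prevalence;
    the prevalent-fracture preload is a type-free flag that raises
    subsequent fracture risk but carries no acute costs and no excess
    mortality (it predates model start).
    """
    ai = scenario.start_age - 50
    state = WomanState(person_index=person_index, age=scenario.start_age)

    if scenario.disease == "O":
        state.osteoporotic = True
    elif scenario.disease == "avO":
        u = rng.person_uniform(seed, scenario.start_age, rng.SLOT_PRELOAD_OSTEO, person_index)
        state.osteoporotic = u <= params.osteo_prevalence[ai]
    else:  # nO — never develops osteoporosis
        state.osteoporotic = False
        state.can_develop_osteoporosis = False

    if scenario.history == "P":
        state.prevalent_fracture = True
    elif scenario.history == "avP":
        u = rng.person_uniform(seed, scenario.start_age, rng.SLOT_PRELOAD_PREVFX, person_index)
        state.prevalent_fracture = u <= params.prevfx_prevalence[ai]

    if scenario.residence == "N":
        state.residence = NURSING_HOME
        state.residence_cause = "none"  # pre-existing, never fracture-attributable
    return state


def annual_fracture_probabilities(state: WomanState, params: ParameterSet,
                                  trend_factor: float = 1.0) -> np.ndarray:
    """Per-type annual fracture probabilities for the woman's current profile."""
    if not state.alive:
        raise ValueError("fracture probabilities requested for a dead state")
    return np.array([
        params.fracture_probability(f, state.age, state.osteoporotic,
                                    state.has_previous_fracture, state.in_nh,
                                    trend_factor)
        for f in range(N_TYPES)
    ])


def draw_events(probabilities: np.ndarray, uniforms: np.ndarray) -> np.ndarray:
    """Independent event draws, one slot per type; an event fires iff u <= p."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities outside [0, 1]")
    return np.asarray(uniforms) <= p


def nh_entry_decision(state: WomanState, acute_hospitalized: list, params: ParameterSet,
                      u_fracture: float, u_background: float) -> str:
    """NH-entry outcome for this interval: 'none', 'fracture' or 'background'.

    Only community-dwelling women at or above the entry age are at risk.
    Fracture-related entry applies the *highest* admission probability among
    this interval's hospitalized fractures; failing that, background entry
    is drawn from the care-prevalence-derived annual probability.
    """
    if state.in_nh or state.age < params.min_nh_entry_age or not state.alive:
        return "none"
    ac = age_class_index(state.age)
    if acute_hospitalized:
        p_fx = max(params.nh_admission_prob[f, ac] for f in acute_hospitalized)
        if p_fx > 0 and u_fracture <= p_fx:
            return "fracture"
    if u_background <= params.bg_nh_incidence[state.age - 50]:
        return "background"
    return "none"


def background_nh_counterfactual(state: WomanState, params: ParameterSet,
                                 u: float) -> bool:
    """Draw the parallel-track (any-cause) NH entry used only by cost attribution."""
    if state.background_nh_entered or state.age < params.min_nh_entry_age:
        return False
    return u <= params.bg_nh_incidence[state.age - 50]


def mortality_probability(state: WomanState, params: ParameterSet) -> float:
    """Annual death probability: life-table risk x residence RR x fracture RR.

    The fracture RR is the maximum over in-window history entries (buckets:
    fracture year, years 2-5, years 6-10; nothing beyond 10 years; wrist
    entries carry RR 1 by parameterization).
    """
    if not state.alive:
        raise ValueError("mortality requested for a dead state")
    q = params.all_cause_q[state.age - 50]
    q *= params.rr_mortality_nh if state.in_nh \
        else params.rr_mortality_comm[state.age - 50]
    q *= fracture_mortality_rr(state, params)
    return float(min(q, 1.0))


def fracture_mortality_rr(state: WomanState, params: ParameterSet) -> float:
    rr = 1.0
    for f, year, _ in state.fracture_history:
        rr = max(rr, params.fracture_mortality_rr(f, state.age, state.year - year))
    return rr


def step_year(state: WomanState, params: ParameterSet, seed: int) -> YearRecord:
    """Advance one yearly interval, mutating `state` and returning its record."""
    if not state.alive:
        raise ValueError("cannot step a dead state")
    if state.age > AGE_MAX - 1:
        raise ValueError("no fracture-bearing intervals beyond age 99")
    i = state.person_index
    age = state.age
    ac = age_class_index(age)
    trend = (1.0 + params.trend_rate) ** state.year
    rec = YearRecord(year=state.year, model_year=params.base_year + state.year, age=age)

    # (1) osteoporosis onset — before the fracture draws, so incident
    # osteoporosis already affects this interval's fracture risk
    if state.can_develop_osteoporosis and not state.osteoporotic:
        u = rng.person_uniform(seed, age, rng.SLOT_OSTEO_ONSET, i)
        if u <= params.osteo_incidence[age - 50]:
            state.osteoporotic = True
            rec.osteoporosis_onset = True

    # (2) fracture draws, (3) hospitalization / rehabilitation
    probs = annual_fracture_probabilities(state, params, trend)
    hospitalized_types: list[int] = []
    for f in range(N_TYPES):
        u = rng.person_uniform(seed, age, rng.SLOT_FRACTURE_BASE + f, i)
        if u <= probs[f]:
            uh = rng.person_uniform(seed, age, rng.SLOT_HOSPITALIZATION_BASE + f, i)
            hosp = uh <= params.hospitalization_prob[f]
            rehab = False
            if hosp:
                ur = rng.person_uniform(seed, age, rng.SLOT_REHAB_BASE + f, i)
                rehab = ur <= params.rehab_prob[f]
                hospitalized_types.append(f)
            rec.fractures.append((FractureType(f), hosp, rehab))
            state.fracture_history.append((FractureType(f), state.year, hosp))

    # (4) nursing-home entry (absorbing)
    entry = nh_entry_decision(
        state, hospitalized_types, params,
        rng.person_uniform(seed, age, rng.SLOT_NH_FRACTURE, i),
        rng.person_uniform(seed, age, rng.SLOT_NH_BACKGROUND, i),
    )
    if entry != "none":
        state.residence = NURSING_HOME
        state.residence_cause = entry
        rec.nh_entry = entry

    # (5) counterfactual background-NH track
    if background_nh_counterfactual(
            state, params, rng.person_uniform(seed, age, rng.SLOT_NH_COUNTERFACTUAL, i)):
        state.background_nh_entered = True
        state.background_nh_year = state.year
        rec.background_nh_entry = True

    # (6) survival, with this interval's fractures already in the history
    q = mortality_probability(state, params)
    u = rng.person_uniform(seed, age, rng.SLOT_SURVIVAL, i)
    if u <= q:
        rec.died = True
        rec.fracture_related_death = fracture_mortality_rr(state, params) > 1.0
        state.alive = False

    state.age += 1
    state.year += 1
    return rec


def simulate_individual(scenario: ScenarioSpec, params: ParameterSet, seed: int,
                        person_index: int) -> PersonHistory:
    """Preload, then step yearly until death or the age-100 exit."""
    state = preload_state(scenario, params, seed, person_index)
    history = PersonHistory(person_index=person_index, scenario=scenario,
                            osteo_preloaded=state.osteoporotic,
                            prevfx_preloaded=state.prevalent_fracture)
    for _ in range(scenario.n_years):
        history.records.append(step_year(state, params, seed))
        if not state.alive:
            return history
    # terminal record: she exits alive at the end of the age-100 interval
    history.records.append(YearRecord(year=state.year,
                                      model_year=params.base_year + state.year,
                                      age=AGE_MAX))
    return history
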