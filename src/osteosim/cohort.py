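"""Vectorized cohort simulation.

Simulates all n women of a scenario simultaneously, one yearly interval at
a time, drawing whole uniform vectors from the keyed streams in
:mod:`osteosim.rng`.  Because draws are keyed by (seed, age, slot) with the
person index as stream position, this engine is draw-for-draw identical to
the per-woman reference engine in :mod:`osteosim.engine` — the tests assert
that — and it carries the common-random-numbers contract needed for paired
excess estimation.  200,000 women over a 50-year horizon run in seconds.

Excess-mortality bookkeeping uses one 10-bit occurrence mask per woman and
fracture type (bit k set = a fracture of that type happened k model years
ago), shifted once per interval; the three years-since buckets read bit 0,
bits 1-4 and bits 5-9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rng
from .parameters import (
    N_TYPES,
    ParameterSet,
    age_class_index,
    mortality_age_class_index,
)
from .engine import ScenarioSpec

#: sentinel year index meaning "never happened"
NEVER = 10_000

NH_CAUSE_NONE = 0        # community throughout, or pre-existing NH residence
NH_CAUSE_FRACTURE = 1
NH_CAUSE_BACKGROUND = 2


@dataclass
class EventTable:
    """Flat arrays of fracture events: one row per (woman, interval, type)."""

    person: np.ndarray
    year: np.ndarray
    ftype: np.ndarray
    hospitalized: np.ndarray
    rehab: np.ndarray

    def __len__(self) -> int:
        return len(self.person)


@dataclass
class CohortResult:
    """Event-level outcome of one simulated cohort (input to the cost engine)."""

    scenario: ScenarioSpec
    n: int
    seed: int

    death_year: np.ndarray          # (n,) interval index of death; -1 = alive at exit
    fracture_related_death: np.ndarray  # (n,) death fired while fracture RR > 1
    osteo_start: np.ndarray         # (n,) osteoporotic at model start
    osteo_onset_year: np.ndarray    # (n,) -1 = never
    prevfx_start: np.ndarray        # (n,) prevalent fracture preloaded
    nh_entry_year: np.ndarray       # (n,) NEVER = never; -1 = resident at start
    nh_cause: np.ndarray            # (n,) NH_CAUSE_*
    cf_entry_year: np.ndarray       # (n,) counterfactual background entry; NEVER = never
    events: EventTable
    counts: np.ndarray              # (n, 6) lifetime fracture counts
    alive_at_start: np.ndarray      # (T,) women alive entering each interval
    fractures_by_year: np.ndarray   # (T, 6) fracture tallies per interval

    @property
    def start_age(self) -> int:
        return self.scenario.start_age

    @property
    def n_years(self) -> int:
        return self.scenario.n_years

    def last_alive_year(self) -> np.ndarray:
        """Index of the final interval each woman occupies (death year or last)."""
        return np.where(self.death_year >= 0, self.death_year, self.n_years - 1)

    def person_years_by_age_class(self) -> np.ndarray:
        """(10,) person-years at risk per 5-year age class (alive at interval start)."""
        out = np.zeros(10)
        ages = self.start_age + np.arange(self.n_years)
        np.add.at(out, age_class_index(ages), self.alive_at_start.astype(float))
        return out

    def fractures_by_age_class(self) -> np.ndarray:
        """(10, 6) fracture tallies per 5-year age class."""
        out = np.zeros((10, N_TYPES))
        ages = self.start_age + np.arange(self.n_years)
        np.add.at(out, age_class_index(ages), self.fractures_by_year)
        return out


def run_cohort(scenario: ScenarioSpec, params: ParameterSet, n: int, seed: int) -> CohortResult:
    """Simulate n women of one scenario; deterministic for fixed (seed, n, params).

    Paired runs for excess estimation reuse identical per-woman streams:
    call with the same seed and a scenario differing only in risk group.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    start = scenario.start_age
    T = scenario.n_years

    # ---- preload ------------------------------------------------------
    ai0 = start - 50
    if scenario.disease == "O":
        osteo = np.ones(n, dtype=bool)
    elif scenario.disease == "avO":
        u = rng.uniforms(seed, start, rng.SLOT_PRELOAD_OSTEO, n)
        osteo = u <= params.osteo_prevalence[ai0]
    else:
        osteo = np.zeros(n, dtype=bool)
    can_onset = scenario.disease == "avO"
    osteo_start = osteo.copy()

    if scenario.history == "P":
        prevfx_pre = np.ones(n, dtype=bool)
    elif scenario.history == "avP":
        u = rng.uniforms(seed, start, rng.SLOT_PRELOAD_PREVFX, n)
        prevfx_pre = u <= params.prevfx_prevalence[ai0]
    else:
        prevfx_pre = np.zeros(n, dtype=bool)

    in_nh = np.full(n, scenario.residence == "N")
    nh_entry_year = np.where(in_nh, -1, NEVER)
    nh_cause = np.zeros(n, dtype=np.int8)

    alive = np.ones(n, dtype=bool)
    has_prev = prevfx_pre.copy()
    death_year = np.full(n, -1, dtype=np.int32)
    fx_death = np.zeros(n, dtype=bool)
    osteo_onset_year = np.full(n, -1, dtype=np.int32)
    cf_entry_year = np.full(n, NEVER, dtype=np.int32)
    fx_bits = np.zeros((n, N_TYPES), dtype=np.uint16)
    counts = np.zeros((n, N_TYPES), dtype=np.uint16)
    alive_at_start = np.zeros(T, dtype=np.int64)
    fx_by_year = np.zeros((T, N_TYPES), dtype=np.int64)

    ev_person: list[np.ndarray] = []
    ev_year: list[np.ndarray] = []
    ev_type: list[np.ndarray] = []
    ev_hosp: list[np.ndarray] = []
    ev_rehab: list[np.ndarray] = []

    for t in range(T):
        age = start + t
        ac = age_class_index(age)
        acm = mortality_age_class_index(age)
        trend = (1.0 + params.trend_rate) ** t
        alive_at_start[t] = int(alive.sum())
        fx_bits = (fx_bits << np.uint16(1)) & np.uint16(0x3FF)

        # (1) osteoporosis onset
        if can_onset:
            u = rng.uniforms(seed, age, rng.SLOT_OSTEO_ONSET, n)
            onset = alive & ~osteo & (u <= params.osteo_incidence[age - 50])
            osteo |= onset
            osteo_onset_year[onset] = t

        # (2) fracture draws + (3) hospitalization / rehab
        adm_max = np.zeros(n)
        new_fx = np.zeros(n, dtype=bool)
        for f in range(N_TYPES):
            p = params.fracture_probability(f, age, osteo, has_prev, in_nh, trend)
            u = rng.uniforms(seed, age, rng.SLOT_FRACTURE_BASE + f, n)
            fx = alive & (u <= p)
            if not fx.any():
                continue
            uh = rng.uniforms(seed, age, rng.SLOT_HOSPITALIZATION_BASE + f, n)
            hosp = fx & (uh <= params.hospitalization_prob[f])
            ur = rng.uniforms(seed, age, rng.SLOT_REHAB_BASE + f, n)
            rehab = hosp & (ur <= params.rehab_prob[f])
            fx_bits[fx, f] |= np.uint16(1)
            counts[fx, f] += 1
            new_fx |= fx
            fx_by_year[t, f] = int(fx.sum())
            adm_max = np.where(hosp, np.maximum(adm_max, params.nh_admission_prob[f, ac]),
                               adm_max)
            idx = np.nonzero(fx)[0]
            ev_person.append(idx.astype(np.int32))
            ev_year.append(np.full(idx.size, t, dtype=np.int32))
            ev_type.append(np.full(idx.size, f, dtype=np.int8))
            ev_hosp.append(hosp[idx])
            ev_rehab.append(rehab[idx])

        # (4) nursing-home entry (absorbing, community women >= entry age only)
        eligible = alive & ~in_nh & (age >= params.min_nh_entry_age)
        u_fx = rng.uniforms(seed, age, rng.SLOT_NH_FRACTURE, n)
        fx_entry = eligible & (adm_max > 0) & (u_fx <= adm_max)
        u_bg = rng.uniforms(seed, age, rng.SLOT_NH_BACKGROUND, n)
        bg_entry = eligible & ~fx_entry & (u_bg <= params.bg_nh_incidence[age - 50])
        in_nh = in_nh | fx_entry | bg_entry
        nh_entry_year = np.where(fx_entry | bg_entry, t, nh_entry_year)
        nh_cause = np.where(fx_entry, NH_CAUSE_FRACTURE,
                            np.where(bg_entry, NH_CAUSE_BACKGROUND, nh_cause)).astype(np.int8)

        # (5) counterfactual background-NH track (cost attribution only)
        cf_elig = alive & (age >= params.min_nh_entry_age) & (cf_entry_year == NEVER)
        u_cf = rng.uniforms(seed, age, rng.SLOT_NH_COUNTERFACTUAL, n)
        cf_entry_year = np.where(cf_elig & (u_cf <= params.bg_nh_incidence[age - 50]),
                                 t, cf_entry_year)

        # (6) survival, this interval's fractures included in the history
        rr_fx = np.ones(n)
        for f in range(N_TYPES):
            bits = fx_bits[:, f]
            rr_row = params.rr_fracture_mortality[f, acm]
            rr_fx = np.maximum(rr_fx, np.where(bits & np.uint16(0x001), rr_row[0], 1.0))
            rr_fx = np.maximum(rr_fx, np.where(bits & np.uint16(0x01E), rr_row[1], 1.0))
            rr_fx = np.maximum(rr_fx, np.where(bits & np.uint16(0x3E0), rr_row[2], 1.0))
        q = params.all_cause_q[age - 50] \
            * np.where(in_nh, params.rr_mortality_nh, params.rr_mortality_comm[age - 50]) \
            * rr_fx
        q = np.minimum(q, 1.0)
        u_s = rng.uniforms(seed, age, rng.SLOT_SURVIVAL, n)
        die = alive & (u_s <= q)
        death_year[die] = t
        fx_death[die] = rr_fx[die] > 1.0
        alive &= ~die

        has_prev |= new_fx  # previous-fracture status activates next interval

    cat = lambda chunks, dtype: (np.concatenate(chunks) if chunks
                                 else np.zeros(0, dtype=dtype))
    events = EventTable(
        person=cat(ev_person, np.int32),
        year=cat(ev_year, np.int32),
        ftype=cat(ev_type, np.int8),
        hospitalized=cat(ev_hosp, bool),
        rehab=cat(ev_rehab, bool),
    )
    return CohortResult(
        scenario=scenario, n=n, seed=seed,
        death_year=death_year, fracture_related_death=fx_death,
        osteo_start=osteo_start, osteo_onset_year=osteo_onset_year,
        prevfx_start=prevfx_pre,
        nh_entry_year=nh_entry_year.astype(np.int32), nh_cause=nh_cause,
        cf_entry_year=cf_entry_year, events=events, counts=counts,
        alive_at_start=alive_at_start, fractures_by_year=fx_by_year,
    )
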