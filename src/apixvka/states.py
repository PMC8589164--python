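"""Health-state space of the Markov cohort model.

Alive states are identified by
  * a history of up to two long-term events (MI, IS, ICH, OMB),
  * a phase: ``event_free``, ``acute`` (the cycle of an incident event,
    lasting exactly one cycle) or ``post_acute``,
  * treatment status (on/off the assigned anticoagulation strategy),
plus one absorbing ``Dead`` state.  With two-event histories restricted to
recurrences of the events already experienced, this yields 27 alive state
shapes x 2 treatment statuses + Dead = 55 states.

Short-term events (CRNMB, REV, SE) never change state; their per-cycle
probabilities are tracked as intensities for costing and disutility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .parameters import LONG_TERM_EVENTS

_LT_INDEX = {e: i for i, e in enumerate(LONG_TERM_EVENTS)}


@dataclass(frozen=True)
class HealthState:
    """One cohort state; ``history`` is sorted in canonical event order."""

    history: tuple = ()
    phase: str = "event_free"      # event_free | acute | post_acute | dead
    acute_event: Optional[str] = None
    on_treatment: Optional[bool] = None   # None only for Dead

    def label(self) -> str:
        if self.phase == "dead":
            return "dead"
        tx = "on" if self.on_treatment else "off"
        if self.phase == "event_free":
            return f"event_free|{tx}"
        hist = "+".join(self.history)
        if self.phase == "acute":
            return f"acute[{self.acute_event}]|{hist}|{tx}"
        return f"post|{hist}|{tx}"


DEAD = HealthState(phase="dead")


def _sorted_history(events) -> tuple:
    return tuple(sorted(set(events), key=_LT_INDEX.__getitem__))


def allowed_future_events(history: tuple) -> tuple:
    """Events a patient with this history can still experience.

    With fewer than two distinct prior events, all four long-term events
    remain possible; once two have occurred, only recurrences of those two.
    """
    if len(history) < 2:
        return LONG_TERM_EVENTS
    return history


class StateSpace:
    """Ordered state list plus the index arrays the engine vectorizes over."""

    def __init__(self):
        states: list[HealthState] = []
        for on in (True, False):
            states.append(HealthState(phase="event_free", on_treatment=on))
            for e in LONG_TERM_EVENTS:
                h = (e,)
                states.append(HealthState(history=h, phase="acute",
                                          acute_event=e, on_treatment=on))
                states.append(HealthState(history=h, phase="post_acute",
                                          on_treatment=on))
            for i, e1 in enumerate(LONG_TERM_EVENTS):
                for e2 in LONG_TERM_EVENTS[i + 1:]:
                    h = _sorted_history((e1, e2))
                    for ae in h:
                        states.append(HealthState(history=h, phase="acute",
                                                  acute_event=ae,
                                                  on_treatment=on))
                    states.append(HealthState(history=h, phase="post_acute",
                                              on_treatment=on))
        states.append(DEAD)
        self.states = states
        self.index = {s: i for i, s in enumerate(states)}
        self.n = len(states)
        self.dead = self.n - 1
        self.n_alive = self.n - 1
        self._build_arrays()

    # -- structural queries -------------------------------------------------

    def acute_state(self, history: tuple, event: str, on: bool) -> HealthState:
        """Destination acute state after ``event`` given a prior history.

        A recurrence maps back to the acute state for that (event, history);
        a new event joins the history (at most two distinct events).
        """
        new_hist = _sorted_history(history + (event,))
        if len(new_hist) > 2:
            raise ValueError(f"event {event} not allowed with history {history}")
        return HealthState(history=new_hist, phase="acute", acute_event=event,
                           on_treatment=on)

    def progression(self, state: HealthState, on: bool) -> HealthState:
        """Where a patient with no new event goes: acute states progress to
        post-acute after exactly one cycle, others persist."""
        if state.phase == "acute":
            return HealthState(history=state.history, phase="post_acute",
                               on_treatment=on)
        return HealthState(history=state.history, phase=state.phase,
                           on_treatment=on)

    # -- vectorized structure ----------------------------------------------

    def _build_arrays(self) -> None:
        na = self.n_alive
        ne = len(LONG_TERM_EVENTS)
        self.on_mask = np.zeros(na, dtype=bool)
        self.is_acute = np.zeros(na, dtype=bool)
        self.is_post = np.zeros(na, dtype=bool)
        self.hist_mask = np.zeros((na, ne), dtype=bool)
        self.acute_event_idx = np.full(na, -1, dtype=int)
        self.allowed = np.zeros((na, ne), dtype=bool)
        self.dest_on = np.zeros((na, ne), dtype=int)
        self.dest_off = np.zeros((na, ne), dtype=int)
        self.prog_on = np.zeros(na, dtype=int)
        self.prog_off = np.zeros(na, dtype=int)

        for i, s in enumerate(self.states[:na]):
            self.on_mask[i] = bool(s.on_treatment)
            self.is_acute[i] = s.phase == "acute"
            self.is_post[i] = s.phase == "post_acute"
            for e in s.history:
                self.hist_mask[i, _LT_INDEX[e]] = True
            if s.acute_event is not None:
                self.acute_event_idx[i] = _LT_INDEX[s.acute_event]
            for e in allowed_future_events(s.history):
                j = _LT_INDEX[e]
                self.allowed[i, j] = True
                self.dest_on[i, j] = self.index[
                    self.acute_state(s.history, e, True)]
                self.dest_off[i, j] = self.index[
                    self.acute_state(s.history, e, False)]
            self.prog_on[i] = self.index[self.progression(s, True)]
            self.prog_off[i] = self.index[self.progression(s, False)]

    def history_multipliers(self, hrs, combination: str = "product") -> np.ndarray:
        """(n_alive, 4) multiplier on each future long-term event hazard from
        the state's event history (proportional-hazards stacking)."""
        na, ne = self.n_alive, len(LONG_TERM_EVENTS)
        out = np.ones((na, ne))
        for i, s in enumerate(self.states[:na]):
            for j, future in enumerate(LONG_TERM_EVENTS):
                vals = [hrs.subsequent[prior][future] for prior in s.history]
                if not vals:
                    continue
                out[i, j] = (np.prod(vals) if combination == "product"
                             else max(vals))
        return out

    def mortality_hrs(self, hrs) -> np.ndarray:
        """Excess-mortality HR vs the general population per alive state.

        Event-free states carry the prior-ACS/PCI HR; OMB history has no
        excess-mortality estimate and conservatively uses the same value.
        Two-event histories combine multiplicatively.
        """
        base = hrs.postacute_mortality
        out = np.empty(self.n_alive)
        for i, s in enumerate(self.states[:self.n_alive]):
            if not s.history:
                out[i] = base["event_free"]
            else:
                hr = 1.0
                for e in s.history:
                    hr *= base.get(e, base["event_free"])
                out[i] = hr
        return out


def enumerate_states() -> StateSpace:
    """Build the 55-state space with its deterministic ordering."""
    return StateSpace()
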