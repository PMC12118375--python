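"""Candidate tray scenarios and the set-assignment / tray-counting rules.

A *tray scenario* partitions (or covers, when an overlapping size is
allowed) the seven modeled femoral sizes into one to three *size sets*;
each set is housed on physical surgical trays — one tray for up to three
sizes, two trays beyond that. Preoperatively, the predicted size selects
the set to prepare; if the predicted size sits in two sets, the set with
the higher summed size probability is prepared. When the implanted size
turns out to lie outside the prepared set, the trays of the cheapest set
containing it are opened in addition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .size_model import MODEL_SIZES, normalize_size

_ORDER = {s: i for i, s in enumerate(MODEL_SIZES)}


def _merged(size) -> str:
    s = normalize_size(size)
    return "4" if s == "4N" else s


@dataclass(frozen=True)
class TrayScenario:
    """An identifier plus 1–3 ordered size sets covering all seven sizes."""

    id: str
    sets: tuple

    def __post_init__(self):
        sets = tuple(tuple(_merged(s) for s in ss) for ss in self.sets)
        object.__setattr__(self, "sets", sets)
        if not 1 <= len(sets) <= 3:
            raise ValueError("a scenario has between 1 and 3 size sets")
        seen = []
        for ss in sets:
            if len(ss) == 0:
                raise ValueError("size sets must be nonempty")
            if len(set(ss)) != len(ss):
                raise ValueError(f"duplicate size within a set: {ss}")
            seen.extend(ss)
        if set(seen) != set(MODEL_SIZES):
            raise ValueError(f"scenario {self.id}: sets must jointly cover all "
                             f"sizes {MODEL_SIZES}")

    @property
    def overlap(self) -> bool:
        """True iff some size appears in at least two sets."""
        all_members = [s for ss in self.sets for s in ss]
        return len(all_members) != len(set(all_members))

    def sets_containing(self, size) -> list:
        s = _merged(size)
        return [i for i, ss in enumerate(self.sets) if s in ss]

    def describe(self) -> str:
        return " | ".join(" & ".join(ss) for ss in self.sets)


_CATALOG_SPEC = {
    "A": (("1.5", "6"), ("2", "2.5"), ("3", "4", "5")),
    "B": (("1.5", "6"), ("2", "2.5"), ("2.5", "3", "4", "5")),
    "C": (("1.5", "6"), ("2", "2.5", "3"), ("4", "5")),
    "D": (("1.5", "6"), ("2", "2.5", "3"), ("3", "4", "5")),
    "E": (("1.5", "6"), ("2", "2.5", "3", "4"), ("4", "5")),
    "F": (("1.5", "2", "2.5"), ("3", "4", "5", "6")),
    "G": (("1.5", "2", "2.5"), ("2.5", "3", "4", "5", "6")),
    "H": (("1.5", "2", "2.5", "3"), ("4", "5", "6")),
    "I": (("1.5", "2", "2.5", "3"), ("3", "4", "5", "6")),
    "J": (("1.5", "2", "2.5", "3", "4"), ("5", "6")),
    "K": (("1.5", "2", "2.5", "3", "4"), ("4", "5", "6")),
    "L": (("1.5", "2", "2.5", "3", "4", "5", "6"),),
}


def catalog() -> dict:
    """The twelve investigated tray scenarios, keyed A–L."""
    return {sid: TrayScenario(id=sid, sets=sets) for sid, sets in _CATALOG_SPEC.items()}


def trays_required(size_set: Sequence) -> int:
    """Physical trays to house a size set: 1 for up to 3 sizes, else 2."""
    n = len(size_set)
    if n == 0:
        raise ValueError("empty size set")
    return 1 if n <= 3 else 2


def cheapest_containing_set(scenario: TrayScenario, size) -> int:
    """Index of the containing set with the fewest trays (ties: lower index)."""
    members = scenario.sets_containing(size)
    if not members:
        raise ValueError(f"size {size!r} is in no set of scenario {scenario.id}")
    return min(members, key=lambda i: (trays_required(scenario.sets[i]), i))


def assign_set(probs: Mapping, scenario: TrayScenario, rule: str = "anchored") -> int:
    """Choose the set to prepare from per-size probabilities (0-based index).

    ``rule="anchored"`` (default): the most probable size identifies the
    candidate sets; if it belongs to two sets, the one with the higher summed
    member probability wins (ties: lower index). ``rule="sum"`` skips the
    anchoring and directly takes the set with the highest summed probability.
    """
    p = {_merged(k): float(v) for k, v in dict(probs).items()}
    vals = np.asarray(list(p.values()))
    if np.any(vals < -1e-9) or abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be a simplex over the sizes")
    sums = [sum(p.get(s, 0.0) for s in ss) for ss in scenario.sets]
    if rule == "sum":
        return int(np.argmax(sums))
    if rule != "anchored":
        raise ValueError(f"unknown assignment rule {rule!r}")
    predicted = max(sorted(p, key=lambda s: _ORDER[s]), key=lambda s: p[s])
    # max() returns the first maximal element, i.e. the smaller size on ties
    candidates = scenario.sets_containing(predicted)
    if not candidates:
        raise ValueError(f"predicted size {predicted!r} is in no set")
    if len(candidates) == 1:
        return candidates[0]
    return max(candidates, key=lambda i: (sums[i], -i))


def is_correct(scenario: TrayScenario, assigned: int, actual_size) -> bool:
    """True iff the implanted size was in the prepared set."""
    return _merged(actual_size) in scenario.sets[assigned]


def patient_tray_count(scenario: TrayScenario, assigned: int, actual_size) -> int:
    """Size-specific trays opened for one case.

    The prepared set's trays are always opened; a misprediction additionally
    opens the trays of the cheapest set containing the implanted size.
    """
    count = trays_required(scenario.sets[assigned])
    if not is_correct(scenario, assigned, actual_size):
        count += trays_required(scenario.sets[cheapest_containing_set(scenario, actual_size)])
    return count


def membership_arrays(scenario: TrayScenario):
    """Vectorized scenario tables over the seven modeled sizes.

    Returns ``(membership, trays, cheapest_addon)`` where ``membership`` is a
    bool array (n_sets, 7) over :data:`MODEL_SIZES`, ``trays`` the per-set
    tray count, and ``cheapest_addon`` the per-size tray cost of the cheapest
    containing set.
    """
    m = np.zeros((len(scenario.sets), len(MODEL_SIZES)), dtype=bool)
    for i, ss in enumerate(scenario.sets):
        for s in ss:
            m[i, _ORDER[s]] = True
    trays = np.asarray([trays_required(ss) for ss in scenario.sets])
    cheapest = np.asarray([trays[cheapest_containing_set(scenario, s)] for s in MODEL_SIZES])
    return m, trays, cheapest


# ------------------------------------------------------------- JSON config

def scenarios_to_json(scenarios: Mapping) -> str:
    return json.dumps({sid: [list(ss) for ss in sc.sets]
                       for sid, sc in scenarios.items()}, indent=1)


def scenarios_from_json(text: str) -> dict:
    doc = json.loads(text)
    return {sid: TrayScenario(id=sid, sets=tuple(tuple(ss) for ss in sets))
            for sid, sets in doc.items()}
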