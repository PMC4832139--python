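"""Trial outcome categorization and detection rates.

Each trial is assigned exactly one category from the set of response types
present: express/regular saccades (from the detector) and explicit
detection (a button press attributed to the trial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError

CATEGORIES = ("express_only", "regular_only", "explicit_only",
              "express+regular", "express+explicit", "regular+explicit",
              "multiple_other", "undetected")

#: Categories used for kernel estimation (mutually exclusive responses).
KERNEL_CATEGORIES = ("express_only", "regular_only", "explicit_only")

DEFAULT_PRESS_DEADLINE_MS = 1500.0


@dataclass
class TrialOutcome:
    trial_id: int
    category: str
    press_latency_ms: float | None = None


def _category_from_types(has_express: bool, has_regular: bool,
                         has_explicit: bool) -> str:
    types = (has_express, has_regular, has_explicit)
    mapping = {
        (True, False, False): "express_only",
        (False, True, False): "regular_only",
        (False, False, True): "explicit_only",
        (True, True, False): "express+regular",
        (True, False, True): "express+explicit",
        (False, True, True): "regular+explicit",
        (True, True, True): "multiple_other",
        (False, False, False): "undetected",
    }
    return mapping[types]


def bin_trial(trial_id: int, saccades, presses, t_disp: float,
              t_next: float = np.inf,
              press_deadline_ms: float = DEFAULT_PRESS_DEADLINE_MS,
              ) -> TrialOutcome:
    """Categorize one trial from its classified saccades and button presses.

    A press belongs to the trial if it falls in (t_disp, min(t_next,
    t_disp + deadline)].  ``saccades`` is any iterable with ``klass``
    attributes (unclassified events are ignored).
    """
    has_express = any(s.klass == "express" for s in saccades)
    has_regular = any(s.klass == "regular" for s in saccades)
    cutoff = min(t_next, t_disp + press_deadline_ms)
    attributed = [p for p in presses if t_disp < p <= cutoff]
    has_explicit = bool(attributed)
    latency = min(attributed) - t_disp if attributed else None
    return TrialOutcome(
        trial_id=trial_id,
        category=_category_from_types(has_express, has_regular, has_explicit),
        press_latency_ms=latency)


def bin_session(saccade_table: pd.DataFrame, presses,
                displacement_times,
                press_deadline_ms: float = DEFAULT_PRESS_DEADLINE_MS,
                ) -> pd.DataFrame:
    """Bin every trial of a session; returns one row per trial."""
    times = np.asarray(displacement_times, dtype=float)
    rows = []
    for trial_id, t_disp in enumerate(times):
        t_next = times[trial_id + 1] if trial_id + 1 < len(times) else np.inf
        if len(saccade_table):
            sub = saccade_table[saccade_table["trial_id"] == trial_id]
            sacc = list(sub.itertuples())
        else:
            sacc = []
        out = bin_trial(trial_id, sacc, presses, t_disp, t_next,
                        press_deadline_ms)
        rows.append({"trial_id": out.trial_id, "category": out.category,
                     "press_latency_ms": out.press_latency_ms})
    return pd.DataFrame(rows, columns=["trial_id", "category",
                                       "press_latency_ms"])


def detection_rates(outcomes: pd.DataFrame) -> pd.Series:
    """Percentage of all trials in each category (sums to 100)."""
    if len(outcomes) == 0:
        raise InsufficientDataError("no trials to compute rates from")
    counts = outcomes["category"].value_counts()
    rates = pd.Series(0.0, index=list(CATEGORIES))
    for cat, c in counts.items():
        rates[cat] = 100.0 * c / len(outcomes)
    return rates
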