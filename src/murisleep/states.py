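"""Arousal-state vocabulary.

Four states are scored per 10-s epoch: wake, theta-dominated wake, NREM and
REM sleep. A fifth label marks epochs removed by quality control.
"""
from __future__ import annotations

from enum import IntEnum


class State(IntEnum):
    WAKE = 0
    THETA_WAKE = 1
    NREM = 2
    REM = 3
    ARTEFACT = 4


#: The four scorable states, in transition-matrix index order.
SCORABLE_STATES = (State.WAKE, State.THETA_WAKE, State.NREM, State.REM)

#: Fixed tie-break order used by the classifier.
TIEBREAK_ORDER = (State.NREM, State.REM, State.THETA_WAKE, State.WAKE)

#: States counted as wakefulness in architecture metrics (theta-dominated
#: wake is reported merged into wake).
WAKE_LIKE = (State.WAKE, State.THETA_WAKE)

#: States counted as sleep.
SLEEP_STATES = (State.NREM, State.REM)
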