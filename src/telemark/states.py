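"""State and observation spaces of the multistate (Arnason-Schwarz) model.

The study region is a sound connected to an open gulf through three
monitored entrances.  A tagged fish occupies exactly one of eight latent
states each week:

    1  expired (absorbing; tag shedding and permanent emigration are
       confounded with death)
    2  at a spawning-ground receiver array
    3  at an interior receiver array
    4  inside the sound but away from every receiver
    5  at the Hinchinbrook entrance array
    6  at the Strait entrance array
    7  at the Passages entrance array
    8  in the gulf (no receivers)

Detection is assumed certain when a fish passes an array, so the
observation code is a deterministic function of the state: states 1, 4
and 8 all emit "no detection" (code 1) and each array state emits its own
code.  The allowed one-step moves encode the geography: the spawning
grounds and interior arrays exchange fish only with the open sound
(state 4); each entrance exchanges fish with the sound and the gulf;
mortality is only possible from states 4 and 8 (a fish within reception
range is always detected, hence cannot silently disappear there).
"""

from __future__ import annotations

import numpy as np

N_STATES = 8
N_OBS = 6

EXPIRED = 1
SPAWN = 2
INTERIOR = 3
SOUND = 4
HINCHINBROOK = 5
STRAIT = 6
PASSAGES = 7
GULF = 8

STATES = tuple(range(1, N_STATES + 1))
OBS_CODES = tuple(range(1, N_OBS + 1))

#: entrance states, in the fixed order used throughout
ENTRANCE_STATES = (HINCHINBROOK, STRAIT, PASSAGES)

#: states from which death (transition to state 1) is possible
MORTAL_STATES = (SOUND, GULF)

#: allowed destinations (including death) per origin state
ALLOWED_TRANSITIONS = {
    1: (1,),
    2: (2, 4),
    3: (3, 4),
    4: (1, 2, 3, 4, 5, 6, 7),
    5: (4, 5, 8),
    6: (4, 6, 8),
    7: (4, 7, 8),
    8: (1, 5, 6, 7, 8),
}

#: movement destinations (conditional on survival) per live origin state;
#: the order fixes the layout of every Dirichlet block
MOVE_DESTS = {
    2: (2, 4),
    3: (3, 4),
    4: (2, 3, 4, 5, 6, 7),
    5: (4, 5, 8),
    6: (4, 6, 8),
    7: (4, 7, 8),
    8: (5, 6, 7, 8),
}

#: deterministic emission: state -> observation code
STATE_TO_OBS = {1: 1, 2: 2, 3: 3, 4: 1, 5: 4, 6: 5, 7: 6, 8: 1}

#: inverse emission: observation code -> feasible states
OBS_TO_STATES = {1: (1, 4, 8), 2: (2,), 3: (3,), 4: (5,), 5: (6,), 6: (7,)}

#: entrance name <-> entrance state
ENTRANCE_STATE_BY_ID = {"hinchinbrook": 5, "strait": 6, "passages": 7}
ENTRANCE_ID_BY_STATE = {v: k for k, v in ENTRANCE_STATE_BY_ID.items()}


def feasible_states(x: int) -> tuple[int, ...]:
    """States compatible with observation code ``x``.

    Code 1 (no detection) is ambiguous between expired, in-sound away
    from receivers, and in-gulf; every array code pins the state down.
    """
    try:
        return OBS_TO_STATES[x]
    except KeyError:
        raise ValueError(f"observation code must be in 1..{N_OBS}, got {x!r}") from None


def emission_matrix() -> np.ndarray:
    """The fixed 6x8 zero/one emission matrix, rows = codes, cols = states."""
    E = np.zeros((N_OBS, N_STATES))
    for r, t in STATE_TO_OBS.items():
        E[t - 1, r - 1] = 1.0
    return E


def feasible_mask() -> np.ndarray:
    """Boolean (7, 8) lookup: row x (codes 0..6, 0 unused) -> feasible states."""
    mask = np.zeros((N_OBS + 1, N_STATES), dtype=bool)
    for x, states in OBS_TO_STATES.items():
        for s in states:
            mask[x, s - 1] = True
    return mask


def pair_is_possible(x1: int, x2: int) -> bool:
    """Can observation ``x2`` follow ``x1`` on consecutive occasions?

    True iff some allowed state transition links a state feasible for
    ``x1`` to one feasible for ``x2``.
    """
    for r in feasible_states(x1):
        for s in feasible_states(x2):
            if s in ALLOWED_TRANSITIONS[r]:
                return True
    return False
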