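"""The two-state behavioral track type shared by the simulator and the
analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["RUN", "TURN", "STATE_CODES", "StateTrack"]

RUN = "RUN"
TURN = "TURN"

#: Integer coding used internally: RUN = 0, TURN = 1.
STATE_CODES = {RUN: 0, TURN: 1}
_CODE_STATES = {v: k for k, v in STATE_CODES.items()}


@dataclass(frozen=True)
class StateTrack:
    """One animal's RUN/TURN state sequence on the stimulus clock.

    ``states`` is stored as an int8 array (0 = RUN, 1 = TURN); ``speed``
    is optional and, when present, has the same length as ``states``.
    """

    animal_id: str
    t0: float
    dt: float
    states: np.ndarray = field(repr=False)
    speed: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.dtype.kind in "UO":
            try:
                states = np.array([STATE_CODES[s] for s in states], dtype=np.int8)
            except KeyError as exc:
                raise InvalidArgumentError(f"unknown state label {exc.args[0]!r}") from None
        else:
            states = states.astype(np.int8)
            if not np.isin(states, (0, 1)).all():
                raise InvalidArgumentError("state codes must be 0 (RUN) or 1 (TURN)")
        if states.ndim != 1 or states.size < 1:
            raise InvalidArgumentError("states must be a non-empty 1-D sequence")
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        object.__setattr__(self, "states", states)
        if self.speed is not None:
            speed = np.asarray(self.speed, dtype=np.float64)
            if speed.shape != states.shape:
                raise InvalidArgumentError("speed must have the same length as states")
            object.__setattr__(self, "speed", speed)

    @property
    def n_samples(self) -> int:
        return int(self.states.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def state_labels(self) -> list[str]:
        """States as 'RUN'/'TURN' strings (for serialization)."""
        return [_CODE_STATES[int(c)] for c in self.states]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_samples
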