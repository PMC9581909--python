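"""Sleep/wake stage vocabulary and disease-state labels.

Staging follows AASM-style 30-s epoch scoring adapted to macaques: two wake
stages (active wake ``A`` and quiet wake ``W``), three non-REM stages
(``N1``, ``N2``, ``N3``) and REM sleep (``R``).  An ``UNSCORED`` sentinel
marks epochs without a valid score; such epochs are excluded from every
"total scoring time" denominator.
"""

from __future__ import annotations

import enum


class StageLabel(enum.Enum):
    """One 30-s epoch's sleep/wake score."""

    A = "A"    # active wake
    W = "W"    # quiet wake
    N1 = "N1"  # light non-REM, stage 1
    N2 = "N2"  # light non-REM, stage 2
    N3 = "N3"  # deep (slow-wave) non-REM
    R = "R"    # REM sleep
    UNSCORED = "UNSCORED"

    @property
    def is_wake(self) -> bool:
        """True for the wake group {A, W}."""
        return self in _WAKE

    @property
    def is_sleep(self) -> bool:
        """True for the sleep group {N1, N2, N3, R}."""
        return self in _SLEEP

    @property
    def is_scored(self) -> bool:
        return self is not StageLabel.UNSCORED

    def __str__(self) -> str:  # tokens used in hypnogram CSVs
        return self.value


_WAKE = frozenset({StageLabel.A, StageLabel.W})
_SLEEP = frozenset({StageLabel.N1, StageLabel.N2, StageLabel.N3, StageLabel.R})

#: The six scorable stages, in canonical order.
SCORED_STAGES: tuple[StageLabel, ...] = (
    StageLabel.A,
    StageLabel.W,
    StageLabel.N1,
    StageLabel.N2,
    StageLabel.N3,
    StageLabel.R,
)

WAKE_STAGES: tuple[StageLabel, ...] = (StageLabel.A, StageLabel.W)
SLEEP_STAGES: tuple[StageLabel, ...] = (
    StageLabel.N1,
    StageLabel.N2,
    StageLabel.N3,
    StageLabel.R,
)


class Condition(enum.Enum):
    """Disease state of a progressive parkinsonian induction."""

    HEALTHY = "healthy"
    PRESYMPTOMATIC = "presymptomatic"
    SYMPTOMATIC = "symptomatic"

    def __str__(self) -> str:
        return self.value


def parse_stage(token: str) -> StageLabel:
    """Parse a stage token (``A``, ``W``, ``N1``...``N3``, ``R``, ``UNSCORED``).

    Raises
    ------
    ValueError
        If the token is not one of the seven defined labels.
    """
    try:
        return StageLabel(token.strip())
    except ValueError:
        valid = ", ".join(s.value for s in StageLabel)
        raise ValueError(f"unknown stage token {token!r}; expected one of {valid}") from None
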