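"""Oddball stimulus sequences.

Two-block passive oddball design with syllables /pa/ (266 ms) and /ga/
(409 ms): one block uses /ga/ as the frequent standard and /pa/ as the rare
deviant, the other block swaps the assignment.  A block presents 600 stimuli
by default — 510 standards (85%) and 90 deviants (15%) — with at least two
standards between consecutive deviants and an offset-to-onset ISI drawn
uniformly from 1450–1750 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: syllable durations in ms, used for offset-to-onset bookkeeping
SYLLABLE_DURATION_MS = {"pa": 266.0, "ga": 409.0}

#: standard/deviant syllable assignment per block (block 2 swaps block 1)
BLOCK_SYLLABLES = {1: {"standard": "ga", "deviant": "pa"},
                   2: {"standard": "pa", "deviant": "ga"}}

STANDARD = "standard"
DEVIANT = "deviant"


class SpacingInfeasibleError(ValueError):
    """Deviant count incompatible with the minimum-spacing constraint."""

    def __init__(self, n_total: int, n_deviant: int, min_spacing: int):
        self.max_feasible = max_feasible_deviants(n_total, min_spacing)
        super().__init__(
            f"cannot place {n_deviant} deviants among {n_total} trials with "
            f">={min_spacing} standards between deviants; the maximum feasible "
            f"number of deviants is {self.max_feasible}"
        )


def max_feasible_deviants(n_total: int, min_spacing: int) -> int:
    """Largest deviant count d with d + (d-1)*min_spacing <= n_total."""
    return (n_total + min_spacing) // (min_spacing + 1)


@dataclass(frozen=True)
class StimulusSequence:
    """One ordered oddball block.

    ``trials`` holds one row per stimulus with columns ``onset_ms`` (from
    block start), ``condition`` (standard/deviant) and ``syllable``.
    """

    trials: pd.DataFrame
    block_id: int
    isi_range_ms: tuple[float, float]
    lead_in_ms: float = field(default=1000.0)

    @property
    def n_total(self) -> int:
        return len(self.trials)

    @property
    def n_deviant(self) -> int:
        return int((self.trials["condition"] == DEVIANT).sum())

    def to_events(self) -> pd.DataFrame:
        """Events table (onset_ms, condition, syllable, block) for disk I/O."""
        ev = self.trials.copy()
        ev["block"] = self.block_id
        return ev


def _deviant_positions(rng: np.random.Generator, n_total: int, n_deviant: int,
                       min_spacing: int) -> np.ndarray:
    """Uniform draw over deviant position sets obeying the spacing rule.

    Stars-and-bars bijection: choose ``n_deviant`` sorted slots from a
    contracted range, then re-expand by ``min_spacing`` per preceding deviant.
    """
    if n_deviant == 0:
        return np.empty(0, dtype=int)
    m = n_total - (n_deviant - 1) * min_spacing
    slots = np.sort(rng.choice(m, size=n_deviant, replace=False))
    return slots + min_spacing * np.arange(n_deviant)


def generate_stimulus_block(block_id: int, n_total: int = 600, n_deviant: int = 90,
                            min_spacing: int = 2,
                            isi_range_ms: tuple[float, float] = (1450.0, 1750.0),
                            seed: int | np.random.SeedSequence = 0,
                            lead_in_ms: float = 1000.0) -> StimulusSequence:
    """Generate one pseudorandomized oddball block.

    Raises
    ------
    SpacingInfeasibleError
        If ``n_deviant`` deviants cannot be placed with ``min_spacing``
        standards between consecutive deviants; the error names the maximum
        feasible count.
    """
    if block_id not in BLOCK_SYLLABLES:
        raise ValueError(f"block_id must be 1 or 2, got {block_id}")
    if n_total <= 0 or n_deviant < 0 or n_deviant >= n_total and n_deviant > 0:
        raise ValueError(f"need n_total > n_deviant >= 0, got {n_total}, {n_deviant}")
    if n_deviant > max_feasible_deviants(n_total, min_spacing):
        raise SpacingInfeasibleError(n_total, n_deviant, min_spacing)
    lo, hi = isi_range_ms
    if not 0 < lo <= hi:
        raise ValueError(f"invalid ISI range {isi_range_ms}")

    rng = np.random.default_rng(seed)
    condition = np.full(n_total, STANDARD, dtype=object)
    condition[_deviant_positions(rng, n_total, n_deviant, min_spacing)] = DEVIANT
    syllables = BLOCK_SYLLABLES[block_id]
    syllable = np.where(condition == DEVIANT, syllables[DEVIANT], syllables[STANDARD])

    durations = np.array([SYLLABLE_DURATION_MS[s] for s in syllable])
    isis = rng.uniform(lo, hi, size=n_total)  # ISI after each stimulus offset
    onsets = np.empty(n_total)
    onsets[0] = lead_in_ms
    np.cumsum(durations[:-1] + isis[:-1], out=onsets[1:])
    onsets[1:] += lead_in_ms

    trials = pd.DataFrame({"onset_ms": onsets, "condition": condition,
                           "syllable": syllable})
    return StimulusSequence(trials=trials, block_id=block_id,
                            isi_range_ms=(float(lo), float(hi)),
                            lead_in_ms=lead_in_ms)
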