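"""Repetition priming of oral-reading latencies.

A reading session is a sequence of visually presented non-words with voice
onset/offset times.  Some non-words occur twice; the second reading is
faster, and the benefit decays with the interval since the first reading.
This module pairs the repetitions and summarizes the benefit per interval
bin, in both milliseconds and percent of the first-presentation RT (the
percent measure is invariant to a uniform slowdown, which is what makes
groups with different baseline speeds comparable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReadingSession", "RepetitionPair", "pair_repetitions",
           "repetition_benefit", "DEFAULT_BINS"]

#: interval bins in seconds: "short" (< 2 s) and "long" (>= 2 s)
DEFAULT_BINS: tuple[tuple[float, float], ...] = ((0.0, 2.0), (2.0, np.inf))

REQUIRED_COLUMNS = ("token", "block", "visual_onset_ms", "voice_onset_ms",
                    "voice_offset_ms", "correct")


@dataclass
class ReadingSession:
    """Ordered oral-reading trials backed by a DataFrame with columns
    token, block, visual_onset_ms, voice_onset_ms, voice_offset_ms, correct."""

    trials: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        t = self.trials
        if not t["visual_onset_ms"].is_monotonic_increasing:
            raise ValueError("visual onsets must be increasing")
        if not (t["voice_onset_ms"] > t["visual_onset_ms"]).all():
            raise ValueError("voice onset must follow visual onset")
        if not (t["voice_offset_ms"] > t["voice_onset_ms"]).all():
            raise ValueError("voice offset must follow voice onset")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def rt_ms(self) -> pd.Series:
        return self.trials["voice_onset_ms"] - self.trials["visual_onset_ms"]

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReadingSession":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class RepetitionPair:
    """First and second presentation of one twice-presented non-word."""

    token: str
    rt_first: float       # ms
    rt_second: float      # ms
    delta_t: float        # s, first voice offset -> second visual onset
    n_intervening: int

    def __post_init__(self):
        if self.n_intervening < 1:
            raise ValueError("repetitions must have >= 1 intervening item")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")

    @property
    def benefit_ms(self) -> float:
        return self.rt_first - self.rt_second

    @property
    def benefit_pct(self) -> float:
        return 100.0 * (self.rt_first - self.rt_second) / self.rt_first


def pair_repetitions(
    session: ReadingSession,
    require_correct: bool = True,
    delta_t_mode: str = "offset_to_onset",
) -> list[RepetitionPair]:
    """One pair per twice-presented token.

    Tokens occurring more than twice raise a validation error.  With
    ``require_correct`` (default), pairs with a reading error at either
    presentation are dropped.  ``delta_t_mode`` selects the interval
    definition: first voice offset to second visual onset (default) or
    ``onset_to_onset`` (visual onsets).
    """
    if delta_t_mode not in ("offset_to_onset", "onset_to_onset"):
        raise ValueError("unknown delta_t_mode")
    t = session.trials.reset_index(drop=True)
    counts = t["token"].value_counts()
    if (counts > 2).any():
        bad = counts[counts > 2].index[0]
        raise ValueError(f"token {bad!r} appears more than twice")

    rt = (t["voice_onset_ms"] - t["visual_onset_ms"]).to_numpy()
    pairs: list[RepetitionPair] = []
    for token in counts[counts == 2].index:
        i1, i2 = np.flatnonzero((t["token"] == token).to_numpy())
        if require_correct and not (t.loc[i1, "correct"] and t.loc[i2, "correct"]):
            continue
        if delta_t_mode == "offset_to_onset":
            dt = (t.loc[i2, "visual_onset_ms"] - t.loc[i1, "voice_offset_ms"]) / 1000.0
        else:
            dt = (t.loc[i2, "visual_onset_ms"] - t.loc[i1, "visual_onset_ms"]) / 1000.0
        pairs.append(RepetitionPair(token=token, rt_first=float(rt[i1]),
                                    rt_second=float(rt[i2]), delta_t=float(dt),
                                    n_intervening=int(i2 - i1 - 1)))
    pairs.sort(key=lambda p: p.delta_t)
    return pairs


def repetition_benefit(
    pairs: list[RepetitionPair],
    bins: tuple[tuple[float, float], ...] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Mean benefit per interval bin.

    Returns one row per bin with mean percent benefit, mean millisecond
    benefit and pair count; empty bins are flagged (``valid = False``) and
    must be excluded from group statistics.
    """
    rows = []
    for lo, hi in bins:
        sel = [p for p in pairs if lo <= p.delta_t < hi]
        rows.append(dict(
            bin_lo_s=lo, bin_hi_s=hi, n=len(sel),
            benefit_pct=np.mean([p.benefit_pct for p in sel]) if sel else np.nan,
            benefit_ms=np.mean([p.benefit_ms for p in sel]) if sel else np.nan,
            mean_delta_t_s=np.mean([p.delta_t for p in sel]) if sel else np.nan,
            valid=bool(sel),
        ))
    return pd.DataFrame(rows)
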