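"""Extreme-emotion stimulus selection from a rated pool.

From a large rated pool, two excerpts are chosen per discrete emotion
(rated very high on that scale and low on the other four), two per pole
of each dimensional scale, and two per pole of the merged
Beauty/Liking *Preference* variable.  The scoring statistics:

* discrete:   rating(target) − max(other four discrete ratings)
* dimensional, high pole: rating(target) − max(other two); low pole:
  rating(target) − min(other two), minimised
* Preference: mean(Beauty, Liking)

Slot arithmetic gives 5·2 + 3·2·2 + 2·2 = 26 labelled slots; the
de-duplicated list may be smaller (a stimulus can win several slots) and
is returned alongside the slots rather than forced to any fixed count.
Ties are broken by stimulus id order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .simulate import DISCRETE_SCALES, DIMENSIONAL_SCALES, StimulusRecord

__all__ = ["SelectionResult", "discrete_score", "dimensional_score",
           "merge_preference", "select_extremes", "selection_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    scale: str
    pole: str                      # "high" or "low"
    chosen: tuple[str, ...]        # stimulus ids, best first
    scores: tuple[float, ...]


def discrete_score(record: StimulusRecord, target: str) -> float:
    if target not in DISCRETE_SCALES:
        raise ValueError(f"unknown discrete scale {target!r}")
    others = [record.discrete[s] for s in DISCRETE_SCALES if s != target]
    return record.discrete[target] - max(others)


def dimensional_score(record: StimulusRecord, target: str, pole: str) -> float:
    if target not in DIMENSIONAL_SCALES:
        raise ValueError(f"unknown dimensional scale {target!r}")
    if pole not in ("high", "low"):
        raise ValueError(f"pole must be 'high' or 'low', got {pole!r}")
    others = [record.dimensional[s] for s in DIMENSIONAL_SCALES if s != target]
    if pole == "high":
        return record.dimensional[target] - max(others)
    return record.dimensional[target] - min(others)


def merge_preference(record: StimulusRecord) -> float:
    """Beauty and Liking merged into a single Preference score."""
    return (record.beauty + record.liking) / 2.0


def _top2(scored: list[tuple[float, str]], largest: bool) -> tuple[tuple[str, ...], tuple[float, ...]]:
    # sort by (score, id); id ascending breaks ties deterministically
    ordered = sorted(scored, key=lambda t: (-t[0] if largest else t[0], t[1]))
    ids = tuple(s for _, s in ordered[:2])
    vals = tuple(v for v, _ in ordered[:2])
    return ids, vals


def select_extremes(pool: list[StimulusRecord]) -> list[SelectionResult]:
    """Fill all 26 extreme slots from the pool (2 stimuli per slot pair)."""
    if len(pool) < 30:
        raise ValueError(f"pool of {len(pool)} too small; need at least 30")
    results = []
    for scale in DISCRETE_SCALES:
        ids, vals = _top2([(discrete_score(r, scale), r.id) for r in pool], True)
        results.append(SelectionResult(scale, "high", ids, vals))
    for scale in DIMENSIONAL_SCALES:
        for pole in ("high", "low"):
            scored = [(dimensional_score(r, scale, pole), r.id) for r in pool]
            ids, vals = _top2(scored, largest=(pole == "high"))
            results.append(SelectionResult(scale, pole, ids, vals))
    for pole in ("high", "low"):
        scored = [(merge_preference(r), r.id) for r in pool]
        ids, vals = _top2(scored, largest=(pole == "high"))
        results.append(SelectionResult("Preference", pole, ids, vals))
    distinct = {s for r in results for s in r.chosen}
    log.info("selection: %d slots, %d distinct stimuli",
             sum(len(r.chosen) for r in results), len(distinct))
    return results


def selection_table(results: list[SelectionResult]) -> pd.DataFrame:
    """Long-format slot table (slot, pole, stimulus, score)."""
    rows = [
        {"scale": r.scale, "pole": r.pole, "stimulus": s, "score": v}
        for r in results for s, v in zip(r.chosen, r.scores)
    ]
    return pd.DataFrame(rows)
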