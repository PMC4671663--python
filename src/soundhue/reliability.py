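"""Inter-rater agreement and discordant-participant screening.

Participants are treated as items and stimuli as cases; agreement per
colour parameter is Cronbach's α.  A participant whose responses on a
parameter correlate *negatively* with the mean of everyone else is
discordant; the exclusion decided on the a* parameter is applied
jointly to all four parameters (one-shot, not iterated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["cronbach_alpha", "flag_discordant", "AgreementReport", "agreement_report"]

log = logging.getLogger(__name__)

PARAMETERS = ("size", "L", "a", "b")


def _alpha_label(a: float) -> str:
    return "good" if a >= 0.7 else "acceptable" if a >= 0.5 else "poor"


def cronbach_alpha(matrix) -> float:
    """Cronbach's α of a stimuli × participants matrix.

    α = k/(k−1) · (1 − Σ item variances / variance of the item sums),
    with participants as items and sample (n−1) variances.  Raises on a
    degenerate (zero-variance) total score.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 stimuli and 2 participants")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def flag_discordant(matrix: pd.DataFrame) -> tuple[list, list]:
    """Participants negatively correlated with the mean of the others.

    Single pass: for each column, Pearson r against the mean of the
    remaining columns; r < 0 is discordant.  Constant (uninformative)
    columns cannot be correlated and are returned separately.

    Returns ``(discordant_ids, uninformative_ids)``.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 participants")
    vals = matrix.to_numpy(dtype=float)
    discordant, uninformative = [], []
    for j, col in enumerate(matrix.columns):
        x = vals[:, j]
        others = np.delete(vals, j, axis=1).mean(axis=1)
        if np.std(x) == 0 or np.std(others) == 0:
            uninformative.append(col)
            continue
        r = np.corrcoef(x, others)[0, 1]
        if r < 0:
            discordant.append(col)
    return discordant, uninformative


@dataclass
class AgreementReport:
    parameter: str
    alpha: float
    excluded: list = field(default_factory=list)
    alpha_after: float | None = None

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "alpha": self.alpha,
            "label": _alpha_label(self.alpha),
            "excluded": list(self.excluded),
            "alpha_after": self.alpha_after,
            "label_after": None if self.alpha_after is None else _alpha_label(self.alpha_after),
        }


def agreement_report(patches: pd.DataFrame, screen_parameter: str = "a"
                     ) -> list[AgreementReport]:
    """Per-parameter α before/after excluding discordant participants.

    ``patches`` is the long table (participant, stimulus, size, L, a, b).
    The exclusion is decided on ``screen_parameter`` (a* by default, the
    parameter on which discordance shows up) and applied to all four.
    """
    wide = {p: patches.pivot(index="stimulus", columns="participant", values=p)
            for p in PARAMETERS}
    disc, uninf = flag_discordant(wide[screen_parameter])
    excluded = sorted(set(disc) | set(uninf))
    reports = []
    for p in PARAMETERS:
        before = cronbach_alpha(wide[p])
        kept = wide[p].drop(columns=excluded, errors="ignore")
        after = cronbach_alpha(kept) if kept.shape[1] >= 2 else None
        log.info("agreement %s: alpha=%.3f (%s) -> %.3f after excluding %s",
                 p, before, _alpha_label(before),
                 after if after is not None else float("nan"), excluded)
        reports.append(AgreementReport(p, before, excluded, after))
    return reports
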