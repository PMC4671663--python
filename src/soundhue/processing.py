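"""Envelope → colour-patch summarisation.

Participants search before settling, so only the late part of each
response stream represents the association.  The weighting curve gives
zero weight to the first half of the samples, ramps linearly from the
midpoint to the three-quarter point, and holds the maximum to the end.
The weighted (Size, L, a, b) average over pen-down samples — after
snapping each sample through the hybrid display grid, matching the
on-screen pipeline — is the colour patch association for that
participant × stimulus; averaging those across participants gives the
per-stimulus mean patch.

Ramp convention (the endpoint convention is ours; the summation oracle
in the tests is the reference): 1-based sample index i, midpoint
h = floor(n/2), three-quarter point q = floor(3n/4),
w_i = 0 for i ≤ h, (i − h)/(q − h) for h < i ≤ q, and 1 beyond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colour import ColourPatch, HybridColourGrid, map_interface_arrays, mean_patch

__all__ = ["WeightCurve", "make_weight_curve", "summarise_envelope",
           "MissingResponse", "process_envelopes", "aggregate_by_stimulus"]

log = logging.getLogger(__name__)


class MissingResponse(Exception):
    """No pen-down sample fell in the weighted window; response excluded."""


@dataclass(frozen=True)
class WeightCurve:
    n: int
    weights: np.ndarray


def make_weight_curve(n: int) -> WeightCurve:
    """Zero / linear-ramp / plateau weights for an n-sample envelope."""
    if n < 4:
        raise ValueError("weight curve needs at least 4 samples")
    i = np.arange(1, n + 1)
    h = n // 2
    q = (3 * n) // 4
    w = np.clip((i - h) / (q - h), 0.0, 1.0)
    return WeightCurve(n=n, weights=w)


def summarise_envelope(env: pd.DataFrame, grid: HybridColourGrid) -> ColourPatch:
    """Weighted mean displayed patch of one response stream.

    ``env`` needs columns pen_down, x, y, pressure, throttle in time
    order at a fixed rate.  Pen-up samples get zero weight; raises
    :class:`MissingResponse` if nothing remains.
    """
    n = len(env)
    curve = make_weight_curve(n)
    w = curve.weights * env["pen_down"].to_numpy(dtype=float)
    if not np.any(w > 0):
        raise MissingResponse("no weighted pen-down sample in envelope")
    live = w > 0
    mapped = map_interface_arrays(
        env["x"].to_numpy()[live], env["y"].to_numpy()[live],
        env["pressure"].to_numpy()[live], env["throttle"].to_numpy()[live], grid)
    m = (mapped * w[live, None]).sum(axis=0) / w[live].sum()
    return ColourPatch(size=float(m[0]), L=float(m[1]), a=float(m[2]), b=float(m[3]))


def process_envelopes(envelopes: pd.DataFrame, grid: HybridColourGrid) -> pd.DataFrame:
    """Summarise every participant × stimulus stream.

    Returns a table (participant, stimulus, size, L, a, b); streams with
    no weighted pen-down sample are dropped and counted in the log.
    """
    rows, missing = [], 0
    for (part, stim), env in envelopes.groupby(["participant", "stimulus"], sort=True):
        try:
            p = summarise_envelope(env, grid)
        except MissingResponse:
            missing += 1
            log.warning("missing response: participant=%s stimulus=%s", part, stim)
            continue
        rows.append({"participant": part, "stimulus": stim,
                     "size": p.size, "L": p.L, "a": p.a, "b": p.b})
    if missing:
        log.info("%d missing responses excluded", missing)
    return pd.DataFrame(rows)


def aggregate_by_stimulus(patches: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean patch per stimulus across participants."""
    if patches.empty:
        raise ValueError("no patches to aggregate")
    counts = patches.groupby("stimulus").size()
    if (counts == 0).any():
        raise ValueError(f"empty stimulus group: {counts[counts == 0].index.tolist()}")
    out = (patches.groupby("stimulus")[["size", "L", "a", "b"]]
           .mean().reset_index())
    return out
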