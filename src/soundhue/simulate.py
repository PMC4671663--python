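"""Synthetic study-data generator.

Emulates the three inputs of the music–colour association experiment so
the whole analysis chain can be exercised without the (undeposited)
study data:

* a stimulus table — per-excerpt emotion ratings (five discrete, three
  dimensional, plus Beauty/Liking, all on 1–9) and 19 audio features;
* continuous response envelopes — 10 Hz streams of the four interface
  channels for every participant × stimulus, with a pen-up gap, a
  search phase, and a settle phase near an emotion-determined target;
* a participant table with gender and an optional patch-size bias.

The built-in mediation effect is the dial of interest: with
``mediation_strength`` = 1 the settled colour is a deterministic
function of the perceived emotion; at 0 it is an emotion-independent
random distractor.  Audio features are noisy linear functions of
Valence/Energy, so features predict colour only through their shared
emotional structure — the statistical shape the mediation analysis
assumes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .colour import ColourPatch

__all__ = [
    "DISCRETE_SCALES",
    "DIMENSIONAL_SCALES",
    "FEATURE_NAMES",
    "StimulusRecord",
    "GeneratorConfig",
    "generate_stimuli",
    "emotion_to_target",
    "generate_envelope",
    "generate_participants",
    "generate_dataset",
    "write_dataset",
]

DISCRETE_SCALES = ("Anger", "Fear", "Happy", "Sad", "Tender")
DIMENSIONAL_SCALES = ("Valence", "Energy", "Tension")

# 4 psychoacoustic + 15 musical features (means/medians over time frames).
FEATURE_NAMES = (
    "Loudness", "Sharpness", "Roughness", "Fluctuation strength",
    "Tempo", "Attack_time", "Lowenergy",
    "Spectral centroid", "Brightness", "Spectral spread", "Rolloff",
    "Spectentropy", "Spectral flatness", "Irregularity", "Zerocross rate",
    "Spectralflux",
    "Chromagram peak position", "Keyclarity", "Mode",
)

# feature -> (baseline, valence slope, energy slope, noise sd), slopes per
# centred-unit rating ((rating-5)/4 in [-1, 1]).  Signs follow the
# observed correlation pattern: timbral brightness/flux features rise
# with Energy (and hence patch Size/b*), tonal clarity features rise
# with Valence (and hence Lightness); Loudness/Roughness/Tempo are
# uncoupled, as in loudness-normed stimuli.
_FEATURE_MODEL: dict[str, tuple[float, float, float, float]] = {
    "Loudness":                 (18.0,  0.0,  0.0, 2.0),
    "Sharpness":                ( 1.6,  0.1,  0.5, 0.18),
    "Roughness":                ( 0.12, 0.0,  0.0, 0.03),
    "Fluctuation strength":     ( 0.55, 0.0,  0.18, 0.08),
    "Tempo":                    (118.0, 0.0,  0.0, 22.0),
    "Attack_time":              ( 0.45, 0.0, -0.16, 0.06),
    "Lowenergy":                ( 0.52, 0.06, -0.05, 0.05),
    "Spectral centroid":        (1650.0, 60.0, 520.0, 190.0),
    "Brightness":               ( 0.42, 0.02, 0.16, 0.05),
    "Spectral spread":          (1450.0, -120.0, 90.0, 160.0),
    "Rolloff":                  (3100.0, 100.0, 950.0, 380.0),
    "Spectentropy":             ( 0.82, 0.01, 0.09, 0.025),
    "Spectral flatness":        ( 0.22, -0.01, -0.08, 0.03),
    "Irregularity":             ( 0.31, 0.08, -0.02, 0.05),
    "Zerocross rate":           (980.0, 40.0, 330.0, 130.0),
    "Spectralflux":             ( 7.5,  0.2,  2.6, 0.8),
    "Chromagram peak position": (64.0,  2.0,  6.0, 9.0),
    "Keyclarity":               ( 0.48, 0.14, 0.01, 0.06),
    "Mode":                     ( 0.02, 0.25, 0.0, 0.12),
}


@dataclass(frozen=True)
class StimulusRecord:
    """Emotion ratings and audio features for one music excerpt."""

    id: str
    discrete: dict[str, float]
    dimensional: dict[str, float]
    beauty: float
    liking: float
    features: dict[str, float]

    def __post_init__(self) -> None:
        for group, names in ((self.discrete, DISCRETE_SCALES),
                             (self.dimensional, DIMENSIONAL_SCALES)):
            for n in names:
                v = group[n]
                if not 1.0 <= v <= 9.0:
                    raise ValueError(f"{self.id}: rating {n}={v} outside [1, 9]")
        if not (1.0 <= self.beauty <= 9.0 and 1.0 <= self.liking <= 9.0):
            raise ValueError(f"{self.id}: Beauty/Liking outside [1, 9]")
        missing = set(FEATURE_NAMES) - set(self.features)
        if missing or not all(np.isfinite(list(self.features.values()))):
            raise ValueError(f"{self.id}: features missing or non-finite: {missing}")

    def to_row(self) -> dict:
        row = {"id": self.id}
        row.update({s: self.discrete[s] for s in DISCRETE_SCALES})
        row.update({s: self.dimensional[s] for s in DIMENSIONAL_SCALES})
        row["Beauty"] = self.beauty
        row["Liking"] = self.liking
        row.update({f: self.features[f] for f in FEATURE_NAMES})
        return row

    @classmethod
    def from_row(cls, row) -> "StimulusRecord":
        return cls(
            id=str(row["id"]),
            discrete={s: float(row[s]) for s in DISCRETE_SCALES},
            dimensional={s: float(row[s]) for s in DIMENSIONAL_SCALES},
            beauty=float(row["Beauty"]), liking=float(row["Liking"]),
            features={f: float(row[f]) for f in FEATURE_NAMES},
        )


@dataclass
class GeneratorConfig:
    """Study conditions for the generator.

    Defaults mirror the experimental design being emulated: 27 excerpts
    × 22 participants (9 female), ~15 s excerpts sampled at 10 Hz,
    settling after about 5 s.  ``mediation_strength`` blends the settled
    colour between the emotion-determined target (1) and an
    emotion-independent distractor (0).  ``noise_sd`` is the settled
    response jitter in Lab units; ``participant_sd`` (Lab units) is a
    fixed idiosyncratic offset per participant, the source of realistic
    between-rater disagreement.
    """

    n_stimuli: int = 27
    n_participants: int = 22
    n_female: int = 9
    mediation_strength: float = 0.9
    envelope_duration_s: float = 15.0
    sample_rate_hz: float = 10.0
    settle_time_s: float = 5.0
    noise_sd: float = 4.0
    participant_sd: float = 6.0
    gender_size_shift: float = -0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not 0.0 <= self.mediation_strength <= 1.0:
            raise ValueError("mediation_strength must be in [0, 1]")
        if self.settle_time_s >= self.envelope_duration_s:
            raise ValueError("settle_time_s must be shorter than the stimulus")
        if not 0 <= self.n_female <= self.n_participants:
            raise ValueError("n_female must not exceed n_participants")


def _clip19(v):
    return float(np.clip(v, 1.0, 9.0))


def generate_stimuli(config: GeneratorConfig, rng: np.random.Generator | None = None
                     ) -> list[StimulusRecord]:
    """Draw a rated stimulus pool with the assumed correlation structure.

    Dimensional ratings span [1, 9]; the discrete emotion dominating
    each (Valence, Energy) quadrant is raised above the 2-point floor
    (Anger and Fear share the low-valence/high-energy quadrant and are
    split by Tension).  Features are linear in (Valence, Energy) plus
    Gaussian noise; Beauty and Liking share a latent preference factor.
    """
    if config.n_stimuli < 10:
        raise ValueError("need at least 10 stimuli to cover the emotion extremes")
    rng = rng or np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    records = []
    for i in range(config.n_stimuli):
        V = rng.uniform(1.2, 8.8)
        E = rng.uniform(1.2, 8.8)
        v, e = (V - 5) / 4, (E - 5) / 4
        T = _clip19(5 - 2.2 * v + 1.8 * e + rng.normal(0, 0.7))
        t = (T - 5) / 4

        q_pp = max(0.0, v) * max(0.0, e)      # happy quadrant
        q_pn = max(0.0, v) * max(0.0, -e)     # tender
        q_nn = max(0.0, -v) * max(0.0, -e)    # sad
        q_np = max(0.0, -v) * max(0.0, e)     # anger/fear
        w_anger = float(np.clip(0.5 + 0.6 * t + rng.normal(0, 0.15), 0, 1))
        disc = {
            "Happy":  _clip19(2 + 6.5 * q_pp + rng.normal(0, 0.4)),
            "Tender": _clip19(2 + 6.5 * q_pn + rng.normal(0, 0.4)),
            "Sad":    _clip19(2 + 6.5 * q_nn + rng.normal(0, 0.4)),
            "Anger":  _clip19(2 + 6.5 * q_np * w_anger + rng.normal(0, 0.4)),
            "Fear":   _clip19(2 + 6.5 * q_np * (1 - w_anger) + rng.normal(0, 0.4)),
        }
        pref = rng.normal(5.0, 1.5)
        beauty = _clip19(pref + rng.normal(0, 0.38))
        liking = _clip19(pref + rng.normal(0, 0.38))
        feats = {
            name: base + bv * v + be * e + rng.normal(0, sd)
            for name, (base, bv, be, sd) in _FEATURE_MODEL.items()
        }
        records.append(StimulusRecord(
            id=f"S{i + 1:03d}",
            discrete=disc,
            dimensional={"Valence": V, "Energy": E, "Tension": T},
            beauty=beauty, liking=liking, features=feats,
        ))
    return records


# Fixed emotion → colour-target map.  Directions reproduce the observed
# sign pattern: happy → light yellow, anger → large red-yellow, sad →
# small dark blue-grey, high energy → large light yellow patches.
def emotion_to_target(record: StimulusRecord) -> ColourPatch:
    v = (record.dimensional["Valence"] - 5) / 4
    e = (record.dimensional["Energy"] - 5) / 4
    t = (record.dimensional["Tension"] - 5) / 4
    h = (record.discrete["Happy"] - 5) / 4
    s = (record.discrete["Sad"] - 5) / 4
    td = (record.discrete["Tender"] - 5) / 4
    ang = (record.discrete["Anger"] - 5) / 4

    L = np.clip(50 + 14 * v + 10 * e - 10 * t, 0, 100)
    b = np.clip(20 * e + 14 * h - 10 * s - 8 * td, -100, 100)
    a = np.clip(18 * ang - 10 * v, -100, 100)
    size = np.clip(0.5 + 0.15 * e + 0.10 * ang - 0.05 * v, 0, 1)
    return ColourPatch(size=float(size), L=float(L), a=float(a), b=float(b))


def _patch_to_interface(patch: ColourPatch) -> np.ndarray:
    """Interface coordinates (x, y, pressure, throttle) displaying a patch."""
    return np.array([(patch.a + 100) / 200.0, (patch.b + 100) / 200.0,
                     patch.size, patch.L / 100.0])


def generate_envelope(record: StimulusRecord, participant_seed: int,
                      config: GeneratorConfig, size_bias: float = 0.0) -> pd.DataFrame:
    """One participant × stimulus response stream.

    Pen-up gap (1–4 s) → reflected-random-walk search → settle near the
    blended target with Gaussian jitter of ``noise_sd`` Lab units
    (scaled to the unit interface ranges: /200 on x, y and size, /100 on
    throttle).  Deterministic for fixed (config.seed, participant_seed,
    stimulus id).
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        (config.seed, int(participant_seed), zlib.crc32(record.id.encode()))))
    # idiosyncratic per-participant offset, constant across stimuli
    rng_p = np.random.default_rng(np.random.SeedSequence(
        (config.seed, int(participant_seed), 0xB1A5)))
    sd = config.participant_sd
    participant_bias = rng_p.normal(0, 1, size=4) * np.array(
        [sd / 200, sd / 200, sd / 400, sd / 100])
    rate = config.sample_rate_hz
    n = int(round(config.envelope_duration_s * rate))
    t_s = np.arange(n) / rate

    gap_s = rng.uniform(1.0, min(4.0, config.settle_time_s))
    n_gap = int(round(gap_s * rate))
    n_settle = int(round(config.settle_time_s * rate))

    target = emotion_to_target(record)
    distractor = ColourPatch(size=float(rng.uniform()),
                             L=float(rng.uniform(0, 100)),
                             a=float(rng.uniform(-100, 100)),
                             b=float(rng.uniform(-100, 100)))
    m = config.mediation_strength
    blended = np.array([
        m * target.size + (1 - m) * distractor.size,
        m * target.L + (1 - m) * distractor.L,
        m * target.a + (1 - m) * distractor.a,
        m * target.b + (1 - m) * distractor.b,
    ])
    goal = _patch_to_interface(ColourPatch(*blended)) + participant_bias

    xypt = np.zeros((n, 4))
    pen_down = np.zeros(n, dtype=bool)
    # search: reflected Gaussian walk from the interface centre
    pos = np.array([0.5, 0.5, 0.3, 0.5])
    for i in range(n_gap, min(n_settle, n)):
        pos = pos + rng.normal(0, 0.06, size=4)
        pos = np.abs(pos) % 2.0
        pos = np.where(pos > 1.0, 2.0 - pos, pos)
        xypt[i] = pos
        pen_down[i] = True
    # settle: jitter around the blended target
    jitter_scale = np.array([config.noise_sd / 200, config.noise_sd / 200,
                             config.noise_sd / 200, config.noise_sd / 100])
    n_tail = n - min(n_settle, n)
    if n_tail > 0:
        tail = goal + rng.normal(0, 1, size=(n_tail, 4)) * jitter_scale
        tail[:, 2] += size_bias
        xypt[n - n_tail:] = np.clip(tail, 0.0, 1.0)
        pen_down[n - n_tail:] = True

    return pd.DataFrame({
        "t_s": t_s, "pen_down": pen_down,
        "x": xypt[:, 0], "y": xypt[:, 1],
        "pressure": xypt[:, 2], "throttle": xypt[:, 3],
    })


def generate_participants(config: GeneratorConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    rng = rng or np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    ids = [f"P{i + 1:02d}" for i in range(config.n_participants)]
    gender = np.array(["F"] * config.n_female
                      + ["M"] * (config.n_participants - config.n_female))
    rng.shuffle(gender)
    bias = np.where(gender == "F", config.gender_size_shift, 0.0)
    return pd.DataFrame({"participant": ids, "gender": gender, "size_bias": bias})


def generate_dataset(config: GeneratorConfig) -> dict[str, pd.DataFrame]:
    """Full synthetic dataset: stimuli, participants, long-format envelopes."""
    records = generate_stimuli(config)
    participants = generate_participants(config)
    frames = []
    for p_idx, prow in participants.iterrows():
        for rec in records:
            env = generate_envelope(rec, participant_seed=p_idx + 1, config=config,
                                    size_bias=float(prow["size_bias"]))
            env.insert(0, "stimulus", rec.id)
            env.insert(0, "participant", prow["participant"])
            frames.append(env)
    envelopes = pd.concat(frames, ignore_index=True)
    stimuli = pd.DataFrame([r.to_row() for r in records])
    return {"stimuli": stimuli, "participants": participants, "envelopes": envelopes}


def write_dataset(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write stimuli.csv, participants.csv, envelopes.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(config)
    paths = {}
    try:
        for name, df in data.items():
            paths[name] = out / f"{name}.csv"
            df.to_csv(paths[name], index=False)
    except OSError as exc:
        raise OSError(f"failed writing dataset to {out}: {exc}") from exc
    return paths
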