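"""End-to-end orchestration of the analysis stages.

Stage order: simulate (rated pool → extreme-stimulus selection →
participants → response envelopes) → grid → process → agreement →
tests → correlations → pls.  Every stage funnels its randomness through
a named seed derived from the run seed, all outputs are plain CSV/JSON
under ``out_dir``, and a manifest records versions, seeds, and content
digests so a re-run with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colour import build_hybrid_grid
from .correlation import correlation_table
from .grouptests import (bootstrap_median_ci, cohens_d, kruskal_wallis,
                         tukey_hsd, wilcoxon_rank_sum)
from .processing import aggregate_by_stimulus, process_envelopes
from .reliability import agreement_report
from .pls import compare_models
from .selection import select_extremes, selection_table
from .simulate import (DISCRETE_SCALES, DIMENSIONAL_SCALES, FEATURE_NAMES,
                       GeneratorConfig, StimulusRecord, generate_envelope,
                       generate_participants, generate_stimuli)

__all__ = ["RunConfig", "run"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "grid", "process", "agreement", "tests",
              "correlations", "pls")


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # generator / study conditions
    n_pool: int = 110
    n_participants: int = 22
    n_female: int = 9
    mediation_strength: float = 0.9
    noise_sd: float = 4.0
    participant_sd: float = 6.0
    gender_size_shift: float = -0.08
    # statistical knobs
    grid_step: float = 2.0
    alpha_fw: float = 0.05
    m_comparisons: int | None = None
    n_folds: int = 9
    n_reps: int = 500
    n_boot: int = 5000
    n_sim: int = 500
    p_eff_mode: str = "components"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            n_stimuli=self.n_pool, n_participants=self.n_participants,
            n_female=self.n_female, mediation_strength=self.mediation_strength,
            noise_sd=self.noise_sd, participant_sd=self.participant_sd,
            gender_size_shift=self.gender_size_shift, seed=self.seed)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {p}; enable the producing stage or provide the file")
    return p


def _stars_join(hsd: pd.DataFrame) -> str:
    sig = hsd[hsd["significant"]]
    return "; ".join(f"{r.group_1} vs {r.group_2} {r.stars}" for r in sig.itertuples())


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns output paths.

    A stage failure aborts the run with the stage named; outputs of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stage = "init"
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            _STAGE_FUNCS[stage](config, out, outputs)
            timings[stage] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", stage, timings[stage])
    except Exception:
        log.error("pipeline aborted in stage %r", stage)
        raise

    manifest = {
        "soundhue_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "timings_s": timings,
        "digests": {p.name: _digest(p) for p in sorted(outputs.values())
                    if p.suffix in (".csv", ".json")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = out / "manifest.json"
    return {k: str(v) for k, v in outputs.items()}


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, outputs: dict) -> None:
    gcfg = config.generator_config()
    pool = generate_stimuli(gcfg)
    results = select_extremes(pool)
    sel = selection_table(results)
    chosen = sorted({s for r in results for s in r.chosen})
    records = [r for r in pool if r.id in chosen]
    log.info("selected %d distinct stimuli from pool of %d", len(records), len(pool))

    participants = generate_participants(gcfg)
    frames = []
    for p_idx, prow in participants.iterrows():
        for rec in records:
            env = generate_envelope(rec, participant_seed=p_idx + 1, config=gcfg,
                                    size_bias=float(prow["size_bias"]))
            env.insert(0, "stimulus", rec.id)
            env.insert(0, "participant", prow["participant"])
            frames.append(env)
    envelopes = pd.concat(frames, ignore_index=True)

    pd.DataFrame([r.to_row() for r in pool]).to_csv(out / "pool.csv", index=False)
    sel.to_csv(out / "selection.csv", index=False)
    pd.DataFrame([r.to_row() for r in records]).to_csv(out / "stimuli.csv", index=False)
    participants.to_csv(out / "participants.csv", index=False)
    envelopes.to_csv(out / "envelopes.csv", index=False)
    for name in ("pool", "selection", "stimuli", "participants", "envelopes"):
        outputs[name] = out / f"{name}.csv"


def _stage_grid(config: RunConfig, out: Path, outputs: dict) -> None:
    grid = build_hybrid_grid(config.grid_step)
    (out / "grid_stats.json").write_text(json.dumps(grid.stats(), indent=2))
    outputs["grid_stats"] = out / "grid_stats.json"


def _stage_process(config: RunConfig, out: Path, outputs: dict) -> None:
    env = pd.read_csv(_require(out, "envelopes.csv", "process"))
    grid = build_hybrid_grid(config.grid_step)
    patches = process_envelopes(env, grid)
    patches.to_csv(out / "patches.csv", index=False)
    aggregate_by_stimulus(patches).to_csv(out / "patches_mean.csv", index=False)
    outputs["patches"] = out / "patches.csv"
    outputs["patches_mean"] = out / "patches_mean.csv"


def _stage_agreement(config: RunConfig, out: Path, outputs: dict) -> None:
    patches = pd.read_csv(_require(out, "patches.csv", "agreement"))
    reports = agreement_report(patches)
    (out / "agreement.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=2))
    excluded = reports[0].excluded
    kept = patches[~patches["participant"].isin(excluded)]
    kept.to_csv(out / "patches_kept.csv", index=False)
    aggregate_by_stimulus(kept).to_csv(out / "patches_mean.csv", index=False)
    outputs["agreement"] = out / "agreement.json"
    outputs["patches_kept"] = out / "patches_kept.csv"


def _patches_for_tests(out: Path, stage: str) -> pd.DataFrame:
    p = out / "patches_kept.csv"
    return pd.read_csv(p if p.exists() else _require(out, "patches.csv", stage))


def _stage_tests(config: RunConfig, out: Path, outputs: dict) -> None:
    patches = _patches_for_tests(out, "tests")
    sel = pd.read_csv(_require(out, "selection.csv", "tests"))
    participants = pd.read_csv(_require(out, "participants.csv", "tests"))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 40)))
    params = ["size", "L", "a", "b"]

    def values_for(stims) -> dict[str, np.ndarray]:
        sub = patches[patches["stimulus"].isin(stims)]
        return {p: sub[p].to_numpy() for p in params}

    # discrete emotions: 5-group omnibus + HSD per colour parameter
    disc_rows, med_rows = [], []
    disc_groups = {s: sel[(sel["scale"] == s) & (sel["pole"] == "high")]["stimulus"]
                   for s in DISCRETE_SCALES}
    for p in params:
        groups = [values_for(disc_groups[s])[p] for s in DISCRETE_SCALES]
        kw = kruskal_wallis(groups, labels=DISCRETE_SCALES)
        hsd = tukey_hsd(groups, labels=DISCRETE_SCALES, alpha_fw=config.alpha_fw)
        disc_rows.append({"parameter": p, "chi2": kw.statistic, "p": kw.p,
                          "stars": kw.stars, "hsd": _stars_join(hsd)})
        for s, g in zip(DISCRETE_SCALES, groups):
            med, lo, hi = bootstrap_median_ci(g, n_boot=config.n_boot, rng=rng)
            med_rows.append({"group": s, "pole": "high", "parameter": p,
                             "median": med, "ci_lo": lo, "ci_hi": hi})
    pd.DataFrame(disc_rows).to_csv(out / "tests_discrete.csv", index=False)

    # dimensional emotions and Preference: high vs low rank-sum tests
    dim_rows = []
    for scale in list(DIMENSIONAL_SCALES) + ["Preference"]:
        for p in params:
            hi_v = values_for(sel[(sel["scale"] == scale) & (sel["pole"] == "high")]
                              ["stimulus"])[p]
            lo_v = values_for(sel[(sel["scale"] == scale) & (sel["pole"] == "low")]
                              ["stimulus"])[p]
            res = wilcoxon_rank_sum(hi_v, lo_v)
            dim_rows.append({"scale": scale, "parameter": p, "W": res.statistic,
                             "p": res.p, "stars": res.stars, "d": res.effect_size_d})
            for pole, g in (("high", hi_v), ("low", lo_v)):
                med, lo, hi = bootstrap_median_ci(g, n_boot=config.n_boot, rng=rng)
                med_rows.append({"group": scale, "pole": pole, "parameter": p,
                                 "median": med, "ci_lo": lo, "ci_hi": hi})
    pd.DataFrame(dim_rows).to_csv(out / "tests_dimensional.csv", index=False)
    pd.DataFrame(med_rows).to_csv(out / "medians_ci.csv", index=False)

    # gender comparison over all retained responses
    merged = patches.merge(participants[["participant", "gender"]], on="participant")
    gen_rows = []
    for p in params:
        male = merged.loc[merged["gender"] == "M", p].to_numpy()
        female = merged.loc[merged["gender"] == "F", p].to_numpy()
        res = wilcoxon_rank_sum(male, female)
        gen_rows.append({"parameter": p, "W": res.statistic, "p": res.p,
                         "stars": res.stars, "d": res.effect_size_d,
                         "n_male": len(male), "n_female": len(female)})
    pd.DataFrame(gen_rows).to_csv(out / "tests_gender.csv", index=False)
    for name in ("tests_discrete", "tests_dimensional", "tests_gender", "medians_ci"):
        outputs[name] = out / f"{name}.csv"


def _stage_correlations(config: RunConfig, out: Path, outputs: dict) -> None:
    stimuli = pd.read_csv(_require(out, "stimuli.csv", "correlations"))
    pm = pd.read_csv(_require(out, "patches_mean.csv", "correlations"))
    st = stimuli.sort_values("id").reset_index(drop=True)
    pm = pm.sort_values("stimulus").reset_index(drop=True)
    cells, transforms = correlation_table(
        st[list(FEATURE_NAMES)], pm[["size", "L", "a", "b"]],
        alpha_fw=config.alpha_fw, m=config.m_comparisons)
    cells.to_csv(out / "correlations.csv", index=False)
    transforms.to_csv(out / "transforms.csv", index=False)
    outputs["correlations"] = out / "correlations.csv"
    outputs["transforms"] = out / "transforms.csv"


def _stage_pls(config: RunConfig, out: Path, outputs: dict) -> None:
    stimuli = pd.read_csv(_require(out, "stimuli.csv", "pls"))
    pm = pd.read_csv(_require(out, "patches_mean.csv", "pls"))
    grid = build_hybrid_grid(config.grid_step)
    cmp_ = compare_models(stimuli, pm, grid, n_folds=config.n_folds,
                          n_reps=config.n_reps, n_boot=config.n_boot,
                          n_sim=config.n_sim, p_eff_mode=config.p_eff_mode,
                          seed=np.random.SeedSequence((config.seed, 70)))
    cmp_.table.to_csv(out / "model_comparison.csv", index=False)
    cmp_.noise.to_csv(out / "noise_floor.csv", index=False)
    (out / "verdicts.json").write_text(json.dumps(
        {f"{m}:{r}": bool(v) for (m, r), v in cmp_.verdicts.items()}, indent=2))
    outputs["model_comparison"] = out / "model_comparison.csv"
    outputs["noise_floor"] = out / "noise_floor.csv"
    outputs["verdicts"] = out / "verdicts.json"


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "grid": _stage_grid,
    "process": _stage_process,
    "agreement": _stage_agreement,
    "tests": _stage_tests,
    "correlations": _stage_correlations,
    "pls": _stage_pls,
}
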