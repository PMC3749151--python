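"""Pipeline orchestration: simulate -> measure -> score -> hardness -> stats -> report.

Each stage reads the previous stage's CSV outputs from the configured output
directory and appends to a manifest (inputs, config hash, seed, package
version, outputs). The ``report`` stage is pure: it recomputes the package's
reference statistics from the packaged fixture tables alone and never touches
simulation outputs.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .hardness import class_comparison, hardness_table
from .io import (load_fixture, measures_frame, read_answer_key,
                 read_indentations, read_profiles, read_responses,
                 table3_values, write_profiles)
from .morphometry import NoGrooveError, mark_level_measures, measure_profile
from .scoring import (correspondence_table, diagnose_success, exclusion_effect,
                      experience_correlation, instrument_comparison,
                      locate_success, pedagogy_comparison,
                      size_success_correlation, subset_excluding)
from .stats import kendall_tau, mann_whitney, pca, wilcoxon_signed_rank
from .synthetic import (BlindTestSpec, PopulationSpec, simulate_blind_test,
                        simulate_indentations, simulate_mark_population)

__all__ = ["run_pipeline", "printed_table_statistics", "STAGES"]

STAGES = ("simulate", "measure", "score", "hardness", "stats", "report")


def printed_table_statistics() -> dict:
    """Recompute every fixture-reproducible statistic of the reference study.

    All inputs are the packaged transcriptions of the published summary
    tables (integer percentages); every value is computed at call time by
    the stats/scoring machinery. Returns a flat dict.
    """
    out: dict[str, float] = {}

    def mw(task, abrasion):
        a = table3_values(task, abrasion, "hand_lens")
        b = table3_values(task, abrasion, "microscope")
        return mann_whitney(a, b), len(a) + len(b)

    for task, abrasion, tag in (("locating", "included", "locating_abrasion_included"),
                                ("locating", "excluded", "locating_abrasion_excluded"),
                                ("diagnosing", "included", "diagnosing_abrasion_included"),
                                ("diagnosing", "excluded", "diagnosing_abrasion_excluded")):
        res, n = mw(task, abrasion)
        out[f"instrument_mw_U_{tag}"] = res.statistic
        out[f"instrument_mw_z_{tag}"] = res.z
        out[f"instrument_mw_p_{tag}"] = res.p
        out[f"instrument_mw_n_{tag}"] = n

    for block, task, tag in (("hand_lens", "locating", "hand_lens_locating"),
                             ("hand_lens", "diagnosing", "hand_lens_diagnosing"),
                             ("microscope", "locating", "microscope_locating"),
                             ("microscope", "diagnosing", "microscope_diagnosing")):
        inc = table3_values(task, "included", block)
        exc = table3_values(task, "excluded", block)
        res = wilcoxon_signed_rank(inc, exc)
        out[f"trampling_exclusion_W_{tag}"] = res.statistic
        out[f"trampling_exclusion_z_{tag}"] = res.z
        out[f"trampling_exclusion_n_{tag}"] = len(inc)

    t6 = load_fixture("table6")
    tt1 = t6.loc[t6["group"] == "TT1", "value"].to_numpy(float)
    tt2 = t6.loc[t6["group"] == "TT2", "value"].to_numpy(float)
    res = mann_whitney(tt1, tt2)
    out["pedagogy_mw_U"] = res.statistic
    out["pedagogy_mw_z"] = res.z
    out["pedagogy_mw_n"] = len(tt1) + len(tt2)

    t4 = load_fixture("table4")
    out["hand_lens_diagnosing_success_median_pct"] = float(
        t4.loc[t4["task"] == "diagnosing", "score"].median())
    out["hand_lens_locating_success_mean_pct"] = float(
        round(t4.loc[t4["task"] == "locating", "score"].mean()))
    out["microscope_diagnosing_corr_median_pct"] = float(
        np.median(table3_values("diagnosing", "included", "microscope")))
    out["microscope_locating_corr_mean_pct"] = float(
        round(table3_values("locating", "included", "microscope").mean()))
    out["hand_lens_locating_corr_mean_pct"] = float(
        round(table3_values("locating", "included", "hand_lens").mean()))
    return out


def _paths(config: RunConfig) -> dict[str, Path]:
    out = Path(config.outdir)
    return {
        "profiles": Path(config.profiles_path or out / "profiles.csv"),
        "responses": Path(config.responses_path or out / "responses.csv"),
        "key": Path(config.answer_key_path or out / "answer_key.csv"),
        "participants": out / "participants.csv",
        "indentations": Path(config.indentations_path or out / "indentations.csv"),
        "measures": out / "measures.csv",
        "scores": out / "scores.csv",
        "correspondence": out / "correspondence.csv",
        "hardness": out / "hardness.csv",
        "hardness_report": out / "hardness_report.json",
        "stats": out / "stats.json",
        "report": out / "report.csv",
        "manifest": out / "manifest.json",
    }


def _stage_simulate(config: RunConfig, paths) -> list[str]:
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=4)
    profiles = []
    tables = []
    for group, seed in (("aquatic", seeds[0]), ("terrestrial", seeds[1])):
        pop = PopulationSpec(group=group, n_marks=config.n_marks_per_group,
                             transects_per_mark=config.transects_per_mark,
                             seed=int(seed))
        table, profs = simulate_mark_population(pop, with_profiles=True)
        tables.append(table)
        profiles.extend(profs)
    marks = pd.concat(tables, ignore_index=True)
    write_profiles(profiles, paths["profiles"])
    aquatic = marks[marks["group"] == "aquatic"]
    responses, participants, key = simulate_blind_test(
        BlindTestSpec(seed=int(seeds[2])), aquatic)
    responses.to_csv(paths["responses"], index=False)
    participants.to_csv(paths["participants"], index=False)
    key.to_csv(paths["key"], index=False)
    indents = simulate_indentations(seed=int(seeds[3]),
                                    variant=config.vickers_variant)
    indents.to_csv(paths["indentations"], index=False, float_format="%.17g")
    return ["profiles", "responses", "participants", "key", "indentations"]


def _group_from_mark_id(mark_id: str) -> str | None:
    return {"aqu": "aquatic", "ter": "terrestrial"}.get(mark_id[:3])


def _stage_measure(config: RunConfig, paths) -> list[str]:
    profiles = read_profiles(paths["profiles"])
    by_mark = defaultdict(list)
    for p in profiles:
        by_mark[p.mark_id].append(p)
    marks = []
    n_failed = 0
    for mark_id, profs in by_mark.items():
        transects = []
        for p in profs:
            try:
                transects.append(measure_profile(p))
            except (NoGrooveError, ValueError):
                n_failed += 1
        if len(transects) >= 2:
            marks.append(mark_level_measures(
                transects, mark_id=mark_id, group=_group_from_mark_id(mark_id)))
    if n_failed:
        warnings.warn(f"{n_failed} transects could not be measured", stacklevel=2)
    measures_frame(marks).to_csv(paths["measures"], index=False)
    return ["measures"]


def _stage_score(config: RunConfig, paths) -> list[str]:
    responses = read_responses(paths["responses"])
    key = read_answer_key(paths["key"])
    participants = pd.read_csv(paths["participants"],
                               dtype={"participant": str})
    loc = locate_success(responses, key)
    dia = diagnose_success(responses, key)
    scores = pd.DataFrame({"locate_success_pct": loc,
                           "diagnose_success_pct": dia})
    scores.index.name = "participant"
    scores.to_csv(paths["scores"])
    no_trampling = subset_excluding(key, "trampling")
    frames = []
    for task in ("locate", "diagnose"):
        for label, subset in (("included", None), ("excluded", no_trampling)):
            tab = correspondence_table(responses, key, participants, task=task,
                                       subset=subset, within="instrument")
            tab.insert(0, "task", task)
            tab.insert(1, "trampling", label)
            frames.append(tab)
    pd.concat(frames, ignore_index=True).to_csv(paths["correspondence"],
                                                index=False)
    return ["scores", "correspondence"]


def _stage_hardness(config: RunConfig, paths) -> list[str]:
    indents = read_indentations(paths["indentations"])
    specimens = hardness_table(indents, variant=config.vickers_variant)
    specimens.to_csv(paths["hardness"], index=False)
    report = class_comparison(specimens)
    paths["hardness_report"].write_text(json.dumps(report, indent=2, default=str))
    return ["hardness", "hardness_report"]


def _stage_stats(config: RunConfig, paths) -> list[str]:
    measures = pd.read_csv(paths["measures"])
    out: dict = {}
    aq = measures.loc[measures["group"] == "aquatic", "measure1b"].dropna()
    te = measures.loc[measures["group"] == "terrestrial", "measure1b"].dropna()
    if len(aq) and len(te):
        res = mann_whitney(aq, te)
        out["size_mw"] = {"U": res.statistic, "z": res.z, "p": res.p,
                          "n": [len(aq), len(te)]}
    sized = measures.dropna(subset=["measure6", "measure1b"])
    if len(sized) >= 3:
        tau, p = kendall_tau(sized["measure6"], np.log(sized["measure1b"]))
        out["cv_size_kendall_measure6"] = {"tau": tau, "p": p, "n": len(sized)}
    pca_cols = ["measure1a_norm", "measure2", "measure3", "measure4",
                "measure5", "measure6", "measure7"]
    mat = measures[pca_cols].dropna()
    if len(mat) >= 3:
        res = pca(mat.to_numpy(float), standardize=config.pca_standardize,
                  columns=pca_cols)
        out["pca"] = {"explained_pct": [float(v) for v in res.explained_pct],
                      "n": len(mat)}
    corr = pd.read_csv(paths["correspondence"], dtype={"p1": str, "p2": str})
    for task in ("locate", "diagnose"):
        inc = corr[(corr["task"] == task) & (corr["trampling"] == "included")]
        exc = corr[(corr["task"] == task) & (corr["trampling"] == "excluded")]
        mw = instrument_comparison(inc, round_to_int=config.round_percent)
        out[f"instrument_mw_{task}"] = {"U": mw.statistic, "z": mw.z, "p": mw.p}
        for grp in ("hand_lens", "microscope"):
            w = exclusion_effect(inc, exc, grp, round_to_int=config.round_percent)
            out[f"trampling_exclusion_{task}_{grp}"] = {
                "W": w.statistic, "z": w.z, "p": w.p,
                "degenerate": w.degenerate}
    responses = read_responses(paths["responses"])
    key = read_answer_key(paths["key"])
    participants = pd.read_csv(paths["participants"], dtype={"participant": str})
    dia = diagnose_success(responses, key)
    tau, p = experience_correlation(dia, participants)
    out["experience_kendall"] = {"tau": tau, "p": p}
    try:
        tau, p, dropped = size_success_correlation(responses, key)
        out["size_success_kendall"] = {"tau": tau, "p": p,
                                       "n_dropped": dropped}
    except ValueError as err:
        out["size_success_kendall"] = {"error": str(err)}
    paths["stats"].write_text(json.dumps(out, indent=2))
    return ["stats"]


def _stage_report(config: RunConfig, paths) -> list[str]:
    stats = printed_table_statistics()
    rows = [{"statistic": k, "value": v} for k, v in sorted(stats.items())]
    pd.DataFrame(rows).to_csv(paths["report"], index=False)
    return ["report"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "measure": _stage_measure,
    "score": _stage_score,
    "hardness": _stage_hardness,
    "stats": _stage_stats,
    "report": _stage_report,
}

_STAGE_INPUTS = {
    "simulate": [],
    "measure": ["profiles"],
    "score": ["responses", "key", "participants"],
    "hardness": ["indentations"],
    "stats": ["measures", "correspondence", "responses", "key", "participants"],
    "report": [],
}


def run_pipeline(config: RunConfig, stage: str = "all") -> dict:
    """Run one stage, or every stage in order, writing a manifest."""
    stages = list(STAGES) if stage == "all" else [stage]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    paths = _paths(config)
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.hash(), "seed": config.seed,
                "version": __version__, "stages": {}}
    for st in stages:
        for inp in _STAGE_INPUTS[st]:
            if not paths[inp].exists():
                raise FileNotFoundError(
                    f"stage {st!r} needs {paths[inp]} — run the upstream "
                    "stage first")
        written = _STAGE_FUNCS[st](config, paths)
        manifest["stages"][st] = {
            "inputs": [str(paths[i]) for i in _STAGE_INPUTS[st]],
            "outputs": [str(paths[w]) for w in written],
        }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return manifest
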