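"""Blind-test scoring: success rates, two-way correspondence, subgroup tests.

Schemas (all plain pandas DataFrames):

* answer key — ``specimen``, ``category`` (one of cut/scrape, percussion,
  human-tooth, trampling, none), optional ``size_um`` (mark max dimension);
* responses — one row per answered (participant, specimen):
  ``participant``, ``specimen``, ``present`` (bool), ``diagnosis``
  (category or "none"), ``confidence`` (1-5, nullable). A skipped specimen
  is simply absent;
* participants — ``participant``, ``instrument`` (hand_lens | microscope),
  ``pedagogy`` (TT1 | TT2 | none), ``years``.

Scoring definitions:

* locating success — the presence call matches the key ("none" specimens
  require an absent call);
* diagnosing success — the called category equals the true category; a
  correct "absent" call on an intrinsic-only specimen counts as a correct
  diagnosis;
* two-way correspondence — for a pair of analysts, the percentage of
  specimens answered by BOTH on which both are correct (for diagnosing,
  with the same — necessarily true — category).

Printed-table comparisons in the reference analyses ran on integer-rounded
percentages; the comparison helpers therefore round to integers by default
while full-precision values stay available.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .stats import RankTestResult, kendall_tau, mann_whitney, wilcoxon_signed_rank
from .synthetic import CATEGORIES

__all__ = [
    "locate_success",
    "diagnose_success",
    "two_way_correspondence",
    "correspondence_table",
    "subset_excluding",
    "instrument_comparison",
    "exclusion_effect",
    "pedagogy_comparison",
    "experience_correlation",
    "size_success_correlation",
    "confidence_success_correlation",
]


def _validate_key(key: pd.DataFrame) -> pd.DataFrame:
    bad = set(key["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories in answer key: {sorted(bad)}")
    return key.set_index("specimen") if key.index.name != "specimen" else key


def _correct_mask(responses: pd.DataFrame, key: pd.DataFrame, task: str) -> pd.Series:
    keyed = _validate_key(key)
    cat = responses["specimen"].map(keyed["category"])
    if cat.isna().any():
        missing = responses.loc[cat.isna(), "specimen"].unique()
        raise ValueError(f"responses reference unknown specimens: {missing[:5]}")
    if task == "locate":
        return responses["present"] == (cat != "none")
    if task == "diagnose":
        return responses["diagnosis"] == cat
    raise ValueError("task must be 'locate' or 'diagnose'")


def _restrict(responses: pd.DataFrame, subset) -> pd.DataFrame:
    if subset is None:
        return responses
    subset = list(subset)
    if not subset:
        raise ValueError("specimen subset is empty")
    return responses[responses["specimen"].isin(subset)]


def _success(responses: pd.DataFrame, key: pd.DataFrame, task: str,
             subset=None) -> pd.Series:
    r = _restrict(responses, subset)
    correct = _correct_mask(r, key, task)
    grouped = correct.groupby(r["participant"])
    pct = 100.0 * grouped.sum() / grouped.count()
    pct.name = f"{task}_success_pct"
    return pct  # participants with no answered specimens are simply absent


def locate_success(responses, key, subset=None) -> pd.Series:
    """Per-participant % of answered specimens with a correct presence call."""
    return _success(responses, key, "locate", subset)


def diagnose_success(responses, key, subset=None) -> pd.Series:
    """Per-participant % of answered specimens with a correct diagnosis."""
    return _success(responses, key, "diagnose", subset)


def two_way_correspondence(responses, key, pair: tuple[str, str],
                           task: str = "locate", subset=None) -> float | None:
    """% of jointly answered specimens on which BOTH analysts are correct."""
    p1, p2 = pair
    r = _restrict(responses, subset)
    a = r[r["participant"] == p1].set_index("specimen")
    b = r[r["participant"] == p2].set_index("specimen")
    joint = a.index.intersection(b.index)
    if len(joint) == 0:
        return None
    ca = _correct_mask(a.loc[joint].reset_index(), key, task)
    cb = _correct_mask(b.loc[joint].reset_index(), key, task)
    return float(100.0 * (ca.values & cb.values).mean())


def correspondence_table(responses, key, participants: pd.DataFrame,
                         task: str = "locate", subset=None,
                         within: str | None = "instrument") -> pd.DataFrame:
    """All pairwise two-way correspondences, optionally within-group pairs only.

    Columns: p1, p2, group (shared group label when ``within`` is set),
    value (percent, full precision).
    """
    ids = list(participants["participant"])
    meta = participants.set_index("participant")
    rows = []
    for p1, p2 in itertools.combinations(ids, 2):
        if within is not None:
            g1, g2 = meta.loc[p1, within], meta.loc[p2, within]
            if g1 != g2:
                continue
            group = g1
        else:
            group = None
        val = two_way_correspondence(responses, key, (p1, p2), task, subset)
        rows.append({"p1": p1, "p2": p2, "group": group, "value": val})
    return pd.DataFrame(rows)


def subset_excluding(key: pd.DataFrame, category: str) -> list[str]:
    """Specimens whose true category differs from the excluded one."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return list(key.loc[key["category"] != category, "specimen"])


def _maybe_round(values: np.ndarray, round_to_int: bool) -> np.ndarray:
    return np.round(values) if round_to_int else values


def instrument_comparison(corr_table: pd.DataFrame,
                          groups: tuple[str, str] = ("hand_lens", "microscope"),
                          round_to_int: bool = True) -> RankTestResult:
    """Mann-Whitney on within-instrument pairwise correspondences."""
    vals = corr_table.dropna(subset=["value"])
    a = vals.loc[vals["group"] == groups[0], "value"].to_numpy(float)
    b = vals.loc[vals["group"] == groups[1], "value"].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both instrument groups need at least one pair")
    return mann_whitney(_maybe_round(a, round_to_int), _maybe_round(b, round_to_int))


def exclusion_effect(included: pd.DataFrame, excluded: pd.DataFrame,
                     group: str, round_to_int: bool = True) -> RankTestResult:
    """Wilcoxon signed-rank on paired correspondences with vs without a category.

    ``included``/``excluded`` are correspondence tables (same pairs) computed
    on the full specimen set and on the reduced subset respectively.
    """
    gi = included[included["group"] == group].set_index(["p1", "p2"])["value"]
    ge = excluded[excluded["group"] == group].set_index(["p1", "p2"])["value"]
    if not gi.index.equals(ge.index):
        raise ValueError("included/excluded tables must cover identical pairs")
    x = _maybe_round(gi.to_numpy(float), round_to_int)
    y = _maybe_round(ge.to_numpy(float), round_to_int)
    return wilcoxon_signed_rank(x, y)


def pedagogy_comparison(corr_table: pd.DataFrame,
                        groups: tuple[str, str] = ("TT1", "TT2"),
                        round_to_int: bool = True) -> RankTestResult:
    """Mann-Whitney on within-teaching-tradition pairwise correspondences."""
    return instrument_comparison(corr_table, groups=groups,
                                 round_to_int=round_to_int)


def experience_correlation(success: pd.Series,
                           participants: pd.DataFrame) -> tuple[float, float]:
    """Kendall's tau between per-participant success % and years of experience."""
    meta = participants.set_index("participant")
    common = success.index.intersection(meta.index)
    if len(common) < 3:
        raise ValueError("need at least 3 participants")
    years = meta.loc[common, "years"].to_numpy(float)
    if np.ptp(years) == 0:
        raise ValueError("experience constant across participants")
    return kendall_tau(success.loc[common].to_numpy(float), years)


def size_success_correlation(responses, key, task: str = "diagnose",
                             exclude: tuple[str, ...] = ("percussion",)
                             ) -> tuple[float, float, int]:
    """Kendall's tau of per-specimen success fraction against mark size.

    Success is the fraction of answering participants correct on each
    modified specimen; percussion marks are excluded by default (impact
    damage has no single groove whose dimension is comparable). Specimens
    lacking a size are dropped; the count of dropped specimens is returned.
    """
    keyed = _validate_key(key)
    modified = keyed[(keyed["category"] != "none")
                     & (~keyed["category"].isin(exclude))]
    sized = modified.dropna(subset=["size_um"])
    n_dropped = len(modified) - len(sized)
    r = responses[responses["specimen"].isin(sized.index)]
    correct = _correct_mask(r, key, task)
    frac = correct.groupby(r["specimen"]).mean()
    frac = frac.reindex(sized.index).dropna()
    sizes = sized.loc[frac.index, "size_um"].to_numpy(float)
    if np.ptp(frac.to_numpy()) == 0:
        raise ValueError("success constant across specimens: tau undefined")
    tau, p = kendall_tau(frac.to_numpy(float), sizes)
    return tau, p, n_dropped


def confidence_success_correlation(responses, key) -> tuple[float, float]:
    """Kendall's tau between category-level mean confidence and mean success.

    Both are aggregated over the five mark types (including intrinsic-only
    specimens); a category without confidence scores is dropped with a
    warning via pandas' NaN handling.
    """
    keyed = _validate_key(key)
    cat = responses["specimen"].map(keyed["category"])
    correct = _correct_mask(responses, key, "diagnose")
    success = correct.groupby(cat).mean()
    confidence = responses["confidence"].groupby(cat).mean()
    both = pd.concat({"success": success, "confidence": confidence}, axis=1).dropna()
    if len(both) < 3:
        raise ValueError("need at least 3 categories with confidence scores")
    return kendall_tau(both["confidence"].to_numpy(), both["success"].to_numpy())
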