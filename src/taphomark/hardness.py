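"""Vickers micro-indentation hardness and the bone-class comparison battery.

Hardness here follows the simplified field formula Hv = F / D^2 with F the
load in kgf and D the mean indentation diagonal in mm ("paper" variant, the
default); the conventional engineering definition includes the indenter
geometry factor, Hv = 1.8544 F / D^2 ("standard" variant). Both are exposed;
they differ by the constant only, so comparisons between bone classes are
unaffected by the choice.

Bone classes: catfish (cranial/cleithrum), reptile, mammal_cancellous,
mammal_cortical. The class comparison reports a Shapiro-Wilk normality gate,
one-way ANOVA with Tukey HSD, and nonparametric pairwise Mann-Whitney tests
alongside, since hardness is typically non-normally distributed across bone
classes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mann_whitney, one_way_anova, shapiro_wilk, tukey_hsd

__all__ = [
    "BONE_CLASSES",
    "VICKERS_GEOMETRY_FACTOR",
    "IndentationRecord",
    "HardnessValue",
    "vickers_hardness",
    "specimen_average",
    "hardness_table",
    "class_comparison",
]

BONE_CLASSES = ("catfish", "reptile", "mammal_cancellous", "mammal_cortical")
VICKERS_GEOMETRY_FACTOR = 1.8544


@dataclass
class IndentationRecord:
    """One indent: load (kgf) and the two diagonal lengths (mm)."""

    specimen: str
    bone_class: str
    load_kgf: float
    d1_mm: float
    d2_mm: float
    dwell_s: float = 30.0
    unbalanced: bool = False    # diagonals differ by > 50% of their mean

    def __post_init__(self) -> None:
        if self.load_kgf <= 0:
            raise ValueError("load must be positive")
        if self.d1_mm <= 0 or self.d2_mm <= 0:
            raise ValueError("diagonals must be positive")
        mean = (self.d1_mm + self.d2_mm) / 2.0
        if abs(self.d1_mm - self.d2_mm) / mean > 0.5:
            self.unbalanced = True
            warnings.warn(f"indent {self.specimen}: diagonals differ by more "
                          "than 50% of their mean", stacklevel=2)


@dataclass
class HardnessValue:
    hv: float                   # kgf / mm^2
    variant: str = "paper"

    def __post_init__(self) -> None:
        if self.hv <= 0:
            raise ValueError("hardness must be positive")


def vickers_hardness(record: IndentationRecord,
                     variant: str = "paper") -> HardnessValue:
    """Hv from one indent: F / D^2 (paper) or 1.8544 F / D^2 (standard)."""
    if variant not in ("paper", "standard"):
        raise ValueError("variant must be 'paper' or 'standard'")
    d = (record.d1_mm + record.d2_mm) / 2.0
    hv = record.load_kgf / d ** 2
    if variant == "standard":
        hv *= VICKERS_GEOMETRY_FACTOR
    return HardnessValue(hv=float(hv), variant=variant)


def specimen_average(records: list[IndentationRecord],
                     variant: str = "paper") -> tuple[HardnessValue, float]:
    """Mean Hv over the indents of one specimen, plus the within-specimen CV."""
    if not records:
        raise ValueError("no records supplied")
    classes = {r.bone_class for r in records}
    if len(classes) > 1:
        raise ValueError(f"mixed bone classes in one specimen: {sorted(classes)}")
    hvs = np.array([vickers_hardness(r, variant).hv for r in records])
    mean = float(hvs.mean())
    cv = float(hvs.std(ddof=1) / mean) if len(hvs) > 1 else 0.0
    return HardnessValue(hv=mean, variant=variant), cv


def hardness_table(df: pd.DataFrame, variant: str = "paper") -> pd.DataFrame:
    """Specimen-level hardness from an indentation table.

    Input columns: specimen, bone_class, load_kgf, d1_mm, d2_mm. Multiple
    rows per specimen are averaged. Output: specimen, bone_class, hv, cv, n.
    """
    out = []
    for spec_id, grp in df.groupby("specimen", sort=True):
        records = [IndentationRecord(specimen=str(spec_id),
                                     bone_class=row.bone_class,
                                     load_kgf=row.load_kgf,
                                     d1_mm=row.d1_mm, d2_mm=row.d2_mm)
                   for row in grp.itertuples()]
        value, cv = specimen_average(records, variant)
        out.append({"specimen": spec_id, "bone_class": records[0].bone_class,
                    "hv": value.hv, "cv": cv, "n": len(records)})
    return pd.DataFrame(out)


def class_comparison(specimens: pd.DataFrame) -> dict:
    """Full bone-class hardness comparison report.

    Input: specimen-level table with ``bone_class`` and ``hv``. Classes with
    fewer than 2 specimens are dropped with a warning. Reports:

    * Shapiro-Wilk W and p on the pooled hardness values (normality gate);
    * one-way ANOVA F, df, p across classes, with Tukey HSD per pair;
    * pairwise Mann-Whitney tests (the nonparametric route, reported
      alongside regardless of the normality outcome).
    """
    groups, labels = [], []
    for cls, grp in specimens.groupby("bone_class", sort=True):
        if len(grp) < 2:
            warnings.warn(f"bone class {cls!r} has < 2 specimens: dropped",
                          stacklevel=2)
            continue
        groups.append(grp["hv"].to_numpy(float))
        labels.append(cls)
    if len(groups) < 2:
        raise ValueError("need at least 2 bone classes with >= 2 specimens")
    pooled = np.concatenate(groups)
    sw_w, sw_p = shapiro_wilk(pooled)
    anova = one_way_anova(groups)
    tukey = tukey_hsd(groups, labels=labels)
    pairwise_mw = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        res = mann_whitney(groups[i], groups[j])
        pairwise_mw.append({"pair": (labels[i], labels[j]),
                            "U": res.statistic, "z": res.z, "p": res.p})
    return {
        "classes": labels,
        "n_per_class": [len(g) for g in groups],
        "class_means": [float(g.mean()) for g in groups],
        "shapiro_wilk": {"W": sw_w, "p": sw_p},
        "anova": anova,
        "tukey": tukey,
        "pairwise_mann_whitney": pairwise_mw,
    }
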