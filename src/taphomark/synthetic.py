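"""Synthetic groove profiles, mark populations, blind-test matrices, indentations.

Every downstream stage of the package can be exercised without external data.
The generators emulate the structure the analyses assume:

* grooves are V- or U-sectioned channels cut into a flat reference surface,
  parameterized by breadth, depth, shoulder asymmetry and a superellipse
  wall-curvature exponent, with additive Gaussian height noise;
* mark populations couple a lognormal cross-sectional size distribution to
  longitudinal variability (smaller marks more variable along their length,
  the coupling coefficient <= 0), with the aquatic group smaller than the
  terrestrial group by default;
* the blind test draws presence calls from an instrument-dependent,
  size-monotone detection curve, diagnoses from a per-category confusion
  matrix, and confidence scores negatively coupled to the confusion entropy
  of the true category;
* indentation records are back-computed from sampled hardness values through
  the package's own Vickers formula, so recomputing hardness recovers the
  sampled values exactly.

Ground-truth values returned by the generators are either exact closed forms
of the generating geometry or, for quantities without a simple closed form
(measure 4 on curved walls), the measurement of a dense noiseless profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import (CrossSectionProfile, MarkMeasures, TransectMeasures,
                          measure_profile)

__all__ = [
    "GrooveSpec",
    "GrooveTruth",
    "PopulationSpec",
    "BlindTestSpec",
    "CATEGORIES",
    "simulate_groove_profile",
    "simulate_mark",
    "simulate_mark_population",
    "simulate_blind_test",
    "simulate_indentations",
    "DEFAULT_CLASS_MEANS",
    "DEFAULT_CLASS_SDS",
    "DEFAULT_CLASS_SIZES",
]

CATEGORIES = ("cut/scrape", "percussion", "human-tooth", "trampling", "none")
MARK_CATEGORIES = CATEGORIES[:4]


# --------------------------------------------------------------------------
# groove geometry
# --------------------------------------------------------------------------

@dataclass
class GrooveSpec:
    """Generative parameters of a single groove cross-section.

    The wall shape is a superellipse arc z(t) = -depth + h * g(t) with
    g(t) = 1 - (1 - t**e)**(1/e) for t in [0, 1] measured from the base
    outward; e = 1 + wall_curvature for a V form (straight walls at 0) and
    e = 2 + wall_curvature for a U form (circular arc at 0). The higher wall
    rises ``shoulder_asymmetry`` times the lower wall's height above the
    base; its raised rim decays linearly back to the reference surface.
    """

    form: str = "V"
    breadth: float = 100.0            # um
    depth: float = 50.0               # um
    shoulder_asymmetry: float = 1.0   # higher wall / lower wall, >= 1
    wall_curvature: float = 0.0       # >= 0; 0 = canonical form
    noise_sd: float = 0.0             # um, additive iid Gaussian on z
    n_samples: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.form not in ("V", "U"):
            raise ValueError("form must be 'V' or 'U'")
        if self.breadth <= 0 or self.depth <= 0:
            raise ValueError("breadth and depth must be positive")
        if self.shoulder_asymmetry < 1:
            raise ValueError("shoulder_asymmetry must be >= 1")
        if self.wall_curvature < 0 or self.noise_sd < 0:
            raise ValueError("wall_curvature and noise_sd must be >= 0")
        if self.n_samples < 32:
            raise ValueError("n_samples must be >= 32")

    @property
    def exponent(self) -> float:
        return (1.0 if self.form == "V" else 2.0) + self.wall_curvature


@dataclass
class GrooveTruth:
    """Closed-form ground truth for a generated groove."""

    breadth: float
    depth: float
    h_hi: float
    h_lo: float
    b25: float
    measure1a: float
    measure1b: float
    measure2: float
    measure3: float
    measure4: float


def _g(t: np.ndarray, e: float) -> np.ndarray:
    return 1.0 - (1.0 - np.clip(t, 0.0, 1.0) ** e) ** (1.0 / e)


def _g_inv(c: float, e: float) -> float:
    # solve g(t) = c for t in [0, 1]
    return (1.0 - (1.0 - c) ** e) ** (1.0 / e)


def groove_truth(spec: GrooveSpec, with_measure4: bool = True) -> GrooveTruth:
    """Exact measures of the noiseless generating geometry.

    B, D, shoulder heights, B25 and measures 1-3 are closed forms of the
    superellipse; measure 4 is 1.0 for straight walls (e = 1) and is
    otherwise obtained by measuring a dense noiseless realization (skipped,
    and reported as NaN, when ``with_measure4`` is off — the fast path for
    population-scale Monte-Carlo work).
    """
    b, d, a, e = spec.breadth, spec.depth, spec.shoulder_asymmetry, spec.exponent
    t_r = _g_inv(0.25, e)              # lower wall, height d
    t_l = _g_inv(0.25 / a, e)          # higher wall, height a*d
    b25 = (t_l + t_r) * b / 2.0
    if e == 1.0:
        m4 = 1.0
    elif not with_measure4:
        m4 = float("nan")
    else:
        clean = GrooveSpec(form=spec.form, breadth=b, depth=d,
                           shoulder_asymmetry=a, wall_curvature=spec.wall_curvature,
                           noise_sd=0.0, n_samples=max(spec.n_samples, 2048),
                           seed=0)
        prof, _ = _generate(clean)
        m4 = measure_profile(prof).measure4
    return GrooveTruth(
        breadth=b, depth=d, h_hi=a * d, h_lo=d, b25=b25,
        measure1a=b / d, measure1b=b * d, measure2=b / b25, measure3=a,
        measure4=float(m4),
    )


def _grid(spec: GrooveSpec) -> np.ndarray:
    """Sample grid over [-1.5b, 1.5b] containing the geometry breakpoints exactly.

    Flanks of unmodified surface dominate the transect (as in profilometric
    practice, where the scan window comfortably straddles the mark), so the
    reference line is identifiable even with a raised shoulder rim.
    """
    b = spec.breadth
    knots = np.array([-1.5 * b, -0.75 * b, -0.5 * b, 0.0, 0.5 * b, 1.5 * b])
    lengths = np.diff(knots)
    # distribute samples proportionally; each interior segment >= 4 points
    counts = np.maximum((spec.n_samples * lengths / lengths.sum()).astype(int), 4)
    counts[-1] += (spec.n_samples - 1) - counts.sum()  # len(x) == n_samples
    pieces = []
    for k in range(len(lengths)):
        seg = np.linspace(knots[k], knots[k + 1], counts[k] + 1)
        pieces.append(seg[:-1] if k < len(lengths) - 1 else seg)
    x = np.concatenate(pieces)
    return x


def _groove_z(x: np.ndarray, spec: GrooveSpec) -> np.ndarray:
    b, d, a, e = spec.breadth, spec.depth, spec.shoulder_asymmetry, spec.exponent
    rim = (a - 1.0) * d
    half = b / 2.0
    z = np.zeros_like(x)
    ramp = (x >= -0.75 * b) & (x < -half)
    z[ramp] = rim * (x[ramp] + 0.75 * b) / (0.25 * b)
    left = (x >= -half) & (x < 0)
    t = -x[left] / half
    z[left] = -d + a * d * _g(t, e)
    right = (x >= 0) & (x <= half)
    t = x[right] / half
    z[right] = -d + d * _g(t, e)
    return z


def _generate(spec: GrooveSpec) -> tuple[CrossSectionProfile, GrooveTruth]:
    x = _grid(spec)
    n_groove = int(np.sum((x >= -spec.breadth / 2) & (x <= spec.breadth / 2)))
    if n_groove < 8:
        raise ValueError(f"n_samples too small: only {n_groove} samples across "
                         "the groove (need >= 8)")
    z = _groove_z(x, spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        z = z + rng.normal(0.0, spec.noise_sd, size=len(z))
    profile = CrossSectionProfile(x=x, z=z)
    return profile, None


def simulate_groove_profile(spec: GrooveSpec,
                            mark_id: str = "mark",
                            transect_index: int = 1
                            ) -> tuple[CrossSectionProfile, GrooveTruth]:
    """One noisy transect plus the exact ground truth of its geometry."""
    profile, _ = _generate(spec)
    profile.mark_id = mark_id
    profile.transect_index = transect_index
    return profile, groove_truth(spec)


# --------------------------------------------------------------------------
# marks (several transects) and populations
# --------------------------------------------------------------------------

def _jittered_spec(spec: GrooveSpec, jitter: float, rng: np.random.Generator,
                   seed: int) -> GrooveSpec:
    if jitter == 0:
        return GrooveSpec(**{**spec.__dict__, "seed": seed})
    f = np.exp(rng.normal(0.0, jitter, size=4))
    return GrooveSpec(
        form=spec.form,
        breadth=spec.breadth * f[0],
        depth=spec.depth * f[1],
        shoulder_asymmetry=1.0 + (spec.shoulder_asymmetry - 1.0) * f[2],
        wall_curvature=spec.wall_curvature * f[3],
        noise_sd=spec.noise_sd,
        n_samples=spec.n_samples,
        seed=seed,
    )


def simulate_mark(spec: GrooveSpec, longitudinal_jitter: float = 0.0,
                  transects: int = 3, mark_id: str = "mark",
                  with_profiles: bool = True, with_measure4: bool = True
                  ) -> tuple[list[CrossSectionProfile], MarkMeasures]:
    """A mark as ``transects`` perturbed cross-sections plus true measures.

    Each transect multiplies breadth, depth, asymmetry excess and curvature
    by independent lognormal factors with log-sd ``longitudinal_jitter``.
    True per-transect measures come from the generating parameters; true
    measures 5-7 are their sample CVs. With ``with_profiles=False`` only the
    truth table is built (fast path for Monte-Carlo calibration).
    """
    if longitudinal_jitter < 0:
        raise ValueError("longitudinal jitter must be >= 0")
    if transects < 2:
        raise ValueError("need at least 2 transects")
    rng = np.random.default_rng(spec.seed)
    profiles: list[CrossSectionProfile] = []
    true_transects: list[TransectMeasures] = []
    for t in range(transects):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        sub = _jittered_spec(spec, longitudinal_jitter, rng, sub_seed)
        truth = groove_truth(sub, with_measure4=with_measure4)
        true_transects.append(TransectMeasures(
            breadth=truth.breadth, depth=truth.depth, h_hi=truth.h_hi,
            h_lo=truth.h_lo, b25=truth.b25, measure1a=truth.measure1a,
            measure1b=truth.measure1b, measure2=truth.measure2,
            measure3=truth.measure3, measure4=truth.measure4))
        if with_profiles:
            prof, _ = _generate(sub)
            prof.mark_id = mark_id
            prof.transect_index = t + 1
            profiles.append(prof)
    from .morphometry import mark_level_measures
    truth_mark = mark_level_measures(true_transects, mark_id=mark_id)
    return profiles, truth_mark


@dataclass
class PopulationSpec:
    """A mark population with lognormal size and a CV-size coupling.

    ``log_size_mean``/``log_size_sd`` parameterize log(breadth x depth) in
    log-um^2. ``cv_size_slope`` (<= 0) adds to the baseline longitudinal
    jitter proportionally to the negative centered log size, so smaller marks
    are more variable along their length. Group defaults: the aquatic group
    is smaller (log mean 8.0 ~ 3 000 um^2 vs terrestrial 10.1 ~ 24 000 um^2)
    and more often U-sectioned, reflecting harder, stiffer bone surfaces.
    """

    group: str = "aquatic"
    log_size_mean: float | None = None
    log_size_sd: float = 0.7
    cv_size_slope: float = -0.08
    n_marks: int = 30
    transects_per_mark: int = 3
    base_jitter: float = 0.15
    seed: int = 0

    GROUP_DEFAULTS = {
        "aquatic": {"log_size_mean": 8.0, "u_prob": 0.5, "ratio_mean": 2.5},
        "terrestrial": {"log_size_mean": 10.1, "u_prob": 0.15, "ratio_mean": 2.0},
    }

    def __post_init__(self) -> None:
        if self.group not in self.GROUP_DEFAULTS:
            raise ValueError("group must be 'aquatic' or 'terrestrial'")
        if self.cv_size_slope > 0:
            raise ValueError("cv_size_slope must be <= 0")
        if self.n_marks < 1:
            raise ValueError("n_marks must be >= 1")
        if self.transects_per_mark < 2:
            raise ValueError("transects_per_mark must be >= 2")
        if self.log_size_mean is None:
            self.log_size_mean = self.GROUP_DEFAULTS[self.group]["log_size_mean"]


def simulate_mark_population(spec: PopulationSpec, with_profiles: bool = True
                             ) -> tuple[pd.DataFrame, list[CrossSectionProfile]]:
    """Sample a mark population; returns a tidy truth table and profiles.

    Table columns: mark_id, group, breadth_um, depth_um, size_um2,
    log_size, jitter, measure1a..measure7, max_dimension_um, mean_size_um2.
    """
    rng = np.random.default_rng(spec.seed)
    g = PopulationSpec.GROUP_DEFAULTS[spec.group]
    rows = []
    profiles: list[CrossSectionProfile] = []
    for i in range(spec.n_marks):
        log_s = rng.normal(spec.log_size_mean, spec.log_size_sd)
        size = math.exp(log_s)
        ratio = g["ratio_mean"] * math.exp(rng.normal(0.0, 0.2))
        depth = math.sqrt(size / ratio)
        breadth = size / depth
        form = "U" if rng.random() < g["u_prob"] else "V"
        curvature = float(np.abs(rng.normal(0.0, 0.3)))
        asym = 1.0 + float(np.abs(rng.normal(0.0, 0.15)))
        jitter = float(np.clip(
            spec.base_jitter + spec.cv_size_slope * (log_s - spec.log_size_mean),
            0.02, 0.6))
        mark_id = f"{spec.group[:3]}_{i:03d}"
        gspec = GrooveSpec(form=form, breadth=breadth, depth=depth,
                           shoulder_asymmetry=asym, wall_curvature=curvature,
                           noise_sd=0.02 * depth, n_samples=256,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        profs, truth = simulate_mark(gspec, longitudinal_jitter=jitter,
                                     transects=spec.transects_per_mark,
                                     mark_id=mark_id, with_profiles=with_profiles,
                                     with_measure4=with_profiles)
        profiles.extend(profs)
        t0 = truth.transects[0]
        rows.append({
            "mark_id": mark_id, "group": spec.group,
            "breadth_um": breadth, "depth_um": depth,
            "size_um2": size, "log_size": log_s, "jitter": jitter,
            "measure1a": t0.measure1a, "measure1b": t0.measure1b,
            "measure2": t0.measure2, "measure3": t0.measure3,
            "measure4": t0.measure4,
            "measure5": truth.measure5, "measure6": truth.measure6,
            "measure7": truth.measure7,
            "max_dimension_um": truth.max_dimension,
            "mean_size_um2": truth.mean_size,
        })
    return pd.DataFrame(rows), profiles


# --------------------------------------------------------------------------
# blind test
# --------------------------------------------------------------------------

def _default_confusion() -> dict[str, dict[str, float]]:
    # rows: true category -> distribution over called categories.
    # Trampling abrasion is the classic cut-mark mimic; intrinsic vascular
    # grooves pull false cut/scrape calls.
    c = {
        "cut/scrape":  {"cut/scrape": 0.55, "percussion": 0.05,
                        "human-tooth": 0.05, "trampling": 0.25, "none": 0.10},
        "percussion":  {"cut/scrape": 0.10, "percussion": 0.60,
                        "human-tooth": 0.10, "trampling": 0.10, "none": 0.10},
        "human-tooth": {"cut/scrape": 0.10, "percussion": 0.10,
                        "human-tooth": 0.55, "trampling": 0.10, "none": 0.15},
        "trampling":   {"cut/scrape": 0.30, "percussion": 0.05,
                        "human-tooth": 0.05, "trampling": 0.50, "none": 0.10},
    }
    return c


def _logistic_detection(pmin: float, pmax: float, x0: float, k: float = 2.0):
    def f(log_size: float) -> float:
        return pmin + (pmax - pmin) / (1.0 + math.exp(-k * (log_size - x0)))
    return f


@dataclass
class BlindTestSpec:
    """Design of a simulated inter-analyst blind test.

    Defaults mirror the reference protocol: 9 participants (5 hand-lens,
    4 microscope; 4 in teaching-tradition group TT1), 36 specimens of which
    5 carry only intrinsic features ('none') and 31 are modified, spread
    near-evenly over four mark categories; one participant skips 4 specimens.
    Detection probability is logistic and non-decreasing in log mark size,
    with the microscope curve dominating the hand-lens curve.
    """

    n_participants: int = 9
    instruments: tuple[str, ...] = ("hand_lens",) * 5 + ("microscope",) * 4
    pedagogy: tuple[str, ...] = ("TT1", "TT1", "TT2", "TT2", "TT1",
                                 "TT1", "TT2", "TT2", "TT2")
    years_experience: tuple[float, ...] = (12, 8, 6, 10, 18, 14, 4, 25, 37)
    n_specimens: int = 36
    category_counts: dict = field(default_factory=lambda: {
        "cut/scrape": 8, "percussion": 8, "human-tooth": 8,
        "trampling": 7, "none": 5})
    detection: dict = field(default_factory=lambda: {
        # argument is log max dimension in um: a ~75 um mark sits near the
        # hand-lens midpoint while the microscope curve saturates earlier
        "hand_lens": _logistic_detection(0.25, 0.95, math.log(70.0), k=2.0),
        "microscope": _logistic_detection(0.40, 0.99, math.log(50.0), k=2.0)})
    false_positive: dict = field(default_factory=lambda: {
        "hand_lens": 0.30, "microscope": 0.20})
    confusion: dict = field(default_factory=_default_confusion)
    n_skipped: int = 4          # specimens skipped by one participant
    skipper_index: int = 5      # 0-based; the 14-years-experience analyst
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.instruments) != self.n_participants:
            raise ValueError("one instrument per participant required")
        if len(self.pedagogy) != self.n_participants:
            raise ValueError("one pedagogy group per participant required")
        if len(self.years_experience) != self.n_participants:
            raise ValueError("one experience value per participant required")
        if sum(self.category_counts.values()) != self.n_specimens:
            raise ValueError("category frequencies must sum to n_specimens")
        if any(c not in CATEGORIES for c in self.category_counts):
            raise ValueError("unknown category in category_counts")
        for cat, row in self.confusion.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"confusion row for {cat!r} must sum to 1")


def _row_entropy(row: dict[str, float]) -> float:
    p = np.array([v for v in row.values() if v > 0])
    return float(-(p * np.log(p)).sum())


def simulate_blind_test(spec: BlindTestSpec, marks: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a response matrix against a generated answer key.

    ``marks`` must provide at least as many rows (with ``max_dimension_um``)
    as there are modified specimens. Returns (responses, participants, key).
    """
    rng = np.random.default_rng(spec.seed)
    n_modified = spec.n_specimens - spec.category_counts.get("none", 0)
    if len(marks) < n_modified:
        raise ValueError(f"need >= {n_modified} marks to populate the modified "
                         f"specimens, got {len(marks)}")
    cats = []
    for cat, cnt in spec.category_counts.items():
        cats.extend([cat] * cnt)
    cats = list(rng.permutation(cats))
    mark_rows = marks.sample(n=n_modified, random_state=int(rng.integers(2 ** 31)),
                             replace=False).reset_index(drop=True)
    key_rows = []
    mi = 0
    for s, cat in enumerate(cats):
        size = None
        if cat != "none":
            size = float(mark_rows.loc[mi, "max_dimension_um"])
            mi += 1
        key_rows.append({"specimen": f"S{s + 1:02d}", "category": cat,
                         "size_um": size})
    key = pd.DataFrame(key_rows)

    participants = pd.DataFrame({
        "participant": [f"P{i + 1}" for i in range(spec.n_participants)],
        "instrument": list(spec.instruments),
        "pedagogy": list(spec.pedagogy),
        "years": list(spec.years_experience),
    })

    max_h = math.log(len(CATEGORIES))
    skipped = set()
    if spec.n_skipped > 0:
        skipped_specs = rng.choice(spec.n_specimens, size=spec.n_skipped,
                                   replace=False)
        skipped = {(spec.skipper_index, int(s)) for s in skipped_specs}

    rows = []
    for pi in range(spec.n_participants):
        instr = spec.instruments[pi]
        detect = spec.detection[instr]
        fp = spec.false_positive[instr]
        for si in range(spec.n_specimens):
            if (pi, si) in skipped:
                continue
            cat = key.loc[si, "category"]
            if cat == "none":
                present = rng.random() < fp
                if present:
                    diagnosis = str(rng.choice(MARK_CATEGORIES))
                    q = 0.3
                else:
                    diagnosis = "none"
                    q = 1.0 - fp
            else:
                p_det = detect(math.log(key.loc[si, "size_um"]))
                if not 0.0 <= p_det <= 1.0:
                    raise ValueError("detection probability outside [0, 1]")
                present = rng.random() < p_det
                if present:
                    row = spec.confusion[cat]
                    diagnosis = str(rng.choice(list(row), p=list(row.values())))
                    q = 1.0 - _row_entropy(row) / max_h
                else:
                    diagnosis = "none"
                    q = 0.4
            conf = int(np.clip(round(1 + 4 * q + rng.normal(0, 0.5)), 1, 5))
            rows.append({"participant": f"P{pi + 1}",
                         "specimen": key.loc[si, "specimen"],
                         "present": bool(present), "diagnosis": diagnosis,
                         "confidence": conf})
    responses = pd.DataFrame(rows)
    return responses, participants, key


# --------------------------------------------------------------------------
# indentations
# --------------------------------------------------------------------------

DEFAULT_CLASS_MEANS = {"catfish": 48.0, "reptile": 38.0,
                       "mammal_cancellous": 30.0, "mammal_cortical": 36.0}
DEFAULT_CLASS_SDS = {"catfish": 8.0, "reptile": 7.0,
                     "mammal_cancellous": 6.0, "mammal_cortical": 6.0}
DEFAULT_CLASS_SIZES = {"catfish": 45, "reptile": 10,
                       "mammal_cancellous": 13, "mammal_cortical": 39}


def simulate_indentations(class_means: dict[str, float] | None = None,
                          class_sds: dict[str, float] | None = None,
                          load: float = 10.0,
                          n_per_class: dict[str, int] | int | None = None,
                          seed: int = 0,
                          variant: str = "paper") -> pd.DataFrame:
    """Indentation records whose recomputed hardness equals the sampled values.

    Hardness is sampled per bone class from a Gaussian; the mean diagonal is
    back-computed through the selected Vickers formula variant and split into
    two diagonals with a small symmetric imbalance (their mean is exact, so
    the round trip is lossless). Non-positive draws are resampled; the count
    is recorded in ``df.attrs['n_resampled']``.
    """
    class_means = dict(DEFAULT_CLASS_MEANS if class_means is None else class_means)
    class_sds = dict(DEFAULT_CLASS_SDS if class_sds is None else class_sds)
    if any(m <= 0 for m in class_means.values()):
        raise ValueError("all class means must be positive")
    if n_per_class is None:
        n_per_class = {c: DEFAULT_CLASS_SIZES.get(c, 10) for c in class_means}
    elif isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in class_means}
    factor = 1.8544 if variant == "standard" else 1.0
    rng = np.random.default_rng(seed)
    rows = []
    n_resampled = 0
    for cls, mean in class_means.items():
        sd = class_sds.get(cls, 0.0)
        for i in range(n_per_class.get(cls, 0)):
            hv = rng.normal(mean, sd) if sd > 0 else mean
            while hv <= 0:
                n_resampled += 1
                hv = rng.normal(mean, sd)
            d_mean = math.sqrt(factor * load / hv)
            delta = rng.uniform(0.0, 0.05)
            rows.append({"specimen": f"{cls}_{i:03d}", "bone_class": cls,
                         "load_kgf": load,
                         "d1_mm": d_mean * (1 + delta),
                         "d2_mm": d_mean * (1 - delta)})
    cols = ["specimen", "bone_class", "load_kgf", "d1_mm", "d2_mm"]
    df = pd.DataFrame(rows, columns=cols)
    if n_resampled:
        warnings.warn(f"resampled {n_resampled} non-positive hardness draws",
                      stacklevel=2)
    df.attrs["n_resampled"] = n_resampled
    return df
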