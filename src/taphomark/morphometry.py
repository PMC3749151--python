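"""Groove segmentation and cross-section morphometrics for bone-surface marks.

A cut-mark transect is an ordered (x, z) profile in micrometers crossing a
single groove. The surrounding unmodified surface is modeled as a line (the
reference plane in cross-section); all heights and depths are measured after
detrending by that line. Per-transect measures:

* breadth B — horizontal distance between the two shoulder points
* depth D — vertical drop from the reference line to the groove base
* measure 1a = B / D (optionally normalized by the geometric mean of
  {B, D, h_hi, h_lo}); measure 1b = B * D (a cross-sectional size proxy)
* measure 2 = B / B25, where B25 is the groove width at 25% of the depth
  above the base (linear interpolation between bracketing samples)
* measure 3 = higher wall height / lower wall height (>= 1 by construction)
* measure 4 = depth of the hypothetical apex where the two wall lines,
  least-squares fitted over a mid-depth band, intersect, divided by D
  (1.0 for an ideal V; > 1 for blunted or truncated bases)

Per-mark measures 5-7 are the coefficients of variation (sample sd / mean) of
measures 2-4 across the transects of one mark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrossSectionProfile",
    "ReferenceLine",
    "GrooveSegmentation",
    "TransectMeasures",
    "MarkMeasures",
    "NoGrooveError",
    "fit_reference_surface",
    "auto_exclusion",
    "segment_groove",
    "measure_transect",
    "wall_projection",
    "normalize_measure1a",
    "mark_level_measures",
    "measure_profile",
    "measure_mark",
]


class NoGrooveError(ValueError):
    """Raised when a profile contains no groove distinguishable from noise."""


@dataclass
class CrossSectionProfile:
    """One transect across a mark: ordered (x, z) micrometer samples."""

    x: np.ndarray
    z: np.ndarray
    mark_id: str = "mark"
    transect_index: int = 1

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.z.shape:
            raise ValueError("x and z must be 1-D arrays of equal length")
        if len(self.x) < 8:
            raise ValueError("profile needs at least 8 samples")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.z))):
            raise ValueError("profile contains non-finite values")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")


@dataclass
class ReferenceLine:
    slope: float
    intercept: float
    residual_sd: float
    n_used: int

    def __call__(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class GrooveSegmentation:
    """Base and shoulder geometry of one groove after reference detrending."""

    reference: ReferenceLine
    base: tuple[float, float]            # (x, detrended z) of the deepest point
    left_shoulder: tuple[float, float]   # (x, detrended z)
    right_shoulder: tuple[float, float]
    left_wall: tuple[int, int]           # sample index range [i0, i1] inclusive
    right_wall: tuple[int, int]
    base_index: int

    def __post_init__(self) -> None:
        if not (self.left_shoulder[0] < self.base[0] < self.right_shoulder[0]):
            raise ValueError("shoulders must flank the base in x")
        if not (self.base[1] < self.left_shoulder[1]
                and self.base[1] < self.right_shoulder[1]):
            raise ValueError("base must lie below both shoulders")


@dataclass
class TransectMeasures:
    breadth: float
    depth: float
    h_hi: float
    h_lo: float
    b25: float | None
    measure1a: float
    measure1b: float
    measure2: float | None
    measure3: float
    measure4: float | None = None
    measure4_unstable: bool = False
    wall_residual_sd: float | None = None
    measure1a_norm: float | None = None
    gm: float | None = None


@dataclass
class MarkMeasures:
    """Mark-level measurement vector: per-transect fields plus CV measures."""

    mark_id: str
    transects: list[TransectMeasures]
    measure5: float | None = None
    measure6: float | None = None
    measure7: float | None = None
    max_dimension: float | None = None   # max transect breadth (proxy)
    mean_size: float | None = None       # mean of measure 1b
    group: str | None = None


def fit_reference_surface(profile: CrossSectionProfile,
                          exclusion: tuple[float, float] | None) -> ReferenceLine:
    """Least-squares line through samples outside the exclusion x-interval."""
    if exclusion is None:
        mask = np.ones(len(profile.x), dtype=bool)
    else:
        lo, hi = exclusion
        mask = (profile.x < lo) | (profile.x > hi)
    if mask.sum() < 4:
        raise ValueError("need at least 4 samples outside the exclusion interval")
    xs, zs = profile.x[mask], profile.z[mask]
    slope, intercept = np.polyfit(xs, zs, 1)
    resid = zs - (slope * xs + intercept)
    sd = float(np.sqrt((resid ** 2).sum() / max(len(xs) - 2, 1)))
    return ReferenceLine(float(slope), float(intercept), sd, int(mask.sum()))


def _disturbed_interval(resid: np.ndarray, base: int, thresh: float,
                        run: int) -> tuple[int, int]:
    """Index interval around ``base`` outside which the residual is calm.

    Walking outward from the groove base, the mark (walls, raised rims,
    decay ramps) keeps |residual| above the threshold with at most short
    calm gaps; the boundary is placed where ``run`` consecutive samples
    return to within the threshold.
    """
    n = len(resid)
    bounds = []
    for step in (-1, +1):
        i = base
        last_active = base
        calm = 0
        while 0 < i < n - 1:
            i += step
            if abs(resid[i]) > thresh:
                last_active = i
                calm = 0
            else:
                calm += 1
                if calm >= run:
                    break
        bounds.append(last_active)
    return bounds[0], bounds[1]


def _robust_line(x: np.ndarray, z: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Trimmed iterative line fit: peel off groove/rim samples round by round.

    Successive refits keep a shrinking quantile of smallest absolute
    residuals (75% -> 60% -> 50%), then a final 2.5-sigma MAD band; this
    tolerates a groove plus rim occupying a large minority of the transect.
    """
    keep = np.ones(len(x), dtype=bool)
    slope = intercept = 0.0
    for frac in (0.75, 0.60, 0.50, None):
        slope, intercept = np.polyfit(x[keep], z[keep], 1)
        resid = z - (slope * x + intercept)
        med = np.median(resid[keep])
        dev = np.abs(resid - med)
        if frac is not None:
            band = np.quantile(dev, frac)
        else:
            mad = np.median(np.abs(resid[keep] - med))
            band = max(2.5 * 1.4826 * mad, 1e-12)
        new_keep = dev <= band
        if new_keep.sum() < 4:
            break
        keep = new_keep
    slope, intercept = np.polyfit(x[keep], z[keep], 1)
    return slope, intercept, keep


def auto_exclusion(profile: CrossSectionProfile,
                   margin_frac: float = 0.05) -> tuple[float, float]:
    """Estimate the groove-spanning x-interval to exclude from the reference fit.

    A trimmed iterative line fit identifies the unmodified flanks (the
    groove and any raised rim are peeled away as residual outliers round by
    round); the exclusion interval is then the contiguous residual
    disturbance around the deepest point, with short calm gaps (wall
    zero-crossings) bridged, plus a margin proportional to the profile span.
    """
    n = len(profile.x)
    run = max(4, n // 32)
    span = profile.x[-1] - profile.x[0]
    slope, intercept, keep = _robust_line(profile.x, profile.z)
    resid = profile.z - (slope * profile.x + intercept)
    base = int(np.argmin(resid))
    mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
    thresh = max(3 * 1.4826 * mad, 1e-12)
    li, ri = _disturbed_interval(resid, base, thresh, run)
    return (float(profile.x[li] - margin_frac * span),
            float(profile.x[ri] + margin_frac * span))


def _interp_crossing(x0: float, z0: float, x1: float, z1: float,
                     level: float) -> float:
    if z1 == z0:
        return x1
    return x0 + (level - z0) * (x1 - x0) / (z1 - z0)


def _find_shoulder(x: np.ndarray, zd: np.ndarray, base: int, step: int,
                   noise_sd: float, depth: float) -> tuple[float, float, int]:
    """Walk outward from the base; return (x, z, index) of the shoulder.

    The shoulder is the nearest local maximum rising clearly above the
    reference plane (a raised rim); when the wall simply returns to the
    unmodified surface, the interpolated reference-crossing point is used.
    """
    n = len(zd)
    # a genuine raised rim must stand clear of both the noise floor and a
    # small fraction of the groove depth; smaller rims are unresolvable and
    # the wall is treated as returning flush to the reference surface
    rim_thresh = max(4.0 * noise_sd, 0.03 * depth, 1e-12)
    i = base
    crossing = None           # (x, z) interpolated at level 0
    cross_idx = None
    while 0 <= i + step < n:
        j = i + step
        if crossing is None and zd[i] < 0 <= zd[j]:
            cx = _interp_crossing(x[i], zd[i], x[j], zd[j], 0.0)
            crossing = (cx, 0.0)
            cross_idx = j
        i = j
        if crossing is not None:
            break
    if crossing is None:
        # wall never reaches the reference plane: use the endpoint sample
        end = 0 if step < 0 else n - 1
        return float(x[end]), float(zd[end]), end

    # beyond the crossing, look for a raised rim before the surface settles
    peak_idx = cross_idx
    peak = zd[cross_idx]
    i = cross_idx
    drop_tol = max(3.0 * noise_sd, 0.02 * depth)
    while 0 <= i + step < n:
        i += step
        if zd[i] > peak:
            peak, peak_idx = zd[i], i
        elif peak - zd[i] > drop_tol:
            break
    if peak > rim_thresh:
        return float(x[peak_idx]), float(zd[peak_idx]), peak_idx
    if noise_sd > 1e-6 * depth:
        # under noise the first upward crossing is biased toward the base;
        # refine by fitting a line to the wall samples just inside and
        # projecting it to the reference level
        k = max(5, n // 32)
        idx = []
        i = cross_idx - step
        while 0 <= i != base and zd[i] < 0 and len(idx) < k:
            idx.append(i)
            i -= step
        if len(idx) >= 3:
            slope, inter = np.polyfit(x[idx], zd[idx], 1)
            if slope != 0:
                x0 = -inter / slope
                spacing = abs(x[idx[0]] - x[idx[-1]]) / max(len(idx) - 1, 1)
                if abs(x0 - crossing[0]) <= 3 * k * spacing:
                    return float(x0), 0.0, cross_idx
    return float(crossing[0]), 0.0, cross_idx


def segment_groove(profile: CrossSectionProfile,
                   reference: ReferenceLine) -> GrooveSegmentation:
    """Locate the groove base and shoulders in a detrended profile.

    The base is the global minimum of the detrended heights; it must lie
    below the reference by more than twice the reference-fit residual sd,
    otherwise no groove is declared. If a second depression of comparable
    depth exists outside the segmented groove, a warning is emitted and the
    deeper one is kept.
    """
    x = profile.x
    zd = profile.z - reference(x)
    base = int(np.argmin(zd))
    depth = -zd[base]
    noise = reference.residual_sd
    if base in (0, len(zd) - 1) or depth <= 2.0 * noise:
        raise NoGrooveError("no groove found: no interior minimum below the "
                            "reference beyond the noise level")
    lx, lz, li = _find_shoulder(x, zd, base, -1, noise, depth)
    rx, rz, ri = _find_shoulder(x, zd, base, +1, noise, depth)
    seg = GrooveSegmentation(
        reference=reference,
        base=(float(x[base]), float(zd[base])),
        left_shoulder=(lx, lz),
        right_shoulder=(rx, rz),
        left_wall=(li, base),
        right_wall=(base, ri),
        base_index=base,
    )
    outside = np.ones(len(zd), dtype=bool)
    outside[li:ri + 1] = False
    if outside.any():
        rest = np.where(outside, zd, np.inf)
        if rest.min() < -max(2.0 * noise, 0.25 * depth):
            warnings.warn("profile contains a second groove; the deeper one "
                          "was segmented", stacklevel=2)
    return seg


def _wall_width_at(x: np.ndarray, zd: np.ndarray, seg: GrooveSegmentation,
                   level: float) -> float | None:
    """Horizontal width of the groove at a detrended height, or None."""
    base = seg.base_index
    crossings = []
    for step, (i0, i1) in ((-1, seg.left_wall), (+1, seg.right_wall)):
        found = None
        i = base
        stop = i0 if step < 0 else i1
        while i != stop:
            j = i + step
            z0, z1 = zd[i], zd[j]
            if (z0 - level) * (z1 - level) <= 0 and z0 != z1:
                found = _interp_crossing(x[i], z0, x[j], z1, level)
                break
            i = j
        if found is None:
            return None
        crossings.append(found)
    width = crossings[1] - crossings[0]
    return float(width) if width > 0 else None


def measure_transect(profile: CrossSectionProfile,
                     seg: GrooveSegmentation) -> TransectMeasures:
    """Per-transect measures 1a, 1b, 2 and 3 from a segmented groove."""
    x = profile.x
    zd = profile.z - seg.reference(x)
    breadth = seg.right_shoulder[0] - seg.left_shoulder[0]
    depth = -seg.base[1]
    if breadth <= 0 or depth <= 0:
        raise ValueError("degenerate segmentation: non-positive breadth or depth")
    h_l = seg.left_shoulder[1] - seg.base[1]
    h_r = seg.right_shoulder[1] - seg.base[1]
    h_hi, h_lo = max(h_l, h_r), min(h_l, h_r)
    level = seg.base[1] + 0.25 * depth
    b25 = _wall_width_at(x, zd, seg, level)
    if b25 is None:
        warnings.warn("breadth at 25% depth unresolved; measure 2 flagged "
                      "missing", stacklevel=2)
    m = TransectMeasures(
        breadth=float(breadth),
        depth=float(depth),
        h_hi=float(h_hi),
        h_lo=float(h_lo),
        b25=b25,
        measure1a=float(breadth / depth),
        measure1b=float(breadth * depth),
        measure2=float(breadth / b25) if b25 else None,
        measure3=float(h_hi / h_lo) if h_lo > 0 else float("inf"),
    )
    m.gm, m.measure1a_norm = normalize_measure1a(m)
    return m


def wall_projection(profile: CrossSectionProfile, seg: GrooveSegmentation,
                    fit_band: tuple[float, float] = (0.25, 0.75)) -> TransectMeasures:
    """Measure 4: projected-apex depth ratio from straight-line wall fits.

    Each wall is least-squares fitted over samples whose detrended height lies
    within ``fit_band`` (fractions of depth above the base, default the middle
    half, excluding the curved base and shoulder rounding). The fitted lines
    are projected to their intersection, the hypothetical apex; measure 4 is
    the apex depth below the reference divided by the observed depth, so an
    ideal V scores 1.0 and blunter bases score above 1. Wall-fit residual sd
    is reported as a straightness diagnostic; a near-parallel intersection
    (apex deeper than 10x the observed depth) is flagged unstable.
    """
    x = profile.x
    zd = profile.z - seg.reference(x)
    depth = -seg.base[1]
    lo = seg.base[1] + fit_band[0] * depth
    hi = seg.base[1] + fit_band[1] * depth
    lines = []
    resid_all = []
    for (i0, i1) in (seg.left_wall, seg.right_wall):
        idx = np.arange(i0, i1 + 1)
        band = idx[(zd[idx] >= lo) & (zd[idx] <= hi)]
        if len(band) < 3:
            raise ValueError("wall has fewer than 3 samples inside the fit band")
        coef = np.polyfit(x[band], zd[band], 1)
        resid_all.append(zd[band] - np.polyval(coef, x[band]))
        lines.append(coef)
    (s1, c1), (s2, c2) = lines
    resid_sd = float(np.sqrt(np.mean(np.concatenate(resid_all) ** 2)))
    out = measure_transect(profile, seg)
    out.wall_residual_sd = resid_sd
    if s1 == s2:
        warnings.warn("parallel walls: apex undefined", stacklevel=2)
        out.measure4 = None
        out.measure4_unstable = True
        return out
    apex_x = (c2 - c1) / (s1 - s2)
    apex_z = s1 * apex_x + c1
    m4 = -apex_z / depth
    out.measure4 = float(m4)
    if m4 > 10.0 or m4 <= 0:
        warnings.warn("near-parallel walls: projected apex unstable "
                      f"(measure 4 = {m4:.3g})", stacklevel=2)
        out.measure4_unstable = True
    return out


def normalize_measure1a(m: TransectMeasures) -> tuple[float, float]:
    """Geometric-mean size normalization of the breadth:depth ratio.

    GM is the geometric mean of {B, D, h_hi, h_lo}; the normalized value is
    (B/D) / GM. Returns (GM, normalized). The raw ratio stays available on
    the measures object.
    """
    vals = np.array([m.breadth, m.depth, m.h_hi, m.h_lo], dtype=float)
    if np.any(vals <= 0):
        raise ValueError("geometric mean requires positive B, D and shoulder heights")
    gm = float(np.exp(np.mean(np.log(vals))))
    return gm, float(m.measure1a / gm)


def mark_level_measures(transects: list[TransectMeasures],
                        mark_id: str = "mark",
                        group: str | None = None) -> MarkMeasures:
    """Measures 5-7 (CVs of measures 2-4 across transects) and size summaries.

    The CV uses the sample standard deviation (divisor k - 1). A measure whose
    across-transect mean is non-positive, or with fewer than two non-missing
    values, is flagged missing (None) rather than zero.
    """
    if len(transects) < 2:
        raise ValueError("need at least 2 transects for mark-level measures")

    def cv(values) -> float | None:
        vals = np.array([v for v in values if v is not None and np.isfinite(v)],
                        dtype=float)
        if len(vals) < 2:
            return None
        mean = vals.mean()
        if mean <= 0:
            return None
        return float(vals.std(ddof=1) / mean)

    return MarkMeasures(
        mark_id=mark_id,
        transects=transects,
        measure5=cv([t.measure2 for t in transects]),
        measure6=cv([t.measure3 for t in transects]),
        measure7=cv([t.measure4 for t in transects]),
        max_dimension=float(max(t.breadth for t in transects)),
        mean_size=float(np.mean([t.measure1b for t in transects])),
        group=group,
    )


def measure_profile(profile: CrossSectionProfile,
                    exclusion: tuple[float, float] | None = None,
                    fit_band: tuple[float, float] = (0.25, 0.75)) -> TransectMeasures:
    """Full single-transect pipeline: reference fit, segmentation, measures 1-4."""
    if exclusion is None:
        exclusion = auto_exclusion(profile)
    ref = fit_reference_surface(profile, exclusion)
    seg = segment_groove(profile, ref)
    return wall_projection(profile, seg, fit_band=fit_band)


def measure_mark(profiles: list[CrossSectionProfile],
                 group: str | None = None, **kwargs) -> MarkMeasures:
    """Measure every transect of one mark and aggregate to mark level."""
    if not profiles:
        raise ValueError("no profiles supplied")
    transects = [measure_profile(p, **kwargs) for p in profiles]
    return mark_level_measures(transects, mark_id=profiles[0].mark_id, group=group)
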