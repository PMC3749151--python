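"""CSV readers/writers and packaged fixture tables.

One flat CSV dialect everywhere: comma-separated, UTF-8, header row. Numeric
fields round-trip at full precision (%.17g on write, round_trip
parsing on read). Fixture
tables are verbatim transcriptions of the published summary tables and are
checksummed on load.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import CrossSectionProfile, MarkMeasures

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_responses",
    "read_answer_key",
    "read_indentations",
    "measures_frame",
    "load_fixture",
    "FIXTURES",
]

FIXTURES = ("table1", "table3", "table4", "table6")

PROFILE_COLUMNS = ["mark_id", "transect", "x_um", "z_um"]
RESPONSE_COLUMNS = ["participant", "specimen", "present", "diagnosis", "confidence"]
INDENT_COLUMNS = ["specimen", "bone_class", "load_kgf", "d1_mm", "d2_mm"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _require_numeric(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {c!r} "
                             f"at row {int(bad[0]) + 2}")  # +2: header + 1-based
        if coerced.isna().any():
            raise ValueError(f"{path}: empty cell in column {c!r}")
        df[c] = coerced


def read_profiles(path) -> list[CrossSectionProfile]:
    """Read transect profiles (mark_id, transect, x_um, z_um) from CSV.

    Samples are sorted by x within each transect (with a warning if the file
    was unsorted); a duplicate x within one transect is an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PROFILE_COLUMNS, path)
    _require_numeric(df, ["transect", "x_um", "z_um"], path)
    profiles = []
    for (mark, transect), grp in df.groupby(["mark_id", "transect"], sort=True):
        x = grp["x_um"].to_numpy(float)
        if not np.all(np.diff(x) > 0):
            if len(np.unique(x)) != len(x):
                raise ValueError(f"{path}: duplicate x within mark {mark!r} "
                                 f"transect {transect}")
            warnings.warn(f"{path}: unsorted x in mark {mark!r} transect "
                          f"{transect}; sorting", stacklevel=2)
            grp = grp.sort_values("x_um")
            x = grp["x_um"].to_numpy(float)
        profiles.append(CrossSectionProfile(
            x=x, z=grp["z_um"].to_numpy(float),
            mark_id=str(mark), transect_index=int(transect)))
    return profiles


def write_profiles(profiles: list[CrossSectionProfile], path) -> None:
    frames = [pd.DataFrame({"mark_id": p.mark_id, "transect": p.transect_index,
                            "x_um": p.x, "z_um": p.z}) for p in profiles]
    # %.17g keeps the float64 round trip lossless
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RESPONSE_COLUMNS, path)
    df["participant"] = df["participant"].astype(str)
    df["specimen"] = df["specimen"].astype(str)
    df["present"] = df["present"].astype(bool)
    dupes = df.duplicated(["participant", "specimen"])
    if dupes.any():
        raise ValueError(f"{path}: duplicate (participant, specimen) record "
                         f"at row {int(df.index[dupes][0]) + 2}")
    return df


def read_answer_key(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["specimen", "category"], path)
    df["specimen"] = df["specimen"].astype(str)
    if "size_um" in df.columns:
        df["size_um"] = pd.to_numeric(df["size_um"], errors="coerce")
    return df


def read_indentations(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, INDENT_COLUMNS, path)
    _require_numeric(df, ["load_kgf", "d1_mm", "d2_mm"], path)
    return df


def measures_frame(marks: list[MarkMeasures]) -> pd.DataFrame:
    """Tidy mark-level measures table, one row per mark."""
    rows = []
    for m in marks:
        t = m.transects
        rows.append({
            "mark_id": m.mark_id,
            "group": m.group,
            "measure1a": float(np.mean([x.measure1a for x in t])),
            "measure1a_norm": float(np.mean([x.measure1a_norm for x in t
                                             if x.measure1a_norm is not None])),
            "measure1b": m.mean_size,
            "measure2": _safe_mean([x.measure2 for x in t]),
            "measure3": float(np.mean([x.measure3 for x in t])),
            "measure4": _safe_mean([x.measure4 for x in t]),
            "measure5": m.measure5,
            "measure6": m.measure6,
            "measure7": m.measure7,
            "max_dimension_um": m.max_dimension,
        })
    return pd.DataFrame(rows)


def _safe_mean(values) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else None


def _fixture_dir():
    return resources.files("taphomark") / "fixtures"


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table (table1, table3, table4 or table6).

    The file's SHA-256 is verified against the packaged checksum so a silent
    edit of a transcription cannot go unnoticed.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
    fdir = _fixture_dir()
    raw = (fdir / f"{name}.csv").read_bytes()
    checksums = json.loads((fdir / "checksums.json").read_text())
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checksums[name]:
        raise ValueError(f"fixture {name!r} failed its checksum")
    import io as _io
    return pd.read_csv(_io.BytesIO(raw))


def table3_values(task: str, abrasion: str, block: str) -> np.ndarray:
    """Correspondence percentages from the packaged pairwise table, in print order."""
    df = load_fixture("table3")
    sel = df[(df["task"] == task) & (df["abrasion"] == abrasion)
             & (df["block"] == block)]
    if sel.empty:
        raise ValueError(f"no table3 rows for {task}/{abrasion}/{block}")
    return sel["value"].to_numpy(float)
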