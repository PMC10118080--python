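"""Core domain types shared across the pipeline.

A molecular *feature* is one deconvoluted compound signal in one LC-MS run,
summarised as (m/z, retention time, peak height, quality score, integrated
abundance).  Feature lists are stored as pandas DataFrames with the columns
``mz, rt_min, height, quality, abundance``; the light dataclasses below carry
the sample- and study-level metadata around those tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Column order of a per-sample feature table.
FEATURE_COLUMNS = ["mz", "rt_min", "height", "quality", "abundance"]

#: Default chromatographic run length in minutes.
RUN_LENGTH_MIN = 30.0


def empty_feature_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in FEATURE_COLUMNS})


def as_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a DataFrame to the canonical feature-table layout.

    Missing ``quality`` defaults to 100 (a vendor quality filter of >= 80 then
    passes); missing ``abundance`` defaults to 100 x height, a peak-integral
    proxy used when only apex heights are available.
    """
    df = df.copy()
    if "quality" not in df.columns:
        df["quality"] = 100.0
    if "abundance" not in df.columns:
        df["abundance"] = 100.0 * df["height"]
    df = df[FEATURE_COLUMNS].astype(float).reset_index(drop=True)
    if len(df):
        if (df["mz"] <= 0).any():
            raise ValueError("feature m/z must be positive")
        if (df["height"] < 0).any():
            raise ValueError("feature height must be non-negative")
    return df


@dataclass(frozen=True)
class ToleranceWindows:
    """Combined relative + absolute alignment tolerances.

    The m/z half-width at mass ``m`` is ``m * mz_ppm * 1e-6 + mz_abs`` (the
    ``mz_abs`` default of 0.002 Da is the "2.0 mDa" term); the RT half-width at
    retention time ``t`` is ``t * rt_rel + rt_abs``.
    """

    rt_rel: float = 0.001   # 0.1 % relative RT window
    rt_abs: float = 0.15    # min
    mz_ppm: float = 5.0
    mz_abs: float = 0.002   # Da (= 2.0 mDa)

    def __post_init__(self) -> None:
        if min(self.rt_rel, self.rt_abs, self.mz_ppm, self.mz_abs) < 0:
            raise ValueError("tolerances must be non-negative")
        if self.rt_rel + self.rt_abs == 0 or self.mz_ppm + self.mz_abs == 0:
            raise ValueError("combined half-widths must be strictly positive")

    def mz_halfwidth(self, mz):
        return np.asarray(mz, dtype=float) * self.mz_ppm * 1e-6 + self.mz_abs

    def rt_halfwidth(self, rt):
        return np.asarray(rt, dtype=float) * self.rt_rel + self.rt_abs


def window_halfwidths(mz: float, rt: float, w: ToleranceWindows) -> tuple[float, float]:
    """Return the (m/z, RT) half-widths of the alignment window at (mz, rt)."""
    if mz <= 0:
        raise ValueError("mz must be positive")
    return float(w.mz_halfwidth(mz)), float(w.rt_halfwidth(rt))


@dataclass(frozen=True)
class MarkerRecord:
    """One row of the marker library: a species-specific metabolomic ion.

    ``rt_tol`` is the +/- spread of the retention time observed across the
    producer/batch samples, used (times a multiplier) as the RT match window
    in targeted screening.  ``detect_1pct``/``detect_5pct`` flag whether the
    marker remains detectable in a two-component mixture containing 1 % or 5 %
    (v/v) of its oil.
    """

    oil: str
    number: int
    precursor_mz: float
    rt_mean: float
    rt_tol: float
    fragments: tuple[float, ...]
    collision_energy: float
    detect_1pct: bool
    detect_5pct: bool

    def __post_init__(self) -> None:
        if self.rt_tol <= 0:
            raise ValueError(f"marker {self.number}: rt_tol must be > 0")
        for f in self.fragments:
            if f >= self.precursor_mz + 0.01:
                raise ValueError(
                    f"marker {self.number}: fragment m/z {f} not below precursor "
                    f"{self.precursor_mz}"
                )


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component v/v mixture: ``fraction`` of the minor oil in the major."""

    minor_species: str
    major_species: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("mixture fraction must lie in (0, 1)")
        if self.minor_species == self.major_species:
            raise ValueError("minor and major species must differ")


@dataclass
class Sample:
    """One LC-MS run: metadata plus its feature table."""

    id: str
    species: str = "unknown"
    producer: str = ""
    batch: str = ""
    role: str = "oil"  # oil | blank | mixture | panel
    features: pd.DataFrame = field(default_factory=empty_feature_table)
    mixture: Optional[MixtureSpec] = None

    def __post_init__(self) -> None:
        if self.role not in {"oil", "blank", "mixture", "panel"}:
            raise ValueError(f"unknown sample role {self.role!r}")
        if self.role == "mixture" and self.mixture is None:
            raise ValueError("mixture samples must carry a MixtureSpec")
        self.features = as_feature_table(self.features)

    def copy(self) -> "Sample":
        return replace(self, features=self.features.copy())


def check_unique_ids(samples: Sequence[Sample]) -> None:
    ids = [s.id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
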