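"""Half-month temporal compositing of multi-band satellite observations.

Raw per-date observations (optical top-of-atmosphere reflectance in [0, 1],
SAR backscatter in dB) are aggregated into calendar half-month ("15-day")
composites: the median of valid observations for optical bands and the
maximum for SAR polarizations.  The normalized difference vegetation index
(NDVI) is derived per composite period from the composited NIR and RED
reflectances.  The result is a :class:`FeatureCube` — a pixels x features
matrix with an explicit missing mask, where a feature is a (band, period)
pair.

Missingness is always carried in the boolean mask, never as a sentinel
inside the value matrix (matrix cells under the mask hold NaN purely for
hygiene and must not be read).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

OPTICAL_BANDS: tuple[str, ...] = ("BLUE", "GREEN", "RED", "NIR")
SAR_BANDS: tuple[str, ...] = ("VV", "VH")
NDVI_BAND = "NDVI"

#: bands whose composite cells count as "optical" for cloud/missing handling
OPTICAL_LIKE: tuple[str, ...] = OPTICAL_BANDS + (NDVI_BAND,)


@dataclass(frozen=True, order=True)
class CompositePeriod:
    """A calendar half-month: days 1–15 (half 1) or day 16–month end (half 2)."""

    year: int
    month: int
    half: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.half not in (1, 2):
            raise ValueError(f"half must be 1 or 2, got {self.half}")

    @property
    def label(self) -> str:
        return f"{self.year:04d}-{self.month:02d}{'a' if self.half == 1 else 'b'}"

    @classmethod
    def from_label(cls, label: str) -> "CompositePeriod":
        year, rest = label.split("-")
        return cls(int(year), int(rest[:2]), 1 if rest[2] == "a" else 2)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def assign_period(date: _dt.date | str) -> CompositePeriod:
    """Map a calendar date to its half-month composite period.

    Days 1–15 fall in the first half, day 16 through month end (including
    leap day February 29) in the second.
    """
    if isinstance(date, str):
        try:
            date = _dt.date.fromisoformat(date)
        except ValueError as exc:
            raise ValueError(f"invalid date: {date!r}") from exc
    if not isinstance(date, _dt.date):
        raise ValueError(f"invalid date: {date!r}")
    return CompositePeriod(date.year, date.month, 1 if date.day <= 15 else 2)


def composite_optical(values: Sequence[float] | np.ndarray) -> float:
    """Median of the valid optical observations in one period (NaN if none)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return float("nan")
    return float(np.median(arr))


def composite_sar(values: Sequence[float] | np.ndarray) -> float:
    """Maximum of the valid SAR backscatter values in one period (NaN if none)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return float("nan")
    return float(np.max(arr))


def ndvi(nir: float, red: float) -> float:
    """(NIR - RED) / (NIR + RED) from TOA reflectance; NaN when undefined.

    Missing (NaN) inputs or a zero denominator yield NaN; negative
    reflectance is a caller error.
    """
    if np.isnan(nir) or np.isnan(red):
        return float("nan")
    if nir < 0 or red < 0:
        raise ValueError(f"reflectance must be nonnegative, got nir={nir}, red={red}")
    denom = nir + red
    if denom == 0:
        return float("nan")
    return (nir - red) / denom


Feature = tuple[str, CompositePeriod]


@dataclass
class FeatureCube:
    """Pixels x features matrix of composited values with a missing mask.

    ``features`` is an ordered sequence of (band, period) pairs;
    ``missing[i, j]`` is True where pixel i has no valid composite for
    feature j, in which case ``values[i, j]`` is NaN.
    """

    pixel_ids: np.ndarray
    features: list[Feature]
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.pixel_ids = np.asarray(self.pixel_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, p = self.values.shape
        if self.missing.shape != (n, p):
            raise ValueError("values and missing shapes differ")
        if len(self.features) != p:
            raise ValueError("feature index length does not match values")
        if len(self.pixel_ids) != n:
            raise ValueError("pixel_ids length does not match values")
        if len(set(self.features)) != p:
            raise ValueError("duplicate features in index")
        if not np.all(np.isfinite(self.values[~self.missing])):
            raise ValueError("non-finite value where mask says present")

    # -- introspection -------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_labels(self) -> list[str]:
        return [f"{band}_{period.label}" for band, period in self.features]

    def bands(self) -> list[str]:
        return sorted({band for band, _ in self.features})

    # -- subsetting ----------------------------------------------------
    def select_features(self, indices: Sequence[int]) -> "FeatureCube":
        idx = list(indices)
        return FeatureCube(
            pixel_ids=self.pixel_ids.copy(),
            features=[self.features[i] for i in idx],
            values=self.values[:, idx].copy(),
            missing=self.missing[:, idx].copy(),
        )

    def select_pixels(self, indices: Sequence[int] | np.ndarray) -> "FeatureCube":
        idx = np.asarray(indices)
        return FeatureCube(
            pixel_ids=self.pixel_ids[idx].copy(),
            features=list(self.features),
            values=self.values[idx].copy(),
            missing=self.missing[idx].copy(),
        )

    def band_feature_indices(self, band: str) -> list[int]:
        return [j for j, (b, _) in enumerate(self.features) if b == band]

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.where(self.missing, np.nan, self.values),
            columns=self.feature_labels(),
        )
        df.insert(0, "pixel_id", self.pixel_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> list[dict]:
        return [
            {"band": band, "period": period.label} for band, period in self.features
        ]

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureCube":
        cols = [c for c in df.columns if c != "pixel_id"]
        features = []
        for c in cols:
            band, label = c.rsplit("_", 1)
            features.append((band, CompositePeriod.from_label(label)))
        values = df[cols].to_numpy(dtype=float)
        return cls(
            pixel_ids=df["pixel_id"].to_numpy(),
            features=features,
            values=values,
            missing=~np.isfinite(values),
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureCube":
        return cls.from_frame(pd.read_csv(path))


def build_cube(
    observations: pd.DataFrame,
    derive_ndvi: bool = True,
) -> FeatureCube:
    """Composite an observation table into a half-month :class:`FeatureCube`.

    ``observations`` needs columns pixel_id, date, band, value and an
    optional boolean ``valid`` column.  Optical bands (BLUE/GREEN/RED/NIR)
    composite by median, SAR polarizations (VV/VH) by maximum, each taken
    per (pixel, band, period).  With ``derive_ndvi`` an NDVI feature is
    added per period that has both NIR and RED composites.
    """
    required = {"pixel_id", "date", "band", "value"}
    if not required.issubset(observations.columns):
        raise ValueError(f"observation table needs columns {sorted(required)}")
    if observations.empty:
        raise ValueError("empty observation table")
    obs = observations.copy()
    if "valid" in obs.columns:
        obs = obs[obs["valid"].astype(bool)]
    obs = obs[np.isfinite(obs["value"].astype(float))]

    optical = obs["band"].isin(OPTICAL_BANDS)
    bad = obs.loc[optical & ((obs["value"] < 0) | (obs["value"] > 1))]
    if len(bad):
        raise ValueError(
            f"{len(bad)} optical observations outside [0, 1] reflectance"
        )

    obs["period"] = [assign_period(d).label for d in obs["date"].astype(str)]

    records = {}
    for (pixel, band, period), group in obs.groupby(["pixel_id", "band", "period"]):
        val = (
            composite_sar(group["value"].to_numpy())
            if band in SAR_BANDS
            else composite_optical(group["value"].to_numpy())
        )
        records[(pixel, band, period)] = val

    pixel_ids = np.array(sorted(obs["pixel_id"].unique()))
    periods = sorted(
        {CompositePeriod.from_label(p) for p in obs["period"].unique()}
    )
    band_order = [b for b in OPTICAL_BANDS + SAR_BANDS if b in set(obs["band"])]
    features: list[Feature] = [
        (band, period) for band in band_order for period in periods
        if any((pix, band, period.label) in records for pix in pixel_ids)
    ]

    n, p = len(pixel_ids), len(features)
    values = np.full((n, p), np.nan)
    for j, (band, period) in enumerate(features):
        for i, pix in enumerate(pixel_ids):
            values[i, j] = records.get((pix, band, period.label), np.nan)

    if derive_ndvi:
        nir_cols = {per: j for j, (b, per) in enumerate(features) if b == "NIR"}
        red_cols = {per: j for j, (b, per) in enumerate(features) if b == "RED"}
        for period in periods:
            if period in nir_cols and period in red_cols:
                col = np.array(
                    [
                        ndvi(values[i, nir_cols[period]], values[i, red_cols[period]])
                        for i in range(n)
                    ]
                )
                features.append((NDVI_BAND, period))
                values = np.column_stack([values, col])

    missing = ~np.isfinite(values)
    return FeatureCube(pixel_ids, features, values, missing)


def drop_sparse_composites(
    cube: FeatureCube, max_missing_fraction: float = 0.5
) -> tuple[FeatureCube, list[Feature]]:
    """Drop feature columns whose missing fraction strictly exceeds the cap.

    Mirrors the discard rule for composites with more than 50 % cloud
    cover; exactly-at-threshold columns are kept.  Returns the reduced
    cube and the list of dropped features.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    if cube.n_pixels == 0 or cube.n_features == 0:
        raise ValueError("empty cube")
    frac = cube.missing.mean(axis=0)
    keep = [j for j in range(cube.n_features) if frac[j] <= max_missing_fraction]
    dropped = [cube.features[j] for j in range(cube.n_features) if j not in set(keep)]
    return cube.select_features(keep), dropped
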