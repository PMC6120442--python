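"""Synthetic crop-phenology scenes for exercising the mapping pipeline.

Each crop follows a double-logistic seasonal NDVI curve — the standard
surrogate for crop greenness trajectories — parameterized by an NDVI floor
and peak, green-up and senescence inflection days, and logistic slopes.
Optical reflectance bands are derived from NDVI so that the vegetation
index computed downstream recovers the generating curve exactly; SAR
backscatter is a per-crop mean in dB plus Gaussian noise and, unlike the
optical bands, is never lost to cloud.

Cloud-driven missingness is period-correlated: one Bernoulli draw per
(pixel, half-month period) removes *all* optical observations of that
period, mimicking the way real cloud cover wipes out whole composite
windows rather than single bands.

The default crop library follows the North China Plain calendar: winter
wheat greens up in March and senesces in early June; cotton and spring
maize are sown in early May (cotton greening slowly, spring maize fast);
summer maize is sown after the wheat harvest in early July and matures in
late September; a "bare" profile stands in for non-vegetated surfaces.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composites import assign_period


@dataclass(frozen=True)
class CropPhenology:
    """Double-logistic NDVI profile parameters for one crop.

    vmin/vmax are the off-season and peak NDVI; t_green/t_senesce the
    green-up and senescence inflection days of year; k1/k2 the logistic
    slopes (1/day); noise_sd the per-observation NDVI noise; vv_db/vh_db
    the mean SAR backscatter of the two polarizations.
    """

    name: str
    vmin: float = 0.12
    vmax: float = 0.85
    t_green: float = 140.0
    t_senesce: float = 250.0
    k1: float = 0.10
    k2: float = 0.10
    noise_sd: float = 0.02
    vv_db: float = -11.0
    vh_db: float = -17.0

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError("vmin must be < vmax")
        if not self.t_green < self.t_senesce:
            raise ValueError("t_green must be < t_senesce")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("slopes must be positive")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def ndvi_profile(phenology: CropPhenology, day) -> np.ndarray | float:
    """Noiseless double-logistic NDVI at a day of year (scalar or array)."""
    t = np.asarray(day, dtype=float)
    v = phenology.vmin + (phenology.vmax - phenology.vmin) * (
        _sigmoid(phenology.k1 * (t - phenology.t_green))
        - _sigmoid(phenology.k2 * (t - phenology.t_senesce))
    )
    return v if v.ndim else float(v)


def bands_from_ndvi(
    ndvi, r0: float = 0.12, a: float = 0.08
) -> tuple[np.ndarray, np.ndarray]:
    """(NIR, RED) reflectances whose NDVI reproduces the input exactly.

    RED = r0 - a * ndvi and NIR = RED (1 + ndvi)/(1 - ndvi), so
    (NIR - RED)/(NIR + RED) = ndvi identically.  Values are clipped into
    (0, 1); ndvi of 1 (or beyond) has no finite NIR and is rejected.
    """
    v = np.asarray(ndvi, dtype=float)
    if np.any(v >= 1.0):
        raise ValueError("ndvi must be < 1")
    red = r0 - a * v
    nir = red * (1.0 + v) / (1.0 - v)
    red = np.clip(red, 1e-6, 1.0)
    nir = np.clip(nir, 1e-6, 1.0)
    if red.ndim:
        return nir, red
    return float(nir), float(red)


#: North China Plain calendar defaults (days of year, 2017 season).
DEFAULT_CROPS: dict[str, CropPhenology] = {
    c.name: c
    for c in (
        CropPhenology(
            "winter_wheat", vmin=0.15, vmax=0.85, t_green=75, t_senesce=160,
            k1=0.10, k2=0.10, vv_db=-10.0, vh_db=-16.0,
        ),
        CropPhenology(
            "cotton", vmin=0.12, vmax=0.80, t_green=145, t_senesce=266,
            k1=0.06, k2=0.08, vv_db=-11.5, vh_db=-17.5,
        ),
        CropPhenology(
            "spring_maize", vmin=0.12, vmax=0.88, t_green=141, t_senesce=243,
            k1=0.12, k2=0.10, vv_db=-11.0, vh_db=-17.0,
        ),
        CropPhenology(
            "summer_maize", vmin=0.12, vmax=0.85, t_green=190, t_senesce=274,
            k1=0.12, k2=0.10, vv_db=-12.0, vh_db=-18.0,
        ),
        CropPhenology(
            "bare", vmin=0.02, vmax=0.08, t_green=150, t_senesce=250,
            k1=0.02, k2=0.02, noise_sd=0.01, vv_db=-14.0, vh_db=-20.0,
        ),
    )
}


def default_dates(
    start: str = "2017-04-01", end: str = "2017-10-31", step_days: int = 5
) -> list[_dt.date]:
    """Regular acquisition calendar over the growing season."""
    d0 = _dt.date.fromisoformat(start)
    d1 = _dt.date.fromisoformat(end)
    out, d = [], d0
    while d <= d1:
        out.append(d)
        d += _dt.timedelta(days=step_days)
    return out


@dataclass
class SceneSpec:
    """Recipe for a labeled synthetic scene."""

    classes: list[str] = field(
        default_factory=lambda: [
            "winter_wheat", "cotton", "spring_maize", "summer_maize",
        ]
    )
    n_per_class: int = 100
    dates: list[_dt.date] = field(default_factory=default_dates)
    missing_prob: float = 0.2
    sar_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_prob <= 1:
            raise ValueError("missing_prob must lie in [0, 1]")
        if self.n_per_class < 1:
            raise ValueError("need at least 1 pixel per class")
        if not self.classes:
            raise ValueError("need at least 1 class")


def simulate_scene(
    spec: SceneSpec,
    crops: dict[str, CropPhenology] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a labeled observation table for the given scene recipe.

    Returns (observations, labels): a long table with columns
    pixel_id/date/band/value/valid and a per-pixel truth label series.
    Optical bands (plus the NDVI they encode) share one noisy NDVI draw per
    (pixel, date); cloud loss invalidates all optical observations of a
    (pixel, period); VV/VH are always valid.
    """
    crops = crops or DEFAULT_CROPS
    unknown = set(spec.classes) - set(crops)
    if unknown:
        raise ValueError(f"no phenology for classes {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)

    labels = np.repeat(spec.classes, spec.n_per_class)
    n = labels.size
    pixel_ids = np.arange(n)
    doys = np.array([d.timetuple().tm_yday for d in spec.dates], dtype=float)
    periods = [assign_period(d).label for d in spec.dates]
    uniq_periods = sorted(set(periods))
    period_col = {p: k for k, p in enumerate(uniq_periods)}

    # one cloud draw per (pixel, period), optical only
    cloudy = rng.random((n, len(uniq_periods))) < spec.missing_prob

    records: list[pd.DataFrame] = []
    for cls in spec.classes:
        phen = crops[cls]
        rows = np.flatnonzero(labels == cls)
        base = ndvi_profile(phen, doys)  # (n_dates,)
        v = base[None, :] + rng.normal(0.0, phen.noise_sd, size=(rows.size, doys.size))
        v = np.clip(v, -0.5, 0.98)
        nir, red = bands_from_ndvi(v)
        blue = np.clip(red * 0.8 + rng.normal(0, 0.005, red.shape), 1e-6, 1.0)
        green = np.clip(red * 0.9 + rng.normal(0, 0.005, red.shape), 1e-6, 1.0)
        vv = phen.vv_db + rng.normal(0, spec.sar_noise_sd, red.shape)
        vh = phen.vh_db + rng.normal(0, spec.sar_noise_sd, red.shape)

        date_period_idx = np.array([period_col[p] for p in periods])
        clouded = cloudy[np.ix_(rows, date_period_idx)]  # (n_rows, n_dates)

        band_values = {
            "BLUE": blue, "GREEN": green, "RED": red, "NIR": nir,
            "VV": vv, "VH": vh,
        }
        for band, vals in band_values.items():
            valid = (
                np.ones_like(clouded) if band in ("VV", "VH") else ~clouded
            )
            records.append(
                pd.DataFrame(
                    {
                        "pixel_id": np.repeat(pixel_ids[rows], doys.size),
                        "date": np.tile(
                            [d.isoformat() for d in spec.dates], rows.size
                        ),
                        "band": band,
                        "value": vals.ravel(),
                        "valid": valid.astype(bool).ravel(),
                    }
                )
            )
    obs = pd.concat(records, ignore_index=True)
    truth = pd.Series(labels, index=pixel_ids, name="label")
    return obs, truth


def inject_missing(cube, fraction: float, seed: int = 0):
    """Knock out an exact fraction of the present optical cells of a cube.

    Cells are drawn uniformly without replacement among present entries of
    optical-like bands (reflectance and NDVI features); SAR features are
    untouched.  Returns a new cube.
    """
    from .composites import OPTICAL_LIKE, FeatureCube

    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    optical_cols = np.array(
        [j for j, (b, _) in enumerate(cube.features) if b in OPTICAL_LIKE]
    )
    missing = cube.missing.copy()
    values = cube.values.copy()
    if optical_cols.size:
        sub_present = ~missing[:, optical_cols]
        flat = np.flatnonzero(sub_present)
        k = int(round(fraction * flat.size))
        rng = np.random.default_rng(seed)
        hit = rng.choice(flat, size=k, replace=False)
        r, c = np.unravel_index(hit, sub_present.shape)
        missing[r, optical_cols[c]] = True
        values[r, optical_cols[c]] = np.nan
    return FeatureCube(
        pixel_ids=cube.pixel_ids.copy(),
        features=list(cube.features),
        values=values,
        missing=missing,
    )
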