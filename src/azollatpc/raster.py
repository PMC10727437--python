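"""Projection of a fitted thermal performance curve onto temperature rasters.

A fitted curve is applied pixel-wise to gridded annual-mean temperature
(WorldClim bio1 style) to yield a habitat-suitability surface: predicted
relative growth rate (d⁻¹) at each location.  Scenario comparison then
reduces to raster arithmetic — pixel-wise differences between a future and
the current layer, regional means over a clip mask, and percent change.

Nodata semantics: a pixel equal to the declared sentinel (or NaN) is
excluded from every computation and propagated unchanged; differences are
defined only where both layers are valid (mask intersection).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._geotiff import GridTransform, read_geotiff, write_geotiff
from .model import RoomParams, room_performance

DEFAULT_NODATA = -9999.0


@dataclass
class TemperatureGrid:
    """A georeferenced 2-D grid of mean annual temperature (°C)."""

    values: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise ValueError(f"grid must be 2-D and non-empty, got {self.values.shape}")

    @property
    def valid_mask(self) -> np.ndarray:
        v = self.values
        return np.isfinite(v) & (v != self.nodata)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SuitabilityGrid(TemperatureGrid):
    """Predicted RGR (d⁻¹) per pixel; inherits georeferencing semantics."""


@dataclass(frozen=True)
class RegionMask:
    """Boolean clip mask aligned to a grid (True = inside the region)."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "inside", np.asarray(self.inside, dtype=bool))
        if self.inside.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class ScenarioSummary:
    """Regional statistics for one (species, scenario) pair.

    ``mean_diff`` and ``pct_change`` are present only for future scenarios
    (relative to the current layer); ``pct_change`` = 100 * mean_diff /
    current mean RGR.
    """

    species: str
    scenario: str
    mean_rgr: float
    mean_diff: float | None = None
    pct_change: float | None = None

    def formatted(self) -> dict:
        """Report-style rounding: 3 decimals for rates, signed 2 for percent."""
        out = {
            "species": self.species,
            "scenario": self.scenario,
            "mean_rgr": round(self.mean_rgr, 3),
        }
        if self.mean_diff is not None:
            out["mean_diff"] = round(self.mean_diff, 5)
        if self.pct_change is not None:
            out["pct_change"] = f"{self.pct_change:+.2f}%"
        return out


def project_suitability(grid: TemperatureGrid, params: RoomParams) -> SuitabilityGrid:
    """Apply the curve pixel-wise; nodata pixels are propagated unchanged."""
    mask = grid.valid_mask
    out = np.full(grid.shape, grid.nodata, dtype=np.float64)
    out[mask] = room_performance(grid.values[mask], params)
    return SuitabilityGrid(
        values=out, transform=grid.transform, crs=grid.crs, nodata=grid.nodata
    )


def clip(grid: TemperatureGrid, mask: RegionMask) -> TemperatureGrid:
    """Set pixels outside the region to nodata; georeferencing unchanged."""
    if mask.inside.shape != grid.shape:
        raise ValueError(
            f"mask shape {mask.inside.shape} does not match grid shape {grid.shape}"
        )
    out = grid.values.copy()
    out[~mask.inside] = grid.nodata
    return type(grid)(
        values=out, transform=grid.transform, crs=grid.crs, nodata=grid.nodata
    )


def _latitude_weights(grid: TemperatureGrid) -> np.ndarray:
    rows = np.arange(grid.shape[0])
    lats = grid.transform.y_origin - (rows + 0.5) * grid.transform.pixel_height
    w = np.cos(np.deg2rad(lats))
    return np.repeat(w[:, None], grid.shape[1], axis=1)


def regional_mean(grid: SuitabilityGrid, weighted: bool = False) -> float:
    """Mean over valid pixels; optionally cos(latitude) area-weighted."""
    mask = grid.valid_mask
    if not mask.any():
        raise ValueError("no valid pixels")
    if weighted:
        w = _latitude_weights(grid)[mask]
        return float(np.sum(grid.values[mask] * w) / np.sum(w))
    return float(np.mean(grid.values[mask]))


def difference_map(future: SuitabilityGrid, current: SuitabilityGrid) -> SuitabilityGrid:
    """Pixel-wise future − current on the intersection of valid masks."""
    if future.shape != current.shape:
        raise ValueError(
            f"grid shapes differ: future {future.shape} vs current {current.shape}"
        )
    mask = future.valid_mask & current.valid_mask
    out = np.full(future.shape, future.nodata, dtype=np.float64)
    out[mask] = future.values[mask] - current.values[mask]
    return SuitabilityGrid(
        values=out, transform=future.transform, crs=future.crs, nodata=future.nodata
    )


def percent_change(mean_diff: float, current_mean: float) -> float:
    """100 × mean_diff / current_mean."""
    if current_mean == 0:
        raise ValueError("current mean is zero; percent change undefined")
    return 100.0 * mean_diff / current_mean


def summarize_scenarios(
    current: TemperatureGrid,
    futures: Sequence[tuple[str, TemperatureGrid]],
    params: RoomParams,
    species: str,
    mask: RegionMask | None = None,
    weighted: bool = False,
    current_label: str = "current",
) -> list[ScenarioSummary]:
    """One summary per scenario: regional mean RGR, mean difference, % change.

    Temperature grids are clipped (optionally), projected through the curve,
    and compared pixel-wise against the current layer on the intersection of
    valid masks.
    """
    if mask is not None:
        current = clip(current, mask)
        futures = [(label, clip(g, mask)) for label, g in futures]
    current_suit = project_suitability(current, params)
    current_mean = regional_mean(current_suit, weighted=weighted)
    summaries = [
        ScenarioSummary(species=species, scenario=current_label, mean_rgr=current_mean)
    ]
    for label, grid in futures:
        suit = project_suitability(grid, params)
        diff = difference_map(suit, current_suit)
        mean_diff = regional_mean(diff, weighted=weighted)
        summaries.append(
            ScenarioSummary(
                species=species,
                scenario=label,
                mean_rgr=regional_mean(suit, weighted=weighted),
                mean_diff=mean_diff,
                pct_change=percent_change(mean_diff, current_mean),
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.species,
                "scenario": s.scenario,
                "mean_rgr_per_day": s.mean_rgr,
                "mean_diff_per_day": s.mean_diff,
                "pct_change": s.pct_change,
            }
            for s in summaries
        ]
    )


def write_summaries(
    summaries: Sequence[ScenarioSummary], csv_path: str | Path, json_path: str | Path
) -> None:
    summaries_to_frame(summaries).to_csv(csv_path, index=False)
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump([s.formatted() for s in summaries], fh, indent=2)


def read_raster(path: str | Path, scale_factor: float = 1.0) -> TemperatureGrid:
    """Read a single-band GeoTIFF into a TemperatureGrid.

    ``scale_factor`` converts stored units to °C (e.g. 0.1 for layers stored
    as tenths of a degree); nodata pixels are never scaled.
    """
    values, transform, crs, nodata = read_geotiff(path)
    values = values.astype(np.float64)
    if scale_factor != 1.0:
        valid = np.isfinite(values) & (values != nodata)
        values[valid] *= scale_factor
    return TemperatureGrid(values=values, transform=transform, crs=crs, nodata=nodata)


def read_mask(path: str | Path) -> RegionMask:
    """Read a 0/1 GeoTIFF region mask aligned to the working grid."""
    values, _, _, nodata = read_geotiff(path)
    inside = np.isfinite(values) & (values != nodata) & (values > 0)
    return RegionMask(inside=inside)


def write_raster(grid: TemperatureGrid, path: str | Path) -> None:
    """Write a grid to single-band float32 GeoTIFF (round-trip safe)."""
    write_geotiff(
        path,
        grid.values.astype(np.float32),
        grid.transform,
        crs=grid.crs,
        nodata=grid.nodata,
    )
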