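"""Run configuration: the constants of the analysis in one flat record."""

from __future__ import annotations

import dataclasses
import tomllib
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RunConfig", "rng_for"]


@dataclass
class RunConfig:
    """All tunable constants of the pipeline.

    Defaults are the study conditions: a 12.5 m analysis grid, the 0.5-5 m
    understory stratum, a 460 m territory border with a 15 m nest radius,
    a 5% no-data tolerance inside buffers, and a 500-3,500 m / 50 m
    candidate grid for the settlement-distance breakpoint.
    """

    grid_cell_size: float = 12.5  # m
    understory_low: float = 0.5  # m, stratum lower bound (inclusive)
    understory_high: float = 5.0  # m, stratum upper bound (exclusive)
    territory_radius: float = 460.0  # m
    nest_radius: float = 15.0  # m
    nodata_fraction_max: float = 0.05
    breakpoint_grid: tuple[float, float, float] = (500.0, 3500.0, 50.0)  # min, max, step m
    close_threshold: float = 1500.0  # m, headline proximity cut
    n_radii: int = 100  # radii beyond the nest radius
    radius_spacing: str = "equal_area"  # or "linear"
    ud_log_floor: float = 0.1  # % floor before log transform
    center_covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.understory_low < self.understory_high:
            raise ValueError("understory_low must be < understory_high")
        for name in (
            "grid_cell_size",
            "understory_low",
            "territory_radius",
            "nest_radius",
            "close_threshold",
        ):
            if getattr(self, name) <= 0 and name != "understory_low":
                raise ValueError(f"{name} must be positive")
        if self.understory_low < 0:
            raise ValueError("understory_low must be non-negative")
        if not 0.0 <= self.nodata_fraction_max <= 1.0:
            raise ValueError("nodata_fraction_max must be in [0, 1]")
        lo, hi, step = self.breakpoint_grid
        if not (lo > 0 and hi > lo and step > 0):
            raise ValueError("breakpoint_grid must satisfy 0 < min < max, step > 0")
        if self.radius_spacing not in ("equal_area", "linear"):
            raise ValueError("radius_spacing must be 'equal_area' or 'linear'")

    def radii(self) -> np.ndarray:
        """Radius schedule: the nest radius plus ``n_radii`` larger radii.

        ``equal_area`` spaces the larger radii so successive discs add equal
        area up to the territory border (r_k = R * sqrt(k / n)); ``linear``
        spaces them evenly between the nest radius and the border.
        """
        r_nest, r_max, n = self.nest_radius, self.territory_radius, self.n_radii
        if self.radius_spacing == "equal_area":
            ring = r_max * np.sqrt(np.arange(1, n + 1) / n)
        else:
            ring = np.linspace(r_nest, r_max, n + 1)[1:]
        radii = np.concatenate([[r_nest], ring[ring > r_nest]])
        return np.unique(radii)

    def breakpoint_candidates(self) -> np.ndarray:
        lo, hi, step = self.breakpoint_grid
        return np.arange(lo, hi + 0.5 * step, step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["breakpoint_grid"] = list(self.breakpoint_grid)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat TOML key-value file; unknown keys are an error."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "breakpoint_grid" in raw:
            raw["breakpoint_grid"] = tuple(raw["breakpoint_grid"])
        return cls(**raw)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, pipeline stage).

    Stages draw from separate streams so regenerating one stage does not
    perturb the others.
    """
    key = zlib.crc32(stage.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(key,)))
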