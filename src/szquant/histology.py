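"""Fluoro-Jade B stack-volume and cell-density arithmetic.

Degenerating neurons are counted in confocal image stacks (450 x 450 um in
XY, 5 or 10 um in Z) from hippocampal subregions CA1, CA3 and the dentate
hilus, both hemispheres, across several sections. Densities are reported as
cells per 10^6 um^3 with n = animals: counts and volumes are pooled *within*
each animal (sum of counts / sum of volume) before averaging across animals,
so stacks with unequal volumes are weighted by volume rather than equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SUBREGIONS", "ImageStackDesign", "stack_volume", "stacks_per_rat", "mean_density"]

SUBREGIONS = ("CA1", "CA3", "hilus")


@dataclass(frozen=True)
class ImageStackDesign:
    """Sampling design for one experiment.

    ``stacks_per_subregion`` may be a single integer (same for all
    subregions) or a per-subregion mapping, e.g. ``{"CA1": 2, "CA3": 1,
    "hilus": 1}``.
    """

    xy_um: float = 450.0
    z_um: float = 5.0
    stacks_per_subregion: int | Mapping[str, int] = 3
    n_sections: int = 3
    n_hemispheres: int = 2
    subregions: tuple[str, ...] = SUBREGIONS

    def stacks_for(self, subregion: str) -> int:
        if isinstance(self.stacks_per_subregion, Mapping):
            return int(self.stacks_per_subregion[subregion])
        return int(self.stacks_per_subregion)


def stack_volume(design: ImageStackDesign) -> float:
    """Volume of one image stack in um^3 (xy^2 * z)."""
    if design.xy_um < 0 or design.z_um < 0:
        raise ValueError("dimensions must be non-negative")
    return design.xy_um**2 * design.z_um


def stacks_per_rat(design: ImageStackDesign) -> dict:
    """Stack counts per subregion and in total for one animal."""
    per = {
        sr: design.stacks_for(sr) * design.n_hemispheres * design.n_sections
        for sr in design.subregions
    }
    return {"per_subregion": per, "total": sum(per.values())}


def mean_density(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM Fluoro-Jade B cell density per subregion, n = animals.

    ``records`` needs columns ``subject``, ``subregion``, ``count``,
    ``volume_um3`` (one row per stack). Per-animal density is pooled:
    sum(count) / sum(volume) within subject x subregion, scaled to cells per
    10^6 um^3, then averaged across animals.
    """
    required = {"subject", "subregion", "count", "volume_um3"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if (records["volume_um3"] <= 0).any():
        raise ValueError("stack volumes must be positive")
    per_subject = (
        records.groupby(["subregion", "subject"])
        .apply(
            lambda g: g["count"].sum() / g["volume_um3"].sum() * 1e6,
            include_groups=False,
        )
        .rename("density_per_1e6_um3")
        .reset_index()
    )
    out = (
        per_subject.groupby("subregion")["density_per_1e6_um3"]
        .agg(
            mean="mean",
            sem=lambda v: v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0,
            n="size",
        )
        .reset_index()
    )
    return out
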