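"""Ternary energy-flow analysis: channel fractions in a fixed triangle.

Decomposition energy reaches the nematode trophic level through three
channels — bacterial (via bacterivores), fungal (via fungivores) and plant
(via root feeders). Each sample's relative channel footprints
(BFMF, FFMF, PPMF normalized to sum 1; OPMF is excluded because
omnivore-predators integrate over channels) place it inside a fixed
equilateral triangle with base (0,0)-(100,0) and apex (50, 86.6).

The apex ordinate is 100·sin 60° reported at the conventional one-decimal
precision (86.6); the same printed frame is used consistently, so
barycentric round-trips are exact within it. Which channel owns which
vertex is configuration: by default bacterial → lower-left, fungal →
lower-right, plant → apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "APEX_Y",
    "EnergyTriangle",
    "reference_frame",
    "channel_fractions",
    "ternary_to_cartesian",
    "cartesian_to_fractions",
    "ternary_table",
]

#: apex ordinate of the side-100 equilateral triangle, 100·sin 60° at 1 decimal
APEX_Y = 86.6

_CHANNELS = ("bacterial", "fungal", "plant")


@dataclass(frozen=True)
class EnergyTriangle:
    """The fixed reference triangle with one vertex per energy channel."""

    bacterial: tuple[float, float] = (0.0, 0.0)
    fungal: tuple[float, float] = (100.0, 0.0)
    plant: tuple[float, float] = (50.0, APEX_Y)

    @property
    def vertices(self) -> dict[str, tuple[float, float]]:
        return {"bacterial": self.bacterial, "fungal": self.fungal, "plant": self.plant}

    @property
    def side_midpoints(self) -> dict[str, tuple[float, float]]:
        """Midpoints of the three sides, named by the channel pair they join."""
        v = self.vertices
        pairs = [("bacterial", "fungal"), ("fungal", "plant"), ("plant", "bacterial")]
        return {
            f"{a}-{b}": ((v[a][0] + v[b][0]) / 2.0, (v[a][1] + v[b][1]) / 2.0)
            for a, b in pairs
        }

    @property
    def centroid(self) -> tuple[float, float]:
        xs, ys = zip(*self.vertices.values())
        return (sum(xs) / 3.0, sum(ys) / 3.0)

    def reference_points(self) -> dict[str, tuple[float, float]]:
        """The 7 frame points: 3 vertices, 3 side midpoints, centroid."""
        points = dict(self.vertices)
        points.update(self.side_midpoints)
        points["centroid"] = self.centroid
        return points


def reference_frame() -> EnergyTriangle:
    """The default reference triangle (apex (50, 86.6), base (0,0)-(100,0))."""
    return EnergyTriangle()


def channel_fractions(bfmf: float, ffmf: float, ppmf: float) -> tuple[float, float, float]:
    """(f_bact, f_fung, f_plant): each channel footprint over the 3-channel sum.

    Returns a NaN triple when all three footprints are zero (the point is
    undefined and reported missing, never placed at an arbitrary vertex).
    """
    if min(bfmf, ffmf, ppmf) < 0:
        raise ValueError("channel footprints must be nonnegative")
    total = bfmf + ffmf + ppmf
    if total <= 0:
        return (math.nan, math.nan, math.nan)
    return (bfmf / total, ffmf / total, ppmf / total)


def ternary_to_cartesian(
    fractions, triangle: EnergyTriangle | None = None
) -> tuple[float, float]:
    """Barycentric interpolation of (f_bact, f_fung, f_plant) into the plane."""
    tri = triangle or reference_frame()
    fb, ff, fp = (float(f) for f in fractions)
    x = fb * tri.bacterial[0] + ff * tri.fungal[0] + fp * tri.plant[0]
    y = fb * tri.bacterial[1] + ff * tri.fungal[1] + fp * tri.plant[1]
    return (x, y)


def cartesian_to_fractions(
    xy, triangle: EnergyTriangle | None = None
) -> tuple[float, float, float]:
    """Invert the barycentric map: solve for the channel fractions of a point."""
    tri = triangle or reference_frame()
    mat = np.array(
        [
            [tri.bacterial[0], tri.fungal[0], tri.plant[0]],
            [tri.bacterial[1], tri.fungal[1], tri.plant[1]],
            [1.0, 1.0, 1.0],
        ]
    )
    rhs = np.array([xy[0], xy[1], 1.0])
    fb, ff, fp = np.linalg.solve(mat, rhs)
    return (float(fb), float(ff), float(fp))


def ternary_table(
    footprints: pd.DataFrame, triangle: EnergyTriangle | None = None
) -> pd.DataFrame:
    """Per-sample channel fractions and plane coordinates from a footprint table.

    ``footprints`` must carry BFMF, FFMF and PPMF columns (as produced by
    :func:`microfoodweb.footprints.group_footprints`).
    """
    tri = triangle or reference_frame()
    rows = []
    for sample, row in footprints.iterrows():
        fb, ff, fp = channel_fractions(row["BFMF"], row["FFMF"], row["PPMF"])
        if math.isnan(fb):
            x = y = math.nan
        else:
            x, y = ternary_to_cartesian((fb, ff, fp), tri)
        rows.append(
            {"sample_id": sample, "f_bact": fb, "f_fung": ff, "f_plant": fp, "x": x, "y": y}
        )
    return pd.DataFrame(rows).set_index("sample_id")
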