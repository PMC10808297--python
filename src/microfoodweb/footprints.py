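"""Nematode metabolic footprints and the functional-footprint rhombus.

The metabolic footprint of a taxon approximates the carbon flux through its
population — a production term scaling with biomass over life-course
(c-p class) plus a respiration term scaling with metabolic body mass:

    F = N · (0.1 · W / m + 0.273 · W^0.75)

with N the abundance, W the mean individual fresh weight (µg) and m the c-p
class. Group footprints (BFMF, FFMF, PPMF, OPMF) sum F over the taxa of
each trophic group; TNMF is their total. The enrichment footprint Fe sums
over the enrichment-opportunist guilds (Ba1, Fu2) and the structure
footprint Fs over free-living c-p 3-5 taxa, following the Ferris (2010)
definitions of the guild families.

The functional footprint plots the community in the (SI, EI) faunal plane
as a rhombus centered at (SI, EI) with horizontal diagonal Fs/k and
vertical diagonal Fe/k; its area Fe·Fs/(2k²) summarizes food-web activity.
The display constant k only rescales footprint units into plot units; by
convention here ``k = max(Fe, Fs)/50`` so the largest diamond spans the
0-100 plane, and every report states the k used.

Footprints need *absolute* abundances (the formula is linear in N);
operations refuse relative-abundance tables unless the caller asserts
absoluteness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotatedNematodeTable
from .traits import CP_CLASSES, TraitRecord, guild_of

__all__ = [
    "AbsoluteCountsError",
    "taxon_footprint",
    "group_footprints",
    "FootprintDiamond",
    "functional_footprint",
    "auto_k",
    "ENRICHMENT_GUILDS",
    "STRUCTURE_CP_CLASSES",
]

#: guilds whose footprints constitute the enrichment footprint Fe
ENRICHMENT_GUILDS = ("Ba1", "Fu2")
#: free-living c-p classes whose footprints constitute the structure footprint Fs
STRUCTURE_CP_CLASSES = (3, 4, 5)

_GROUP_COLUMNS = {"BF": "BFMF", "FF": "FFMF", "PP": "PPMF", "OP": "OPMF"}


class AbsoluteCountsError(ValueError):
    """Footprints requested on a table not asserted to hold absolute counts."""


def taxon_footprint(n: float, fresh_weight: float, cp_class: int) -> float:
    """Footprint contribution N·(0.1·W/m + 0.273·W^0.75) of one taxon."""
    if cp_class not in CP_CLASSES:
        raise ValueError(f"cp_class must be in 1-5, got {cp_class!r}")
    if not fresh_weight > 0:
        raise ValueError(f"fresh_weight must be > 0 µg, got {fresh_weight!r}")
    if n < 0:
        raise ValueError(f"abundance must be nonnegative, got {n!r}")
    return n * (0.1 * (fresh_weight / cp_class) + 0.273 * fresh_weight**0.75)


def _in_fe(record: TraitRecord) -> bool:
    return guild_of(record) in ENRICHMENT_GUILDS


def _in_fs(record: TraitRecord) -> bool:
    return record.is_free_living and record.cp_class in STRUCTURE_CP_CLASSES


def group_footprints(
    annotated: AnnotatedNematodeTable, *, absolute_counts: bool = False
) -> pd.DataFrame:
    """Per-sample footprints: BFMF, FFMF, PPMF, OPMF, TNMF, Fe, Fs.

    ``absolute_counts`` must be asserted by the caller: footprints are
    linear in abundance, so relative abundances would silently rescale the
    carbon flux per sample.
    """
    if not absolute_counts:
        raise AbsoluteCountsError(
            "metabolic footprints require absolute abundances; pass "
            "absolute_counts=True only if the table holds counts of "
            "individuals (or reads treated as such), not proportions"
        )
    data = annotated.table.data
    out = pd.DataFrame(
        0.0,
        index=data.index,
        columns=["BFMF", "FFMF", "PPMF", "OPMF", "TNMF", "Fe", "Fs"],
        dtype=float,
    )
    for genus, record in annotated.traits.items():
        contrib = np.array(
            [taxon_footprint(n, record.fresh_weight, record.cp_class) for n in data[genus]]
        )
        col = _GROUP_COLUMNS[record.trophic_group]
        out[col] += contrib
        if _in_fe(record):
            out["Fe"] += contrib
        if _in_fs(record):
            out["Fs"] += contrib
    out["TNMF"] = out[["BFMF", "FFMF", "PPMF", "OPMF"]].sum(axis=1)
    return out


def auto_k(fe, fs) -> float:
    """Dataset-wide display scaling: k = max(Fe, Fs)/50.

    Chosen so the largest diamond's diagonals span the 0-100 faunal plane.
    Falls back to 1.0 when every footprint is zero.
    """
    top = max(float(np.max(fe)), float(np.max(fs)))
    return top / 50.0 if top > 0 else 1.0


@dataclass(frozen=True)
class FootprintDiamond:
    """Functional-footprint rhombus in the (SI, EI) plane.

    ``vertices`` are, in order, left (SI-0.5·Fs/k, EI), right
    (SI+0.5·Fs/k, EI), bottom (SI, EI-0.5·Fe/k), top (SI, EI+0.5·Fe/k);
    ``area`` = Fe·Fs/(2k²).
    """

    center: tuple[float, float]
    k: float
    vertices: tuple[tuple[float, float], ...]
    area: float

    @property
    def polygon(self) -> tuple[tuple[float, float], ...]:
        """Vertices in drawing order (left, bottom, right, top)."""
        left, right, bottom, top = self.vertices
        return (left, bottom, right, top)


def functional_footprint(
    si: float, ei: float, fe: float, fs: float, k: float
) -> FootprintDiamond:
    """Build the functional-footprint rhombus for one sample or treatment."""
    if not k > 0:
        raise ValueError(f"display constant k must be > 0, got {k!r}")
    if fe < 0 or fs < 0:
        raise ValueError("footprints must be nonnegative")
    if not (math.isfinite(si) and math.isfinite(ei)):
        raise ValueError("SI and EI must be defined to place the diamond")
    half_fs = 0.5 * fs / k
    half_fe = 0.5 * fe / k
    vertices = (
        (si - half_fs, ei),
        (si + half_fs, ei),
        (si, ei - half_fe),
        (si, ei + half_fe),
    )
    area = fe * fs / (2.0 * k**2)
    return FootprintDiamond(center=(si, ei), k=k, vertices=vertices, area=area)
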