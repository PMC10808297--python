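"""Nematode faunal analysis: enrichment/structure/basal/channel indices,
maturity indices, trophic diversity and faunal-profile quadrants.

The guild-weighted framework of Ferris et al. (2001) scores each free-living
guild (feeding letters × c-p digit) into three components:

* enrichment ``e`` — opportunist guilds that flush after resource pulses,
  ``e = 3.2·Ba1 + 0.8·Fu2``;
* basal ``b`` — the stress-tolerant general-purpose fauna,
  ``b = 0.8·(Ba2 + Fu2)``;
* structure ``s`` — higher c-p free-living guilds indicating food-web
  complexity, ``s = Σ_{cp 3-5} w(cp)·N`` with ``w = 1.8, 3.2, 5.0``.

From these, EI = 100·e/(e+b), SI = 100·s/(s+b), BI = 100·b/(e+s+b) and the
channel index CI = 100·0.8·Fu2/(3.2·Ba1 + 0.8·Fu2) (high CI = fungal
decomposition channel). Plant parasites never enter e/b/s. The weights are
configuration, not constants — :class:`FaunalWeights` can be overridden to
match alternative parameterizations.

Maturity indices are abundance-weighted mean c-p values: MI over free-living
taxa, PPI over plant parasites. TD is the reciprocal Simpson dominance of
the four trophic-group proportions.

An index with a zero denominator is *undefined* and emitted as NaN, never
silently 0 — BI = 100 and "EI undefined" are different ecological
statements.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import AnnotatedNematodeTable, aggregate_trophic_groups
from .traits import guild_of

__all__ = [
    "FaunalWeights",
    "DEFAULT_WEIGHTS",
    "GuildComponents",
    "guild_abundances",
    "guild_components",
    "enrichment_structure_basal",
    "channel_index",
    "maturity_indices",
    "trophic_diversity",
    "classify_quadrant",
    "faunal_index_table",
]

logger = logging.getLogger(__name__)


def _default_enrichment() -> dict[str, float]:
    return {"Ba1": 3.2, "Fu2": 0.8}


def _default_basal() -> dict[str, float]:
    return {"Ba2": 0.8, "Fu2": 0.8}


def _default_structure() -> dict[int, float]:
    return {3: 1.8, 4: 3.2, 5: 5.0}


@dataclass(frozen=True)
class FaunalWeights:
    """Guild weighting scheme for the e/b/s components.

    ``enrichment`` and ``basal`` map guild codes to weights; ``structure``
    maps c-p classes (applied to every free-living guild of that class,
    Ba/Fu/Om/Ca alike). Defaults are the canonical Ferris (2001) values.
    """

    enrichment: Mapping[str, float] = field(default_factory=_default_enrichment)
    basal: Mapping[str, float] = field(default_factory=_default_basal)
    structure: Mapping[int, float] = field(default_factory=_default_structure)

    @classmethod
    def from_yaml(cls, path) -> "FaunalWeights":
        """Load overrides from a YAML mapping with any of the three keys."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "enrichment" in raw:
            kwargs["enrichment"] = {str(k): float(v) for k, v in raw["enrichment"].items()}
        if "basal" in raw:
            kwargs["basal"] = {str(k): float(v) for k, v in raw["basal"].items()}
        if "structure" in raw:
            kwargs["structure"] = {int(k): float(v) for k, v in raw["structure"].items()}
        return cls(**kwargs)


DEFAULT_WEIGHTS = FaunalWeights()


@dataclass(frozen=True)
class GuildComponents:
    """Weighted guild components for one sample.

    ``ba1`` and ``fu2`` are the *weighted* enrichment-opportunist terms
    (3.2·N_Ba1 and 0.8·N_Fu2 under default weights); ``e`` is their sum.
    All components are nonnegative and computed over matched taxa only.
    """

    e: float
    b: float
    s: float
    ba1: float
    fu2: float


def guild_abundances(annotated: AnnotatedNematodeTable) -> pd.DataFrame:
    """Samples × guild-code abundance matrix (codes present in the data)."""
    data = annotated.table.data
    out: dict[str, pd.Series] = {}
    for genus, record in annotated.traits.items():
        code = guild_of(record)
        out[code] = out.get(code, 0.0) + data[genus]
    return pd.DataFrame(out, index=data.index).sort_index(axis=1)


def guild_components(
    annotated: AnnotatedNematodeTable,
    sample: str,
    weights: FaunalWeights = DEFAULT_WEIGHTS,
) -> GuildComponents:
    """Compute (e, b, s) and the weighted Ba1/Fu2 terms for one sample."""
    row = annotated.table.data.loc[sample]
    e = b = s = ba1 = fu2 = 0.0
    any_free_living = False
    for genus, record in annotated.traits.items():
        n = float(row[genus])
        if not record.is_free_living:
            continue
        if n > 0:
            any_free_living = True
        code = guild_of(record)
        w_e = weights.enrichment.get(code, 0.0)
        if w_e:
            e += w_e * n
            if code == "Ba1":
                ba1 += w_e * n
            elif code == "Fu2":
                fu2 += w_e * n
        w_b = weights.basal.get(code, 0.0)
        if w_b:
            b += w_b * n
        w_s = weights.structure.get(record.cp_class, 0.0)
        if w_s:
            s += w_s * n
    if not any_free_living:
        logger.warning(
            "sample %r has no free-living nematodes; e/b/s are zero and the "
            "derived indices will be undefined", sample,
        )
    return GuildComponents(e=e, b=b, s=s, ba1=ba1, fu2=fu2)


def enrichment_structure_basal(components: GuildComponents) -> tuple[float, float, float]:
    """(EI, SI, BI) percentages; NaN where the denominator is zero."""
    c = components
    ei = 100.0 * c.e / (c.e + c.b) if c.e + c.b > 0 else math.nan
    si = 100.0 * c.s / (c.s + c.b) if c.s + c.b > 0 else math.nan
    bi = 100.0 * c.b / (c.e + c.s + c.b) if c.e + c.s + c.b > 0 else math.nan
    return ei, si, bi


def channel_index(components: GuildComponents) -> float:
    """CI = 100·(weighted Fu2)/(weighted Ba1 + weighted Fu2); NaN when both are 0.

    CI near 100 indicates fungal-channel decomposition, near 0 bacterial.
    """
    denom = components.ba1 + components.fu2
    return 100.0 * components.fu2 / denom if denom > 0 else math.nan


def maturity_indices(
    annotated: AnnotatedNematodeTable,
    sample: str,
    include_cp1: bool = True,
) -> tuple[float, float, float]:
    """(MI, PPI, PPI/MI) for one sample.

    MI is the abundance-weighted mean c-p over free-living taxa (cp-1
    opportunists included by default; set ``include_cp1=False`` for the
    tradition that excludes them), PPI the same over plant parasites.
    Undefined pieces (no taxa in the partition) propagate as NaN.
    """
    row = annotated.table.data.loc[sample]
    fl_n = fl_cp = pp_n = pp_cp = 0.0
    for genus, record in annotated.traits.items():
        n = float(row[genus])
        if n == 0:
            continue
        if record.is_free_living:
            if record.cp_class == 1 and not include_cp1:
                continue
            fl_n += n
            fl_cp += record.cp_class * n
        else:
            pp_n += n
            pp_cp += record.cp_class * n
    mi = fl_cp / fl_n if fl_n > 0 else math.nan
    ppi = pp_cp / pp_n if pp_n > 0 else math.nan
    ratio = ppi / mi if (mi == mi and ppi == ppi and mi > 0) else math.nan
    return mi, ppi, ratio


def trophic_diversity(groups) -> float:
    """TD = 1/Σ p_i² over the four trophic-group proportions.

    Reciprocal Simpson dominance: 1 when a single group holds everything,
    4 when the four groups are equally abundant.
    """
    vec = np.asarray(groups, dtype=float)
    if (vec < 0).any() or not np.isfinite(vec).all():
        raise ValueError("group abundances must be finite and nonnegative")
    total = vec.sum()
    if total <= 0:
        raise ValueError("all-zero trophic-group vector: TD undefined")
    p = vec / total
    return float(1.0 / (p**2).sum())


def classify_quadrant(ei: float, si: float) -> str | None:
    """Faunal-profile quadrant from (EI, SI); ≥50 counts as high.

    A: enriched, unstructured (EI≥50, SI<50); B: enriched, structured;
    C: structured, low enrichment (EI<50, SI≥50); D: degraded (both <50).
    ``None`` when either index is undefined.
    """
    if not (math.isfinite(ei) and math.isfinite(si)):
        return None
    if ei >= 50.0:
        return "B" if si >= 50.0 else "A"
    return "C" if si >= 50.0 else "D"


def faunal_index_table(
    annotated: AnnotatedNematodeTable,
    weights: FaunalWeights = DEFAULT_WEIGHTS,
    include_cp1: bool = True,
) -> pd.DataFrame:
    """Per-sample EI, SI, BI, CI, TD, MI, PPI, PPI/MI and quadrant.

    Undefined values are NaN (serialized as ``NA``); the quadrant column is
    ``None`` where EI or SI is undefined.
    """
    groups = aggregate_trophic_groups(annotated)
    rows = []
    for sample in annotated.samples:
        comp = guild_components(annotated, sample, weights)
        ei, si, bi = enrichment_structure_basal(comp)
        ci = channel_index(comp)
        mi, ppi, ratio = maturity_indices(annotated, sample, include_cp1)
        gvec = groups.loc[sample].to_numpy()
        td = trophic_diversity(gvec) if gvec.sum() > 0 else math.nan
        rows.append(
            {
                "sample_id": sample,
                "EI": ei,
                "SI": si,
                "BI": bi,
                "CI": ci,
                "TD": td,
                "MI": mi,
                "PPI": ppi,
                "PPI_MI": ratio,
                "quadrant": classify_quadrant(ei, si),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
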