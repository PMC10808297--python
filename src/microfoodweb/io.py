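"""Reading, validating and annotating sample × genus community tables.

One :class:`CommunityTable` holds one kingdom (bacteria, fungi or nematodes)
as a samples × taxa matrix of nonnegative abundances. The canonical on-disk
dialect is tab-separated, samples as rows, ``.`` decimal, no locale
dependence; a ``taxa_as_rows`` flag accepts transposed files.

Abundance semantics matter downstream: every index in
:mod:`microfoodweb.faunal` is scale-invariant, but metabolic footprints
need absolute abundances — :func:`microfoodweb.footprints.group_footprints`
therefore demands an explicit flag rather than guessing.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traits import TROPHIC_GROUPS, TraitDatabase, TraitRecord

__all__ = [
    "CommunityTable",
    "CommunityTableError",
    "AnnotatedNematodeTable",
    "AnnotationError",
    "read_community_table",
    "read_metadata",
    "validate_metadata",
    "annotate_nematodes",
    "aggregate_trophic_groups",
]

logger = logging.getLogger(__name__)


class CommunityTableError(ValueError):
    """Parse failure or invariant violation in a community table."""


class AnnotationError(ValueError):
    """Nematode table could not be bound to traits (no matched taxa)."""


@dataclass
class CommunityTable:
    """Validated samples × taxa abundance matrix for one kingdom.

    ``data`` is a :class:`pandas.DataFrame` with unique sample IDs as the
    index and unique genus names as columns; entries are nonnegative and
    finite. Construction validates; downstream code can rely on the
    invariants.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise CommunityTableError("community table needs ≥1 sample and ≥1 taxon")
        if df.index.has_duplicates:
            raise CommunityTableError("duplicate sample IDs")
        if df.columns.has_duplicates:
            raise CommunityTableError("duplicate taxon names")
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise CommunityTableError(f"non-numeric abundance entry: {exc}") from exc
        values = df.to_numpy()
        if np.isnan(values).any():
            raise CommunityTableError("missing (NaN) abundance entries")
        if not np.isfinite(values).all():
            raise CommunityTableError("non-finite abundance entries")
        if (values < 0).any():
            raise CommunityTableError("negative abundance entries")
        df.index = df.index.astype(str).str.strip()
        df.columns = df.columns.astype(str).str.strip()
        df.index.name = "sample_id"
        df.columns.name = None
        self.data = df

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def write(self, path: str | Path) -> None:
        """Emit the canonical dialect (TSV, samples as rows)."""
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    def subset_taxa(self, taxa) -> "CommunityTable":
        return CommunityTable(self.data[list(taxa)].copy())


def read_community_table(
    source, *, taxa_as_rows: bool = False, sep: str | None = None
) -> CommunityTable:
    """Read a delimited community table; orientation normalized to samples × taxa.

    The first column holds sample IDs (or taxon names with
    ``taxa_as_rows=True``). The delimiter defaults to tab, or comma for
    ``.csv`` paths; pass ``sep`` to override.
    """
    if sep is None:
        sep = "," if str(source).lower().endswith(".csv") else "\t"
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    header = next(
        (line for line in text.splitlines() if line and not line.startswith("#")), ""
    )
    names = [c.strip() for c in header.split(sep)[1:]]
    if len(names) != len(set(names)):
        kind = "sample" if taxa_as_rows else "taxon"
        raise CommunityTableError(f"duplicate {kind} names in header")
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise CommunityTableError(f"malformed community table: {exc}") from exc
    if taxa_as_rows:
        df = df.T
    return CommunityTable(df)


def read_metadata(source, *, sep: str | None = None) -> pd.DataFrame:
    """Read sample metadata (columns ``sample_id``, ``treatment``, ``replicate``)."""
    if sep is None:
        sep = "," if str(source).lower().endswith(".csv") else "\t"
    meta = pd.read_csv(source, sep=sep, comment="#", dtype={"sample_id": str})
    required = {"sample_id", "treatment", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise CommunityTableError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise CommunityTableError("duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def validate_metadata(table: CommunityTable, metadata: pd.DataFrame) -> None:
    """Every table sample must have exactly one metadata row."""
    missing = [s for s in table.samples if s not in metadata.index]
    if missing:
        raise CommunityTableError(f"samples without metadata: {missing}")


@dataclass
class AnnotatedNematodeTable:
    """A nematode :class:`CommunityTable` restricted to trait-matched taxa.

    ``table`` holds only the matched genera (what index math sees);
    ``traits`` maps each retained column name to its :class:`TraitRecord`;
    ``unmatched`` lists genera dropped for lack of trait data.
    """

    table: CommunityTable
    traits: dict[str, TraitRecord]
    unmatched: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return self.table.samples


def annotate_nematodes(table: CommunityTable, db: TraitDatabase) -> AnnotatedNematodeTable:
    """Bind a nematode genus table to the trait database.

    Genera absent from ``db`` are excluded (logged, never imputed). All
    taxa unmatched is a hard error — every downstream index would be
    vacuous.
    """
    matched: dict[str, TraitRecord] = {}
    unmatched: list[str] = []
    for genus in table.taxa:
        if genus in db:
            matched[genus] = db.lookup(genus)
        else:
            unmatched.append(genus)
    if not matched:
        raise AnnotationError("no taxon in the table matches the trait database")
    if unmatched:
        logger.warning(
            "excluding %d/%d genera without trait records: %s",
            len(unmatched), len(table.taxa), ", ".join(unmatched),
        )
    return AnnotatedNematodeTable(
        table=table.subset_taxa(matched), traits=matched, unmatched=unmatched
    )


def aggregate_trophic_groups(annotated: AnnotatedNematodeTable) -> pd.DataFrame:
    """Per-sample abundance summed into the four trophic groups (BF/FF/PP/OP).

    Row sums equal the matched-genus totals — the partition conserves
    abundance.
    """
    data = annotated.table.data
    out = pd.DataFrame(
        0.0, index=data.index, columns=list(TROPHIC_GROUPS), dtype=float
    )
    for genus, record in annotated.traits.items():
        out[record.trophic_group] += data[genus]
    return out
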