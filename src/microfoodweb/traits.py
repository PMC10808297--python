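"""Nematode trait reference: feeding guilds, colonizer-persister classes, body masses.

Every faunal index and metabolic footprint downstream keys off three
genus-level traits:

* **trophic group** — BF (bacterivore), FF (fungivore), PP (plant parasite),
  OP (omnivore-predator);
* **c-p class** — the 1-5 colonizer-persister score, low values marking
  fast-breeding enrichment opportunists and high values long-lived,
  disturbance-sensitive taxa;
* **fresh weight** — mean individual fresh body mass in micrograms, the
  biomass term of the metabolic-footprint equation.

The *guild* of a genus is its feeding-group letter pair crossed with the c-p
digit (``Ba1``, ``Fu2``, ``Om4`` ...) — the unit of the Ferris weighting
scheme used by :mod:`microfoodweb.faunal`.

A packaged genus-level reference table compiled from the public Nemaplex
trait compendium ships with the package (:func:`packaged_traits`). It is a
plain, user-replaceable TSV; fresh weights are genus means and carry no
within-genus size distribution.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "TROPHIC_GROUPS",
    "CP_CLASSES",
    "FREE_LIVING_GROUPS",
    "TraitRecord",
    "TraitDatabase",
    "TraitTableError",
    "UnknownGenusError",
    "load_trait_table",
    "packaged_traits",
    "guild_of",
    "all_guild_codes",
    "normalize_genus",
]

TROPHIC_GROUPS = ("BF", "FF", "PP", "OP")
CP_CLASSES = (1, 2, 3, 4, 5)
#: groups whose members are "free-living" for maturity / structure purposes
FREE_LIVING_GROUPS = ("BF", "FF", "OP")

_FEEDING_LETTERS = {"BF": "Ba", "FF": "Fu", "PP": "Pp"}
#: OP genera are coded Om unless a per-genus override marks them carnivore Ca
OP_CODES = ("Om", "Ca")

_REQUIRED_COLUMNS = ("genus", "trophic_group", "cp_class", "fresh_weight")


class TraitTableError(ValueError):
    """A trait table failed parsing or violated a trait invariant."""


class UnknownGenusError(KeyError):
    """Lookup of a genus absent from the trait database.

    Deliberately a typed miss: callers convert it to "exclude and log",
    never to a silent zero.
    """


def normalize_genus(name: str) -> str:
    """Canonical lookup key for a genus name: trimmed and case-folded.

    No fuzzy matching — a silent mis-assignment is worse than a miss.
    """
    return str(name).strip().casefold()


@dataclass(frozen=True)
class TraitRecord:
    """Genus-level nematode traits.

    Parameters
    ----------
    genus
        Genus name as written in the source table (display form).
    trophic_group
        One of ``BF``, ``FF``, ``PP``, ``OP``.
    cp_class
        Colonizer-persister class, integer 1-5.
    fresh_weight
        Mean individual fresh body mass, micrograms; strictly positive.
    op_code
        Feeding-letter override for OP genera: ``Om`` (default) or ``Ca``
        for carnivores. Ignored for the other trophic groups.
    """

    genus: str
    trophic_group: str
    cp_class: int
    fresh_weight: float
    op_code: str = "Om"

    def __post_init__(self) -> None:
        if self.trophic_group not in TROPHIC_GROUPS:
            raise TraitTableError(
                f"{self.genus!r}: trophic_group must be one of {TROPHIC_GROUPS}, "
                f"got {self.trophic_group!r}"
            )
        if self.cp_class not in CP_CLASSES:
            raise TraitTableError(
                f"{self.genus!r}: cp_class must be an integer in 1-5, got {self.cp_class!r}"
            )
        if not self.fresh_weight > 0:
            raise TraitTableError(
                f"{self.genus!r}: fresh_weight must be > 0 µg, got {self.fresh_weight!r}"
            )
        if self.op_code not in OP_CODES:
            raise TraitTableError(
                f"{self.genus!r}: op_code must be one of {OP_CODES}, got {self.op_code!r}"
            )

    @property
    def is_free_living(self) -> bool:
        return self.trophic_group in FREE_LIVING_GROUPS


def guild_of(record: TraitRecord) -> str:
    """Guild code of a trait record: feeding letters + c-p digit.

    BF→Ba, FF→Fu, PP→Pp; OP→Om by default, Ca when the record carries the
    carnivore override. E.g. ``(BF, cp1) → "Ba1"``.
    """
    letters = _FEEDING_LETTERS.get(record.trophic_group, record.op_code)
    return f"{letters}{record.cp_class}"


def all_guild_codes() -> list[str]:
    """Enumerate the 20 guild codes of the 4 trophic groups × 5 c-p classes
    (OP under its default Om coding)."""
    codes = []
    for group in TROPHIC_GROUPS:
        letters = _FEEDING_LETTERS.get(group, "Om")
        codes.extend(f"{letters}{cp}" for cp in CP_CLASSES)
    return codes


class TraitDatabase(Mapping):
    """Lookup of :class:`TraitRecord` keyed by normalized genus name.

    Iteration order follows insertion order of the source table. Genus
    names must be unique after normalization.
    """

    def __init__(self, records: Iterable[TraitRecord]):
        self._records: dict[str, TraitRecord] = {}
        for rec in records:
            key = normalize_genus(rec.genus)
            if key in self._records:
                raise TraitTableError(f"duplicate genus {rec.genus!r} in trait table")
            self._records[key] = rec

    def lookup(self, genus: str) -> TraitRecord:
        """Exact case-insensitive lookup; raises :class:`UnknownGenusError`."""
        key = normalize_genus(genus)
        try:
            return self._records[key]
        except KeyError:
            raise UnknownGenusError(genus) from None

    def __getitem__(self, genus: str) -> TraitRecord:
        return self.lookup(genus)

    def __contains__(self, genus: object) -> bool:
        return normalize_genus(str(genus)) in self._records

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> list[TraitRecord]:
        return list(self._records.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genus": r.genus,
                "trophic_group": r.trophic_group,
                "cp_class": r.cp_class,
                "fresh_weight": r.fresh_weight,
                "op_code": r.op_code if r.trophic_group == "OP" else "",
            }
            for r in self.records()
        ]
        return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + ["op_code"])

    def write_tsv(self, path: str | Path) -> None:
        """Serialize in the canonical dialect read by :func:`load_trait_table`."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_trait_table(source) -> TraitDatabase:
    """Read a trait table into a :class:`TraitDatabase`.

    The table is tab-separated UTF-8 with header columns ``genus``,
    ``trophic_group``, ``cp_class``, ``fresh_weight`` and an optional
    ``op_code`` column (``Om``/``Ca`` for OP genera). ``#`` lines are
    comments.

    Raises
    ------
    TraitTableError
        On malformed rows (named by data-row number), invariant violations
        (e.g. cp_class outside 1-5) or duplicate genera.
    """
    try:
        frame = pd.read_csv(source, sep="\t", comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise TraitTableError(f"malformed trait table: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TraitTableError(f"trait table missing required columns: {missing}")

    records = []
    for ordinal, (_, row) in enumerate(frame.iterrows(), start=1):
        genus = row["genus"]
        if not isinstance(genus, str) or not genus.strip():
            raise TraitTableError(f"data row {ordinal}: empty genus name")
        try:
            cp = _parse_int(row["cp_class"])
            weight = float(row["fresh_weight"])
        except (TypeError, ValueError) as exc:
            raise TraitTableError(f"data row {ordinal} ({genus!r}): {exc}") from exc
        op_code = row.get("op_code", "")
        if not isinstance(op_code, str) or not op_code.strip():
            op_code = "Om"
        try:
            records.append(
                TraitRecord(
                    genus=genus.strip(),
                    trophic_group=str(row["trophic_group"]).strip(),
                    cp_class=cp,
                    fresh_weight=weight,
                    op_code=op_code.strip(),
                )
            )
        except TraitTableError as exc:
            raise TraitTableError(f"data row {ordinal}: {exc}") from exc
    return TraitDatabase(records)


def _parse_int(value) -> int:
    as_float = float(value)
    if as_float != int(as_float):
        raise ValueError(f"cp_class must be an integer, got {value!r}")
    return int(as_float)


def packaged_traits() -> TraitDatabase:
    """The packaged genus-level trait reference (30 common soil genera)."""
    ref = resources.files("microfoodweb") / "data" / "nematode_traits.tsv"
    with resources.as_file(ref) as path:
        return load_trait_table(path)
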