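"""Core domain records: barcodes, reference sequences, the reference library.

Taxonomy is exactly three ranks (family, genus, species). A species field may
be a genus-level placeholder such as ``"Rhinogobius spp"`` — common in egg
surveys where congeners cannot be separated by the barcode alone.
"""
from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field

from .errors import InputError

#: Default sampling season. River surveys of drifting eggs target the
#: reproductive season; columns are configurable but this is the default.
MONTHS = ("May", "June", "July", "August", "September")

_MONTH_NAMES = {
    m.lower(): m
    for m in (
        "January February March April May June July August September "
        "October November December".split()
    )
}
_MONTH_BY_NUMBER = {
    i + 1: m
    for i, m in enumerate(
        "January February March April May June July August September "
        "October November December".split()
    )
}

SPECIMEN_TYPES = ("egg", "larva")

_PLACEHOLDER_RE = re.compile(r"^(?P<genus>\S+)\s+spp?\d*$")


def normalize_month(value) -> str:
    """Map a month name, abbreviation, month number or ISO date to a
    canonical month name ("May", "June", ...).

    Raises :class:`InputError` if the value cannot be interpreted.
    """
    if isinstance(value, _dt.date):
        return _MONTH_BY_NUMBER[value.month]
    if isinstance(value, int):
        if value in _MONTH_BY_NUMBER:
            return _MONTH_BY_NUMBER[value]
        raise InputError(f"month number out of range: {value!r}")
    s = str(value).strip()
    if not s:
        raise InputError("empty month value")
    if re.fullmatch(r"\d{4}-\d{2}-\d{2}", s):
        try:
            return _MONTH_BY_NUMBER[_dt.date.fromisoformat(s).month]
        except ValueError as exc:
            raise InputError(f"unparseable date {s!r}: {exc}") from None
    if s.isdigit():
        return normalize_month(int(s))
    low = s.lower()
    if low in _MONTH_NAMES:
        return _MONTH_NAMES[low]
    # three-letter abbreviations
    for name in _MONTH_NAMES.values():
        if low == name[:3].lower():
            return name
    raise InputError(f"unparseable month or date: {value!r}")


@dataclass
class BarcodeRecord:
    """One query sequence (an egg or larva) with specimen metadata."""

    id: str
    sequence: str
    specimen_type: str = "egg"
    month: str | None = None
    time_slot: str | None = None

    def __post_init__(self):
        if not self.id:
            raise InputError("barcode record id must be nonempty")
        if not self.sequence:
            raise InputError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        if self.specimen_type not in SPECIMEN_TYPES:
            raise InputError(
                f"record {self.id!r}: specimen_type must be one of "
                f"{SPECIMEN_TYPES}, got {self.specimen_type!r}"
            )
        if self.month is not None:
            self.month = normalize_month(self.month)


@dataclass
class ReferenceRecord:
    """A reference barcode with three-rank taxonomy.

    ``species`` is a binomial, or a genus-level placeholder of the form
    ``"Genus spp"`` / ``"Genus spp1"``.
    """

    id: str
    sequence: str
    family: str
    genus: str
    species: str

    def __post_init__(self):
        if not self.id:
            raise InputError("reference record id must be nonempty")
        if not self.sequence:
            raise InputError(f"reference {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        for rank in ("family", "genus", "species"):
            if not getattr(self, rank):
                raise InputError(f"reference {self.id!r}: empty {rank}")
        m = _PLACEHOLDER_RE.match(self.species)
        parts = self.species.split()
        if m is None and len(parts) >= 2 and parts[0] != self.genus:
            raise InputError(
                f"reference {self.id!r}: species {self.species!r} does not "
                f"match genus {self.genus!r}"
            )

    @property
    def is_placeholder_species(self) -> bool:
        return _PLACEHOLDER_RE.match(self.species) is not None


class ReferenceLibrary:
    """An in-memory reference library with taxon lookups.

    Stands in for a curated public barcode database: every record carries a
    family/genus/species label and searches run exhaustively against all
    records (library sizes here are desk-scale).
    """

    def __init__(self, records: list[ReferenceRecord]):
        if not records:
            raise InputError("reference library must contain at least one record")
        seen: set[str] = set()
        for r in records:
            if r.id in seen:
                raise InputError(f"duplicate reference id {r.id!r}")
            seen.add(r.id)
        self.records: list[ReferenceRecord] = list(records)
        self._by_id = {r.id: r for r in self.records}
        self.index: dict[str, list[str]] = {}
        for r in self.records:
            for taxon in (r.family, r.genus, r.species):
                self.index.setdefault(taxon, []).append(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> ReferenceRecord:
        return self._by_id[record_id]

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.species not in out:
                out.append(r.species)
        return out

    @property
    def genera(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.genus not in out:
                out.append(r.genus)
        return out

    def ids_for(self, taxon: str) -> list[str]:
        return list(self.index.get(taxon, []))

    def without_species(self, species: str) -> "ReferenceLibrary":
        """A copy of the library with every record of ``species`` removed."""
        kept = [r for r in self.records if r.species != species]
        if not kept:
            raise InputError(
                f"removing species {species!r} would empty the library"
            )
        return ReferenceLibrary(kept)

    def taxonomy(self, record_id: str) -> tuple[str, str, str]:
        r = self._by_id[record_id]
        return (r.family, r.genus, r.species)
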