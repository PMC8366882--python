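"""Community and phenology summaries over dated assignments.

The phenology unit is the month: a taxon "occurs" in a month if at least one
assigned specimen was collected then. Species-level verdicts keep their
binomials; genus-level verdicts become "Genus spp" rows (numbered spp1, spp2
when lineage clustering separates them); unidentified specimens become
"Unknown species k" rows, one per lineage cluster.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import AssignmentResult
from .errors import ConsistencyError, InputError
from .phylogeny import LineagePartition
from .records import MONTHS, ReferenceLibrary, normalize_month


@dataclass
class OccurrenceMatrix:
    """Taxa x months occurrence with per-cell supporting specimen counts."""

    counts: pd.DataFrame  # int counts, index = taxon labels, columns = months
    families: dict[str, str] = field(default_factory=dict)
    levels: dict[str, str] = field(default_factory=dict)  # species|genus|unknown

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise InputError("occurrence counts must be nonnegative")

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def months(self) -> list[str]:
        return list(self.counts.columns)

    def species_level_taxa(self) -> list[str]:
        return [t for t in self.taxa if self.levels.get(t) == "species"]


@dataclass
class SpawningPeriod:
    taxon: str
    months_present: list[str]
    n_months: int
    first: str
    last: str
    continuous: bool


@dataclass
class SurveyCounts:
    """Specimen accounting for a survey (the denominators of the pipeline)."""

    n_selected_eggs: int
    n_hq_eggs: int
    n_hq_larvae: int = 0
    n_species_assigned_eggs: int | None = None

    def __post_init__(self):
        if self.n_selected_eggs <= 0:
            raise ConsistencyError("n_selected_eggs must be positive")
        if self.n_hq_eggs > self.n_selected_eggs:
            raise ConsistencyError(
                "more high-quality eggs than selected eggs "
                f"({self.n_hq_eggs} > {self.n_selected_eggs})"
            )


@dataclass
class CompositionSummary:
    n_selected_eggs: int
    n_hq_eggs: int
    n_hq_larvae: int
    n_failed: int
    failure_rate: float
    n_aligned: int
    n_species_level_taxa: int
    per_family_species_counts: dict[str, int]
    family_proportions: dict[str, float]
    egg_species_assignment_rate: float | None = None


def _metadata_lookup(metadata) -> dict[str, dict]:
    """Normalize metadata (DataFrame indexed by id, or mapping) to
    id -> {specimen_type, month}."""
    if isinstance(metadata, pd.DataFrame):
        out = {}
        for sid, row in metadata.iterrows():
            month = row.get("month")
            out[str(sid)] = {
                "specimen_type": row.get("specimen_type", "egg"),
                "month": normalize_month(month) if pd.notna(month) else None,
            }
        return out
    out = {}
    for sid, entry in metadata.items():
        if isinstance(entry, dict):
            month = entry.get("month")
            out[str(sid)] = {
                "specimen_type": entry.get("specimen_type", "egg"),
                "month": normalize_month(month) if month else None,
            }
        else:  # (specimen_type, month) tuple
            stype, month = entry
            out[str(sid)] = {
                "specimen_type": stype,
                "month": normalize_month(month) if month else None,
            }
    return out


def occurrence_matrix(
    results: list[AssignmentResult],
    metadata,
    months: tuple[str, ...] = MONTHS,
    lineages: LineagePartition | None = None,
    library: ReferenceLibrary | None = None,
    eggs_only: bool = False,
) -> OccurrenceMatrix:
    """Build the taxa-by-month occurrence matrix from assignment verdicts.

    Specimens without a month in the metadata are dropped with a warning.
    When a lineage partition over the query ids is supplied, genus-level
    verdicts of one genus are split into numbered "Genus spp1/spp2" rows when
    their members fall in different lineages, and unidentified specimens
    become one "Unknown species k" row per lineage.
    """
    meta = _metadata_lookup(metadata)
    months = tuple(months)

    def family_of(taxon: str, level: str) -> str:
        if library is None:
            return ""
        for r in library:
            if level == "species" and r.species == taxon:
                return r.family
            if level == "genus" and r.genus == taxon:
                return r.family
        return ""

    usable: list[tuple[AssignmentResult, str]] = []  # (result, month)
    for res in results:
        m = meta.get(res.query_id)
        if m is None or m["month"] is None:
            warnings.warn(
                f"specimen {res.query_id!r} has no month in metadata; dropped",
                stacklevel=2,
            )
            continue
        if eggs_only and m["specimen_type"] != "egg":
            continue
        if m["month"] not in months:
            warnings.warn(
                f"specimen {res.query_id!r} collected in {m['month']}, outside "
                f"the configured months {months}; dropped",
                stacklevel=2,
            )
            continue
        usable.append((res, m["month"]))

    def lineage_of(qid: str) -> int | None:
        if lineages is None or qid not in lineages.labels:
            return None
        return lineages.cluster_of(qid)

    # taxon label per result, in input order
    labels: list[str] = []
    levels: dict[str, str] = {}
    families: dict[str, str] = {}

    # genus-level: decide pooled vs split per genus
    genus_clusters: dict[str, list[int]] = {}
    for res, _ in usable:
        if res.level == "genus":
            c = lineage_of(res.query_id)
            if c is not None:
                genus_clusters.setdefault(res.taxon, [])
                if c not in genus_clusters[res.taxon]:
                    genus_clusters[res.taxon].append(c)
    unknown_clusters: list[int] = []

    for res, _ in usable:
        if res.level == "species":
            label = res.taxon
            levels[label] = "species"
        elif res.level == "genus":
            clusters = genus_clusters.get(res.taxon, [])
            if len(clusters) > 1:
                c = lineage_of(res.query_id)
                label = f"{res.taxon} spp{clusters.index(c) + 1}"
            else:
                label = f"{res.taxon} spp"
            levels[label] = "genus"
        else:
            c = lineage_of(res.query_id)
            if c is None:
                label = "Unknown species 1"
            else:
                if c not in unknown_clusters:
                    unknown_clusters.append(c)
                label = f"Unknown species {unknown_clusters.index(c) + 1}"
            levels[label] = "unknown"
        if label not in families:
            families[label] = family_of(res.taxon, res.level) if res.level != "unidentified" else ""
        labels.append(label)

    taxa: list[str] = []
    for label in labels:
        if label not in taxa:
            taxa.append(label)
    counts = pd.DataFrame(0, index=taxa, columns=list(months), dtype=int)
    for (res, month), label in zip(usable, labels):
        counts.loc[label, month] += 1
    return OccurrenceMatrix(counts=counts, families=families, levels=levels)


def monthly_richness(m: OccurrenceMatrix) -> pd.Series:
    """Taxon count per month. All rows count — species-level, genus-level
    ("spp") lineages and unknown lineages alike."""
    return m.presence.sum(axis=0).astype(int)


def spawning_periods(m: OccurrenceMatrix) -> list[SpawningPeriod]:
    """Per-taxon occupied months, span, and whether the span is gap-free."""
    months = m.months
    out = []
    for taxon in m.taxa:
        row = m.presence.loc[taxon]
        present = [mo for mo in months if row[mo]]
        if not present:
            continue
        i0, i1 = months.index(present[0]), months.index(present[-1])
        out.append(
            SpawningPeriod(
                taxon=taxon,
                months_present=present,
                n_months=len(present),
                first=present[0],
                last=present[-1],
                continuous=(i1 - i0 + 1) == len(present),
            )
        )
    return out


def composition_summary(
    counts: SurveyCounts,
    occurrence: OccurrenceMatrix | None = None,
    results: list[AssignmentResult] | None = None,
    metadata=None,
) -> CompositionSummary:
    """Success/failure accounting plus family composition.

    Family proportions run over species-level taxa only (genus-level and
    unknown rows are excluded). The egg species-assignment rate is taken from
    ``counts`` when given, else computed from ``results`` + ``metadata``.
    """
    n_failed = counts.n_selected_eggs - counts.n_hq_eggs
    failure_rate = n_failed / counts.n_selected_eggs
    n_aligned = counts.n_hq_eggs + counts.n_hq_larvae

    per_family: dict[str, int] = {}
    n_species_level = 0
    if occurrence is not None:
        for taxon in occurrence.species_level_taxa():
            n_species_level += 1
            fam = occurrence.families.get(taxon, "")
            per_family[fam] = per_family.get(fam, 0) + 1
    total = sum(per_family.values())
    proportions = {f: c / total for f, c in per_family.items()} if total else {}

    rate = None
    if counts.n_species_assigned_eggs is not None:
        rate = counts.n_species_assigned_eggs / counts.n_hq_eggs
    elif results is not None and metadata is not None:
        meta = _metadata_lookup(metadata)
        egg_results = [
            r for r in results
            if meta.get(r.query_id, {}).get("specimen_type") == "egg"
        ]
        if egg_results:
            rate = sum(r.level == "species" for r in egg_results) / len(egg_results)

    return CompositionSummary(
        n_selected_eggs=counts.n_selected_eggs,
        n_hq_eggs=counts.n_hq_eggs,
        n_hq_larvae=counts.n_hq_larvae,
        n_failed=n_failed,
        failure_rate=failure_rate,
        n_aligned=n_aligned,
        n_species_level_taxa=n_species_level,
        per_family_species_counts=per_family,
        family_proportions=proportions,
        egg_species_assignment_rate=rate,
    )
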