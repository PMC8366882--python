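"""Hierarchical taxonomic assignment of barcode queries.

The cascade mirrors how practitioners combine a curated barcode database
with a general sequence archive:

Primary rules (curated-database semantics, per-species best/second-best):
  P1  best species identity > 99% and second-best species < 99% (or no
      second species)            -> species of the best hit
  P1g best > 99% and second-best > 99%, both top species in one genus
                                  -> that genus
  P2  the top 100 hits all belong to one species, and best > 99%
                                  -> that species

Fallback rules (archive-BLAST semantics, per-record top hits):
  F1  the top 5 hits are one species and best identity > 99%  -> species
  F2  best identity > 95%  -> genus (majority genus of the top 5;
      a tie leaves the query unidentified)
  F3  otherwise            -> unidentified

All thresholds are strict inequalities; an identity exactly at a threshold
falls through to the next rule. An :class:`ExclusionOverride` removes
ecologically implausible species (e.g. taxa absent from recent field
surveys) and re-runs the cascade once.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .config import RunConfig
from .errors import InputError
from .pairwise import HitList, search_library
from .records import BarcodeRecord, ReferenceLibrary

LEVELS = ("species", "genus", "unidentified")

RULE_IDS = (
    "P1_best_second",
    "P1_genus",
    "P2_top100",
    "F1_top5_species",
    "F2_genus_floor",
    "F3_below_floor",
    "X_excluded_override",
)


@dataclass
class AssignmentResult:
    """The cascade's verdict for one query, with its audit trail."""

    query_id: str
    level: str
    taxon: str
    rule_id: str
    best_identity: float
    second_best_identity: float | None
    n_consensus_hits: int
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.level not in LEVELS:
            raise InputError(f"unknown level {self.level!r}")
        if self.rule_id not in RULE_IDS:
            raise InputError(f"unknown rule id {self.rule_id!r}")
        if self.level == "unidentified" and self.taxon:
            raise InputError("unidentified results carry an empty taxon")
        if self.level != "unidentified" and not self.taxon:
            raise InputError(f"{self.level}-level result needs a taxon")


@dataclass
class ExclusionOverride:
    """Species to exclude on external (ecological) grounds, with the
    justification recorded alongside the verdicts."""

    excluded_species: list[str] = field(default_factory=list)
    justification: str = ""

    def validate_against(self, library: ReferenceLibrary) -> None:
        known = set(library.species)
        missing = [s for s in self.excluded_species if s not in known]
        if missing:
            raise InputError(
                f"excluded species not present in library taxonomy: {missing}"
            )


def assign_primary(hits: HitList, cfg: RunConfig) -> AssignmentResult | None:
    """Primary (curated-database) rules; ``None`` means unresolved."""
    if not hits.hits:
        raise InputError("empty hit list")
    thr = cfg.species_identity_threshold
    best = hits.best_species_identity
    second = hits.second_best_species_identity
    top = hits.hits[0]
    common = dict(
        query_id=hits.query_id,
        best_identity=best,
        second_best_identity=second,
    )
    if best > thr and (second is None or second < thr):
        return AssignmentResult(
            level="species", taxon=top.species, rule_id="P1_best_second",
            n_consensus_hits=1, **common,
        )
    if best > thr and second is not None and second > thr:
        second_hit = next(
            h for h in hits.hits if h.species != top.species
        ) if any(h.species != top.species for h in hits.hits) else None
        if second_hit is not None and second_hit.genus == top.genus:
            return AssignmentResult(
                level="genus", taxon=top.genus, rule_id="P1_genus",
                n_consensus_hits=2, **common,
            )
    window = hits.hits[: min(cfg.top_n_primary, len(hits.hits))]
    species_set = {h.species for h in window}
    if len(species_set) == 1 and best > thr:
        return AssignmentResult(
            level="species", taxon=top.species, rule_id="P2_top100",
            n_consensus_hits=len(window), **common,
        )
    return None


def assign_fallback(hits: HitList, cfg: RunConfig) -> AssignmentResult:
    """Fallback (archive-search) rules; always produces a verdict."""
    if not hits.hits:
        raise InputError("empty hit list")
    thr = cfg.species_identity_threshold
    floor = cfg.genus_identity_floor
    top5 = hits.hits[: min(cfg.top_n_fallback, len(hits.hits))]
    best = hits.hits[0].identity
    common = dict(
        query_id=hits.query_id,
        best_identity=best,
        second_best_identity=hits.second_best_species_identity,
    )
    species_set = {h.species for h in top5}
    if len(species_set) == 1 and best > thr:
        return AssignmentResult(
            level="species", taxon=top5[0].species, rule_id="F1_top5_species",
            n_consensus_hits=len(top5), **common,
        )
    if best > floor:
        counts = Counter(h.genus for h in top5)
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            # genus tie among the top hits: refuse to guess
            return AssignmentResult(
                level="unidentified", taxon="", rule_id="F2_genus_floor",
                n_consensus_hits=0, evidence={"genus_tie": dict(counts)},
                **common,
            )
        return AssignmentResult(
            level="genus", taxon=ranked[0][0], rule_id="F2_genus_floor",
            n_consensus_hits=ranked[0][1], **common,
        )
    return AssignmentResult(
        level="unidentified", taxon="", rule_id="F3_below_floor",
        n_consensus_hits=0, **common,
    )


def _cascade(hits: HitList, cfg: RunConfig) -> AssignmentResult:
    res = assign_primary(hits, cfg)
    return res if res is not None else assign_fallback(hits, cfg)


def assign(
    query: BarcodeRecord,
    library: ReferenceLibrary,
    cfg: RunConfig | None = None,
    override: ExclusionOverride | None = None,
) -> AssignmentResult:
    """Search the library and run the full cascade for one query.

    The exclusion override re-runs the cascade once with the excluded
    species' records removed when an excluded species decided or blocked the
    verdict: either the winning species itself is excluded, or the verdict
    fell short of species level while an excluded species sits among the
    hits above the genus identity floor (the equidistant-congener case).
    The final verdict is then tagged ``X_excluded_override`` with the re-run
    rule kept in the evidence dict.
    """
    cfg = cfg or RunConfig()
    scoring = dict(match=cfg.match_score, mismatch=cfg.mismatch_score,
                   gap_open=cfg.gap_open, gap_extend=cfg.gap_extend)
    excluded = list(cfg.exclusion_taxa)
    if override is not None:
        override.validate_against(library)
        excluded += list(override.excluded_species)
    hits = search_library(query, library, top_n=cfg.top_n_primary, **scoring)
    res = _cascade(hits, cfg)
    won_excluded = res.level == "species" and res.taxon in excluded
    blocked_by_excluded = (
        excluded
        and res.level != "species"
        and any(
            h.species in excluded and h.identity > cfg.genus_identity_floor
            for h in hits.hits
        )
    )
    if won_excluded or blocked_by_excluded:
        reduced = library
        involved = {h.species for h in hits.hits if h.species in excluded}
        for sp in sorted(involved):
            reduced = reduced.without_species(sp)
        hits2 = search_library(query, reduced, top_n=cfg.top_n_primary, **scoring)
        res2 = _cascade(hits2, cfg)
        evidence = dict(res2.evidence)
        evidence.update(
            excluded_species=sorted(involved),
            post_override_rule=res2.rule_id,
        )
        if override is not None and override.justification:
            evidence["justification"] = override.justification
        return AssignmentResult(
            query_id=res2.query_id, level=res2.level, taxon=res2.taxon,
            rule_id="X_excluded_override",
            best_identity=res2.best_identity,
            second_best_identity=res2.second_best_identity,
            n_consensus_hits=res2.n_consensus_hits,
            evidence=evidence,
        )
    return res


def assign_batch(
    queries: list[BarcodeRecord],
    library: ReferenceLibrary,
    cfg: RunConfig | None = None,
    override: ExclusionOverride | None = None,
) -> tuple[list[AssignmentResult], dict]:
    """Assign every query (input order preserved) and tally the verdicts.

    Returns ``(results, summary)``; the summary counts levels overall and per
    specimen type.
    """
    cfg = cfg or RunConfig()
    results = [assign(q, library, cfg, override) for q in queries]
    summary: dict = {
        "n_queries": len(results),
        "n_species_level": sum(r.level == "species" for r in results),
        "n_genus_level": sum(r.level == "genus" for r in results),
        "n_unidentified": sum(r.level == "unidentified" for r in results),
        "by_specimen_type": {},
    }
    for stype in ("egg", "larva"):
        sub = [r for q, r in zip(queries, results) if q.specimen_type == stype]
        summary["by_specimen_type"][stype] = {
            "n": len(sub),
            "species": sum(r.level == "species" for r in sub),
            "genus": sum(r.level == "genus" for r in sub),
            "unidentified": sum(r.level == "unidentified" for r in sub),
        }
    return results, summary


class BarcodeClassifier(ClassifierMixin, BaseEstimator):
    """Identity-threshold barcode classifier with hierarchical fallback.

    A scikit-learn style wrapper around the assignment cascade: ``fit`` takes
    reference sequences with (family, genus, species) labels and builds the
    searchable library; ``predict`` returns one taxon label per query —
    a binomial for species-level calls, a genus name for genus-level calls,
    and ``"unidentified"`` otherwise. ``predict_result`` exposes the full
    audit trail.

    Parameters mirror the run configuration: identity thresholds are
    fractions, strict inequalities apply at both thresholds.
    """

    def __init__(
        self,
        species_identity_threshold: float = 0.99,
        genus_identity_floor: float = 0.95,
        top_n_primary: int = 100,
        top_n_fallback: int = 5,
        exclusion_taxa: tuple[str, ...] = (),
        match_score: float = 1.0,
        mismatch_score: float = -1.0,
        gap_open: float = -5.0,
        gap_extend: float = -2.0,
    ):
        self.species_identity_threshold = species_identity_threshold
        self.genus_identity_floor = genus_identity_floor
        self.top_n_primary = top_n_primary
        self.top_n_fallback = top_n_fallback
        self.exclusion_taxa = exclusion_taxa
        self.match_score = match_score
        self.mismatch_score = mismatch_score
        self.gap_open = gap_open
        self.gap_extend = gap_extend

    def _config(self) -> RunConfig:
        return RunConfig(
            species_identity_threshold=self.species_identity_threshold,
            genus_identity_floor=self.genus_identity_floor,
            top_n_primary=self.top_n_primary,
            top_n_fallback=self.top_n_fallback,
            exclusion_taxa=list(self.exclusion_taxa),
            match_score=self.match_score,
            mismatch_score=self.mismatch_score,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    def fit(self, X, y=None):
        """Build the reference library.

        ``X`` may be a :class:`ReferenceLibrary` (then ``y`` is ignored) or a
        sequence of reference sequences with ``y`` an array-like of
        (family, genus, species) rows.
        """
        from .records import ReferenceRecord

        if isinstance(X, ReferenceLibrary):
            self.library_ = X
        else:
            if y is None:
                raise InputError(
                    "y (family, genus, species rows) is required unless X is "
                    "a ReferenceLibrary"
                )
            y = np.asarray(y, dtype=object)
            if y.ndim != 2 or y.shape[1] != 3 or y.shape[0] != len(X):
                raise InputError(
                    "y must be an (n_references, 3) array of "
                    "(family, genus, species)"
                )
            records = [
                ReferenceRecord(
                    id=f"ref{i}", sequence=seq,
                    family=str(fam), genus=str(gen), species=str(sp),
                )
                for i, (seq, (fam, gen, sp)) in enumerate(zip(X, y))
            ]
            self.library_ = ReferenceLibrary(records)
        self.classes_ = np.array(
            self.library_.species + self.library_.genera + ["unidentified"],
            dtype=object,
        )
        self.n_features_in_ = 1
        return self

    def _check_fitted(self):
        if not hasattr(self, "library_"):
            raise InputError("BarcodeClassifier is not fitted yet; call fit first")

    def predict_result(self, X) -> list[AssignmentResult]:
        """Full cascade verdicts (one :class:`AssignmentResult` per query)."""
        self._check_fitted()
        cfg = self._config()
        queries = [
            q if isinstance(q, BarcodeRecord) else BarcodeRecord(id=f"q{i}", sequence=q)
            for i, q in enumerate(X)
        ]
        results, _ = assign_batch(queries, self.library_, cfg)
        return results

    def predict(self, X) -> np.ndarray:
        """Taxon label per query (binomial, genus, or "unidentified")."""
        results = self.predict_result(X)
        return np.array(
            [r.taxon if r.level != "unidentified" else "unidentified"
             for r in results],
            dtype=object,
        )

    def score(self, X, y):
        """Species-level accuracy against true binomials ``y``."""
        pred = self.predict(X)
        y = np.asarray(y, dtype=object)
        return float(np.mean(pred == y))
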