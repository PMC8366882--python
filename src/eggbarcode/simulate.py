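"""Synthetic reference libraries and egg surveys.

The generator inverts the analysis model: barcodes evolve under the Kimura
two-parameter substitution process (transition/transversion ratio kappa), a
barcoding gap separates within-species from between-species divergence,
species spawn in species-specific monthly windows, and a specimen-level
Bernoulli dropout emulates failed DNA extraction/amplification of
poorly preserved eggs.

Defaults describe a realistic riverine ichthyoplankton survey: 569-bp
barcodes, ~0.3% within-species and >=3% between-species divergence, a
May-September season, and a 38% dropout rate.

:func:`table1_fixture` packages a fixed in-study occurrence table (19 taxa
over five months) and its specimen accounting, used as a known-answer input
for the phenology summaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .phenology import OccurrenceMatrix, SurveyCounts
from .records import (
    MONTHS,
    BarcodeRecord,
    ReferenceLibrary,
    ReferenceRecord,
)


@dataclass
class SimulationParams:
    n_families: int = 4
    n_species: int = 10
    individuals_per_species: int = 3
    barcode_length: int = 569
    kappa: float = 4.0
    intraspecific_divergence: float = 0.003
    interspecific_divergence: float = 0.03
    spawning_windows: dict[str, list[str]] | None = None
    #: expected egg count per active species per month
    monthly_sampling: dict[str, float] | None = None
    dropout_rate: float = 0.38
    unknown_species_fraction: float = 0.0
    months: tuple[str, ...] = MONTHS
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.intraspecific_divergence < self.interspecific_divergence):
            raise InputError(
                "barcoding gap violated: need intraspecific_divergence < "
                "interspecific_divergence"
            )
        for frac in (self.dropout_rate, self.unknown_species_fraction):
            if not (0.0 <= frac <= 1.0):
                raise InputError("fractions must be in [0, 1]")
        if self.n_species < 1 or self.individuals_per_species < 1:
            raise InputError("need at least one species and one individual")
        if self.barcode_length < 1:
            raise InputError("barcode_length must be >= 1")
        self.months = tuple(self.months)
        if self.spawning_windows is not None:
            for sp, window in self.spawning_windows.items():
                bad = set(window) - set(self.months)
                if bad:
                    raise InputError(
                        f"spawning window of {sp!r} includes months outside "
                        f"the configured season: {sorted(bad)}"
                    )


# --- K2P sequence evolution -------------------------------------------------

_BASES = np.array(list("ACGT"))


def _k2p_site_probs(distance: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) after expected
    ``distance`` substitutions/site at transition/transversion ratio kappa."""
    b = distance / (kappa + 2.0)  # beta * t
    a = kappa * b                 # alpha * t
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * b) - 0.5 * np.exp(-2.0 * (a + b))
    p_tv_each = 0.25 - 0.25 * np.exp(-4.0 * b)
    return float(p_ts), float(p_tv_each)


def evolve_sequence(
    ancestor: str,
    distance: float,
    kappa: float = 4.0,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Evolve a sequence under the K2P process to an expected divergence.

    The realized K2P distance between ancestor and descendant estimates
    ``distance``. A warning is raised when the requested distance approaches
    saturation (site substitution probability > 0.7).
    """
    if distance < 0:
        raise InputError("distance must be >= 0")
    if distance == 0:
        return ancestor
    rng = np.random.default_rng(rng)
    p_ts, p_tv = _k2p_site_probs(distance, kappa)
    if p_ts + 2 * p_tv > 0.7:
        warnings.warn(
            f"distance {distance} is near saturation for kappa={kappa}",
            stacklevel=2,
        )
    codes = np.frombuffer(ancestor.encode("ascii"), np.uint8)
    enc = np.full(codes.shape, 255, np.uint8)
    for i, c in enumerate("ACGT"):
        enc[codes == ord(c)] = i
    if (enc == 255).any():
        raise InputError("ancestor must contain only A/C/G/T")
    u = rng.random(enc.shape[0])
    out = enc.copy()
    # transitions flip bit 1 (A<->G, C<->T); transversions flip parity
    out[u < p_ts] ^= 2
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[tv1] ^= 1
    out[tv2] ^= 3
    return "".join(_BASES[out])


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# --- reference library ------------------------------------------------------

@dataclass
class ReferenceTruth:
    """Ground truth behind a simulated library."""

    root: str
    species_sequences: dict[str, str]
    taxonomy: dict[str, tuple[str, str, str]]  # species -> (family, genus, species)


def _species_names(params: SimulationParams) -> list[tuple[str, str, str]]:
    """(family, genus, species) triples: two species per genus, genera dealt
    round-robin across families."""
    out = []
    for i in range(params.n_species):
        g = i // 2 + 1
        fam = (g - 1) % params.n_families + 1
        name = f"Genus{g} sp{i + 1}"
        out.append((f"Family{fam}", f"Genus{g}", name))
    return out


def simulate_reference(
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[ReferenceLibrary, ReferenceTruth]:
    """Simulate a reference library honouring the barcoding gap.

    Species sequences radiate from a common ancestor at the interspecific
    divergence; realized pairwise K2P distances below the configured minimum
    trigger re-draws (bounded retries). Individuals scatter around their
    species sequence at half the intraspecific divergence, so conspecific
    pairs sit near the configured within-species divergence.
    """
    from .phylogeny import k2p_matrix  # local import to avoid cycle

    rng = np.random.default_rng(params.seed if rng is None else rng)
    root = random_sequence(params.barcode_length, rng)
    names = _species_names(params)
    species_seqs: list[str] = []
    for _ in names:
        species_seqs.append(
            evolve_sequence(root, params.interspecific_divergence, params.kappa, rng)
        )
    # rejection: enforce min pairwise interspecific K2P
    for _ in range(200):
        dm = k2p_matrix([(t[2], s) for t, s in zip(names, species_seqs)])
        d = dm.data + np.eye(len(species_seqs)) * 1e9
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= params.interspecific_divergence:
            break
        species_seqs[int(j)] = evolve_sequence(
            root, params.interspecific_divergence, params.kappa, rng
        )
    else:
        raise InputError(
            "could not satisfy the interspecific divergence floor; "
            "lower interspecific_divergence or barcode_length constraints"
        )
    records = []
    truth_species = {}
    taxonomy = {}
    for (fam, gen, sp), seq in zip(names, species_seqs):
        truth_species[sp] = seq
        taxonomy[sp] = (fam, gen, sp)
        for k in range(params.individuals_per_species):
            records.append(
                ReferenceRecord(
                    id=f"REF_{sp.replace(' ', '_')}_{k + 1}",
                    sequence=evolve_sequence(
                        seq, params.intraspecific_divergence / 2.0,
                        params.kappa, rng,
                    ),
                    family=fam,
                    genus=gen,
                    species=sp,
                )
            )
    return ReferenceLibrary(records), ReferenceTruth(
        root=root, species_sequences=truth_species, taxonomy=taxonomy
    )


# --- survey -----------------------------------------------------------------

@dataclass
class TruthRow:
    specimen_id: str
    true_species: str
    month: str
    dropped: bool
    in_library: bool


def default_spawning_windows(
    species: list[str],
    months: tuple[str, ...],
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Random contiguous windows of 2-4 months per species, emulating
    species-specific spawning seasons."""
    out = {}
    for sp in species:
        width = int(rng.integers(2, min(4, len(months)) + 1))
        start = int(rng.integers(0, len(months) - width + 1))
        out[sp] = list(months[start : start + width])
    return out


def simulate_survey(
    library: ReferenceLibrary,
    truth: ReferenceTruth,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[BarcodeRecord], pd.DataFrame, list[TruthRow]]:
    """Simulate a monthly egg survey against a simulated library.

    Per month, each species active that month contributes a Poisson number
    of eggs (mean = ``monthly_sampling[month]``). Each egg's barcode evolves
    from a random conspecific reference individual at half the intraspecific
    divergence. A fraction of eggs comes from off-library ("unknown") taxa
    generated well beyond the barcoding gap. Dropout removes a specimen's
    sequence but keeps its metadata row, mirroring failed PCR.

    Returns (usable queries, metadata for ALL specimens, truth table).
    """
    from .phylogeny import k2p_matrix

    rng = np.random.default_rng(params.seed + 1 if rng is None else rng)
    species = list(truth.species_sequences)
    windows = params.spawning_windows or default_spawning_windows(
        species, params.months, rng
    )
    sampling = params.monthly_sampling or {m: 12.0 for m in params.months}

    # off-library taxa, rejected until >= 5% divergent from every reference
    n_unknown_taxa = 2 if params.unknown_species_fraction > 0 else 0
    unknown_seqs: list[str] = []
    for u in range(n_unknown_taxa):
        for _ in range(100):
            cand = evolve_sequence(
                truth.root, max(3.0 * params.interspecific_divergence, 0.08),
                params.kappa, rng,
            )
            dm = k2p_matrix(
                [("cand", cand)] + [(r.id, r.sequence) for r in library]
            )
            if dm.data[0, 1:].min() >= 0.05:
                unknown_seqs.append(cand)
                break
        else:
            raise InputError("could not generate a sufficiently divergent unknown taxon")

    by_species: dict[str, list[str]] = {}
    for r in library:
        by_species.setdefault(r.species, []).append(r.sequence)

    queries: list[BarcodeRecord] = []
    meta_rows = []
    truth_rows: list[TruthRow] = []
    counter = 0
    for month in params.months:
        active = [sp for sp in species if month in windows.get(sp, [])]
        for sp in active:
            n_eggs = int(rng.poisson(sampling.get(month, 0.0)))
            for _ in range(n_eggs):
                counter += 1
                sid = f"EGG{counter:05d}"
                if unknown_seqs and rng.random() < params.unknown_species_fraction:
                    k = int(rng.integers(0, len(unknown_seqs)))
                    seq = evolve_sequence(
                        unknown_seqs[k], params.intraspecific_divergence / 2.0,
                        params.kappa, rng,
                    )
                    true_sp, in_lib = f"Unknown taxon {k + 1}", False
                else:
                    anc = by_species[sp][int(rng.integers(0, len(by_species[sp])))]
                    seq = evolve_sequence(
                        anc, params.intraspecific_divergence / 2.0,
                        params.kappa, rng,
                    )
                    true_sp, in_lib = sp, True
                dropped = bool(rng.random() < params.dropout_rate)
                meta_rows.append(
                    {"id": sid, "specimen_type": "egg", "month": month,
                     "time_slot": ""}
                )
                truth_rows.append(
                    TruthRow(sid, true_sp, month, dropped, in_lib)
                )
                if not dropped:
                    queries.append(
                        BarcodeRecord(id=sid, sequence=seq,
                                      specimen_type="egg", month=month)
                    )
    metadata = pd.DataFrame(meta_rows).set_index("id") if meta_rows else pd.DataFrame(
        columns=["specimen_type", "month", "time_slot"]
    )
    return queries, metadata, truth_rows


# --- in-study fixture -------------------------------------------------------

# (family, taxon, level, presence in May..September)
_TABLE1 = [
    ("Cyprinidae", "Pseudohemiculter dispar", "species", (1, 1, 1, 1, 0)),
    ("Cyprinidae", "Squaliobarbus curriculus", "species", (0, 1, 0, 1, 0)),
    ("Cyprinidae", "Ctenopharyngodon idella", "species", (0, 1, 0, 0, 0)),
    ("Cyprinidae", "Xenocypris spp", "genus", (0, 1, 0, 0, 0)),
    ("Cyprinidae", "Zacco platypus", "species", (0, 0, 0, 1, 0)),
    ("Cyprinidae", "Pseudolaubuca sinensis", "species", (1, 0, 0, 0, 0)),
    ("Cyprinidae", "Squalidus argentatus", "species", (1, 1, 1, 1, 0)),
    ("Cyprinidae", "Gobiobotia meridionalis", "species", (1, 1, 1, 1, 0)),
    ("Cyprinidae", "Onychostoma gerlachi", "species", (1, 1, 0, 1, 0)),
    ("Cyprinidae", "Garra orientalis", "species", (0, 1, 0, 0, 0)),
    ("Cyprinidae", "Sinogastromyzon wui", "species", (1, 0, 0, 0, 0)),
    ("Botiidae", "Sinibotia pulchra", "species", (0, 1, 0, 0, 0)),
    ("Botiidae", "Sinibotia robusta", "species", (0, 0, 1, 1, 1)),
    ("Mastacembelidae", "Mastacembelus armatus", "species", (1, 1, 1, 1, 0)),
    ("Serranidae", "Siniperca scherzeri", "species", (0, 0, 0, 1, 0)),
    ("Gobiidae", "Rhinogobius spp1", "genus", (0, 1, 1, 1, 0)),
    ("Gobiidae", "Rhinogobius spp2", "genus", (0, 0, 1, 0, 0)),
    ("", "Unknown species 1", "unknown", (0, 0, 1, 0, 0)),
    ("", "Unknown species 2", "unknown", (0, 0, 1, 0, 0)),
]


def table1_fixture() -> tuple[OccurrenceMatrix, SurveyCounts]:
    """The packaged in-study occurrence table and specimen accounting.

    19 taxon rows (14 species-level, 3 genus-level lineages, 2 unknown
    lineages) over May-September, plus the survey's counts: 641 eggs selected
    for molecular work, 397 eggs and 17 larvae yielding high-quality
    barcodes, and 392 eggs assigned to species level.
    """
    counts = pd.DataFrame(
        [list(row[3]) for row in _TABLE1],
        index=[row[1] for row in _TABLE1],
        columns=list(MONTHS),
        dtype=int,
    )
    matrix = OccurrenceMatrix(
        counts=counts,
        families={row[1]: row[0] for row in _TABLE1},
        levels={row[1]: row[2] for row in _TABLE1},
    )
    survey_counts = SurveyCounts(
        n_selected_eggs=641,
        n_hq_eggs=397,
        n_hq_larvae=17,
        n_species_assigned_eggs=392,
    )
    return matrix, survey_counts
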