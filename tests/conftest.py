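import pytest

from eggbarcode import (
    MONTHS,
    Hit,
    HitList,
    RunConfig,
    align_pair,
    assign_batch,
    simulate_reference,
    simulate_survey,
)
from eggbarcode.simulate import SimulationParams


@pytest.fixture(scope="session", autouse=True)
def warm_aligner():
    """Trigger numba JIT once so individual tests time only their own work."""
    align_pair("ACGTACGT", "ACGTCCGT")


@pytest.fixture
def cfg():
    return RunConfig()


def make_hits(rows, query_id="q", second_best=None):
    """Build a HitList from (identity, family, genus, species) rows (already
    sorted by identity descending). ``second_best`` overrides the second-best
    species identity, emulating a hit outside the retained list."""
    hits = [
        Hit(reference_id=f"r{k}", family=f, genus=g, species=s,
            identity=i, rank=k + 1)
        for k, (i, f, g, s) in enumerate(rows)
    ]
    best_species = hits[0].species
    best = hits[0].identity
    if second_best is None:
        second_best = next(
            (h.identity for h in hits if h.species != best_species), None
        )
    return HitList(
        query_id=query_id,
        hits=hits,
        best_species_identity=best,
        second_best_species_identity=second_best,
    )


@pytest.fixture(scope="session")
def small_survey():
    """A small seeded survey with a clean barcoding gap and no dropout,
    shared across tests: (params, library, truth, queries, metadata,
    truth_rows, results, summary)."""
    params = SimulationParams(
        n_species=6,
        individuals_per_species=2,
        monthly_sampling={m: 5.0 for m in MONTHS},
        dropout_rate=0.0,
        seed=11,
    )
    library, truth = simulate_reference(params)
    queries, metadata, truth_rows = simulate_survey(library, truth, params)
    results, summary = assign_batch(queries, library)
    return {
        "params": params,
        "library": library,
        "truth": truth,
        "queries": queries,
        "metadata": metadata,
        "truth_rows": truth_rows,
        "results": results,
        "summary": summary,
    }
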