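# eggbarcode

A COI DNA-barcoding pipeline for identifying drifting fish eggs and larvae
and summarizing when the identified species spawn.

Riverine ichthyoplankton surveys catch thousands of fish eggs that are
morphologically almost indistinguishable. Matching each egg's mitochondrial
COI barcode (~569–648 bp) against a curated reference library assigns it to
a species, and the collection months of the assigned eggs delimit each
species' spawning period. `eggbarcode` implements that workflow end to end
for desk-scale reference libraries: exhaustive identity search, a
hierarchical decision cascade, distance-based verification, and
month-resolved community summaries — plus a synthetic-survey generator for
validating the whole pipeline against known truth.

## What it computes

**Assignment cascade.** Each query is ranked against every reference by
percent identity (matching columns / compared columns, gaps and ambiguous
bases excluded) under semi-global alignment with free end gaps on the query.
Verdicts follow strict thresholds:

- species, when the best species exceeds 99% identity and the best *other*
  species stays below 99% (or when the top hits unanimously agree on one
  species above 99%);
- genus, when two congeners both exceed 99%, or when the best identity
  exceeds 95% without species-level support (majority genus of the top 5);
- unidentified below 95%.

A declarative exclusion list removes ecologically implausible species (e.g.
taxa absent from recent field surveys) and re-runs the cascade once.

**Verification.** Kimura two-parameter distances
`d = -½ ln[(1 − 2P − Q)·√(1 − 2Q)]` (P, Q = transition and transversion
proportions), Saitou–Nei neighbor joining with column-bootstrap supports,
and single-linkage clustering at 1% divergence to count independent
lineages — the reproducible counterpart of counting lineages on a tree
figure.

**Phenology.** A taxa × months occurrence matrix, per-month richness,
spawning-period spans (with gap detection), family composition, and
sequencing success/failure accounting.

**Simulation.** Barcodes evolve under the K2P substitution process
(transition/transversion ratio κ) with an enforced barcoding gap
(within-species divergence ≪ between-species), species-specific monthly
spawning windows, and specimen-level Bernoulli dropout emulating failed
amplification of poorly preserved eggs.

## Worked example

```python
from eggbarcode import (
    MONTHS, LineageClusterer, assign_batch, monthly_richness,
    occurrence_matrix, simulate_reference, simulate_survey,
)
from eggbarcode.simulate import SimulationParams

params = SimulationParams(
    n_species=6, individuals_per_species=2,
    monthly_sampling={m: 8.0 for m in MONTHS},
    dropout_rate=0.38, seed=42,
)
library, truth = simulate_reference(params)
queries, metadata, truth_rows = simulate_survey(library, truth, params)
print(f"{len(truth_rows)} eggs collected, {len(queries)} usable after dropout")

results, summary = assign_batch(queries, library)
print(f"species-level: {summary['n_species_level']}, "
      f"genus-level: {summary['n_genus_level']}, "
      f"unidentified: {summary['n_unidentified']}")

truth_map = {t.specimen_id: t.true_species for t in truth_rows}
acc = sum(r.taxon == truth_map[r.query_id] for r in results) / len(results)
print(f"accuracy vs simulation truth: {acc:.3f}")

clu = LineageClusterer(threshold=0.01).fit([q.sequence for q in queries])
print(f"independent lineages at 1% K2P: {clu.n_clusters_}")

matrix = occurrence_matrix(results, metadata)
print("monthly richness:", monthly_richness(matrix).to_dict())
```

Output:

```
172 eggs collected, 109 usable after dropout
species-level: 109, genus-level: 0, unidentified: 0
accuracy vs simulation truth: 1.000
independent lineages at 1% K2P: 6
monthly richness: {'May': 3, 'June': 5, 'July': 5, 'August': 4, 'September': 1}
```

All 109 surviving eggs are assigned to their true species (the simulated
library has a clean barcoding gap), lineage clustering independently finds
the six simulated species, and the monthly richness reflects each species'
spawning window. `BarcodeClassifier` and `LineageClusterer` follow
scikit-learn conventions (`fit`/`predict`, `get_params`, `clone`-safe), so
they compose with sklearn tooling; `assign_batch`, `cluster_lineages` and
friends are the equivalent functional surface.

## Command line

```bash
eggbarcode simulate  --outdir run --seed 1
eggbarcode assign    run/queries.fasta run/reference.fasta run/taxonomy.tsv \
                     --metadata run/metadata.tsv --outdir run
eggbarcode tree      run/queries.fasta --outdir run --bootstrap-reps 1000
eggbarcode phenology --assignments run/assignments.tsv \
                     --metadata run/metadata.tsv --outdir run
eggbarcode run-all   --outdir run --seed 1
```

Stages communicate only through plain files (FASTA/TSV/Newick/JSON). Exit
codes: 0 success, 2 input error, 3 internal invariant violation.

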