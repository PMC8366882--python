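# Methods

This note documents the models and procedures `eggbarcode` implements, the
parameters that matter, the numerical choices, and what the synthetic-data
validation does and does not demonstrate.

## Pairwise alignment and percent identity

Queries are aligned to references with an affine-gap Gotoh dynamic program
in semi-global mode: end gaps on the **query row** (reference overhang) are
free, internal gaps and query-consuming end gaps are charged. A gap run of
length L costs `gap_open + (L−1)·gap_extend`; defaults are match +1,
mismatch −1, open −5, extend −2. These defaults suit COI barcodes — length-
variable fragments of a single locus in which internal indels are rare but
must be representable. The kernel is numba-compiled; its scores are verified
in the test suite against exhaustive enumeration on short strings and
against an independently configured Biopython `PairwiseAligner` on random
pairs.

Among co-optimal alignments the traceback deterministically prefers
substitution columns over gaps and the smallest reference end coordinate.

**Percent identity** = matching columns / compared columns, where a compared
column has an unambiguous base (A/C/G/T) in both rows. Excluding gap and
IUPAC-ambiguous columns makes a "99% identity" criterion independent of
fragment length and of ambiguity calls, which is how barcode databases
report similarity. The flat mismatch score applied to ambiguity codes is a
simplification; those columns never enter identity or distance denominators.

One caveat: because end-gap freedom is attached to the query row only, the
alignment problem is not symmetric in its arguments, and for degenerate
repeat sequences (e.g. poly-A runs differing in length) identity can differ
slightly by direction. For substitution-only pairs — the generic barcode
case — identity is symmetric, and the tests assert exactly that.

Query orientation is resolved empirically: the query and its reverse
complement are both searched and the strand with the higher best-hit
identity wins (tie → forward). This reflects a fixed, primer-defined locus
where strand is the only unknown.

## The assignment cascade

Hit lists rank every reference by identity (ties broken by reference id).
Best and second-best identities follow the interspecific-match convention of
curated barcode databases: best identity of the top species versus best
identity of the best *other* species, computed over the full library before
any top-n truncation — per-record ranks would let a well-sampled species
flood the top ranks and make the second-best rule vacuous.

Rules fire in a fixed order; every threshold is a strict inequality, so an
identity exactly at a threshold falls through to the next rule:

1. **P1** best species > 99% and second-best species < 99% (or no second
   species) → species of the best hit.
2. **P1g** best and second-best both > 99% and their top hits congeneric →
   that genus.
3. **P2** the top 100 retained hits unanimous for one species *and* best
   identity > 99% → that species. The identity guard is a deliberate
   addition: an unguarded consensus rule would assign species at arbitrary
   divergence, contradicting the 95% floor that governs every other rule.
4. **F1** top 5 hits unanimous and best > 99% → species ("all five" is the
   strict reading; a majority variant would be laxer than any stated rule).
5. **F2** best > 95% → genus, chosen by majority among the top 5; a tie
   leaves the query unidentified rather than guessing.
6. **F3** otherwise unidentified.

**Exclusion override.** Rare species known to be absent from the study area
can be declared excluded. The cascade re-runs once without the excluded
species' records when such a species either won the verdict or *blocked* a
species-level call (it sits among the hits above the genus floor while the
verdict fell short of species level — the case of a query equidistant to
two congeners, one of them implausible). The re-run verdict carries rule id
`X_excluded_override` with the post-override rule in the evidence trail.

A note on threshold monotonicity: the best/second-best rule is two-sided,
so raising the species threshold can legitimately flip genus ↔ species
verdicts. What never happens — and what the tests assert — is an
unidentified verdict turning into a species verdict as the threshold rises,
with one documented exception: a 1–1 genus tie above the floor resolves to
unidentified by the tie rule, and raising the threshold past the second-best
identity can then re-enable the best/second-best species rule.

## Distances, trees, lineages

**K2P distance.** `d = −½ ln[(1 − 2P − Q)·√(1 − 2Q)]` with P and Q the
transition (A↔G, C↔T) and transversion proportions over compared sites.
Sites with a gap or ambiguity in either sequence are deleted pairwise
(complete deletion would discard more signal on 569-bp fragments than
necessary). Pairs outside the formula's domain (`1 − 2P − Q ≤ 0` or
`1 − 2Q ≤ 0`) are flagged saturated and assigned twice the largest finite
pairwise distance — large enough to keep them peripheral in trees while the
flag records the information loss.

**Neighbor joining** follows Saitou–Nei: join the pair minimizing
`Q(i,j) = (n−2)·d(i,j) − r_i − r_j`, with standard limb lengths and
distance reduction. Ties break on the lowest (row, column) index pair under
the current node ordering and negative limb lengths clamp to zero — both
common conventions, fixed here so builds are bit-reproducible. The result is
the standard unrooted representation rooted at the final trifurcation. On
additive matrices NJ provably recovers the generating topology; the tests
exercise this on hundreds of random trees up to 12 taxa and cross-check
against scikit-bio's independent implementation.

**Bootstrap supports** resample alignment columns with replacement, rebuild
the NJ tree per replicate, and report for each internal edge of the original
tree the percentage of replicates containing the same leaf-set bipartition.
The default of 1,000 replicates is the field's customary depth; the column
resampler is seeded and reproducible.

**Lineage delimitation** operationalizes "independent lineages" — usually
counted by eye on a tree figure — as single-linkage clusters at 1% K2P
divergence: two barcodes share a lineage iff a chain of pairwise distances
≤ 0.01 connects them. Single linkage matches the chaining behaviour of
visual clade grouping and is threshold-consistent with the 99% identity
criterion. Implemented with scipy's linkage/fcluster.

**Common coordinate frame.** Rather than a multiple alignment, barcodes are
projected onto an anchor reference: each sequence is semi-globally aligned
to the anchor, columns inserted relative to the anchor are dropped, and
unmatched anchor positions pad with gaps. For a single-locus amplicon with
rare indels this reference-anchored projection is an adequate, deterministic
stand-in for a full MSA; it is not suitable for indel-rich data.

## Phenology

The phenology unit is the month; a taxon occurs in a month if at least one
assigned specimen was collected then (presence, not abundance). Richness
counts all taxon rows — species-level binomials, genus-level "spp" lineages
and unknown lineages — while the species count and family proportions run
over species-level rows only; both statistics are exposed separately
because they answer different questions. Genus-level verdicts of one genus
split into numbered `Genus spp1/spp2` rows when lineage clustering separates
their members; unidentified specimens become one `Unknown species k` row per
lineage. A spawning period is the set of occupied months, flagged continuous
when no gap months interrupt the span. Both eggs and larvae count by
default; an `eggs_only` flag restricts the matrix.

The packaged in-study occurrence table (19 taxa × 5 months, with the
survey's counts: 641 eggs selected, 397 eggs + 17 larvae high-quality, 392
eggs species-assigned) serves as a known-answer input. Its source text and
table disagree on two species' spans (one species lacks a mid-season month
in the table; another starts later than the text implies); the package
reports what the matrix supports and does not attempt to reconcile the two.

## Synthetic data

The generator inverts the analysis model, so pipeline validation is a
closed loop:

- **Sequence evolution** is a per-site K2P process. For an expected
  divergence d and transition/transversion rate ratio κ (default 4, typical
  of fish mitochondrial COI), site substitution probabilities follow the
  closed-form K2P transition functions; realized distances estimate d and
  the tests verify both the distance and the ts:tv ratio.
- **Reference libraries** radiate species from a common ancestor at the
  between-species divergence (default 0.03 expected substitutions/site),
  with rejection sampling enforcing a realized pairwise floor, and scatter
  individuals around each species at half the within-species divergence
  (default 0.003) so conspecific pairs sit near it. Defaults give a wide
  barcoding gap (~0.3% vs ≥3%), the regime in which threshold assignment is
  reliable. Base composition at the root is uniform.
- **Surveys** draw, per month and per species active that month, a Poisson
  number of eggs with mean `monthly_sampling[month]` — interpreted as
  expected eggs **per active species**, the quantity that directly controls
  window recoverability. Each egg's barcode evolves from a random
  conspecific reference individual. Optional off-library taxa (≥5% divergent
  from every reference, rejection-checked) model species missing from the
  library. Dropout is a specimen-level Bernoulli (default 0.38, the failure
  rate typical of ethanol-degraded material), independent of species and
  month, since preservation failure — not sequence content — drives it.
  Dropped specimens keep metadata rows but yield no sequence, mirroring
  failed PCR.
- **No indels** are simulated: the analysis frame is a clean fixed-length
  alignment; indel handling is exercised by the alignment unit tests
  instead.

**What passing tests show — and don't.** With a clean barcoding gap and all
species in the library, the pipeline attains 100% species-level accuracy,
exact spawning-window recovery under dense sampling (~30 eggs per species
per active month), and one lineage cluster per species; under sparse
sampling inferred windows are subsets of the truth, never supersets. Real
surveys violate these idealizations: reference libraries are incomplete and
contain misidentifications, real intra/interspecific divergences overlap for
recently diverged or introgressed taxa, sequencing failure correlates with
taxon and season, and real identity scores come from a different aligner
than any public database's. Synthetic recovery therefore validates the
pipeline's logic, not the field-data error rate.

## Problem sizes and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `species_identity_threshold` | 0.99 | strict species floor (fraction) |
| `genus_identity_floor` | 0.95 | strict genus floor (fraction) |
| `top_n_primary` / `top_n_fallback` | 100 / 5 | consensus window sizes |
| `bootstrap_reps` | 1000 | bootstrap replicates |
| `lineage_cluster_threshold` | 0.01 | K2P divergence for lineages |
| `barcode_length` | 569 | simulated alignment columns |
| `kappa` | 4.0 | ts/tv rate ratio |
| `intraspecific_divergence` | 0.003 | expected within-species K2P |
| `interspecific_divergence` | 0.03 | minimum between-species K2P |
| `dropout_rate` | 0.38 | specimen-level failure probability |

The recovery experiments in the tests and in `scripts/acceptance.py` use 10
species × 2 reference individuals, ~30 eggs per species per active month
(≈800–1000 queries), and a separate ≈10,000-egg survey for the dropout
check — sizes chosen so the exhaustive search stays comfortably desk-scale
while the binomial checks have narrow error bars.

## Known limitations

- Exhaustive search only; no heuristic seeding. Fine for thousands of
  references, wrong tool for millions.
- Identity values are aligner-dependent; exact parity with public
  databases' reported similarities is not claimed, only the same decision
  logic.
- The saturated-distance fallback (2× max finite distance) is a pragmatic
  device; saturated pairs should be interpreted via their flag, not their
  placeholder value.
- Taxonomy is exactly three ranks (family, genus, species); deeper ranks
  are out of scope.
- Months outside the configured season are accepted in metadata but flagged
  and dropped from the occurrence matrix with a warning.
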