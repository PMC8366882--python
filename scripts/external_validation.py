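#!/usr/bin/env python
"""Optional external validation on the study's deposited barcodes.

The deposited egg sequences (GenBank accessions MZ148846-MZ149250) are not
bundled with the package; download them yourself, e.g. with NCBI's efetch,
into a FASTA file, then run:

    python scripts/external_validation.py deposited.fasta --outdir results/external

The script projects all sequences onto a common coordinate frame, builds the
K2P/NJ tree with bootstrap supports, and counts independent lineages by
single-linkage clustering at 1% divergence. Note the deposited set contains
only egg sequences identified to species level, so the lineage count may
differ from the full survey's count (which included genus-level and unknown
lineages). This script is exploratory and is not part of the test suite.
"""
from __future__ import annotations

import argparse
from pathlib import Path

from eggbarcode import bootstrap_supports, cluster_lineages, k2p_matrix
from eggbarcode.io import read_fasta, write_distance_tsv, write_newick
from eggbarcode.phylogeny import anchor_project


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("fasta", type=Path,
                        help="FASTA of downloaded barcode sequences")
    parser.add_argument("--outdir", type=Path, default=Path("external_validation"))
    parser.add_argument("--threshold", type=float, default=0.01,
                        help="K2P divergence threshold for lineage clustering")
    parser.add_argument("--bootstrap-reps", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    records = read_fasta(args.fasta)
    if len(records) < 3:
        raise SystemExit("need at least three sequences")
    anchor = records[0].sequence
    aligned = [
        (r.id, r.sequence if len(r.sequence) == len(anchor)
         else anchor_project(r.sequence, anchor))
        for r in records
    ]
    dm = k2p_matrix(aligned)
    part = cluster_lineages(dm, args.threshold)
    tree = bootstrap_supports(aligned, n_reps=args.bootstrap_reps, seed=args.seed)

    args.outdir.mkdir(parents=True, exist_ok=True)
    write_newick(tree, args.outdir / "tree.nwk")
    write_distance_tsv(dm, args.outdir / "distances.tsv")
    lines = ["id\tlineage"]
    for label in dm.labels:
        lines.append(f"{label}\t{part.cluster_of(label) + 1}")
    (args.outdir / "lineages.tsv").write_text("\n".join(lines) + "\n")
    print(f"{len(records)} sequences -> {part.n_clusters} independent lineages "
          f"at K2P <= {args.threshold}")


if __name__ == "__main__":
    main()
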