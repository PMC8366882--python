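"""File formats: FASTA, taxonomy/metadata TSV, assignment reports, Newick,
occurrence tables.

Readers normalize case and strip alignment gap characters ("-") from
sequences (alignment is internal to the pipeline); writers are deterministic
so identical inputs give byte-identical files. FASTA is wrapped at 80
columns on write; wrapping is ignored on read. Parse errors name the
offending line.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cascade import AssignmentResult
from .errors import InputError, ParseError
from .phenology import OccurrenceMatrix, monthly_richness
from .phylogeny import DistanceMatrix, TreeNode
from .records import normalize_month


@dataclass
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Parse a FASTA file; order preserved, sequences uppercased, "-"
    stripped. Errors report 1-based line numbers."""
    path = Path(path)
    records: list[FastaRecord] = []
    seen: set[str] = set()
    header_line = None
    rid = desc = None
    chunks: list[str] = []

    def flush():
        nonlocal rid
        if rid is None:
            return
        seq = "".join(chunks).upper().replace("-", "")
        if not seq:
            raise ParseError(f"record {rid!r} has an empty sequence", header_line)
        records.append(FastaRecord(id=rid, sequence=seq, description=desc or ""))
        rid = None
        chunks.clear()

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError("empty FASTA header", lineno)
                parts = header.split(None, 1)
                rid = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                if rid in seen:
                    raise ParseError(f"duplicate sequence id {rid!r}", lineno)
                seen.add(rid)
                header_line = lineno
            else:
                if rid is None:
                    raise ParseError(
                        "sequence data before the first FASTA header", lineno
                    )
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(records, path: str | Path, width: int = 80) -> None:
    """Write (id, sequence) records as FASTA, wrapped at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            rid = rec.id if hasattr(rec, "id") else rec[0]
            seq = rec.sequence if hasattr(rec, "sequence") else rec[1]
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_reference_library(fasta_path: str | Path, taxonomy_path: str | Path):
    """Load a reference library from FASTA plus a tab-separated taxonomy
    table (columns: id, family, genus, species)."""
    from .records import ReferenceLibrary, ReferenceRecord

    seqs = read_fasta(fasta_path)
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
    required = {"id", "family", "genus", "species"}
    missing_cols = required - set(tax.columns)
    if missing_cols:
        raise InputError(
            f"taxonomy table missing columns: {sorted(missing_cols)}"
        )
    if tax["id"].duplicated().any():
        dups = sorted(tax.loc[tax["id"].duplicated(), "id"].unique())
        raise InputError(f"duplicate ids in taxonomy table: {dups}")
    tax = tax.set_index("id")
    missing = [r.id for r in seqs if r.id not in tax.index]
    if missing:
        raise InputError(
            f"FASTA ids missing from the taxonomy table: {missing}"
        )
    records = [
        ReferenceRecord(
            id=r.id,
            sequence=r.sequence,
            family=tax.at[r.id, "family"],
            genus=tax.at[r.id, "genus"],
            species=tax.at[r.id, "species"],
        )
        for r in seqs
    ]
    return ReferenceLibrary(records)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated specimen metadata table (columns: id,
    specimen_type, month or date, optional time_slot), indexed by id with a
    normalized ``month`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns or "specimen_type" not in df.columns:
        raise InputError("metadata needs 'id' and 'specimen_type' columns")
    month_col = None
    for cand in ("month", "date"):
        if cand in df.columns:
            month_col = cand
            break
    if month_col is None:
        raise InputError("metadata needs a 'month' or 'date' column")
    months = []
    for i, value in enumerate(df[month_col]):
        if pd.isna(value) or not str(value).strip():
            months.append(None)
            continue
        try:
            months.append(normalize_month(value))
        except InputError as exc:
            # +2: one for the header row, one for 1-based numbering
            raise ParseError(str(exc), i + 2) from None
    time_slot = (
        df["time_slot"].fillna("").to_numpy()
        if "time_slot" in df.columns else [""] * len(df)
    )
    out = pd.DataFrame(
        {
            "specimen_type": df["specimen_type"].str.strip().str.lower().to_numpy(),
            "month": months,
            "time_slot": time_slot,
        },
        index=pd.Index(df["id"].to_numpy(), name="id"),
    )
    bad = ~out["specimen_type"].isin(("egg", "larva"))
    if bad.any():
        raise InputError(
            f"unknown specimen_type values: {sorted(out.loc[bad, 'specimen_type'].unique())}"
        )
    return out


_REPORT_COLUMNS = (
    "id\tlevel\ttaxon\trule_id\tbest_identity\tsecond_best_identity\tn_supporting_hits"
)


def write_assignments(results: list[AssignmentResult], path: str | Path) -> None:
    """Tab-separated assignment report, one row per query in input order."""
    path = Path(path)
    lines = [_REPORT_COLUMNS]
    for r in results:
        second = "" if r.second_best_identity is None else f"{r.second_best_identity:.6f}"
        lines.append(
            "\t".join(
                [
                    r.query_id,
                    r.level,
                    r.taxon,
                    r.rule_id,
                    f"{r.best_identity:.6f}",
                    second,
                    str(r.n_consensus_hits),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_assignments(path: str | Path) -> list[AssignmentResult]:
    """Read an assignment report back into results (evidence not preserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            AssignmentResult(
                query_id=row["id"],
                level=row["level"],
                taxon=row["taxon"],
                rule_id=row["rule_id"],
                best_identity=float(row["best_identity"]),
                second_best_identity=(
                    float(row["second_best_identity"])
                    if row["second_best_identity"] else None
                ),
                n_consensus_hits=int(row["n_supporting_hits"]),
            )
        )
    return out


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths and integer bootstrap
    supports as internal node labels."""
    Path(path).write_text(tree.to_newick() + "\n")


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=dm.labels, columns=dm.labels)
    df.to_csv(path, sep="\t", float_format="%.6f")


def write_occurrence_tsv(m: OccurrenceMatrix, path: str | Path) -> None:
    """Occurrence table: family, taxon, one "+"/"" column per month, plus a
    Total row of per-month taxon counts."""
    lines = ["\t".join(["family", "taxon"] + m.months)]
    pres = m.presence
    for taxon in m.taxa:
        cells = ["+" if pres.loc[taxon, mo] else "" for mo in m.months]
        lines.append("\t".join([m.families.get(taxon, ""), taxon] + cells))
    totals = monthly_richness(m)
    lines.append("\t".join(["", "Total"] + [str(int(totals[mo])) for mo in m.months]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_tsv(truth_rows, path: str | Path) -> None:
    lines = ["\t".join(["id", "true_species", "month", "dropped", "in_library"])]
    for t in truth_rows:
        lines.append(
            "\t".join(
                [t.specimen_id, t.true_species, t.month,
                 str(int(t.dropped)), str(int(t.in_library))]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="id")


def write_taxonomy_tsv(library, path: str | Path) -> None:
    lines = ["\t".join(["id", "family", "genus", "species"])]
    for r in library:
        lines.append("\t".join([r.id, r.family, r.genus, r.species]))
    Path(path).write_text("\n".join(lines) + "\n")
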