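"""Readers and writers for the external formats the toolkit touches.

FASTA goes through Biopython, Newick through dendropy and alignments through
Bio.AlignIO; this module adds the validation the QC pipeline relies on
(duplicate-ID rejection, IUPAC ambiguity handling, coordinate checks) and the
report writers.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO

from .records import GeneCall, MarkerSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_protein_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_marker_list",
    "read_newick",
    "read_alignment",
    "write_report",
]

# IUPAC nucleotide ambiguity codes other than N; all are collapsed to N.
_AMBIGUITY = set("RYSWKMBDHV")
_VALID_AFTER_MAP = set("ACGTN")

GENE_TABLE_COLUMNS = [
    "gene_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "taxon_domain",
    "taxon_phylum",
    "marker_id",
]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read DNA FASTA records as (id, sequence) in file order.

    Sequences are uppercased, U is mapped to T, and IUPAC ambiguity codes
    other than N are mapped to N (count logged).  Any other character is
    rejected, as are duplicate IDs and empty files.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    n_ambiguous = 0
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate FASTA ID {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper().replace("U", "T")
            amb = sum(1 for ch in seq if ch in _AMBIGUITY)
            if amb:
                n_ambiguous += amb
                seq = "".join("N" if ch in _AMBIGUITY else ch for ch in seq)
            bad = set(seq) - _VALID_AFTER_MAP
            if bad:
                raise ValueError(
                    f"{path}: record {rec.id!r} has invalid characters "
                    f"{sorted(bad)!r}"
                )
            records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no records")
    if n_ambiguous:
        logger.info("%s: mapped %d ambiguity bases to N", path, n_ambiguous)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read protein FASTA (uppercased, no alphabet mapping; validation is
    left to the pI calculator, which logs and skips non-standard residues)."""
    records = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate FASTA ID {rec.id!r}")
            seen.add(rec.id)
            records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def _parse_gene_row(fields: list[str], lineno: int) -> GeneCall:
    if len(fields) < 7:
        raise ValueError(f"gene table line {lineno}: expected ≥7 columns")
    gene_id, contig_id, start, end, strand = fields[:5]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValueError(
            f"gene table line {lineno}: non-integer coordinates "
            f"({start!r}, {end!r})"
        ) from exc
    if start_i > end_i:
        raise ValueError(
            f"gene table line {lineno}: start={start_i} > end={end_i}"
        )
    strand = strand.replace("−", "-")  # unicode minus
    domain = fields[5].strip() or "unclassified"
    phylum = fields[6].strip() or "unclassified"
    marker = fields[7].strip() if len(fields) > 7 else ""
    return GeneCall(
        gene_id=gene_id,
        contig_id=contig_id,
        start=start_i,
        end=end_i,
        strand=strand,
        taxon_domain=domain,
        taxon_phylum=phylum,
        marker_id=marker or None,
    )


def read_gene_table(path: str | Path) -> list[GeneCall]:
    """Read the 8-column gene annotation TSV.

    Header row required.  Empty taxon fields normalize to "unclassified";
    contig linkage is validated later, at SAGAssembly construction.
    """
    genes: list[GeneCall] = []
    with _open_text(path) as handle:
        header = handle.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty gene table")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            genes.append(_parse_gene_row(line.rstrip("\n").split("\t"), lineno))
    return genes


def write_gene_table(genes: Iterable[GeneCall], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            out.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.contig_id,
                        str(g.start),
                        str(g.end),
                        g.strand,
                        g.taxon_domain,
                        g.taxon_phylum,
                        g.marker_id or "",
                    ]
                )
                + "\n"
            )


def read_marker_list(path: str | Path, name: str | None = None) -> MarkerSet:
    """One marker ID per line; blank lines and '#' comments skipped;
    duplicates rejected."""
    ids: list[str] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line)
    return MarkerSet(name=name or Path(path).stem, marker_ids=tuple(ids))


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree (leaf labels + optional branch lengths; lengths are
    ignored by the parsimony statistics)."""
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def read_alignment(path: str | Path, fmt: str = "fasta") -> "pd.DataFrame | object":
    """Read a multiple sequence alignment (FASTA or relaxed PHYLIP) into a
    Bio.Align.MultipleSeqAlignment; unequal row lengths are rejected."""
    fmt = {"phylip": "phylip-relaxed", "phylip-relaxed": "phylip-relaxed", "fasta": "fasta"}[fmt]
    if fmt == "fasta":
        # AlignIO's fasta reader raises a bare ValueError on ragged input;
        # produce a clearer message and tolerate file order.
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no records")
        lengths = {len(r.seq) for r in records}
        if len(lengths) > 1:
            raise ValueError(
                f"{path}: unequal alignment row lengths {sorted(lengths)}"
            )
        from Bio.Align import MultipleSeqAlignment

        return MultipleSeqAlignment(records)
    return AlignIO.read(str(path), fmt)


def write_report(report, out_dir: str | Path, prefix: str = "qc") -> tuple[Path, Path]:
    """Write a QCReport as one TSV row per contig plus a JSON summary.

    Returns (tsv_path, json_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / f"{prefix}_report.tsv"
    json_path = out_dir / f"{prefix}_summary.json"
    report.per_contig.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    with open(json_path, "w") as out:
        json.dump(report.summary(), out, indent=2, sort_keys=True)
        out.write("\n")
    return tsv_path, json_path
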