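"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, GFF3 through an in-memory gffutils database,
Newick through dendropy, tables through pandas.  Everything returns the
package's own domain types.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CodonAlignment,
    DomainPartition,
    ExpressionMatrix,
    GeneRecord,
    ProteinAlignment,
)
from .errors import ConfigError


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_alignment(path) -> ProteinAlignment:
    seqs = read_fasta(path)
    return ProteinAlignment(ids=list(seqs), rows=list(seqs.values()))


def read_codon_alignment(path) -> CodonAlignment:
    """Read a gapped in-frame nucleotide FASTA as a codon alignment."""
    seqs = read_fasta(path)
    rows = []
    for name, s in seqs.items():
        if len(s) % 3:
            raise ConfigError(
                f"{name}: aligned CDS length {len(s)} not divisible by 3"
            )
        rows.append([s[i : i + 3] for i in range(0, len(s), 3)])
    return CodonAlignment(ids=list(seqs), rows=rows)


def write_codon_alignment_fasta(ca: CodonAlignment, path) -> None:
    write_fasta(
        {name: "".join(row) for name, row in zip(ca.ids, ca.rows)}, path
    )


def write_codon_alignment_phylip(ca: CodonAlignment, path) -> None:
    """Relaxed-PHYLIP writer (id, two spaces, full row on one line)."""
    with open(path, "w") as fh:
        fh.write(f" {len(ca.ids)}  {3 * ca.ncol}\n")
        for name, row in zip(ca.ids, ca.rows):
            fh.write(f"{name}  {''.join(row)}\n")


# ---------------------------------------------------------------- GFF3

def read_gff3_gene_models(path) -> dict[str, dict]:
    """Extract per-gene exon and CDS intervals from a GFF3 file.

    Returns {gene_id: {chrom, strand, start, end, exons, cds_exons}} with
    1-based inclusive intervals sorted in transcription order (reversed on
    the minus strand).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out = {}
    for gene in db.features_of_type("gene"):
        exons = [
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        ]
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        exons.sort()
        cds.sort()
        if gene.strand == "-":
            exons = exons[::-1]
            cds = cds[::-1]
        out[gene.id] = {
            "chromosome": gene.seqid,
            "strand": gene.strand,
            "start": gene.start,
            "end": gene.end,
            "exons": exons,
            "cds_exons": cds,
        }
    return out


# ---------------------------------------------------------------- tables

GENE_TABLE_COLUMNS = [
    "gene_id",
    "species",
    "side",
    "chromosome",
    "start",
    "end",
    "strand",
    "class",
]


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"gene table missing columns: {sorted(missing)}")
    return df


def read_domain_partition(path) -> DomainPartition:
    """TSV with columns name, start_col, end_col (half-open codon columns)."""
    df = pd.read_csv(path, sep="\t")
    return DomainPartition.from_ranges(
        {
            str(r["name"]): (int(r["start_col"]), int(r["end_col"]))
            for _, r in df.iterrows()
        },
        note=f"read from {path}",
    )


def write_domain_partition(part: DomainPartition, path) -> None:
    rows = []
    for name, cols in part.domains.items():
        cols = sorted(cols)
        rows.append(
            {"name": name, "start_col": cols[0], "end_col": cols[-1] + 1}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> ExpressionMatrix:
    """TSV: first column gene_id, remaining columns condition calls."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return ExpressionMatrix(
        genes=list(df.index),
        conditions=list(df.columns),
        calls={g: dict(df.loc[g]) for g in df.index},
    )


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(
        [[em.calls[g][c] for c in em.conditions] for g in em.genes],
        index=pd.Index(em.genes, name="gene_id"),
        columns=em.conditions,
    )
    df.to_csv(path, sep="\t")


def gene_records_from_tables(
    gene_table: pd.DataFrame,
    cds_map: dict[str, str],
    gene_models: dict[str, dict] | None = None,
) -> list[GeneRecord]:
    """Assemble GeneRecords from the TSV gene table + CDS FASTA (+ GFF3)."""
    records = []
    for _, row in gene_table.iterrows():
        gid = str(row["gene_id"])
        model = (gene_models or {}).get(gid, {})
        records.append(
            GeneRecord(
                gene_id=gid,
                species=str(row["species"]),
                taxon_side=_opt(row.get("side")),
                cds=cds_map[gid],
                chromosome=_opt(row.get("chromosome")),
                start=_opt_int(row.get("start")),
                end=_opt_int(row.get("end")),
                strand=_opt(row.get("strand")),
                exons=model.get("exons", []),
                cds_exons=model.get("cds_exons", []),
                class_label=_opt(row.get("class")) or "unknown",
            )
        )
    return records


def _opt(v):
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return str(v)


def _opt_int(v):
    s = _opt(v)
    return None if s is None else int(float(s))


def dataframe_to_tsv_string(df: pd.DataFrame) -> str:
    """Deterministic TSV serialization (fixed float format)."""
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    return buf.getvalue()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
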