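"""Readers and writers for the standard interchange formats.

Genomes and miRNA catalogues come in as FASTA (via Biopython); sites go out
as BED6+5 or a headered TSV; gene annotations come in as BED or GFF3;
expression matrices are TSV with one header row of identifiers.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import pandas as pd
from Bio import SeqIO

from .pairing import BindingMode, Orientation
from .scan import GenomeSequence, TriplexSite

SITE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "mirna_id",
    "mode",
    "orientation",
    "n_units",
    "score",
    "energy_kcal_mol",
    "grade",
]


def read_genome_fasta(path) -> List[GenomeSequence]:
    """Multi-record genome FASTA (wrapped or unwrapped)."""
    records = [
        GenomeSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_mirna_fasta(path) -> Dict[str, str]:
    """miRNA FASTA (U or T alphabet); keyed by the first header token."""
    mirnas: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in mirnas:
            raise ValueError(f"duplicate miRNA identifier {rec.id!r} in {path}")
        mirnas[rec.id] = str(rec.seq).upper().replace("T", "U")
    if not mirnas:
        raise ValueError(f"no FASTA records in {path}")
    return mirnas


def write_fasta(records: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sites_to_frame(sites: List[TriplexSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "mirna_id": s.mirna_id,
                "mode": s.mode.value,
                "orientation": s.orientation.value,
                "n_units": s.n_units,
                "score": s.score,
                "energy_kcal_mol": s.energy,
                "grade": s.grade,
            }
            for s in sites
        ],
        columns=SITE_COLUMNS,
    )


def frame_to_sites(df: pd.DataFrame) -> List[TriplexSite]:
    return [
        TriplexSite(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            mirna_id=str(r.mirna_id),
            mode=BindingMode(r.mode),
            orientation=Orientation(r.orientation),
            n_units=int(r.n_units),
            score=float(r.score),
            energy=float(r.energy_kcal_mol),
            grade=int(r.grade),
        )
        for r in df.itertuples()
    ]


def write_sites_tsv(sites: List[TriplexSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> List[TriplexSite]:
    return frame_to_sites(pd.read_csv(path, sep="\t"))


def write_sites_bed(sites: List[TriplexSite], path) -> None:
    """BED6+5: name is the miRNA, the BED score column is capped at 1000
    (the full heuristic score is n_units x points-per-unit, recoverable from
    the n_units extra column); extras are n_units, energy, mode,
    orientation, grade."""
    with open(path, "w") as fh:
        for s in sites:
            bed_score = int(min(1000, round(s.score)))
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.mirna_id}\t{bed_score}\t{s.strand}"
                f"\t{s.n_units}\t{s.energy!r}\t{s.mode.value}\t{s.orientation.value}"
                f"\t{s.grade}\n"
            )


def read_genes_bed(path) -> pd.DataFrame:
    """Gene intervals from BED (>= 4 columns; strand from column 6 if present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("gene BED needs at least chrom,start,end,name")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "gene_id": df[3].astype(str),
            "strand": df[5].astype(str) if df.shape[1] >= 6 else ".",
        }
    )
    return out


def _gff3_attr(attrs: str, keys=("ID", "Name", "gene_id")) -> Optional[str]:
    for part in attrs.split(";"):
        k, _, v = part.strip().partition("=")
        if k in keys and v:
            return v
    return None


def read_genes_gff3(path, feature: str = "gene") -> pd.DataFrame:
    """Gene intervals from GFF3 (1-based inclusive -> 0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )
    df = df[df["type"] == feature]
    if df.empty:
        raise ValueError(f"no {feature!r} features in {path}")
    return pd.DataFrame(
        {
            "chrom": df["seqid"].astype(str),
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
            "gene_id": [
                _gff3_attr(a) or f"feature{i}" for i, a in enumerate(df["attributes"])
            ],
            "strand": df["strand"].astype(str),
        }
    ).reset_index(drop=True)


def read_genes(path) -> pd.DataFrame:
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        return read_genes_gff3(path)
    return read_genes_bed(path)


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression matrix TSV; first column holds row identifiers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicated identifiers in {path}")
    return df
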