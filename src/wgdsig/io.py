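"""Readers and writers for the pipeline's standard text formats.

GFF3 gene coordinates (1-based closed), 12-column tabular similarity hits,
FASTA (via Biopython), bedgraph coverage (0-based half-open), TSV count
matrices and newick trees.  All formats round-trip with the synthetic
generator so fixtures can be materialized on disk and re-read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import CoverageTrack, SyntheticGenomeLayout

BLAST_COLUMNS = [
    "query", "subject", "pct_identity", "aln_length", "mismatches", "gap_opens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# -- GFF3 -------------------------------------------------------------------


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file as a coordinate table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                raise ValueError(f"gene feature without ID attribute: {line!r}")
            rows.append((gene_id, parts[0], int(parts[3]), int(parts[4]), parts[6]))
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\twgdsig\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# -- 12-column tabular hits --------------------------------------------------


def read_blast_tab(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS)
    return df.rename(columns={"query": "gene_a", "subject": "gene_b"})


def write_blast_tab(pairs: pd.DataFrame, path) -> None:
    """Write homolog pairs in 12-column tabular layout (dummy alignment
    fields where the generator does not model them)."""
    with open(path, "w") as fh:
        for row in pairs.itertuples(index=False):
            fh.write(
                f"{row.gene_a}\t{row.gene_b}\t95.0\t300\t10\t0\t1\t300\t1\t300\t"
                f"{row.evalue:.2e}\t{row.bitscore:.1f}\n"
            )


# -- FASTA ------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# -- bedgraph ---------------------------------------------------------------


def read_bedgraph(path) -> CoverageTrack:
    """Bedgraph (0-based half-open) to a per-base coverage track."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["scaffold", "start", "end", "depth"],
        comment="t",  # skips optional "track ..." header lines
    )
    depths = {}
    for scf, sub in df.groupby("scaffold", sort=False):
        length = int(sub["end"].max())
        arr = np.zeros(length, dtype=np.int64)
        for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
            arr[int(s):int(e)] = int(d)
        depths[scf] = arr
    return CoverageTrack(depths=depths)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length encoded per-base depths, the format genome-coverage tools emit."""
    with open(path, "w") as fh:
        for scf in sorted(track.depths):
            arr = track.depths[scf]
            if len(arr) == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{scf}\t{s}\t{e}\t{arr[s]}\n")


# -- count matrices and misc TSV --------------------------------------------


def read_count_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def write_layout_bundle(layout: SyntheticGenomeLayout, outdir) -> dict:
    """Materialize a synthetic genome layout as GFF3 + tabular hits + registry."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gff3_genes(layout.genes, outdir / "genes.gff3")
    write_blast_tab(layout.pairs, outdir / "hits.tsv")
    layout.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    layout.blocks.to_csv(outdir / "registry.tsv", sep="\t", index=False)
    return {
        "gff3": str(outdir / "genes.gff3"),
        "hits": str(outdir / "hits.tsv"),
        "pairs": str(outdir / "pairs.tsv"),
        "registry": str(outdir / "registry.tsv"),
    }
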