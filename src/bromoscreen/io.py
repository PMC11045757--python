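"""Readers and writers for the plain-text formats the pipeline exchanges.

Tables are TSV/CSV via pandas; gene models come from GTF (via pyranges,
1-based inclusive converted to 0-based half-open) or BED12; promoters from
FASTA via Biopython; gene-set collections from GMT.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyranges as pr
from Bio import SeqIO

SCREEN_COLUMNS = ["cell_line", "lineage", "compound", "dose_molar", "viability"]


def read_screen_table(path) -> pd.DataFrame:
    """Long-format viability TSV: cell_line, lineage, compound, dose_molar, viability."""
    table = pd.read_csv(path, sep="\t")
    missing = set(SCREEN_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    return table


def read_count_matrix(path) -> pd.DataFrame:
    """Counts TSV, first column row ids, remaining columns samples."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique()
        raise ValueError(f"duplicate row ids: {list(dupes[:5])}")
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    return counts


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition"}
    if missing := required - set(sheet.columns):
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def read_gtf_exons(path) -> pd.DataFrame:
    """Exon intervals per gene from GTF; output is 0-based half-open."""
    gr = pr.read_gtf(str(path))
    df = gr.df
    exons = df[df["Feature"] == "exon"]
    if exons.empty:
        raise ValueError("GTF contains no exon features")
    return exons.rename(
        columns={"Chromosome": "chromosome", "Start": "start", "End": "end"}
    )[["chromosome", "start", "end", "gene_id"]].reset_index(drop=True)


def read_bed12_exons(path) -> pd.DataFrame:
    """Exon intervals from BED12 blocks; BED is already 0-based half-open.

    The name field (column 4) is taken as the gene/transcript id.
    """
    names = [
        "chromosome", "start", "end", "gene_id", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    bed = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    rows = []
    for rec in bed.itertuples(index=False):
        sizes = [int(x) for x in str(rec.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(rec.block_starts).rstrip(",").split(",")]
        if len(sizes) != int(rec.block_count) or len(starts) != int(rec.block_count):
            raise ValueError(f"malformed BED12 blocks for {rec.gene_id}")
        for size, offset in zip(sizes, starts):
            rows.append((rec.chromosome, rec.start + offset, rec.start + offset + size, rec.gene_id))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene_id"])


def read_lengths(path) -> pd.Series:
    """Two-column TSV (id, length_bp) -> Series."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError("length table needs id and length_bp columns")
    return table.set_index(table.columns[0])[table.columns[1]].astype(float)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_gmt(path) -> dict[str, set]:
    """GMT: one gene set per line — name, description, then member genes."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def read_gene_set(path) -> set[str]:
    """One gene id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_edge_list(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    if missing := {"gene_a", "gene_b", "confidence"} - set(edges.columns):
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    return edges


def read_dependency_matrix(path) -> pd.DataFrame:
    """Chronos-style CSV, rows genes, header row of cell-line names."""
    return pd.read_csv(path, index_col=0)


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
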