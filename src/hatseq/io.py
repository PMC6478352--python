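"""Readers and writers for the pipeline's on-disk dialects.

Genomes travel as FASTA, repeat and known-insertion annotation as BED6,
gene models as a genePred-style TSV, reads as FASTQ, and alignments as a
tabular dialect (one row per merged contig) so pipeline stages are
independently runnable.  All user-facing interval tables are 1-based
inclusive; in-memory everything is 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomic_stats import Transcript
from .simdata import SyntheticGenome

ALIGNMENT_COLUMNS = [
    "contig_id", "truth_id", "sample", "individual", "sequence", "chrom",
    "start", "end", "strand", "mapq", "mismatches", "aligned_len", "dup_group",
    "start_position", "l1_off", "l1_len", "flank_off", "flank_len",
    "alt_chrom", "alt_start", "alt_strand", "phase",
]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = [f"ivl{i}" for i in range(len(out))]
    if "score" not in out.columns:
        out["score"] = 0
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return df


def write_genepred(models: Iterable[Transcript], path: str | Path) -> None:
    rows = []
    for tx in models:
        rows.append({
            "name": tx.tx_id, "gene": tx.gene, "chrom": tx.chrom, "strand": tx.strand,
            "txStart": tx.tx_start, "txEnd": tx.tx_end,
            "cdsStart": tx.cds_start, "cdsEnd": tx.cds_end,
            "exonCount": len(tx.exons),
            "exonStarts": ",".join(str(s) for s, _ in tx.exons) + ",",
            "exonEnds": ",".join(str(e) for _, e in tx.exons) + ",",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genepred(path: str | Path) -> list[Transcript]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for _, r in df.iterrows():
        starts = [int(x) for x in str(r.exonStarts).split(",") if x]
        ends = [int(x) for x in str(r.exonEnds).split(",") if x]
        models.append(Transcript(
            gene=str(r.gene), tx_id=str(r["name"]), chrom=str(r.chrom),
            strand=str(r.strand), tx_start=int(r.txStart), tx_end=int(r.txEnd),
            cds_start=int(r.cdsStart), cds_end=int(r.cdsEnd),
            exons=tuple(zip(starts, ends))))
    return models


def write_fastq(df: pd.DataFrame, path: str | Path) -> None:
    """Contig sequences as FASTQ (uniform quality; the simulator does not
    model base-quality errors)."""
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(f"@{row.contig_id}\n{row.sequence}\n+\n{'I' * len(row.sequence)}\n")


def write_alignment_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ALIGNMENT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_alignment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"alt_chrom": str})
    return df


def write_genome(genome: SyntheticGenome, outdir: str | Path, prefix: str = "genome") -> dict[str, Path]:
    """Write FASTA + repeat BED + gene models (+ mappability as BED-like)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}.fa",
        "repeats": outdir / f"{prefix}.repeats.bed",
        "genes": outdir / f"{prefix}.genes.tsv",
    }
    write_fasta(genome.sequences, paths["fasta"])
    rep = genome.repeats.rename(columns={"name": "name"}).copy()
    rep["score"] = 0
    rep["name"] = rep["name"] + "|" + rep["family"]
    write_bed6(rep, paths["repeats"])
    write_genepred(genome.gene_models, paths["genes"])
    return paths


def read_repeats_bed(path: str | Path) -> pd.DataFrame:
    df = read_bed6(path)
    split = df["name"].str.rsplit("|", n=1, expand=True)
    df["name"], df["family"] = split[0], split[1]
    return df


def write_calls(calls, path: str | Path) -> None:
    rows = [{
        "chrom": c.chrom, "position": c.position, "strand": c.strand or ".",
        "category": c.category, "sample": c.sample, "individual": c.individual,
        "rpm": round(c.features.rpm, 4) if c.features else "",
        "width": c.features.width if c.features else "",
        "signal_count": c.features.signal_count if c.features else "",
        "signal_depths": ",".join(map(str, c.features.signal_depths)) if c.features else "",
        "rejection_reasons": ";".join(c.rejection_reasons),
        "flags": ";".join(c.flags),
    } for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    Path(path).write_text(json.dumps(obj, indent=1, default=default))
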