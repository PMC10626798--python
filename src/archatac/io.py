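"""Readers and writers for the plain-text formats used throughout.

FASTA for genome sequence, BED3 for fragments, BED6+p+q for peaks, bedGraph
for tracks, and TSV for annotation, methylation calls and count tables.
Everything is written 0-based half-open; a GFF3-subset reader converts the
1-based inclusive convention on the way in.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    CONTEXTS,
    CountTable,
    FragmentSet,
    Gene,
    GenomeAnnotation,
    MethylCallTable,
    PeakSet,
    Replicon,
    SignalTrack,
)


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[Replicon]:
    """Read a genome FASTA into Replicon records (sequence upper-cased)."""
    replicons: list[Replicon] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate replicon {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        replicons.append(Replicon(rec.id, len(seq), seq))
    if not replicons:
        raise ValueError(f"no FASTA records in {path}")
    return replicons


def write_fasta(replicons: list[Replicon], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rep in replicons:
            if rep.sequence is None:
                raise ValueError(f"replicon {rep.name!r} has no sequence to write")
            fh.write(f">{rep.name}\n")
            for i in range(0, rep.length, width):
                fh.write(rep.sequence[i : i + width] + "\n")


# ------------------------------------------------------------- intervals

def write_fragments_bed(frags: FragmentSet, path: str | Path) -> None:
    frags.records.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(
    path: str | Path,
    genome: GenomeAnnotation | None = None,
    collapse_duplicates: bool = False,
    **meta,
) -> FragmentSet:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["replicon", "start", "end"],
        dtype={"replicon": str, "start": np.int64, "end": np.int64},
    )
    fs = FragmentSet(df, genome=genome, **meta)
    return fs.collapse_duplicates() if collapse_duplicates else fs


def write_peaks_bed(peaks: PeakSet, path: str | Path, header: str | None = None) -> None:
    """BED6+p+q: chrom start end name score strand p q summit."""
    df = peaks.records
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for i, row in df.iterrows():
            fh.write(
                f"{row['replicon']}\t{row['start']}\t{row['end']}\tpeak_{i + 1}\t"
                f"{row['score']:.6g}\t.\t{row['p']:.6g}\t{row['q']:.6g}\t{row['summit']}\n"
            )


def read_peaks_bed(path: str | Path) -> PeakSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["replicon", "start", "end", "name", "score", "strand", "p", "q", "summit"],
        dtype={"replicon": str},
    )
    return PeakSet(df[["replicon", "start", "end", "summit", "score", "p", "q"]])


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """bedGraph with 0-based half-open intervals, one line per bin run."""
    with open(path, "w") as fh:
        for rep in track.replicon_names:
            vals = track[rep]
            b = track.bin_size
            i = 0
            n = len(vals)
            while i < n:
                j = i
                while j + 1 < n and vals[j + 1] == vals[i]:
                    j += 1
                fh.write(f"{rep}\t{i * b}\t{(j + 1) * b}\t{vals[i]:.10g}\n")
                i = j + 1


def read_bedgraph(path: str | Path, bin_size: int = 1) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["replicon", "start", "end", "value"],
        dtype={"replicon": str},
    )
    if len(df) and (df["start"].to_numpy() >= df["end"].to_numpy()).any():
        raise ValueError("bedGraph intervals must satisfy start < end")
    values: dict[str, np.ndarray] = {}
    for rep, grp in df.groupby("replicon", sort=False):
        n_bins = int(np.ceil(grp["end"].max() / bin_size))
        v = np.zeros(n_bins)
        for _, row in grp.iterrows():
            v[row["start"] // bin_size : -(-row["end"] // bin_size)] = row["value"]
        values[rep] = v
    return SignalTrack(values, bin_size=bin_size)


# ------------------------------------------------------------ annotation

_ANN_COLS = ["gene_id", "replicon", "start", "end", "strand", "operon"]


def write_annotation_tsv(ann: GenomeAnnotation, path: str | Path) -> None:
    rows = [
        (g.gene_id, g.replicon, g.start, g.end, g.strand, g.operon or ".")
        for g in ann.genes
    ]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_ANN_COLS) + "\n")
        fh.write("#replicon_lengths\t" + ";".join(f"{r.name}={r.length}" for r in ann.replicons) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_annotation_tsv(path: str | Path, replicons: list[Replicon] | None = None) -> GenomeAnnotation:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#replicon_lengths"):
                for tok in line.strip().split("\t")[1].split(";"):
                    name, L = tok.split("=")
                    lengths[name] = int(L)
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_ANN_COLS,
                     dtype={"gene_id": str, "replicon": str, "strand": str, "operon": str})
    genes = [
        Gene(r.gene_id, r.replicon, int(r.start), int(r.end), r.strand,
             None if r.operon in (".", None) or pd.isna(r.operon) else r.operon)
        for r in df.itertuples()
    ]
    if replicons is None:
        if not lengths:
            # fall back to gene extents
            lengths = {g.replicon: 0 for g in genes}
            for g in genes:
                lengths[g.replicon] = max(lengths[g.replicon], g.end)
        replicons = [Replicon(n, L) for n, L in lengths.items()]
    return GenomeAnnotation(replicons, genes)


def read_annotation_gff(path: str | Path, replicons: list[Replicon] | None = None,
                        feature_type: str = "gene") -> GenomeAnnotation:
    """Map gene features from a GFF3 subset onto the annotation table.

    GFF3 is 1-based inclusive; converted to 0-based half-open on read.
    Operon membership read from an ``operon=`` attribute when present.
    """
    genes: list[Gene] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, name, _, end = line.split()[:4]
                lengths[name] = int(end)
                continue
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id") or f"gene{len(genes) + 1}"
            genes.append(
                Gene(gid, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6],
                     attrs.get("operon"))
            )
    if replicons is None:
        for g in genes:
            lengths[g.replicon] = max(lengths.get(g.replicon, 0), g.end)
        replicons = [Replicon(n, L) for n, L in lengths.items()]
    return GenomeAnnotation(replicons, genes)


# ---------------------------------------------------------- methyl calls

_METHYL_COLS = ["molecule_id", "replicon", "frag_start", "frag_end", "pos", "context", "call"]


def write_methyl_calls(table: MethylCallTable, path: str | Path) -> None:
    df = table.records.copy()
    df["call"] = np.where(df.pop("methylated"), "methylated", "unmethylated")
    df.to_csv(path, sep="\t", index=False)


def read_methyl_calls(path: str | Path) -> MethylCallTable:
    df = pd.read_csv(path, sep="\t", dtype={"molecule_id": str, "replicon": str, "context": str})
    missing = [c for c in _METHYL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"methylation call file missing columns: {missing}")
    bad = set(df["call"].unique()) - {"methylated", "unmethylated"}
    if bad:
        raise ValueError(f"unknown call token(s): {sorted(bad)}")
    df["methylated"] = df.pop("call") == "methylated"
    return MethylCallTable(df)


# ----------------------------------------------------------- count tables

def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="feature")


def read_count_table(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col="feature")
    return CountTable(df)


def log(msg: str) -> None:
    print(f"[archatac] {msg}", file=sys.stderr)
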