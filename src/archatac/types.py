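"""Core domain types shared by every analysis stage.

All coordinates are 0-based half-open (BED convention) on named replicons.
A genome is a set of replicons (a main chromosome plus plasmids, possibly at
very different per-cell copy numbers); genes carry strand and optional operon
membership, and the transcription start site (TSS) of a gene is its start for
``+`` strand genes and its end for ``-`` strand genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
CONTEXTS = ("GpC", "CpG")


@dataclass(frozen=True)
class Replicon:
    """An independently replicating DNA element (chromosome or plasmid)."""

    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"replicon {self.name!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"replicon {self.name!r}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    operon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: need 0 <= start < end")

    @property
    def tss(self) -> int:
        """TSS position: start for + strand, end - 1 for - strand."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Replicons plus gene/TSS/operon annotation for a multi-replicon genome."""

    replicons: list[Replicon]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.replicons]
        if len(set(names)) != len(names):
            raise ValueError("duplicate replicon names")
        self._by_name = {r.name: r for r in self.replicons}
        for g in self.genes:
            rep = self._by_name.get(g.replicon)
            if rep is None:
                raise ValueError(f"gene {g.gene_id!r}: unknown replicon {g.replicon!r}")
            if g.end > rep.length:
                raise ValueError(f"gene {g.gene_id!r} exceeds replicon bounds")
        ops = self.operons()
        for op_id, members in ops.items():
            reps = {g.replicon for g in members}
            strands = {g.strand for g in members}
            if len(reps) > 1 or len(strands) > 1:
                raise ValueError(f"operon {op_id!r}: members must share replicon and strand")
            ordered = sorted(members, key=lambda g: g.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.end:
                    raise ValueError(f"operon {op_id!r}: overlapping members")

    def replicon(self, name: str) -> Replicon:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown replicon {name!r}") from None

    @property
    def replicon_names(self) -> list[str]:
        return [r.name for r in self.replicons]

    def genes_on(self, replicon: str) -> list[Gene]:
        return [g for g in self.genes if g.replicon == replicon]

    def operons(self) -> dict[str, list[Gene]]:
        """Operon id -> member genes in coordinate order."""
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            if g.operon is not None:
                out.setdefault(g.operon, []).append(g)
        return {k: sorted(v, key=lambda g: g.start) for k, v in out.items()}

    def tss_table(self) -> pd.DataFrame:
        """One row per gene: gene_id, replicon, tss, strand."""
        if not self.genes:
            raise ValueError("annotation contains no genes, no TSSs available")
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "replicon": [g.replicon for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )


class FragmentSet:
    """Aligned paired-end fragments as replicon intervals.

    The unit of all bulk signal.  Records are held in a DataFrame with
    columns ``replicon``, ``start``, ``end`` (0-based half-open).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        library_id: str = "lib",
        assay: str = "ATAC",
        condition: str = "exponential",
        replicate: int = 1,
        genome: GenomeAnnotation | None = None,
    ) -> None:
        records = records.reset_index(drop=True)
        for col in ("replicon", "start", "end"):
            if col not in records.columns:
                raise ValueError(f"fragment records need a {col!r} column")
        starts = records["start"].to_numpy()
        ends = records["end"].to_numpy()
        if len(records) and ((starts < 0).any() or (starts >= ends).any()):
            raise ValueError("fragments must satisfy 0 <= start < end")
        if genome is not None:
            for rep, grp in records.groupby("replicon", sort=False):
                L = genome.replicon(str(rep)).length
                if (grp["end"].to_numpy() > L).any():
                    raise ValueError(f"fragment end beyond replicon {rep!r} length {L}")
        self.records = records[["replicon", "start", "end"]]
        self.library_id = library_id
        self.assay = assay
        self.condition = condition
        self.replicate = replicate

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> np.ndarray:
        return (self.records["end"] - self.records["start"]).to_numpy()

    def on(self, replicon: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (starts, ends) arrays for one replicon."""
        sub = self.records[self.records["replicon"] == replicon]
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        return (
            sub["start"].to_numpy()[order],
            sub["end"].to_numpy()[order],
        )

    def counts_per_replicon(self) -> dict[str, int]:
        return self.records["replicon"].value_counts().to_dict()

    def collapse_duplicates(self) -> "FragmentSet":
        """Drop byte-identical (replicon, start, end) duplicates."""
        return FragmentSet(
            self.records.drop_duplicates(),
            self.library_id,
            self.assay,
            self.condition,
            self.replicate,
        )


class SignalTrack:
    """Per-replicon numeric coverage vectors at a fixed bin size."""

    def __init__(
        self,
        values: dict[str, np.ndarray],
        bin_size: int = 1,
        normalization: str = "raw",
    ) -> None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if normalization not in ("raw", "RPM"):
            raise ValueError("normalization must be 'raw' or 'RPM'")
        for name, v in values.items():
            v = np.asarray(v, dtype=float)
            if (v < 0).any():
                raise ValueError(f"track {name!r}: negative values")
            values[name] = v
        self.values = values
        self.bin_size = bin_size
        self.normalization = normalization

    def __getitem__(self, replicon: str) -> np.ndarray:
        return self.values[replicon]

    @property
    def replicon_names(self) -> list[str]:
        return list(self.values)


class MethylCallTable:
    """Per-molecule, per-site methylation calls from footprinting data.

    Methylated == accessible; unmethylated == protected.  Backed by a
    DataFrame with columns ``molecule_id``, ``replicon``, ``frag_start``,
    ``frag_end``, ``pos``, ``context``, ``methylated`` (bool).
    """

    COLUMNS = ("molecule_id", "replicon", "frag_start", "frag_end", "pos", "context", "methylated")

    def __init__(self, records: pd.DataFrame) -> None:
        records = records.reset_index(drop=True)
        missing = [c for c in self.COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"methylation call table missing columns: {missing}")
        bad_ctx = set(records["context"].unique()) - set(CONTEXTS)
        if bad_ctx:
            raise ValueError(f"unknown context token(s): {sorted(bad_ctx)}")
        pos = records["pos"].to_numpy()
        fs = records["frag_start"].to_numpy()
        fe = records["frag_end"].to_numpy()
        if len(records) and ((pos < fs).any() or (pos >= fe).any()):
            raise ValueError("site position must lie within [frag_start, frag_end)")
        if records.duplicated(subset=["molecule_id", "pos"]).any():
            raise ValueError("duplicate (molecule, site) pair")
        self.records = records[list(self.COLUMNS)]

    def __len__(self) -> int:
        return len(self.records)

    def filter_context(self, contexts: Iterable[str]) -> "MethylCallTable":
        keep = self.records["context"].isin(list(contexts))
        return MethylCallTable(self.records[keep])


class PeakSet:
    """Called peaks: (replicon, start, end, summit, score, p, q)."""

    COLUMNS = ("replicon", "start", "end", "summit", "score", "p", "q")

    def __init__(self, records: pd.DataFrame) -> None:
        records = records.reset_index(drop=True)
        for col in self.COLUMNS:
            if col not in records.columns:
                raise ValueError(f"peak records need a {col!r} column")
        if len(records):
            if (records["start"].to_numpy() >= records["end"].to_numpy()).any():
                raise ValueError("peak start must be < end")
            if (records["score"].to_numpy() < 0).any():
                raise ValueError("peak scores must be non-negative")
        self.records = records[list(self.COLUMNS)]

    def __len__(self) -> int:
        return len(self.records)


class CountTable:
    """Feature x library matrix of non-negative integer counts."""

    def __init__(self, counts: pd.DataFrame, coords: pd.DataFrame | None = None) -> None:
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        if coords is not None:
            unknown = set(counts.index) - set(coords.index)
            if unknown:
                raise ValueError(f"features without coordinates: {sorted(unknown)[:5]}")
        self.counts = counts
        self.coords = coords

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> pd.Index:
        return self.counts.columns
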