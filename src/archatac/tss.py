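"""Strand-aware TSS metaprofiles, heatmaps and the TSS ratio score.

The TSS ratio score is the QC statistic used to judge ATAC library quality:
mean signal pooled over TSS +/- 100 bp windows divided by mean signal pooled
over 100-bp background windows centered 2 kb on either side of each TSS.
A library with no promoter enrichment scores ~1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import GenomeAnnotation, SignalTrack


@dataclass
class Metaprofile:
    offsets: np.ndarray   # bp relative to TSS, strand-oriented
    mean: np.ndarray      # mean signal per offset (NaN where no data)
    n: np.ndarray         # contributing TSS count per offset

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean, "n": self.n})


@dataclass
class TssScore:
    library_id: str
    numerator: float      # mean per-base signal, pooled TSS +/- 100 bp
    denominator: float    # mean per-base signal, pooled background windows
    score: float
    n_tss_used: int
    n_tss_skipped: int
    signal_mode: str = "fragment-coverage"


def _oriented_positions(tss: int, strand: str, offsets: np.ndarray) -> np.ndarray:
    return tss + offsets if strand == "+" else tss - offsets


def tss_metaprofile(
    track: SignalTrack,
    annotation: GenomeAnnotation,
    flank: int = 500,
) -> Metaprofile:
    """Mean signal per strand-oriented offset around all TSSs.

    Offsets running off a replicon are excluded from the mean at that
    offset, not zero-filled.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if track.bin_size != 1:
        raise ValueError("tss_metaprofile expects a per-base track")
    tsses = annotation.tss_table()
    offsets = np.arange(-flank, flank + 1)
    total = np.zeros(len(offsets))
    n = np.zeros(len(offsets), dtype=int)
    any_used = False
    for row in tsses.itertuples():
        vals = track[row.replicon]
        pos = _oriented_positions(row.tss, row.strand, offsets)
        valid = (pos >= 0) & (pos < len(vals))
        if not valid.any():
            continue
        any_used = True
        total[valid] += vals[pos[valid]]
        n[valid] += 1
    if not any_used:
        raise ValueError("no TSS within usable range of the track")
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return Metaprofile(offsets=offsets, mean=mean, n=n)


def tss_ratio_score(
    track: SignalTrack,
    annotation: GenomeAnnotation,
    center_halfwidth: int = 100,
    background_distance: int = 2000,
    background_halfwidth: int = 50,
) -> TssScore:
    """Pooled-window TSS enrichment ratio.

    Numerator pools signal over ``[TSS - 100, TSS + 101)`` for every TSS;
    denominator pools the two 100-bp windows centered at +/- 2 kb.  A TSS
    whose background windows do not both fit inside its replicon is
    skipped entirely (and counted).
    """
    if track.bin_size != 1:
        raise ValueError("tss_ratio_score expects a per-base track")
    tsses = annotation.tss_table()
    num_sum = num_n = den_sum = den_n = 0.0
    used = skipped = 0
    for row in tsses.itertuples():
        vals = track[row.replicon]
        L = len(vals)
        t = row.tss
        windows = [
            (t - center_halfwidth, t + center_halfwidth + 1),
            (t - background_distance - background_halfwidth,
             t - background_distance + background_halfwidth),
            (t + background_distance - background_halfwidth,
             t + background_distance + background_halfwidth),
        ]
        if any(lo < 0 or hi > L for lo, hi in windows):
            skipped += 1
            continue
        used += 1
        (clo, chi), (b1lo, b1hi), (b2lo, b2hi) = windows
        num_sum += vals[clo:chi].sum()
        num_n += chi - clo
        den_sum += vals[b1lo:b1hi].sum() + vals[b2lo:b2hi].sum()
        den_n += (b1hi - b1lo) + (b2hi - b2lo)
    if used == 0:
        raise ValueError("no TSS with both background windows inside its replicon")
    numerator = num_sum / num_n
    denominator = den_sum / den_n
    if denominator == 0:
        raise ValueError("no background signal: TSS score denominator is zero")
    return TssScore(
        library_id=getattr(track, "library_id", "track"),
        numerator=numerator,
        denominator=denominator,
        score=numerator / denominator,
        n_tss_used=used,
        n_tss_skipped=skipped,
    )


def tss_heatmap(
    track: SignalTrack,
    annotation: GenomeAnnotation,
    flank: int = 500,
    ordering: str | Sequence[str] | None = None,
    order_signals: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """One strand-oriented row of signal per TSS, in the requested order.

    ``ordering`` is a sequence of gene ids, or a named rule (``"by-kas"``,
    ``"by-atac"``) resolved against ``order_signals`` (gene id -> value,
    sorted descending).  Offsets off the replicon are NaN.
    """
    if track.bin_size != 1:
        raise ValueError("tss_heatmap expects a per-base track")
    tsses = annotation.tss_table().set_index("gene_id")
    offsets = np.arange(-flank, flank + 1)
    if ordering is None:
        order = list(tsses.index)
    elif isinstance(ordering, str):
        key = ordering.removeprefix("by-")
        if order_signals is None or key not in order_signals:
            raise ValueError(f"named ordering {ordering!r} needs order_signals[{key!r}]")
        order = list(order_signals[key].sort_values(ascending=False).index)
    else:
        order = list(ordering)
    unknown = set(order) - set(tsses.index)
    if unknown:
        raise ValueError(f"ordering references unknown gene(s): {sorted(unknown)[:5]}")
    mat = np.full((len(order), len(offsets)), np.nan)
    for i, gid in enumerate(order):
        row = tsses.loc[gid]
        vals = track[row["replicon"]]
        pos = _oriented_positions(int(row["tss"]), row["strand"], offsets)
        valid = (pos >= 0) & (pos < len(vals))
        mat[i, valid] = vals[pos[valid]]
    return pd.DataFrame(mat, index=pd.Index(order, name="gene_id"), columns=offsets)
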