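"""Coverage tracks, fragment-length spectra, replicon copy number, GC bias.

Per-base occupancy counts every fragment overlapping a base; RPM scales raw
coverage by 1e6 / total fragment count pooled over all replicons (the
pooled convention matters on a genome where a small plasmid sits at ~26
copies per chromosome; a per-replicon variant is available via the
``per_replicon_rpm`` flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import FragmentSet, GenomeAnnotation, SignalTrack


@dataclass
class CopyNumberEstimate:
    """Per-replicon coverage ratios to a designated main replicon."""

    main: str
    per_replicate: pd.DataFrame   # replicon x replicate ratio matrix
    mean_ratio: pd.Series         # arithmetic mean over replicates

    def __getitem__(self, replicon: str) -> float:
        return float(self.mean_ratio[replicon])


@dataclass
class LengthHistogram:
    counts: pd.Series  # index = fragment length (bp)

    @property
    def mode(self) -> int:
        """Smallest length attaining the maximum count."""
        m = self.counts.max()
        return int(self.counts.index[self.counts == m].min())

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def coverage_track(
    fragments: FragmentSet,
    genome: GenomeAnnotation,
    bin_size: int = 1,
    normalization: str = "raw",
    per_replicon_rpm: bool = False,
    cutsites: bool = False,
) -> SignalTrack:
    """Fragment (or Tn5 cut-site) coverage on every replicon.

    Binned value is the mean per-base occupancy inside the bin; RPM
    multiplies raw coverage by 1e6 / total fragments.
    """
    if len(fragments) == 0:
        raise ValueError("empty fragment set")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    values: dict[str, np.ndarray] = {}
    counts = fragments.counts_per_replicon()
    total = len(fragments)
    for rep in genome.replicon_names:
        L = genome.replicon(rep).length
        depth = np.zeros(L + 1)
        starts, ends = fragments.on(rep)
        if len(starts):
            if cutsites:
                # the two Tn5 insertion points instead of the fragment body
                np.add.at(depth, starts, 1.0)
                np.add.at(depth, ends - 1, 1.0)
                np.add.at(depth, starts + 1, -1.0)
                np.add.at(depth, np.minimum(ends, L), -1.0)
            else:
                np.add.at(depth, starts, 1.0)
                np.add.at(depth, np.minimum(ends, L), -1.0)
        per_base = np.cumsum(depth[:-1])
        if bin_size == 1:
            binned = per_base
        else:
            n_bins = -(-L // bin_size)
            pad = n_bins * bin_size - L
            padded = np.concatenate([per_base, np.zeros(pad)])
            sums = padded.reshape(n_bins, bin_size).sum(axis=1)
            widths = np.full(n_bins, bin_size, dtype=float)
            if pad:
                widths[-1] = bin_size - pad
            binned = sums / widths
        if normalization == "RPM":
            denom = counts.get(rep, 0) if per_replicon_rpm else total
            if denom == 0:
                binned = np.zeros_like(binned)
            else:
                binned = binned * (1e6 / denom)
        values[rep] = binned
    return SignalTrack(values, bin_size=bin_size, normalization=normalization)


def fragment_length_histogram(fragments: FragmentSet) -> LengthHistogram:
    if len(fragments) == 0:
        raise ValueError("empty fragment set")
    counts = pd.Series(fragments.lengths).value_counts().sort_index()
    return LengthHistogram(counts)


def replicon_copy_number(
    naked_replicates: list[FragmentSet],
    genome: GenomeAnnotation,
    main: str,
) -> CopyNumberEstimate:
    """Copy number from naked-DNA tagmentation coverage.

    Per replicate: ratio(X) = (fragments on X / length X) over the same
    quantity on the main replicon; the final estimate is the arithmetic
    mean of per-replicate ratios.
    """
    if not naked_replicates:
        raise ValueError("need at least one replicate")
    genome.replicon(main)  # raises if absent
    lengths = {r.name: r.length for r in genome.replicons}
    cols = {}
    for i, frags in enumerate(naked_replicates, start=1):
        counts = frags.counts_per_replicon()
        if counts.get(main, 0) == 0:
            raise ValueError(f"replicate {i}: zero fragments on main replicon {main!r}")
        per_bp = {rep: counts.get(rep, 0) / lengths[rep] for rep in lengths}
        cols[f"rep{i}"] = pd.Series({rep: per_bp[rep] / per_bp[main] for rep in lengths})
    table = pd.DataFrame(cols).loc[list(lengths)]
    return CopyNumberEstimate(main=main, per_replicate=table,
                              mean_ratio=table.mean(axis=1))


def gc_signal_correlation(
    genome: GenomeAnnotation,
    track: SignalTrack,
    bin_size: int = 1000,
) -> tuple[pd.DataFrame, tuple[float, float], tuple[float, float]]:
    """Binned GC fraction vs mean signal; Pearson and Spearman with p-values.

    Bins containing N, or trailing bins shorter than ``bin_size``, are
    skipped.  Returns (table, (pearson_r, p), (spearman_rho, p)).
    """
    rows = []
    for rep in genome.replicon_names:
        seq = genome.replicon(rep).sequence
        if seq is None:
            continue
        vals = track[rep]
        if track.bin_size != 1:
            raise ValueError("gc_signal_correlation expects a per-base track")
        L = len(seq)
        for s in range(0, L - bin_size + 1, bin_size):
            chunk = seq[s : s + bin_size]
            if "N" in chunk:
                continue
            gc = (chunk.count("G") + chunk.count("C")) / bin_size
            rows.append((rep, s, s + bin_size, gc, float(vals[s : s + bin_size].mean())))
    table = pd.DataFrame(rows, columns=["replicon", "start", "end", "gc", "signal"])
    if len(table) < 3:
        raise ValueError("need at least 3 bins with defined GC")
    if table["gc"].nunique() == 1 or table["signal"].nunique() == 1:
        raise ValueError("correlation undefined: constant GC or constant signal")
    pr = stats.pearsonr(table["gc"], table["signal"])
    sr = stats.spearmanr(table["gc"], table["signal"])
    return table, (float(pr.statistic), float(pr.pvalue)), (float(sr.statistic), float(sr.pvalue))
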