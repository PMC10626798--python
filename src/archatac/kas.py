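"""ssDNA (KAS-type) transcription analysis: scaled gene-body metagenes,
promoter-proximal pausing ratios and operon coordination statistics.

Gene-body quantification uses fragment counts (not per-base coverage) so
units match the count-based differential module; densities are depth- and
copy-number-normalized so operons on polyploid plasmids are comparable to
chromosomal ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FragmentSet, Gene, GenomeAnnotation, PeakSet, SignalTrack


@dataclass
class MetageneProfile:
    positions: pd.DataFrame  # columns: segment (upstream|body|downstream), position, mean, n
    body_bins: int
    flank: int
    n_genes: int
    n_excluded: int          # genes shorter than min_gene_length


@dataclass
class OperonReport:
    operons: pd.DataFrame        # per-operon uniformity statistics and peak flags
    gene_densities: pd.DataFrame  # long-format per-gene normalized densities


def genebody_metaprofile(
    track: SignalTrack,
    annotation: GenomeAnnotation,
    flank: int = 500,
    body_bins: int = 50,
    min_gene_length: int = 300,
) -> MetageneProfile:
    """Strand-oriented metagene: unscaled flanks + gene body rescaled to B bins.

    Each gene body is split into ``body_bins`` equal subintervals and the
    per-base signal averaged within each; flank positions running off a
    replicon are excluded from the mean.
    """
    if body_bins < 10:
        raise ValueError("body_bins must be >= 10")
    if min_gene_length < body_bins:
        raise ValueError("min_gene_length must be >= body_bins")
    if track.bin_size != 1:
        raise ValueError("genebody_metaprofile expects a per-base track")
    genes = [g for g in annotation.genes if g.length >= min_gene_length]
    n_excluded = len(annotation.genes) - len(genes)
    if not genes:
        raise ValueError("no genes pass the minimum length filter")

    up_sum = np.zeros(flank)
    up_n = np.zeros(flank, dtype=int)
    dn_sum = np.zeros(flank)
    dn_n = np.zeros(flank, dtype=int)
    body_sum = np.zeros(body_bins)
    body_n = np.zeros(body_bins, dtype=int)

    for g in genes:
        vals = track[g.replicon]
        L = len(vals)
        # body, 5'->3'
        edges = np.linspace(g.start, g.end, body_bins + 1)
        lo = np.floor(edges[:-1]).astype(int)
        hi = np.ceil(edges[1:]).astype(int)
        means = np.array([vals[a:b].mean() for a, b in zip(lo, hi)])
        if g.strand == "-":
            means = means[::-1]
        body_sum += means
        body_n += 1
        # flanks, oriented: upstream offset -flank..-1, downstream +1..+flank
        if g.strand == "+":
            up_pos = g.start + np.arange(-flank, 0)
            dn_pos = g.end - 1 + np.arange(1, flank + 1)
        else:
            up_pos = g.end - 1 - np.arange(-flank, 0)
            dn_pos = g.start - np.arange(1, flank + 1)
        for pos, tot, cnt in ((up_pos, up_sum, up_n), (dn_pos, dn_sum, dn_n)):
            valid = (pos >= 0) & (pos < L)
            tot[valid] += vals[pos[valid]]
            cnt[valid] += 1

    rows = []
    for i, off in enumerate(range(-flank, 0)):
        m = up_sum[i] / up_n[i] if up_n[i] else np.nan
        rows.append(("upstream", off, m, up_n[i]))
    for b in range(body_bins):
        rows.append(("body", b, body_sum[b] / body_n[b], body_n[b]))
    for i, off in enumerate(range(1, flank + 1)):
        m = dn_sum[i] / dn_n[i] if dn_n[i] else np.nan
        rows.append(("downstream", off, m, dn_n[i]))
    positions = pd.DataFrame(rows, columns=["segment", "position", "mean", "n"])
    return MetageneProfile(positions, body_bins, flank, len(genes), n_excluded)


def promoter_proximal_ratio(
    track: SignalTrack,
    gene: Gene,
    tss_window: int = 50,
    body_offset: int = 250,
) -> float:
    """Mean signal in [TSS, TSS+w) over mean signal in the distal gene body.

    Returns NaN (flagged undefined) when the body has zero signal.
    """
    if gene.length <= body_offset:
        raise ValueError(
            f"gene {gene.gene_id!r} ({gene.length} bp) shorter than body_offset"
        )
    if track.bin_size != 1:
        raise ValueError("promoter_proximal_ratio expects a per-base track")
    vals = track[gene.replicon]
    if gene.strand == "+":
        tss_vals = vals[gene.tss : gene.tss + tss_window]
        body_vals = vals[gene.tss + body_offset : gene.end]
    else:
        tss_vals = vals[gene.tss - tss_window + 1 : gene.tss + 1]
        body_vals = vals[gene.start : gene.tss - body_offset + 1]
    body_mean = float(body_vals.mean())
    if body_mean == 0:
        return float("nan")
    return float(tss_vals.mean()) / body_mean


def operon_coordination(
    kas_fragments: FragmentSet,
    annotation: GenomeAnnotation,
    peaks: PeakSet | None = None,
    copy_weights: dict[str, float] | None = None,
    interior_margin: int = 100,
    start_tolerance: int = 150,
) -> OperonReport:
    """Per-operon transcription uniformity and internal-peak flags.

    Per-gene density = fragment midpoints in the gene / gene length,
    divided by library depth (per million) and replicon copy weight.
    A peak is "internal" when its summit lies >= ``interior_margin`` bp
    inside the operon span and within ``start_tolerance`` bp of the TSS
    of a non-first gene (in transcription order).
    """
    ops = {op: genes for op, genes in annotation.operons().items() if len(genes) >= 2}
    if not ops:
        raise ValueError("no operons with >= 2 genes")
    depth = len(kas_fragments) / 1e6
    if depth == 0:
        raise ValueError("empty fragment set")
    weights = copy_weights or {}
    mids_cache: dict[str, np.ndarray] = {}

    def mids(rep: str) -> np.ndarray:
        if rep not in mids_cache:
            starts, ends = kas_fragments.on(rep)
            mids_cache[rep] = np.sort((starts + ends) // 2)
        return mids_cache[rep]

    gene_rows = []
    op_rows = []
    for op, genes in ops.items():
        rep = genes[0].replicon
        cw = weights.get(rep, 1.0)
        m = mids(rep)
        dens = []
        for g in genes:
            k = int(np.searchsorted(m, g.end) - np.searchsorted(m, g.start))
            d = k / g.length / depth / cw
            dens.append(d)
            gene_rows.append((op, g.gene_id, g.start, g.end, g.strand, k, d))
        dens_arr = np.array(dens)
        cv = float(dens_arr.std(ddof=1) / dens_arr.mean()) if dens_arr.mean() > 0 else np.nan
        ratio = float(dens_arr.max() / dens_arr.min()) if dens_arr.min() > 0 else np.inf
        span_lo, span_hi = genes[0].start, genes[-1].end
        # transcription order: reverse coordinate order for - strand operons
        ordered = genes if genes[0].strand == "+" else genes[::-1]
        internal_tss = [g.tss for g in ordered[1:]]
        flag = False
        flagged_gene = None
        min_dist = np.nan
        if peaks is not None and len(peaks):
            prec = peaks.records[peaks.records["replicon"] == rep]
            for p in prec.itertuples():
                if not (span_lo + interior_margin <= p.summit < span_hi - interior_margin):
                    continue
                for g, t in zip(ordered[1:], internal_tss):
                    d = abs(p.summit - t)
                    if d <= start_tolerance:
                        flag = True
                        if not (d >= min_dist):  # also handles NaN
                            min_dist = d
                            flagged_gene = g.gene_id
        op_rows.append((op, rep, len(genes), span_lo, span_hi,
                        cv, ratio, flag, flagged_gene, min_dist))
    operons = pd.DataFrame(op_rows, columns=[
        "operon", "replicon", "n_genes", "start", "end",
        "cv", "max_min_ratio", "internal_peak", "internal_gene", "summit_to_start",
    ])
    gene_densities = pd.DataFrame(gene_rows, columns=[
        "operon", "gene_id", "start", "end", "strand", "count", "density",
    ])
    return OperonReport(operons, gene_densities)
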