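"""Local-background Poisson peak calling and peak-TSS classification.

A sliding window of width ``w`` and step ``s`` counts fragment midpoints;
the expected count lambda is the maximum of a genome-wide rate (optionally
weighted by replicon copy number so polyploid plasmids are not wall-to-wall
peaks), local 1 kb / 10 kb rates, a control-derived rate when a naked-DNA
control is supplied, and a floor of 0.1.  Window p-values come from the
Poisson upper tail; significant windows are merged into peaks and BH
q-values are computed across all tested windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .types import FragmentSet, GenomeAnnotation, PeakSet, SignalTrack
from .tracks import coverage_track

LAMBDA_FLOOR = 0.1


def poisson_tail(k: int | np.ndarray, lam: float | np.ndarray) -> np.ndarray:
    """Upper-tail P(Poisson(lam) >= k); k = 0 gives exactly 1."""
    return stats.poisson.sf(np.asarray(k) - 1, lam)


def _midpoints(fragments: FragmentSet, rep: str) -> np.ndarray:
    starts, ends = fragments.on(rep)
    return np.sort((starts + ends) // 2)


def _window_counts(mids: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.searchsorted(mids, hi) - np.searchsorted(mids, lo)


def window_scan(
    treatment: FragmentSet,
    genome: GenomeAnnotation,
    control: FragmentSet | None = None,
    w: int = 150,
    s: int = 50,
    copy_weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-window counts, background rate and Poisson p over all replicons."""
    if not (w >= s >= 1):
        raise ValueError("need w >= s >= 1")
    min_rep = min(r.length for r in genome.replicons)
    if w > min_rep:
        raise ValueError(f"window {w} larger than smallest replicon ({min_rep} bp)")
    n_total = len(treatment)
    weights = {r.name: (copy_weights or {}).get(r.name, 1.0) for r in genome.replicons}
    weighted_len = sum(r.length * weights[r.name] for r in genome.replicons)
    n_ctrl = len(control) if control is not None else 0

    frames = []
    for r in genome.replicons:
        L = r.length
        starts = np.arange(0, L - w + 1, s)
        mids = _midpoints(treatment, r.name)
        k = _window_counts(mids, starts, starts + w)
        center = starts + w // 2
        lam_genome = n_total * w * weights[r.name] / weighted_len
        lam = np.full(len(starts), lam_genome)
        for span in (1_000, 10_000):
            if span >= w:
                lo = np.maximum(center - span // 2, 0)
                hi = np.minimum(center + span // 2, L)
                local = _window_counts(mids, lo, hi) * (w / (hi - lo))
                lam = np.maximum(lam, local)
        if control is not None and n_ctrl > 0:
            cmids = _midpoints(control, r.name)
            depth = n_total / n_ctrl
            for span in (w, 1_000, 10_000):
                lo = np.maximum(center - span // 2, 0)
                hi = np.minimum(center + span // 2, L)
                cexp = _window_counts(cmids, lo, hi) * (w / (hi - lo)) * depth
                lam = np.maximum(lam, cexp)
        lam = np.maximum(lam, LAMBDA_FLOOR)
        p = poisson_tail(k, lam)
        frames.append(pd.DataFrame(
            {"replicon": r.name, "start": starts, "end": starts + w,
             "k": k, "lam": lam, "p": p}))
    scan = pd.concat(frames, ignore_index=True)
    scan["q"] = bh_fdr(scan["p"].to_numpy())
    return scan


def call_peaks(
    treatment: FragmentSet,
    genome: GenomeAnnotation,
    control: FragmentSet | None = None,
    w: int = 150,
    s: int = 50,
    p_cutoff: float = 1e-4,
    merge_dist: int = 100,
    min_width: int = 75,
    q_cutoff: float | None = 0.05,
    copy_weights: dict[str, float] | None = None,
) -> PeakSet:
    """Merge significant scan windows into peaks with summits.

    Peak p (and q) is the minimum over merged windows; the summit is the
    leftmost position of maximal treatment coverage inside the peak.
    """
    scan = window_scan(treatment, genome, control, w, s, copy_weights)
    sig = scan[scan["p"] <= p_cutoff]
    cov = coverage_track(treatment, genome) if len(sig) else None
    rows = []
    for rep, grp in sig.groupby("replicon", sort=False):
        grp = grp.sort_values("start")
        cur: dict | None = None
        blocks = []
        for rec in grp.itertuples():
            if cur is not None and rec.start - cur["end"] <= merge_dist:
                cur["end"] = max(cur["end"], rec.end)
                cur["p"] = min(cur["p"], rec.p)
                cur["q"] = min(cur["q"], rec.q)
            else:
                if cur is not None:
                    blocks.append(cur)
                cur = {"start": rec.start, "end": rec.end, "p": rec.p, "q": rec.q}
        if cur is not None:
            blocks.append(cur)
        for b in blocks:
            if b["end"] - b["start"] < min_width:
                continue
            if q_cutoff is not None and b["q"] > q_cutoff:
                continue
            seg = cov[rep][b["start"] : b["end"]]
            summit = b["start"] + int(np.argmax(seg))  # leftmost maximum
            score = float(-np.log10(max(b["p"], 1e-300)))
            rows.append((rep, b["start"], b["end"], summit, score, b["p"], b["q"]))
    df = pd.DataFrame(rows, columns=list(PeakSet.COLUMNS))
    return PeakSet(df)


def peak_tss_distances(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    within: int = 200,
) -> tuple[pd.DataFrame, float]:
    """Signed summit-to-nearest-TSS distance and the fraction within ``within``.

    Distance is oriented by the nearest gene's strand: negative = upstream
    of the TSS.  Peaks on replicons without genes get a missing distance
    and are excluded from the fraction.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks")
    tsses = annotation.tss_table()
    if len(tsses) == 0:
        raise ValueError("no TSSs")
    rows = []
    for rec in peaks.records.itertuples():
        sub = tsses[tsses["replicon"] == rec.replicon]
        if len(sub) == 0:
            rows.append((rec.replicon, rec.summit, None, np.nan))
            continue
        d_abs = (sub["tss"] - rec.summit).abs()
        j = d_abs.idxmin()
        gene = tsses.loc[j]
        signed = rec.summit - gene["tss"]
        if gene["strand"] == "-":
            signed = -signed
        rows.append((rec.replicon, rec.summit, gene["gene_id"], float(signed)))
    df = pd.DataFrame(rows, columns=["replicon", "summit", "nearest_gene", "distance"])
    have = df["distance"].dropna()
    frac = float((have.abs() <= within).mean()) if len(have) else float("nan")
    return df, frac


def region_signal(
    track: SignalTrack,
    regions: pd.DataFrame,
) -> pd.DataFrame:
    """Mean per-base signal per region (columns: replicon, start, end[, name])."""
    if track.bin_size != 1:
        raise ValueError("region_signal expects a per-base track")
    out = []
    for i, rec in enumerate(regions.itertuples()):
        if rec.end <= rec.start:
            raise ValueError(f"empty region at row {i}")
        vals = track[rec.replicon][rec.start : rec.end]
        name = getattr(rec, "name_", None) or getattr(rec, "name", None)
        if not isinstance(name, str):
            name = f"region_{i + 1}"
        out.append((name, rec.replicon, rec.start, rec.end, float(vals.mean())))
    return pd.DataFrame(out, columns=["name", "replicon", "start", "end", "mean_signal"])
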