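"""Single-molecule footprinting: protection matrices, absolute protection,
protection metaprofiles and the upstream-of-TSS footprint detector.

Methylated sites are accessible, unmethylated sites are protected.  The
default context is GpC only ("NOMe mode"); dSMF mode adds CpG.  Absolute
protection is pooled over calls (a bulk "fraction of sites protected"
reading); a per-molecule average is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tss import Metaprofile
from .types import GenomeAnnotation, MethylCallTable

NO_DATA, PROTECTED, ACCESSIBLE = -1, 1, 0


@dataclass
class MoleculeMatrix:
    replicon: str
    start: int
    end: int
    sites: np.ndarray      # ordered site positions
    matrix: np.ndarray     # molecules x sites, entries {-1 no-data, 1 protected, 0 accessible}
    molecule_ids: list[str]

    def per_site_methylated_fraction(self) -> np.ndarray:
        informative = self.matrix != NO_DATA
        acc = (self.matrix == ACCESSIBLE) & informative
        with np.errstate(invalid="ignore"):
            return acc.sum(axis=0) / informative.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.molecule_ids, columns=self.sites)


@dataclass
class ProtectionEstimate:
    condition: str
    n_informative: int
    n_protected: int
    fraction: float
    ci_low: float
    ci_high: float
    mode: str = "call-pooled"


@dataclass
class FootprintCall:
    interval: tuple[int, int]   # offsets relative to TSS
    mean_protection: float
    baseline: float
    elevation: float
    p_value: float


def build_molecule_matrix(
    calls: MethylCallTable,
    region: tuple[str, int, int],
    min_sites: int = 1,
) -> MoleculeMatrix:
    """Molecules x sites protection matrix over a genomic region.

    Keeps molecules overlapping the region with at least ``min_sites``
    informative sites inside it; entries are no-data exactly where the
    site lies outside the molecule's fragment.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    rep, lo, hi = region
    df = calls.records
    in_region = (df["replicon"] == rep) & (df["pos"] >= lo) & (df["pos"] < hi)
    sub = df[in_region]
    counts = sub.groupby("molecule_id").size()
    keep = counts[counts >= min_sites].index
    if len(keep) == 0:
        raise ValueError("no molecules with enough informative sites in region")
    sub = sub[sub["molecule_id"].isin(keep)]
    sites = np.sort(sub["pos"].unique())
    site_idx = {p: i for i, p in enumerate(sites)}
    mol_ids = sorted(keep)
    mol_idx = {m: i for i, m in enumerate(mol_ids)}
    # sites outside a molecule's fragment (or uncalled within it) stay no-data
    mat = np.full((len(mol_ids), len(sites)), NO_DATA, dtype=np.int8)
    for rec in sub.itertuples():
        mat[mol_idx[rec.molecule_id], site_idx[rec.pos]] = (
            ACCESSIBLE if rec.methylated else PROTECTED
        )
    return MoleculeMatrix(rep, lo, hi, sites, mat, mol_ids)


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    phat = k / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))


def absolute_protection(
    calls: MethylCallTable,
    contexts: tuple[str, ...] = ("GpC",),
    min_sites_per_molecule: int = 3,
    per_molecule: bool = False,
    condition: str = "",
) -> ProtectionEstimate:
    """Fraction of informative sites left unmethylated (= protected).

    Pools calls over molecules passing the per-molecule site filter;
    Wilson 95% CI.  ``per_molecule=True`` instead averages per-molecule
    protected fractions (CI then from the molecule-level SE).
    """
    df = calls.records[calls.records["context"].isin(contexts)]
    counts = df.groupby("molecule_id").size()
    keep = counts[counts >= min_sites_per_molecule].index
    df = df[df["molecule_id"].isin(keep)]
    n = len(df)
    if n == 0:
        raise ValueError("zero informative calls after filtering")
    k = int((~df["methylated"]).sum())
    if per_molecule:
        frac_mol = df.groupby("molecule_id")["methylated"].apply(lambda s: 1 - s.mean())
        frac = float(frac_mol.mean())
        se = float(frac_mol.std(ddof=1) / np.sqrt(len(frac_mol))) if len(frac_mol) > 1 else 0.0
        lo, hi = max(frac - 1.96 * se, 0.0), min(frac + 1.96 * se, 1.0)
        return ProtectionEstimate(condition, n, k, frac, lo, hi, mode="molecule-averaged")
    lo, hi = _wilson_ci(k, n)
    return ProtectionEstimate(condition, n, k, k / n, lo, hi)


def protection_metaprofile(
    calls: MethylCallTable,
    annotation: GenomeAnnotation,
    flank: int = 200,
    contexts: tuple[str, ...] = ("GpC",),
    min_calls: int = 20,
) -> Metaprofile:
    """Pooled protected fraction per strand-oriented offset around TSSs.

    Offsets with fewer than ``min_calls`` informative calls are masked
    (NaN in the profile).
    """
    tsses = annotation.tss_table()
    df = calls.records[calls.records["context"].isin(contexts)]
    offsets = np.arange(-flank, flank + 1)
    prot = np.zeros(len(offsets))
    tot = np.zeros(len(offsets))
    for row in tsses.itertuples():
        sub = df[(df["replicon"] == row.replicon)
                 & (df["pos"] >= row.tss - flank)
                 & (df["pos"] <= row.tss + flank)]
        if len(sub) == 0:
            continue
        off = sub["pos"].to_numpy() - row.tss
        if row.strand == "-":
            off = -off
        idx = off + flank
        np.add.at(tot, idx, 1)
        np.add.at(prot, idx, (~sub["methylated"].to_numpy()).astype(float))
    mask = tot >= min_calls
    if not mask.any():
        raise ValueError("all metaprofile offsets masked (too few calls)")
    mean = np.where(mask, np.divide(prot, np.maximum(tot, 1)), np.nan)
    return Metaprofile(offsets=offsets, mean=mean, n=tot.astype(int))


def detect_upstream_footprint(
    metaprofile: Metaprofile,
    search_window: tuple[int, int] = (-100, 0),
    flank_window: tuple[tuple[int, int], ...] = ((-200, -100), (0, 100)),
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> FootprintCall | None:
    """Detect a run of elevated protection upstream of the TSS.

    The candidate is the maximal run of search-window offsets whose
    protection exceeds the flank baseline plus twice its binomial SE; the
    empirical p-value permutes offset labels within the search+flank range.
    Returns None when nothing beats the permutation null at ``alpha``.
    """
    offs = metaprofile.offsets
    mean = metaprofile.mean
    n = metaprofile.n
    s_lo, s_hi = search_window
    in_search = (offs >= s_lo) & (offs < s_hi)
    in_flank = np.zeros_like(in_search)
    for lo, hi in flank_window:
        in_flank |= (offs >= lo) & (offs < hi)
    valid = ~np.isnan(mean)
    if not (in_search & valid).any():
        raise ValueError("profile masked over the entire search window")
    flank_vals = mean[in_flank & valid]
    flank_n = n[in_flank & valid]
    if len(flank_vals) == 0:
        raise ValueError("profile masked over the entire flank window")
    baseline = float(np.average(flank_vals, weights=np.maximum(flank_n, 1)))
    se = float(np.sqrt(baseline * (1 - baseline) / max(flank_n.sum(), 1)))
    threshold = baseline + 2 * se

    def best_run(values: np.ndarray, offsets: np.ndarray) -> tuple[float, tuple[int, int] | None]:
        best, best_iv = 0.0, None
        i = 0
        while i < len(values):
            if not np.isnan(values[i]) and values[i] > threshold:
                j = i
                while j + 1 < len(values) and not np.isnan(values[j + 1]) and values[j + 1] > threshold:
                    j += 1
                stat = float(np.nansum(values[i : j + 1] - baseline))
                if stat > best:
                    best, best_iv = stat, (int(offsets[i]), int(offsets[j]) + 1)
                i = j + 1
            else:
                i += 1
        return best, best_iv

    search_vals = mean[in_search]
    search_offs = offs[in_search]
    obs_stat, obs_iv = best_run(search_vals, search_offs)
    if obs_iv is None:
        return None

    rng = np.random.default_rng(seed)
    pool_idx = np.nonzero((in_search | in_flank) & valid)[0]
    pool_vals = mean[pool_idx]
    n_search = int(in_search.sum())
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pool_vals)
        stat, _ = best_run(perm[:n_search], search_offs)
        if stat >= obs_stat:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    if p > alpha:
        return None
    iv_mask = (offs >= obs_iv[0]) & (offs < obs_iv[1]) & valid
    mean_inside = float(np.nanmean(mean[iv_mask]))
    return FootprintCall(
        interval=obs_iv,
        mean_protection=mean_inside,
        baseline=baseline,
        elevation=mean_inside - baseline,
        p_value=float(p),
    )
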