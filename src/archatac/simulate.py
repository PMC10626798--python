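"""Synthetic multi-replicon assay simulator.

Generates a small genome with the structural features the downstream
analyses assume — a main chromosome plus plasmids at unequal copy number,
genes organised into unidirectional operons, a CRISPR-like locus on a
plasmid — and simulates four assay read-outs over it:

* naked-DNA tagmentation (coverage proportional to copy number only),
* ATAC with promoter-localised accessibility, a unimodal ~95 bp
  fragment-length model and GC-dependent insertion bias,
* KAS-type ssDNA reads with promoter-proximal pausing, gene-body signal,
  operon-internal initiation and a dormant-culture single-locus peak,
* single-molecule methylation footprinting with per-condition per-site
  accessibility and a small occupied footprint upstream of TSSs.

Every generative parameter consumed by a downstream recovery test is
recorded in :class:`SimTruth`.  All entry points are deterministic for a
fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .types import FragmentSet, Gene, GenomeAnnotation, MethylCallTable, Replicon

_BASES_GC = np.array([b"G", b"C"])
_BASES_AT = np.array([b"A", b"T"])


@dataclass
class SimTruth:
    """Realized generative parameters, the single source for recovery tests."""

    copy_numbers: dict[str, float]
    accessibility: dict[str, float]              # per-gene, shared across conditions
    kas_rates: dict[str, dict[str, float]]       # condition -> gene -> rate
    changed_genes: list[str]                     # genes with altered KAS rate
    protection: dict[str, float]                 # condition -> true protected fraction
    footprint_window: tuple[int, int]            # oriented, relative to TSS; stand-in width
    footprint_occupancy: float                   # stand-in value, not paper-quantified
    footprint_leak: float
    crispr_peak_window: tuple[str, int, int]     # dormant-condition ssDNA peak
    internal_start_genes: dict[str, str]         # operon id -> internal-TSS gene

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _draw_fragment_lengths(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Discretized log-normal lengths parameterized by mode; truncated support."""
    sig = cfg.frag_len_log_sd
    mu = np.log(cfg.frag_len_mode) + sig * sig  # continuous mode at frag_len_mode
    x = rng.lognormal(mu, sig, n)
    return np.clip(np.rint(x).astype(np.int64), cfg.frag_len_min, cfg.frag_len_max)


def simulate_genome(config: SimConfig, seed: int) -> tuple[GenomeAnnotation, SimTruth]:
    """Generate replicon sequences, gene/operon annotation and ground truth."""
    rng = np.random.default_rng(seed)
    names = list(config.replicon_names)
    lengths = list(config.replicon_lengths)
    n_rep = len(names)

    # -- assign gene counts proportional to replicon length ----------------
    total_len = sum(lengths)
    targets = [int(round(config.n_genes * L / total_len)) for L in lengths]
    drift = config.n_genes - sum(targets)
    targets[0] += drift

    genes: list[Gene] = []
    gene_spans: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    operon_counter = 0
    gene_counter = 0
    crispr_rep = names[config.crispr_replicon_index] if config.n_genes > 0 else None
    crispr_seq_region: tuple[str, int, int] | None = None
    crispr_peak_window: tuple[str, int, int] | None = None

    budget_spill = 0
    for ri, (rep_name, L) in enumerate(zip(names, lengths)):
        budget = targets[ri] + budget_spill
        budget_spill = 0
        pos = 200
        # reserve the CRISPR-like locus at the start of its replicon
        if crispr_rep == rep_name:
            array_len = config.crispr_n_repeats * (
                config.crispr_repeat_length + config.crispr_spacer_length
            )
            a_start = 1_000
            a_end = a_start + array_len
            crispr_seq_region = (rep_name, a_start, a_end)
            cas_start = a_end + config.crispr_peak_width
            cas_end = cas_start + 800
            if cas_end + 200 > L:
                raise ValueError("infeasible packing: CRISPR locus exceeds replicon")
            genes.append(Gene("cas_like", rep_name, cas_start, cas_end, "+", None))
            gene_spans[rep_name].append((a_start, cas_end))
            crispr_peak_window = (rep_name, a_end, cas_start)
            pos = cas_end + 300
            budget = max(budget - 1, 0)
        while budget > 0:
            op_size = min(
                1 + rng.choice(len(config.operon_size_probs), p=config.operon_size_probs),
                budget,
            )
            strand = "+" if rng.random() < 0.5 else "-"
            glens = np.clip(
                np.rint(rng.lognormal(config.gene_length_log_mean,
                                      config.gene_length_log_sd, op_size)).astype(int),
                config.min_gene_length, None,
            )
            gaps = rng.integers(*config.operon_gap_range, size=op_size)
            span = int(glens.sum() + gaps[:-1].sum()) if op_size > 1 else int(glens[0])
            if pos + span > L - 200:
                budget_spill += budget
                break
            op_id = None
            if op_size > 1:
                operon_counter += 1
                op_id = f"op{operon_counter}"
            p = pos
            for k in range(op_size):
                gene_counter += 1
                g = Gene(f"g{gene_counter:04d}", rep_name, p, p + int(glens[k]), strand, op_id)
                genes.append(g)
                gene_spans[rep_name].append((g.start, g.end))
                p = g.end + int(gaps[k]) if k < op_size - 1 else g.end
            budget -= op_size
            pos = p + int(rng.integers(*config.intergenic_gap_range))
    if budget_spill > 0:
        raise ValueError(
            f"infeasible packing: {budget_spill} genes do not fit the replicons"
        )

    # -- sequence with GC structure ----------------------------------------
    replicons: list[Replicon] = []
    for rep_name, L in zip(names, lengths):
        gc = np.full(L, config.gc_intergenic)
        for s, e in gene_spans[rep_name]:
            gc[s:e] = config.gc_genic
        # AT-rich promoter elements around each TSS
        hw = config.promoter_halfwidth
        for g in genes:
            if g.replicon == rep_name:
                gc[max(g.tss - hw, 0): min(g.tss + hw + 1, L)] = config.gc_promoter
        if rep_name == config.main:
            for _ in range(config.n_gc_patches):
                s = int(rng.integers(0, max(L - config.gc_patch_length, 1)))
                gc[s : s + config.gc_patch_length] = config.gc_patch
        is_gc = rng.random(L) < gc
        pick = rng.integers(0, 2, L)
        seq_arr = np.where(is_gc, _BASES_GC[pick], _BASES_AT[pick])
        seq = seq_arr.tobytes().decode()
        if crispr_seq_region is not None and crispr_seq_region[0] == rep_name:
            _, a_start, a_end = crispr_seq_region
            unit_r = "".join(rng.choice(list("ACGT"), config.crispr_repeat_length))
            parts = []
            for _ in range(config.crispr_n_repeats):
                parts.append(unit_r)
                parts.append("".join(rng.choice(list("ACGT"), config.crispr_spacer_length)))
            array_seq = "".join(parts)[: a_end - a_start]
            seq = seq[:a_start] + array_seq + seq[a_end:]
        replicons.append(Replicon(rep_name, L, seq))

    annotation = GenomeAnnotation(replicons, genes)

    # -- latent per-gene parameters ----------------------------------------
    gene_ids = [g.gene_id for g in genes]
    accessibility = {
        gid: float(v)
        for gid, v in zip(gene_ids, rng.lognormal(0.0, config.accessibility_log_sd, len(genes)))
    }

    # -- internal operon starts ---------------------------------------------
    internal: dict[str, str] = {}
    multi_ops = [op for op, members in annotation.operons().items() if len(members) >= 2]
    n_flag = 0
    if multi_ops and config.internal_start_fraction > 0:
        n_flag = max(1, int(round(config.internal_start_fraction * len(multi_ops))))
    for op in sorted(rng.choice(multi_ops, size=n_flag, replace=False).tolist()) if n_flag else []:
        members = annotation.operons()[op]
        if members[0].strand == "-":
            members = members[::-1]  # transcription order
        pick_idx = int(rng.integers(1, len(members)))
        internal[op] = members[pick_idx].gene_id

    # -- transcription rates: one rate per transcription unit ---------------
    # co-transcribed operon members share their unit's rate; at a flagged
    # internal start the downstream members switch to an independently
    # boosted rate, emulating internal initiation
    units: list[list[str]] = [[g.gene_id] for g in genes if g.operon is None]
    for op, members in annotation.operons().items():
        ordered = members if members[0].strand == "+" else members[::-1]
        ids = [g.gene_id for g in ordered]
        if op in internal:
            cut = ids.index(internal[op])
            units.append(ids[:cut])
            units.append(ids[cut:])
        else:
            units.append(ids)
    units = [u for u in units if u]
    unit_rates = rng.lognormal(0.0, config.kas_rate_log_sd, len(units))
    exp_rates: dict[str, float] = {}
    internal_gene_ids = set(internal.values())
    for u, r in zip(units, unit_rates):
        boost = config.internal_start_boost if u[0] in internal_gene_ids else 1.0
        for gid in u:
            exp_rates[gid] = float(r * boost)

    # condition shifts act on whole transcription units
    unit_order = rng.permutation(len(units))
    changed: list[str] = []
    target = config.kas_changed_fraction * len(genes)
    changed_units = []
    for ui in unit_order:
        if len(changed) >= target:
            break
        changed_units.append(ui)
        changed.extend(units[ui])
    changed = sorted(changed)
    sta_rates = dict(exp_rates)
    signs = rng.choice([-1.0, 1.0], size=len(changed_units))
    for ui, s in zip(changed_units, signs):
        for gid in units[ui]:
            sta_rates[gid] = exp_rates[gid] * 2.0 ** (s * config.kas_change_log2fc)
    dormant_rates = {gid: config.dormant_rate for gid in gene_ids}
    kas_rates: dict[str, dict[str, float]] = {"dormant": dormant_rates}
    for cond in config.accessibility_prob:
        kas_rates[cond] = exp_rates if cond == "exponential" else sta_rates

    if crispr_peak_window is None:
        crispr_peak_window = (names[config.crispr_replicon_index], 1000,
                              1000 + config.crispr_peak_width)

    truth = SimTruth(
        copy_numbers=dict(zip(names, map(float, config.copy_numbers))),
        accessibility=accessibility,
        kas_rates=kas_rates,
        changed_genes=list(changed),
        protection={c: 1.0 - p for c, p in config.accessibility_prob.items()},
        footprint_window=tuple(config.footprint_window),
        footprint_occupancy=config.footprint_occupancy,
        footprint_leak=config.footprint_leak,
        crispr_peak_window=crispr_peak_window,
        internal_start_genes=internal,
    )
    return annotation, truth


class Simulation:
    """A genome realized from a config, with assay simulators over it.

    The genome is a deterministic function of the config (via
    ``config.genome_seed``); per-assay seeds only drive the sampling noise,
    so replicate libraries share one genome and one ground truth.
    """

    def __init__(self, config: SimConfig | None = None) -> None:
        self.config = config or SimConfig()
        self.genome, self.truth = simulate_genome(self.config, self.config.genome_seed)
        self._gc_local: dict[str, np.ndarray] = {}
        self._sites: dict[tuple[str, str], np.ndarray] = {}
        self._atac_weights: dict[str, np.ndarray] | None = None
        self._footprints: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # ------------------------------------------------------------------ utils
    def _seq_array(self, rep: str) -> np.ndarray:
        seq = self.genome.replicon(rep).sequence
        return np.frombuffer(seq.encode(), dtype="S1")

    def gc_local(self, rep: str) -> np.ndarray:
        """Rolling local GC fraction (window from config), edge-corrected."""
        if rep not in self._gc_local:
            arr = self._seq_array(rep)
            is_gc = ((arr == b"G") | (arr == b"C")).astype(float)
            w = self.config.gc_bias_window
            cs = np.concatenate([[0.0], np.cumsum(is_gc)])
            L = len(is_gc)
            idx = np.arange(L)
            lo = np.maximum(idx - w // 2, 0)
            hi = np.minimum(idx + w // 2 + 1, L)
            self._gc_local[rep] = (cs[hi] - cs[lo]) / (hi - lo)
        return self._gc_local[rep]

    def context_sites(self, rep: str, context: str) -> np.ndarray:
        """Positions of methylatable cytosines: the C of GpC or CpG."""
        key = (rep, context)
        if key not in self._sites:
            arr = self._seq_array(rep)
            gpc = np.nonzero((arr[:-1] == b"G") & (arr[1:] == b"C"))[0] + 1
            cpg = np.nonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))[0]
            # GCG cytosines are in both contexts at once; exclude as ambiguous
            amb = np.intersect1d(gpc, cpg)
            if context == "GpC":
                pos = np.setdiff1d(gpc, amb)
            elif context == "CpG":
                pos = np.setdiff1d(cpg, amb)
            else:
                raise ValueError(f"unknown context {context!r}")
            self._sites[key] = pos
        return self._sites[key]

    def _sample_positions(
        self, rng: np.random.Generator, weights: dict[str, np.ndarray], n: int
    ) -> pd.DataFrame:
        """Draw n genomic positions with per-base probability ∝ weights."""
        names = list(weights)
        totals = np.array([weights[r].sum() for r in names])
        counts = rng.multinomial(n, totals / totals.sum())
        frames = []
        for rep, k in zip(names, counts):
            if k == 0:
                continue
            w = weights[rep]
            p = w / w.sum()
            pos = rng.choice(len(w), size=k, p=p)
            frames.append(pd.DataFrame({"replicon": rep, "pos": np.sort(pos)}))
        return pd.concat(frames, ignore_index=True)

    def _positions_to_fragments(
        self, rng: np.random.Generator, mid: pd.DataFrame, lengths: np.ndarray
    ) -> pd.DataFrame:
        rep_len = {r.name: r.length for r in self.genome.replicons}
        L = mid["replicon"].map(rep_len).to_numpy()
        start = mid["pos"].to_numpy() - lengths // 2
        start = np.clip(start, 0, np.maximum(L - lengths, 0))
        end = np.minimum(start + lengths, L)
        return pd.DataFrame({"replicon": mid["replicon"], "start": start, "end": end})

    # ----------------------------------------------------------------- naked
    def naked(self, n_fragments: int, seed: int, replicate: int = 1) -> FragmentSet:
        """Tagmented naked genomic DNA: coverage ∝ replicon copy number only."""
        if n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        rng = np.random.default_rng(seed)
        # per-replicon weight ∝ length x copy number; uniform within replicon
        names = [r.name for r in self.genome.replicons]
        totals = np.array(
            [self.genome.replicon(r).length * self.truth.copy_numbers[r] for r in names]
        )
        counts = rng.multinomial(n_fragments, totals / totals.sum())
        frames = []
        for rep, k in zip(names, counts):
            if k == 0:
                continue
            L = self.genome.replicon(rep).length
            lengths = _draw_fragment_lengths(rng, self.config, k)
            start = rng.integers(0, np.maximum(L - lengths, 1))
            frames.append(pd.DataFrame(
                {"replicon": rep, "start": start,
                 "end": np.minimum(start + lengths, L)}))
        df = pd.concat(frames, ignore_index=True)
        return FragmentSet(df, library_id=f"naked_r{replicate}", assay="naked",
                           condition="none", replicate=replicate)

    # ------------------------------------------------------------------ ATAC
    def atac_insertion_weights(self) -> dict[str, np.ndarray]:
        """Per-base Tn5 insertion weight: copy x (background + promoter) x GC bias."""
        if self._atac_weights is not None:
            return self._atac_weights
        cfg = self.config
        genome_gc = np.mean(np.concatenate(
            [self.gc_local(r.name) for r in self.genome.replicons]))
        weights = {}
        for r in self.genome.replicons:
            w = np.full(r.length, cfg.atac_background)
            for g in self.genome.genes_on(r.name):
                lo = max(g.tss - cfg.promoter_halfwidth, 0)
                hi = min(g.tss + cfg.promoter_halfwidth + 1, r.length)
                w[lo:hi] += cfg.atac_enrichment * self.truth.accessibility[g.gene_id]
            w = w * np.exp(cfg.gc_bias_slope * (self.gc_local(r.name) - genome_gc))
            weights[r.name] = w * self.truth.copy_numbers[r.name]
        self._atac_weights = weights
        return weights

    def atac(self, condition: str, n_fragments: int, seed: int,
             replicate: int = 1) -> FragmentSet:
        """ATAC fragments with promoter-localised accessibility.

        Accessibility is a gene property shared across conditions — by
        construction, changing condition changes transcription (KAS) but
        not the ATAC landscape.
        """
        self.config.require_condition(condition)
        if n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        rng = np.random.default_rng(seed)
        mids = self._sample_positions(rng, self.atac_insertion_weights(), n_fragments)
        lengths = _draw_fragment_lengths(rng, self.config, len(mids))
        df = self._positions_to_fragments(rng, mids, lengths)
        return FragmentSet(df, library_id=f"atac_{condition}_r{replicate}",
                           assay="ATAC", condition=condition, replicate=replicate)

    # ------------------------------------------------------------------- KAS
    def kas_weights(self, condition: str) -> dict[str, np.ndarray]:
        cfg = self.config
        self.config.require_condition(condition)
        rates = self.truth.kas_rates[condition]
        background = cfg.dormant_background if condition == "dormant" else cfg.kas_background
        # promoter-proximal pausing happens at transcription-unit starts:
        # singleton genes and the first gene of each operon (operon-internal
        # genes share the operon promoter unless flagged as internal starts)
        unit_starts: set[str] = {g.gene_id for g in self.genome.genes if g.operon is None}
        for members in self.genome.operons().values():
            first = members[0] if members[0].strand == "+" else members[-1]
            unit_starts.add(first.gene_id)
        unit_starts |= set(self.truth.internal_start_genes.values())
        weights = {}
        for r in self.genome.replicons:
            w = np.full(r.length, background)
            for g in self.genome.genes_on(r.name):
                rate = rates[g.gene_id]
                w[g.start:g.end] += rate
                if g.gene_id not in unit_starts:
                    continue
                pw = cfg.kas_pause_window
                if g.strand == "+":
                    lo, hi = g.tss, min(g.tss + pw, r.length)
                else:
                    lo, hi = max(g.tss - pw + 1, 0), g.tss + 1
                w[lo:hi] += cfg.kas_pause_enrichment * rate
            weights[r.name] = w
        if condition == "dormant":
            rep, lo, hi = self.truth.crispr_peak_window
            weights[rep][lo:hi] += cfg.dormant_peak_weight
        for r in self.genome.replicons:
            weights[r.name] *= self.truth.copy_numbers[r.name]
        return weights

    def kas(self, condition: str, n_reads: int, seed: int,
            replicate: int = 1) -> FragmentSet:
        """ssDNA reads: pausing at TSSs, gene-body signal, internal starts."""
        if n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        rng = np.random.default_rng(seed)
        mids = self._sample_positions(rng, self.kas_weights(condition), n_reads)
        lengths = np.full(len(mids), self.config.read_length, dtype=np.int64)
        df = self._positions_to_fragments(rng, mids, lengths)
        return FragmentSet(df, library_id=f"kas_{condition}_r{replicate}",
                           assay="KAS", condition=condition, replicate=replicate)

    # ------------------------------------------------------ methyl molecules
    def _footprint_intervals(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Genomic [lo, hi) of the upstream footprint for every gene."""
        if self._footprints is not None:
            return self._footprints
        f0, f1 = self.config.footprint_window
        out: dict[str, tuple[list, list]] = {r.name: ([], []) for r in self.genome.replicons}
        for g in self.genome.genes:
            if g.strand == "+":
                lo, hi = g.tss + f0, g.tss + f1
            else:
                lo, hi = g.tss - f1 + 1, g.tss - f0 + 1
            out[g.replicon][0].append(lo)
            out[g.replicon][1].append(hi)
        self._footprints = {}
        for rep, (los, his) in out.items():
            order = np.argsort(los)
            self._footprints[rep] = (np.array(los)[order], np.array(his)[order])
        return self._footprints

    def methyl_molecules(
        self,
        condition: str,
        n_molecules: int,
        window: int = 200,
        seed: int = 0,
        dsmf: bool = False,
    ) -> MethylCallTable:
        """Single molecules with per-site Bernoulli accessibility calls.

        Each molecule covers a contiguous ``window`` bp.  A configurable
        fraction anchors at (jittered) TSSs, the rest land uniformly with
        copy-number weight.  At footprint-bearing promoters an occupied
        fraction of molecules is protected down to the leak rate inside
        the footprint interval.
        """
        cfg = self.config
        if window < 50:
            raise ValueError("molecule window must be >= 50 bp")
        if condition not in cfg.accessibility_prob:
            raise ValueError(f"no protection model for condition {condition!r}")
        acc = cfg.accessibility_prob[condition]
        rng = np.random.default_rng(seed)
        contexts = ["GpC", "CpG"] if dsmf else ["GpC"]
        genes = self.genome.genes
        rep_len = {r.name: r.length for r in self.genome.replicons}
        rep_names = list(rep_len)
        rep_w = np.array([rep_len[r] * self.truth.copy_numbers[r] for r in rep_names])
        rep_p = rep_w / rep_w.sum()
        fp = self._footprint_intervals()

        rows: list[tuple] = []
        for i in range(n_molecules):
            mol_id = f"{condition}_m{i + 1}"
            placed = False
            for _ in range(20):
                if genes and rng.random() < cfg.molecule_promoter_fraction:
                    g = genes[int(rng.integers(len(genes)))]
                    jitter = int(rng.integers(-20, 21))
                    rep = g.replicon
                    start = g.tss + jitter - window // 2
                else:
                    rep = rep_names[int(rng.choice(len(rep_names), p=rep_p))]
                    start = int(rng.integers(0, max(rep_len[rep] - window, 1)))
                start = int(np.clip(start, 0, max(rep_len[rep] - window, 0)))
                end = start + window
                site_pos, site_ctx = [], []
                for ctx in contexts:
                    s = self.context_sites(rep, ctx)
                    sel = s[np.searchsorted(s, start): np.searchsorted(s, end)]
                    site_pos.append(sel)
                    site_ctx.extend([ctx] * len(sel))
                pos = np.concatenate(site_pos) if site_pos else np.array([], int)
                if len(pos) > 0:
                    placed = True
                    break
            if not placed:
                raise ValueError("no context sites in molecule window")
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            ctx_arr = np.array(site_ctx)[order]
            p = np.full(len(pos), acc)
            los, his = fp[rep]
            j0 = np.searchsorted(his, start, side="right")
            j1 = np.searchsorted(los, end, side="left")
            for j in range(j0, j1):
                if rng.random() < cfg.footprint_occupancy:
                    inside = (pos >= los[j]) & (pos < his[j])
                    p[inside] = cfg.footprint_leak
            meth = rng.random(len(pos)) < p
            for q, c, m in zip(pos, ctx_arr, meth):
                rows.append((mol_id, rep, start, end, int(q), c, bool(m)))
        df = pd.DataFrame(rows, columns=list(MethylCallTable.COLUMNS))
        return MethylCallTable(df)


# --------------------------------------------------------- module functions

def simulate_naked(config: SimConfig, n_fragments: int, seed: int) -> FragmentSet:
    return Simulation(config).naked(n_fragments, seed)


def simulate_atac(config: SimConfig, condition: str, n_fragments: int, seed: int) -> FragmentSet:
    return Simulation(config).atac(condition, n_fragments, seed)


def simulate_kas(config: SimConfig, condition: str, n_reads: int, seed: int) -> FragmentSet:
    return Simulation(config).kas(condition, n_reads, seed)


def simulate_methyl_molecules(
    config: SimConfig, condition: str, n_molecules: int, window: int, seed: int,
    dsmf: bool = False,
) -> MethylCallTable:
    return Simulation(config).methyl_molecules(condition, n_molecules, window, seed, dsmf)
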