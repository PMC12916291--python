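"""The iLDS genome scan for gene-specific selective sweeps.

One window is placed around every common (intermediate-frequency,
MAF >= 0.2 by default) non-synonymous SNP, with a width matched to the
distance at which genome-wide LD decays.  Two signed areas are measured per
window among common variants:

* ``r2_dNS = AUC(r2_N - r2_S)`` — the excess of LD among non-synonymous over
  synonymous variants, the hitchhiking signature of a sweep carrying
  deleterious passengers;
* ``r2_dLG = AUC(r2_local - r2_genome_wide)`` — the elevation of total local
  LD over the genomic background expected for a region of that size.

Each component is standardized by its mean and standard deviation across all
windows of the genome, and ``iLDS = z_dNS^2 + z_dLG^2``.  A window is called
significant when (1) both components exceed zero by their per-window tests —
a class-label permutation for the N/S component and a one-sided site
bootstrap for the local component — and (2) iLDS exceeds an empirical
genome-wide quantile (99.9th percentile by default).  Overlapping
significant windows merge into sweep calls annotated with the genes they
span.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import ld_core
from .errors import DegenerateScanError, EmptyCurveError, InsufficientDataError
from .io_annotation import call_snvs
from .types import (
    AUTO,
    GeneModel,
    HaplotypeAlignment,
    LDCurve,
    NONSYN,
    PairData,
    ScanConfig,
    SweepCall,
    SYN,
    WindowScore,
)

logger = logging.getLogger(__name__)


# --- window sizing ----------------------------------------------------------


def auto_window_size(genome_curve: LDCurve) -> float:
    """Window size matched to the genome-wide LD decay distance.

    Finds the smallest bin distance ``d*`` at which the curve has dropped
    halfway from its short-range peak (first populated bin) to its
    long-range background (mean over the largest-distance quartile of
    populated bins), and returns ``2 * d*`` (the decay distance is used as a
    window half-width).  If the curve never decays below the midpoint the
    largest binned distance is used, with a warning.
    """
    m = genome_curve.populated
    if m.sum() < 5:
        raise InsufficientDataError(
            "genome-wide curve needs >= 5 populated bins for window sizing"
        )
    mids = genome_curve.bin_mid[m]
    raw = genome_curve.mean_r2[m]
    # rolling median of three damps single noisy bins before the midpoint rule
    vals = raw.copy()
    if len(raw) >= 3:
        vals[1:-1] = np.median(
            np.column_stack([raw[:-2], raw[1:-1], raw[2:]]), axis=1
        )
    peak = vals[0]
    q = max(1, len(vals) // 4)
    background = float(vals[-q:].mean())
    target = background + 0.5 * (peak - background)
    below = np.nonzero(vals <= target)[0] if peak > background else np.array([])
    if below.size == 0:
        warnings.warn(
            "genome-wide LD never decays below the half-way point; "
            "falling back to the largest binned distance"
        )
        return float(2 * mids[-1])
    return float(2 * mids[below[0]])


# --- per-window components --------------------------------------------------


@dataclass
class _ContigContext:
    """Precomputed per-contig state shared by all windows."""

    contig_id: str
    common: pd.DataFrame  # common SiteTable rows, position-sorted
    positions: np.ndarray
    classes: np.ndarray
    r2m: np.ndarray  # pairwise r^2 among common sites


def _contig_context(
    aln: HaplotypeAlignment, sites: pd.DataFrame, cfg: ScanConfig
) -> _ContigContext:
    common = (
        sites[sites["maf"] >= cfg.common_maf_min]
        .sort_values("position")
        .reset_index(drop=True)
    )
    G = ld_core.genotype_matrix(aln, common)
    return _ContigContext(
        contig_id=aln.contig_id,
        common=common,
        positions=common["position"].to_numpy(),
        classes=common["func_class"].to_numpy(),
        r2m=ld_core.r2_matrix(G),
    )


def _window_pairs(
    ctx: _ContigContext, sel: np.ndarray, window_size: float
) -> PairData:
    idx = np.nonzero(sel)[0]
    sub = ctx.r2m[np.ix_(idx, idx)]
    return ld_core.pair_data(ctx.positions[idx], sub, max_distance=window_size)


def window_components(
    aln: HaplotypeAlignment,
    sites: pd.DataFrame,
    center: int,
    cfg: ScanConfig,
    genome_curve: LDCurve,
    window_size: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    _ctx: Optional[_ContigContext] = None,
) -> Optional[WindowScore]:
    """Unstandardized iLDS components for the window centred on ``center``.

    ``genome_curve`` must be binned on the window bin edges (see
    :func:`genome_reference_curve`).  Returns None when the window lacks the
    minimum non-synonymous/synonymous common SNV content or its curves are
    too sparse to integrate — such windows are skipped, not scored.
    """
    if window_size is None:
        window_size = float(genome_curve.bin_edges[-1])
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ctx = _ctx if _ctx is not None else _contig_context(aln, sites, cfg)
    half = window_size / 2.0
    lo, hi = center - half, center + half
    inside = (ctx.positions >= lo) & (ctx.positions <= hi)
    is_n = inside & (ctx.classes == NONSYN)
    is_s = inside & (ctx.classes == SYN)
    if is_n.sum() < cfg.min_nonsyn_per_window or is_s.sum() < cfg.min_syn_per_window:
        return None
    edges = genome_curve.bin_edges
    try:
        curve_n = ld_core.curve_from_pairs(
            _window_pairs(ctx, is_n, window_size), edges, cfg.min_pairs_per_window_bin
        )
        curve_s = ld_core.curve_from_pairs(
            _window_pairs(ctx, is_s, window_size), edges, cfg.min_pairs_per_window_bin
        )
        dns = ld_core.auc_difference(
            curve_n, curve_s, n_boot=cfg.bootstrap_reps, rng=rng
        )
        # the N-vs-S zero-exceedance test: class-label permutation over the
        # window's pooled common sites — exact under exchangeability and far
        # better powered than a site bootstrap when one class holds only a
        # handful of sites
        pooled_sel = is_n | is_s
        pooled = _window_pairs(ctx, pooled_sel, window_size)
        is_a = ctx.classes[np.nonzero(pooled_sel)[0]] == NONSYN
        try:
            _, p_dns = ld_core.class_label_permutation_test(
                pooled, is_a, edges, cfg.min_pairs_per_window_bin,
                cfg.dns_permutations, rng,
            )
        except InsufficientDataError:
            p_dns = np.nan
        local = ld_core.curve_from_pairs(
            _window_pairs(ctx, inside, window_size),
            edges,
            cfg.min_pairs_per_window_bin,
        )
        # a window can only be called when BOTH components are significant,
        # so the (expensive) local-vs-genome bootstrap runs at full
        # resolution only once the N/S component has already passed
        dns_passed = bool(np.isfinite(p_dns) and p_dns <= cfg.component_alpha)
        dlg_boot = cfg.bootstrap_reps if dns_passed else min(
            200, cfg.bootstrap_reps
        )
        dlg = ld_core.auc_difference(
            local,
            genome_curve,
            n_boot=dlg_boot,
            rng=rng,
            resample_b=False,
        )
    except (InsufficientDataError, EmptyCurveError):
        return None
    return WindowScore(
        contig_id=ctx.contig_id,
        center_position=int(center),
        window_start=int(np.floor(lo)),
        window_end=int(np.ceil(hi)),
        r2_dNS=dns.value,
        r2_dLG=dlg.value,
        dNS_ci=(dns.ci_low, dns.ci_high),
        dLG_ci=(dlg.ci_low, dlg.ci_high),
        p_dNS=p_dns,
        sig_dNS=bool(np.isfinite(p_dns) and p_dns <= cfg.component_alpha),
        sig_dLG=dlg.significant,
    )


# --- standardization, significance, sweep calls ----------------------------


def standardize_and_score(windows: Sequence[WindowScore]) -> list[WindowScore]:
    """Genome-wide z-standardization of both components; iLDS = z1^2 + z2^2.

    Requires at least 10 scored windows and non-zero variance in both
    components (raises :class:`DegenerateScanError` otherwise).  Mutates and
    returns the window list.
    """
    windows = list(windows)
    if len(windows) < 10:
        raise DegenerateScanError(
            f"standardization needs >= 10 scored windows, got {len(windows)}"
        )
    dns = np.array([w.r2_dNS for w in windows])
    dlg = np.array([w.r2_dLG for w in windows])
    sds = dns.std(), dlg.std()
    if min(sds) <= 0:
        raise DegenerateScanError("zero variance across windows")
    z1 = (dns - dns.mean()) / sds[0]
    z2 = (dlg - dlg.mean()) / sds[1]
    for w, a, b in zip(windows, z1, z2):
        w.z_dNS = float(a)
        w.z_dLG = float(b)
        w.ilds = float(a * a + b * b)
    return windows


def ilds_threshold(windows: Sequence[WindowScore], cfg: ScanConfig) -> float:
    """Empirical critical value: a genome-wide quantile of the iLDS scores."""
    scores = np.array([w.ilds for w in windows])
    return float(np.quantile(scores, cfg.ilds_threshold_percentile))


def test_significance(
    w: WindowScore, windows: Sequence[WindowScore], cfg: ScanConfig
) -> WindowScore:
    """Two-part criterion: both components exceed zero AND iLDS is extreme.

    The critical threshold is the ``ilds_threshold_percentile`` quantile of
    the genome-wide empirical iLDS distribution — an outlier criterion, not
    an analytic chi-square cutoff, because the two components are neither
    Gaussian nor independent.
    """
    thr = ilds_threshold(windows, cfg)
    w.significant = bool(w.sig_dNS and w.sig_dLG and w.ilds >= thr)
    return w


def apply_significance(
    windows: Sequence[WindowScore], cfg: ScanConfig
) -> list[WindowScore]:
    windows = list(windows)
    if not windows:
        return windows
    thr = ilds_threshold(windows, cfg)
    for w in windows:
        w.significant = bool(w.sig_dNS and w.sig_dLG and w.ilds >= thr)
    return windows


def call_sweeps(
    windows: Sequence[WindowScore],
    genes: Sequence[GeneModel],
    merge_gap: Optional[float] = None,
) -> list[SweepCall]:
    """Merge significant windows into sweep intervals and annotate genes.

    Windows on one contig merge when they overlap or sit within
    ``merge_gap`` bp of each other (default: the window size).  Windows on
    different contigs never merge.
    """
    sig = [w for w in windows if w.significant]
    if not sig:
        return []
    if merge_gap is None:
        merge_gap = float(np.median([w.window_end - w.window_start for w in sig]))
    calls: list[SweepCall] = []
    for contig in sorted({w.contig_id for w in sig}):
        ws = sorted(
            (w for w in sig if w.contig_id == contig), key=lambda w: w.window_start
        )
        cur = [ws[0]]
        for w in ws[1:]:
            if w.window_start <= cur[-1].window_end + merge_gap:
                cur.append(w)
            else:
                calls.append(_make_call(contig, cur, genes))
                cur = [w]
        calls.append(_make_call(contig, cur, genes))
    return calls


def _make_call(
    contig: str, ws: list[WindowScore], genes: Sequence[GeneModel]
) -> SweepCall:
    start = min(w.window_start for w in ws)
    end = max(w.window_end for w in ws)
    overlapping = [
        g.gene_id
        for g in genes
        if g.contig_id == contig and g.start < end and g.end > start
    ]
    return SweepCall(
        contig_id=contig,
        start=start,
        end=end,
        peak_ilds=max(w.ilds for w in ws),
        n_windows=len(ws),
        genes=overlapping,
    )


# --- orchestrator -----------------------------------------------------------


@dataclass
class ScanResult:
    """Full output of an iLDS scan."""

    windows: list[WindowScore]
    sweeps: list[SweepCall]
    window_size: float
    threshold: float
    genome_curve: LDCurve  # decay curve used for window sizing
    skipped: pd.DataFrame  # contig, center, reason
    config: ScanConfig

    def window_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [w.contig_id for w in self.windows],
                "center": [w.center_position for w in self.windows],
                "start": [w.window_start for w in self.windows],
                "end": [w.window_end for w in self.windows],
                "r2_dNS": [w.r2_dNS for w in self.windows],
                "r2_dLG": [w.r2_dLG for w in self.windows],
                "z_dNS": [w.z_dNS for w in self.windows],
                "z_dLG": [w.z_dLG for w in self.windows],
                "ilds": [w.ilds for w in self.windows],
                "p_dNS": [w.p_dNS for w in self.windows],
                "sig_dNS": [w.sig_dNS for w in self.windows],
                "sig_dLG": [w.sig_dLG for w in self.windows],
                "significant": [w.significant for w in self.windows],
            }
        )


def genome_reference_curve(
    contexts: Sequence[_ContigContext], bin_edges: np.ndarray, min_pairs: int
) -> LDCurve:
    """Genome-wide LD curve over all common variants, pooled across contigs."""
    pos_parts, i_parts, j_parts, r2_parts, d_parts = [], [], [], [], []
    offset = 0
    max_d = float(bin_edges[-1])
    for ctx in contexts:
        p = ld_core.pair_data(ctx.positions, ctx.r2m, max_distance=max_d)
        pos_parts.append(p.site_positions)
        i_parts.append(p.i + offset)
        j_parts.append(p.j + offset)
        r2_parts.append(p.r2)
        d_parts.append(p.dist)
        offset += p.n_sites
    pooled = PairData(
        site_positions=np.concatenate(pos_parts),
        i=np.concatenate(i_parts),
        j=np.concatenate(j_parts),
        r2=np.concatenate(r2_parts),
        dist=np.concatenate(d_parts),
    )
    if pooled.i.size == 0:
        raise EmptyCurveError("no common-variant pairs for the genome-wide curve")
    return ld_core.curve_from_pairs(pooled, bin_edges, min_pairs)


def scan(
    alignments: Union[HaplotypeAlignment, Sequence[HaplotypeAlignment]],
    genes: Sequence[GeneModel],
    cfg: Optional[ScanConfig] = None,
    sites: Optional[Union[pd.DataFrame, Sequence[pd.DataFrame]]] = None,
) -> ScanResult:
    """Run the full iLDS scan over one genome (one or more contigs).

    Windows are computed per contig but standardized and thresholded over
    the pooled genome, matching the within-contig scope of the statistic.
    ``sites`` may supply pre-computed SiteTables (one per alignment);
    otherwise SNVs are called with default filters.  Fully deterministic
    given ``cfg.seed``.
    """
    if cfg is None:
        cfg = ScanConfig()
    if isinstance(alignments, HaplotypeAlignment):
        alignments = [alignments]
        if sites is not None and isinstance(sites, pd.DataFrame):
            sites = [sites]
    if sites is None:
        sites = [call_snvs(aln, [g for g in genes if g.contig_id == aln.contig_id])
                 for aln in alignments]
    rng = np.random.default_rng(cfg.seed)

    contexts = [
        _contig_context(aln, st, cfg) for aln, st in zip(alignments, sites)
    ]

    # genome-wide decay curve (window sizing) on the wide log bins
    max_dist = cfg.max_distance or max(a.length for a in alignments) / 3.0
    wide_edges = ld_core.log_bin_edges(max_dist, cfg.n_bins, cfg.min_bin_distance)
    decay_curve = genome_reference_curve(contexts, wide_edges, cfg.min_pairs_per_bin)
    window_size = (
        auto_window_size(decay_curve)
        if cfg.window_size == AUTO
        else float(cfg.window_size)
    )
    if cfg.window_size == AUTO:
        # feasibility floor: the window must be wide enough to hold the
        # minimum stratified SNV content at the genome's class densities,
        # otherwise a noisy decay estimate degenerates the whole scan
        total_len = float(sum(a.length for a in alignments))
        n_syn = sum((c.classes == SYN).sum() for c in contexts)
        n_non = sum((c.classes == NONSYN).sum() for c in contexts)
        if n_syn > 0 and n_non > 0:
            floor = 1.5 * max(
                cfg.min_syn_per_window * total_len / n_syn,
                cfg.min_nonsyn_per_window * total_len / n_non,
            )
            window_size = max(window_size, min(floor, max_dist / 2.0))

    # genome-wide reference re-binned on the window edges (for r2_dLG)
    win_edges = ld_core.log_bin_edges(
        window_size, cfg.n_window_bins, cfg.min_bin_distance
    )
    genome_ref = genome_reference_curve(contexts, win_edges, cfg.min_pairs_per_bin)

    windows: list[WindowScore] = []
    skipped: list[tuple[str, int, str]] = []
    for aln, ctx in zip(alignments, contexts):
        centers = ctx.positions[(ctx.classes == NONSYN)]
        for center in centers:
            w = window_components(
                aln,
                ctx.common,
                int(center),
                cfg,
                genome_ref,
                window_size=window_size,
                rng=rng,
                _ctx=ctx,
            )
            if w is None:
                skipped.append((ctx.contig_id, int(center), "insufficient_snvs"))
            else:
                windows.append(w)
    if skipped:
        logger.info("scan: skipped %d of %d windows", len(skipped),
                    len(skipped) + len(windows))

    windows = standardize_and_score(windows)
    windows = apply_significance(windows, cfg)
    thr = ilds_threshold(windows, cfg)
    sweeps = call_sweeps(windows, genes, merge_gap=window_size)
    return ScanResult(
        windows=windows,
        sweeps=sweeps,
        window_size=window_size,
        threshold=thr,
        genome_curve=decay_curve,
        skipped=pd.DataFrame(skipped, columns=["contig", "center", "reason"]),
        config=cfg,
    )


# --- output -----------------------------------------------------------------


def write_sweeps_bed(sweeps: Sequence[SweepCall], path) -> None:
    """Write sweep calls as BED (0-based half-open)."""
    with open(str(path), "w") as fh:
        for s in sweeps:
            fh.write(
                f"{s.contig_id}\t{s.start}\t{s.end}\tsweep_n{s.n_windows}\t"
                f"{s.peak_ilds:.3f}\n"
            )


def read_sweeps_bed(path) -> list[SweepCall]:
    """Read sweep calls written by :func:`write_sweeps_bed`."""
    sweeps = []
    with open(str(path)) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "sweep_n1"
            score = float(parts[4]) if len(parts) > 4 else 0.0
            n_win = int(name.rsplit("_n", 1)[-1]) if "_n" in name else 1
            sweeps.append(
                SweepCall(
                    contig_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    peak_ilds=score,
                    n_windows=n_win,
                )
            )
    return sweeps


def plot_scan(result: ScanResult, ax=None):
    """Manhattan-style plot of iLDS along the genome; sweeps as bars below."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    tab = result.window_table()
    colors = np.where(tab["significant"], "tab:orange", "tab:green")
    ax.scatter(tab["center"], tab["ilds"], s=8, c=colors)
    y0 = -0.05 * max(tab["ilds"].max(), 1.0)
    for s in result.sweeps:
        ax.plot([s.start, s.end], [y0, y0], lw=6, color="tab:orange")
    ax.set_xlabel("genome position (bp)")
    ax.set_ylabel("iLDS")
    return ax
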