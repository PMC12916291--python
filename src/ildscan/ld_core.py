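"""Pairwise r^2, distance-binned LD decay curves, and AUC comparisons.

Linkage disequilibrium between two biallelic sites is measured with the
standard r^2 statistic: ``r^2 = D^2 / (p_i (1-p_i) p_j (1-p_j))`` with
``D = p_ij - p_i p_j``, all frequencies taken over haplotypes called at both
sites.  Curves are built by averaging r^2 over site pairs within distance
bins; curve comparisons integrate the binned means with the trapezoid rule
and attach a site-level bootstrap confidence interval (pairs sharing a site
are dependent, so resampling happens at the site level, never the pair
level).  Pairs with undefined r^2 (monomorphic among jointly called
haplotypes) are skipped, never imputed as zero.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyCurveError, InsufficientDataError, UndefinedLDError
from .types import HaplotypeAlignment, LDCurve, AUCResult, PairData, encode_sequence

DEFAULT_MIN_PAIRS_PER_BIN = 10


# --- genotype matrices ------------------------------------------------------


def genotype_matrix(aln: HaplotypeAlignment, sites: pd.DataFrame) -> np.ndarray:
    """Minor-allele indicator matrix, ``(n_sites, n_haplotypes)`` int8.

    1 = minor allele, 0 = major allele, -1 = missing (or a base that is
    neither listed allele).
    """
    pos = sites["position"].to_numpy()
    sub = aln.matrix[:, pos].T  # (k, n)
    major = encode_sequence("".join(sites["major"]))
    minor = encode_sequence("".join(sites["minor"]))
    out = np.full(sub.shape, -1, dtype=np.int8)
    out[sub == major[:, None]] = 0
    out[sub == minor[:, None]] = 1
    return out


def r2_matrix(G: np.ndarray) -> np.ndarray:
    """All pairwise r^2 for a minor-allele indicator matrix ``(k, n)``.

    Missing-aware: frequencies for each pair use only haplotypes called at
    both sites.  Entries are NaN where r^2 is undefined (fewer than two
    jointly called haplotypes, or either site monomorphic among them).
    """
    M = (G >= 0).astype(np.float64)
    X = (G == 1).astype(np.float64)
    n = M @ M.T
    x_ij = X @ X.T
    x_i = X @ M.T  # minor count at row site among jointly called
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = x_i / n
        p_j = x_i.T / n
        p_ij = x_ij / n
        D = p_ij - p_i * p_j
        denom = p_i * (1.0 - p_i) * p_j * (1.0 - p_j)
        r2 = np.where(denom > 0, D * D / denom, np.nan)
    r2[n < 2] = np.nan
    return np.clip(r2, 0.0, 1.0)


def r2(
    aln: HaplotypeAlignment,
    site_i: int,
    site_j: int,
    alleles_i: tuple[str, str],
    alleles_j: tuple[str, str],
) -> float:
    """r^2 between two biallelic sites of an alignment.

    Raises :class:`UndefinedLDError` when fewer than two haplotypes are
    called at both sites or either site is monomorphic among them.
    """
    sites = pd.DataFrame(
        {
            "position": [site_i, site_j],
            "major": [alleles_i[0], alleles_j[0]],
            "minor": [alleles_i[1], alleles_j[1]],
        }
    )
    val = r2_matrix(genotype_matrix(aln, sites))[0, 1]
    if np.isnan(val):
        raise UndefinedLDError(
            f"r^2 undefined for sites {site_i},{site_j} (monomorphic or too few "
            "jointly called haplotypes)"
        )
    return float(val)


# --- pair tables and binning ------------------------------------------------


def log_bin_edges(
    max_distance: float, n_bins: int = 24, min_distance: float = 10.0
) -> np.ndarray:
    """Logarithmically spaced distance bin edges.

    LD decays roughly geometrically with distance, so log bins keep per-bin
    pair counts comparable across the curve.
    """
    if max_distance <= min_distance:
        raise ValueError("max_distance must exceed min_distance")
    return np.geomspace(min_distance, max_distance, n_bins + 1)


def pair_data(
    positions: np.ndarray,
    r2m: np.ndarray,
    max_distance: Optional[float] = None,
) -> PairData:
    """Collect valid site pairs (i < j, finite r^2, within max_distance)."""
    positions = np.asarray(positions, dtype=np.int64)
    k = len(positions)
    iu, ju = np.triu_indices(k, 1)
    dist = np.abs(positions[ju] - positions[iu]).astype(np.float64)
    vals = r2m[iu, ju]
    keep = np.isfinite(vals)
    if max_distance is not None:
        keep &= dist <= max_distance
    return PairData(
        site_positions=positions,
        i=iu[keep],
        j=ju[keep],
        r2=vals[keep],
        dist=dist[keep],
    )


def _bin_index(dist: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Bin of each distance under [low, high) binning; -1 = outside."""
    idx = np.searchsorted(bin_edges, dist, side="right") - 1
    nb = len(bin_edges) - 1
    idx[dist == bin_edges[-1]] = nb - 1  # close the last bin
    idx[(idx < 0) | (idx >= nb)] = -1
    return idx


class _BinnedPairs:
    """Pairs of one curve pre-sorted by distance bin, for fast (re)binning."""

    def __init__(self, pairs: PairData, bin_edges: np.ndarray):
        self.pairs = pairs
        self.bin_edges = np.asarray(bin_edges, dtype=float)
        self.nb = len(bin_edges) - 1
        raw_bin = _bin_index(pairs.dist, self.bin_edges)
        inside = raw_bin >= 0
        order = np.argsort(raw_bin[inside], kind="stable")
        self.i = pairs.i[inside][order]
        self.j = pairs.j[inside][order]
        self.r2 = pairs.r2[inside][order]
        self.bin = raw_bin[inside][order]
        counts = np.bincount(self.bin, minlength=self.nb)
        self.empty = counts == 0
        # reduceat start indices; empty segments are zeroed after the fact,
        # so clipping the out-of-range starts of empty trailing bins is safe
        self.boundaries = np.minimum(
            np.concatenate([[0], np.cumsum(counts)])[:-1],
            max(len(self.bin) - 1, 0),
        )
        self.n_sites = pairs.n_sites

    def binned_sums(self, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Weighted per-bin sums of r^2 and of weights; ``W`` is ``(B, P)``."""
        if self.i.size == 0:
            B = W.shape[0]
            z = np.zeros((B, self.nb))
            return z, z.copy()
        num = np.add.reduceat(W * self.r2.astype(W.dtype), self.boundaries, axis=1)
        den = np.add.reduceat(W, self.boundaries, axis=1)
        num = num.astype(np.float64)
        den = den.astype(np.float64)
        num[:, self.empty] = 0.0
        den[:, self.empty] = 0.0
        return num, den

    def means(self, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin weighted mean r^2 (NaN where empty) and weight totals.

        ``M`` is a ``(B, k)`` site multiplicity matrix; a pair's weight is the
        product of its two site multiplicities.
        """
        # float32 keeps memory traffic down for the big bootstrap batches;
        # single-row calls (actual curve construction) stay in float64 so
        # binned means are exact up to associativity
        dtype = np.float32 if M.shape[0] > 4 else np.float64
        Mf = M.astype(dtype, copy=False)
        W = Mf[:, self.i] * Mf[:, self.j]
        num, den = self.binned_sums(W)
        with np.errstate(invalid="ignore"):
            mean = np.where(den > 0, num / den, np.nan)
        return mean, den


def curve_from_pairs(
    pairs: PairData,
    bin_edges: np.ndarray,
    min_pairs_per_bin: int = DEFAULT_MIN_PAIRS_PER_BIN,
) -> LDCurve:
    """Build a distance-binned LD curve from a pair table."""
    bp = _BinnedPairs(pairs, bin_edges)
    ones = np.ones((1, pairs.n_sites))
    mean, den = bp.means(ones)
    n_pairs = den[0].astype(np.int64)
    mean = mean[0]
    mean[n_pairs < min_pairs_per_bin] = np.nan
    mids = np.sqrt(bin_edges[:-1] * bin_edges[1:])  # geometric mid of log bins
    return LDCurve(
        bin_edges=np.asarray(bin_edges, float),
        bin_mid=mids,
        mean_r2=mean,
        n_pairs=n_pairs,
        pairs=pairs,
    )


def ld_decay_curve(
    aln: HaplotypeAlignment,
    sites: pd.DataFrame,
    bin_edges: Optional[np.ndarray] = None,
    max_distance: Optional[float] = None,
    min_pairs_per_bin: int = DEFAULT_MIN_PAIRS_PER_BIN,
) -> LDCurve:
    """Distance-binned mean r^2 over all pairs of the given sites.

    ``sites`` is a SiteTable subset (all from this contig).  Bin edges
    default to ~24 log-spaced bins from 10 bp to ``max_distance`` (itself
    defaulting to the largest inter-site distance).
    """
    if max_distance is None:
        if len(sites) >= 2:
            p = sites["position"].to_numpy()
            max_distance = float(p.max() - p.min())
        else:
            max_distance = float(aln.length)
    if bin_edges is None:
        bin_edges = log_bin_edges(max(max_distance, 20.0))
    G = genotype_matrix(aln, sites)
    pairs = pair_data(sites["position"].to_numpy(), r2_matrix(G), max_distance)
    if pairs.i.size == 0:
        raise EmptyCurveError("no valid site pairs within max_distance")
    return curve_from_pairs(pairs, bin_edges, min_pairs_per_bin)


# --- AUC --------------------------------------------------------------------


def auc(curve: LDCurve, span: Optional[tuple[float, float]] = None) -> float:
    """Trapezoidal area under the populated bins of a curve.

    ``span`` restricts to bins whose representative distance lies inside the
    closed interval.  Raises :class:`InsufficientDataError` with fewer than
    two populated bins.
    """
    mask = curve.populated
    if span is not None:
        mask = mask & (curve.bin_mid >= span[0]) & (curve.bin_mid <= span[1])
    if mask.sum() < 2:
        raise InsufficientDataError("fewer than two populated bins in span")
    return float(np.trapezoid(curve.mean_r2[mask], curve.bin_mid[mask]))


def _trapz_rows_masked(V: np.ndarray, mids: np.ndarray) -> np.ndarray:
    """Row-wise trapezoid over the defined (finite) bins of each row.

    Equivalent to dropping the NaN bins of a row and integrating the
    remaining points; rows with fewer than two defined bins give NaN.
    Vectorized over rows by enumerating consecutive-defined bin pairs
    (the bin count is small).
    """
    B, nb = V.shape
    defined = np.isfinite(V)
    Vz = np.nan_to_num(V)
    out = np.zeros(B)
    for a in range(nb - 1):
        gap_free = defined[:, a].copy()
        for b in range(a + 1, nb):
            pair = gap_free & defined[:, b]
            if pair.any():
                out += np.where(
                    pair, 0.5 * (Vz[:, a] + Vz[:, b]) * (mids[b] - mids[a]), 0.0
                )
            gap_free &= ~defined[:, b]
            if not gap_free.any():
                break
    out[defined.sum(axis=1) < 2] = np.nan
    return out


def _trapz_rows_diff(VA: np.ndarray, VB: np.ndarray, mids: np.ndarray) -> np.ndarray:
    """Row-wise AUC(VA) - AUC(VB) over bins defined in both rows."""
    mask = np.isfinite(VA) & np.isfinite(VB)
    D = np.where(mask, VA - VB, np.nan)
    return _trapz_rows_masked(D, mids)


def _multiplicities(k: int, B: int, rng: np.random.Generator) -> np.ndarray:
    return rng.multinomial(k, np.full(k, 1.0 / k), size=B).astype(np.float64)


def bootstrap_auc_difference(
    curve_a: LDCurve,
    curve_b: LDCurve,
    shared: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    resample_b: bool = True,
) -> np.ndarray:
    """Bootstrap replicates of AUC(a) - AUC(b) by resampling curve sites.

    Sites of each curve are resampled independently (stratified when the two
    curves hold different site classes).  When the curves share one
    underlying pair table the same resample is applied to both, so identical
    inputs yield exactly zero replicates.  ``resample_b=False`` keeps curve b
    fixed (used against a genome-wide reference curve whose sampling noise is
    negligible relative to a window's).  ``shared`` masks the bins eligible
    for integration.
    """
    pa, pb = curve_a.pairs, curve_b.pairs
    if pa is None:
        raise InsufficientDataError("curve_a carries no site data for bootstrap")
    edges = curve_a.bin_edges
    bpa = _BinnedPairs(pa, edges)
    bpb = None
    if pb is pa:
        bpb = bpa
    elif resample_b and pb is not None:
        bpb = _BinnedPairs(pb, edges)
    off = ~np.asarray(shared, bool)

    def _run(B: int) -> np.ndarray:
        Ma = _multiplicities(pa.n_sites, B, rng)
        VA, _ = bpa.means(Ma)
        if bpb is bpa:
            VB, _ = bpb.means(Ma)
        elif bpb is not None:
            Mb = _multiplicities(pb.n_sites, B, rng)
            VB, _ = bpb.means(Mb)
        else:
            VB = np.tile(curve_b.mean_r2, (B, 1))
        VA[:, off] = np.nan
        VB[:, off] = np.nan
        d = _trapz_rows_diff(VA, VB, curve_a.bin_mid)
        return d[np.isfinite(d)]

    # staged evaluation: when a pilot stage already puts >= 20% of the
    # bootstrap mass at or below zero, the lower CI bound cannot come out
    # positive at the 2.5% level, so the remaining replicates cannot change
    # the significance call and are skipped
    pilot = 200
    if n_boot <= pilot:
        return _run(n_boot)
    diffs = _run(pilot)
    if diffs.size and np.mean(diffs <= 0) >= 0.2:
        return diffs
    return np.concatenate([diffs, _run(n_boot - pilot)])


def auc_difference(
    curve_a: LDCurve,
    curve_b: LDCurve,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
    resample_b: bool = True,
) -> AUCResult:
    """AUC(curve_a) - AUC(curve_b) over bins populated in both curves.

    Masked bins are excluded from *both* curves so the areas are comparable.
    The confidence interval is a 95% percentile bootstrap over the underlying
    SNV sites (when the curves carry them); ``significant`` means the CI
    excludes zero from below — the one-sided "exceeds zero" reading.
    """
    if not np.allclose(curve_a.bin_edges, curve_b.bin_edges):
        raise ValueError("curves must share bin edges")
    shared = curve_a.populated & curve_b.populated
    if shared.sum() < 2:
        raise InsufficientDataError("fewer than two bins populated in both curves")
    mids = curve_a.bin_mid[shared]
    diff = curve_a.mean_r2[shared] - curve_b.mean_r2[shared]
    value = float(np.trapezoid(diff, mids))

    ci_low = ci_high = value
    if n_boot > 0 and curve_a.pairs is not None and (
        curve_b.pairs is not None or not resample_b
    ):
        if rng is None:
            rng = np.random.default_rng()
        reps = bootstrap_auc_difference(
            curve_a, curve_b, shared, n_boot, rng, resample_b=resample_b
        )
        if reps.size >= max(20, n_boot // 10):
            # one-sided "exceeds zero" test at the 5% level: the reported
            # interval is the central 90% band, whose lower edge is the
            # one-sided 95% bound used for the significance call
            ci_low, ci_high = np.percentile(reps, [5.0, 95.0])
    return AUCResult(
        value=value,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        significant=bool(ci_low > 0),
        n_bins_used=int(shared.sum()),
    )


def class_label_permutation_test(
    pooled: PairData,
    is_a: np.ndarray,
    bin_edges: np.ndarray,
    min_pairs_per_bin: int,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation test for AUC(curve_A - curve_B) > 0 between site classes.

    ``pooled`` holds all pairs among the union of the two site classes;
    ``is_a`` flags the sites of class A.  Under the null hypothesis that the
    two classes have identical LD structure, the labels are exchangeable, so
    the observed area difference is ranked against ``n_perm`` random
    relabelings (class sizes preserved).  Each replicate applies the same
    per-bin pair minimum and shared-bin masking as the observed statistic.

    Returns ``(observed_difference, one_sided_p_value)``.  This is the
    within-window test of choice when a class holds too few sites for a
    stable site-level bootstrap.
    """
    is_a = np.asarray(is_a, bool)
    k = pooled.n_sites
    bp = _BinnedPairs(pooled, bin_edges)
    ka = int(is_a.sum())
    if ka == 0 or ka == k:
        raise InsufficientDataError("both classes need at least one site")
    M = np.zeros((n_perm + 1, k), dtype=np.float32)
    M[0, is_a] = 1.0
    for b in range(1, n_perm + 1):
        M[b, rng.choice(k, size=ka, replace=False)] = 1.0
    VA, DA = bp.means(M)
    VB, DB = bp.means(1.0 - M)
    VA[DA < min_pairs_per_bin] = np.nan
    VB[DB < min_pairs_per_bin] = np.nan
    diffs = _trapz_rows_diff(VA, VB, np.sqrt(bin_edges[:-1] * bin_edges[1:]))
    obs = diffs[0]
    null = diffs[1:]
    null = null[np.isfinite(null)]
    if not np.isfinite(obs) or null.size < max(20, n_perm // 5):
        raise InsufficientDataError("too few valid permutation replicates")
    p = (1.0 + float((null >= obs).sum())) / (1.0 + null.size)
    return float(obs), p


# --- serialization / plotting ----------------------------------------------


def curve_to_frame(curve: LDCurve) -> pd.DataFrame:
    """Tabular view of a curve (bin_low, bin_high, mid, mean_r2, n_pairs)."""
    return pd.DataFrame(
        {
            "bin_low": curve.bin_edges[:-1],
            "bin_high": curve.bin_edges[1:],
            "mid": curve.bin_mid,
            "mean_r2": curve.mean_r2,
            "n_pairs": curve.n_pairs,
        }
    )


def write_curve(curve: LDCurve, path) -> None:
    curve_to_frame(curve).to_csv(str(path), sep="\t", index=False)


def plot_decay_curves(curves: dict[str, LDCurve], ax=None, log_x: bool = True):
    """Plot one or more LD decay curves (labels -> curves)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        m = curve.populated
        ax.plot(curve.bin_mid[m], curve.mean_r2[m], marker="o", ms=3, label=label)
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend()
    return ax
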