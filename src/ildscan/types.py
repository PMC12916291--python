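"""Core containers shared across ildscan modules.

Nucleotides are held as small unsigned integers (``A,C,G,T,N,- -> 0..5``) so
that column-wise operations on haplotype-by-position matrices stay vectorized.
Genomic coordinates are 0-based half-open everywhere inside the library; GFF3
input/output converts to and from the 1-based inclusive convention at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

# --- nucleotide encoding ----------------------------------------------------

NUCLEOTIDES = "ACGTN-"
A, C, G, T, MISSING_N, GAP = range(6)
#: codes >= MISSING_N are treated as missing data, never as alleles
FIRST_MISSING_CODE = MISSING_N

_CODE_OF = np.full(256, MISSING_N, dtype=np.uint8)
for _i, _ch in enumerate(NUCLEOTIDES):
    _CODE_OF[ord(_ch)] = _i
    _CODE_OF[ord(_ch.lower())] = _i

_CHAR_OF = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)

#: complement of each valid code (N and gap map to themselves)
COMPLEMENT = np.array([T, G, C, A, MISSING_N, GAP], dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_OF[raw]


def decode_sequence(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a nucleotide string."""
    return _CHAR_OF[codes].tobytes().decode("ascii")


# --- alignment and annotation ----------------------------------------------


@dataclass
class HaplotypeAlignment:
    """One phased sequence per strain/host, all the same length.

    ``matrix`` is ``n_haplotypes x length`` uint8 with the encoding above.
    """

    contig_id: str
    matrix: np.ndarray
    haplotype_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.haplotype_ids) != self.matrix.shape[0]:
            raise ValueError("haplotype_ids length must match matrix rows")
        if len(set(self.haplotype_ids)) != len(self.haplotype_ids):
            from .errors import DuplicateIdentifierError

            raise DuplicateIdentifierError("duplicate haplotype identifiers")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene interval on a contig.

    ``start``/``end`` are 0-based half-open internal coordinates;
    ``frame_offset`` is the number of bases to skip from the translation
    start (gene 5' end on its own strand) before the first complete codon.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")


# SiteTable is a plain pandas DataFrame with this column contract.
SITE_TABLE_COLUMNS = ["position", "major", "minor", "maf", "func_class", "n_called"]

SYN, NONSYN, OTHER = "SYN", "NONSYN", "OTHER"


def empty_site_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": pd.Series(dtype=np.int64),
            "major": pd.Series(dtype=str),
            "minor": pd.Series(dtype=str),
            "maf": pd.Series(dtype=float),
            "func_class": pd.Series(dtype=str),
            "n_called": pd.Series(dtype=np.int64),
        }
    )


# --- LD curves --------------------------------------------------------------


@dataclass
class LDCurve:
    """Distance-binned mean r^2 with pair counts.

    Bins with fewer than the requested minimum number of pairs are masked
    (``mean_r2`` is NaN there).  When built from data (rather than
    synthetically) the curve carries its underlying site/pair table so that
    site-level bootstraps can rebuild it.
    """

    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing
    bin_mid: np.ndarray  # length n_bins
    mean_r2: np.ndarray  # length n_bins, NaN where masked
    n_pairs: np.ndarray  # length n_bins
    pairs: Optional["PairData"] = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_mid = np.asarray(self.bin_mid, dtype=float)
        self.mean_r2 = np.asarray(self.mean_r2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")

    @property
    def populated(self) -> np.ndarray:
        return ~np.isnan(self.mean_r2)


@dataclass
class PairData:
    """Site pairs underlying an LD curve, for site-level bootstrap.

    ``site_positions`` lists the distinct sites; ``i``/``j`` index into it.
    """

    site_positions: np.ndarray  # (k,) contig coordinates
    i: np.ndarray  # (P,) local site index, i < j
    j: np.ndarray  # (P,)
    r2: np.ndarray  # (P,)
    dist: np.ndarray  # (P,) bp

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


@dataclass
class AUCResult:
    """Signed area difference between two LD curves, with bootstrap CI."""

    value: float
    ci_low: float
    ci_high: float
    significant: bool
    n_bins_used: int


# --- scan -------------------------------------------------------------------

AUTO = "auto"


@dataclass
class ScanConfig:
    """Parameters of the iLDS genome scan."""

    common_maf_min: float = 0.2
    window_size: object = AUTO  # bp, or AUTO to match genome-wide LD decay
    min_nonsyn_per_window: int = 5
    min_syn_per_window: int = 3
    bootstrap_reps: int = 1000
    dns_permutations: int = 400
    component_alpha: float = 0.05
    ilds_threshold_percentile: float = 0.999
    min_pairs_per_bin: int = 10
    n_bins: int = 18
    n_window_bins: int = 6
    min_pairs_per_window_bin: int = 2
    min_bin_distance: float = 100.0
    max_distance: Optional[float] = None  # default: third of contig length
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.common_maf_min <= 0.5):
            raise ValueError("common_maf_min must be in (0, 0.5]")
        if self.window_size != AUTO and not self.window_size > 0:
            raise ValueError("window_size must be positive or AUTO")
        if not (0.0 < self.ilds_threshold_percentile < 1.0):
            raise ValueError("ilds_threshold_percentile must be in (0, 1)")


@dataclass
class WindowScore:
    """Per-window iLDS components and significance flags."""

    contig_id: str
    center_position: int
    window_start: int
    window_end: int
    r2_dNS: float
    r2_dLG: float
    dNS_ci: tuple[float, float]
    dLG_ci: tuple[float, float]
    z_dNS: float = np.nan
    z_dLG: float = np.nan
    ilds: float = np.nan
    p_dNS: float = np.nan
    sig_dNS: bool = False
    sig_dLG: bool = False
    significant: bool = False


@dataclass
class SweepCall:
    """A merged run of significant windows: one putative selective sweep."""

    contig_id: str
    start: int
    end: int
    peak_ilds: float
    n_windows: int
    genes: list[str] = field(default_factory=list)


# --- simulation -------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Full parameterization of one forward Wright-Fisher run.

    Rates are per generation.  ``demography`` lists ``(generation, new_N)``
    resize steps, generations counted from the start of the forward phase.
    ``sweep_origin_generation`` (if set) introduces one beneficial mutation at
    that forward generation, re-seeding it on loss.
    """

    Ne: int = 10_000
    n_genes: int = 50
    gene_length: int = 999  # bp, multiple of 3
    spacer_length: int = 21  # intergenic bp between genes
    mu: float = 1.5e-7  # per site per generation
    rho: float = 2.0e-3  # per individual per generation HGT initiation
    tract_mean: float = 3_000.0  # mean recombined tract length, bp
    s_D: float = 0.0  # magnitude of deleterious coefficient on NONSYN
    nonsyn_deleterious_fraction: float = 0.5  # DFE: share of NONSYN hit by s_D
    s_B: float = 0.0  # beneficial coefficient of the sweep allele
    sweep_origin_generation: Optional[int] = None
    sweep_target_frequency: float = 0.5  # stop and sample once reached
    sweep_generation_cap: int = 20_000  # post-introduction cap
    establishment_attempts: int = 2_000  # re-seeds before giving up
    demography: list[tuple[int, int]] = field(default_factory=list)
    burn_in_generations: int = 1_000
    sample_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")
        if self.s_D < 0 or self.s_B < 0:
            raise ValueError("selection coefficients are magnitudes, >= 0")
        if self.tract_mean < 1:
            raise ValueError("tract_mean must be >= 1 bp")
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be a multiple of 3")

    @property
    def L(self) -> int:
        """Total genome length in bp (genes plus flanking/intergenic spacers)."""
        return (
            self.n_genes * self.gene_length + (self.n_genes + 1) * self.spacer_length
        )


@dataclass
class SimulationResult:
    """Sampled haplotypes plus full ground truth of one simulation."""

    config: SimulationConfig
    alignment: HaplotypeAlignment
    genes: list[GeneModel]
    reference: np.ndarray  # ancestral genome, encoded
    truth: pd.DataFrame  # position, effect_class, s, pop_frequency, sample_frequency
    sweep_site: Optional[int]
    sweep_frequency: float


# --- comparative ------------------------------------------------------------


@dataclass
class PopulationSweepSet:
    """Sweep intervals of one population on a shared reference."""

    population_id: str
    group: str  # e.g. industrialized / non_industrialized / other
    sweeps: list[SweepCall]


# --- benchmark --------------------------------------------------------------


@dataclass
class BenchmarkReport:
    """Outcome of a simulate -> scan validation run."""

    scenario: str
    n_replicates: int
    fpr: float
    fpr_ci: tuple[float, float]
    n_windows_total: int
    n_significant_total: int
    power_by_parameters: pd.DataFrame  # columns: s_B, s_D, n, power, locate_rate
    runtime_seconds: float
    config: dict = field(default_factory=dict)
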