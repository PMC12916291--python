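"""Forward-time Wright-Fisher simulation of a recombining bacterial population.

The model is a haploid, clonally reproducing population of ``N`` genomes with:

* a codon-structured genome — tandem protein-coding genes (alternating
  strands) separated by short intergenic spacers — so that the
  synonymous/non-synonymous status of every possible point mutation arises
  mechanistically from the genetic code rather than from a fixed fraction;
* multiplicative selection: each non-synonymous mutation multiplies fitness
  by ``1 - s_D``; a single optional beneficial allele multiplies it by
  ``1 + s_B``;
* HGT-style homologous recombination: each offspring initiates, with
  probability ``rho`` per generation, the replacement of one contiguous
  tract (geometric length, mean ``tract_mean``) by the homologous tract of
  a uniformly chosen donor from the parental generation — the
  gene-conversion-like mechanism by which genomic fragments move between
  strains;
* optional step-wise demography and a sweep conditioned on establishment
  (the beneficial mutation is re-seeded whenever it is lost).

Populations are initialized at neutral coalescent equilibrium using msprime
(haploid samples with gene-conversion recombination at the matching rates),
after which the forward phase imposes selection, demography and the sweep.
This hybrid keeps desk-scale runs fast while preserving equilibrium neutral
diversity; deleterious variation relaxes to mutation-selection balance over
the forward burn-in (a few times ``1/s_D`` generations).

Rescaled ("desk scale") runs keep the diffusion-limit products ``Ne*s``,
``Ne*mu*L`` and ``Ne*rho`` fixed, so the selection/drift/recombination
regimes match the full-scale parameterization.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional

import msprime
import numpy as np
import pandas as pd

from .errors import ConditioningError, UsageError
from .io_annotation import CODON_AA
from .types import (
    COMPLEMENT,
    GeneModel,
    HaplotypeAlignment,
    SimulationConfig,
    SimulationResult,
)

logger = logging.getLogger(__name__)

# effect-class codes used internally
CLS_SYN, CLS_NONSYN, CLS_OTHER, CLS_BENEFICIAL = 0, 1, 2, 3
CLASS_NAMES = np.array(["SYN", "NONSYN", "OTHER", "BENEFICIAL"])

_CODON_AA_ID = np.frombuffer(
    "".join(CODON_AA).encode("ascii"), dtype=np.uint8
)  # amino-acid identity per codon index


# --- genome construction ----------------------------------------------------


def _random_sense_codons(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) nucleotide codes forming stop-free codons."""
    sense = np.array(
        [i for i in range(64) if CODON_AA[i] != "*"], dtype=np.int64
    )
    idx = rng.choice(sense, size=n)
    return np.stack([idx // 16, (idx // 4) % 4, idx % 4], axis=1).astype(np.uint8)


def build_reference_genome(
    cfg: SimulationConfig, rng: np.random.Generator, contig_id: str = "contig_1"
) -> tuple[np.ndarray, list[GeneModel]]:
    """Random codon-structured reference: tandem genes with spacers.

    Genes alternate between the two strands; each gene body is stop-free in
    its own reading direction.
    """
    L = cfg.L
    ref = rng.integers(0, 4, size=L).astype(np.uint8)  # spacers: random bases
    genes: list[GeneModel] = []
    pos = cfg.spacer_length
    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        codons = _random_sense_codons(cfg.gene_length // 3, rng)
        body = codons.reshape(-1)
        if strand == "-":
            body = COMPLEMENT[body[::-1]]
        ref[pos : pos + cfg.gene_length] = body
        genes.append(
            GeneModel(
                gene_id=f"gene_{g + 1:03d}",
                contig_id=contig_id,
                start=pos,
                end=pos + cfg.gene_length,
                strand=strand,
                frame_offset=0,
            )
        )
        pos += cfg.gene_length + cfg.spacer_length
    return ref, genes


def mutation_effect_table(ref: np.ndarray, genes: list[GeneModel]) -> np.ndarray:
    """(L, 4) effect class of substituting each position by each base.

    CLS_OTHER for intergenic positions (and for the no-change column).
    Classes are relative to the ancestral reference codon context.
    """
    L = len(ref)
    table = np.full((L, 4), CLS_OTHER, dtype=np.int8)
    w = np.array([16, 4, 1])
    for gene in genes:
        first = gene.start + gene.frame_offset if gene.strand == "+" else gene.start
        if gene.strand == "+":
            n_codons = (gene.end - first) // 3
            cpos = first + np.arange(3 * n_codons).reshape(-1, 3)
        else:
            last = gene.end - 1 - gene.frame_offset
            n_codons = (last + 1 - gene.start) // 3
            cpos = (last - np.arange(3 * n_codons))[::-1].reshape(-1, 3)
        codon = ref[cpos].astype(np.int64)  # genomic-orientation codon (n, 3)
        if gene.strand == "-":
            codon_read = COMPLEMENT[codon[:, ::-1]].astype(np.int64)
        else:
            codon_read = codon
        idx0 = codon_read @ w
        aa0 = _CODON_AA_ID[idx0]
        for k in range(3):  # genomic slot within codon
            rk = k if gene.strand == "+" else 2 - k  # slot in reading orientation
            for a in range(4):
                base = a if gene.strand == "+" else int(COMPLEMENT[a])
                idx_new = idx0 + (base - codon_read[:, rk]) * w[rk]
                cls = np.where(
                    _CODON_AA_ID[idx_new] == aa0, CLS_SYN, CLS_NONSYN
                ).astype(np.int8)
                same = codon[:, k] == a
                cls[same] = CLS_OTHER  # no change: not a mutation
                table[cpos[:, k], a] = cls
    return table


# --- coalescent initialization ----------------------------------------------


def _initial_population(
    cfg: SimulationConfig, seeds: tuple[int, int], rng: np.random.Generator,
    ref: np.ndarray, effect: np.ndarray,
):
    """Neutral-equilibrium founding population from msprime.

    Returns (pop matrix N x M uint8, positions, derived codes, classes).
    """
    anc = msprime.sim_ancestry(
        samples=cfg.Ne,
        ploidy=1,
        population_size=cfg.Ne,
        sequence_length=cfg.L,
        gene_conversion_rate=cfg.rho / cfg.L if cfg.rho > 0 else None,
        gene_conversion_tract_length=cfg.tract_mean if cfg.rho > 0 else None,
        discrete_genome=True,
        random_seed=seeds[0],
    )
    if cfg.mu > 0:
        ts = msprime.sim_mutations(
            anc,
            rate=cfg.mu,
            model=msprime.BinaryMutationModel(),
            discrete_genome=True,
            random_seed=seeds[1],
        )
    else:
        ts = anc
    if ts.num_sites == 0:
        pop = np.zeros((cfg.Ne, 0), dtype=np.uint8)
        return (pop, np.zeros(0, np.int64), np.zeros(0, np.uint8),
                np.zeros(0, np.int8), np.zeros(0, bool))
    gm = ts.genotype_matrix()  # (sites, samples), 0/1 under the binary model
    positions = np.array([int(s.position) for s in ts.sites()], dtype=np.int64)
    seg = (gm.sum(axis=1) > 0) & (gm.sum(axis=1) < cfg.Ne)
    gm, positions = gm[seg], positions[seg]
    derived = (ref[positions] + 1 + rng.integers(0, 3, size=len(positions))).astype(
        np.uint8
    ) % 4
    classes = effect[positions, derived]
    delflag = (classes == CLS_NONSYN) & (
        rng.random(len(positions)) < cfg.nonsyn_deleterious_fraction
    )
    if cfg.s_D > 0:
        # the coalescent init is neutral; thin standing deleterious variants
        # to the mutation-selection-balance spectrum (frequency-x deleterious
        # alleles are suppressed by ~exp(-2 N s x) relative to neutral), else
        # the forward phase starts with a massive load whose purging crashes
        # diversity genome-wide
        freq = gm.sum(axis=1) / cfg.Ne
        keep_p = np.exp(-2.0 * cfg.Ne * cfg.s_D * freq)
        keep = ~delflag | (rng.random(len(positions)) < keep_p)
        gm, positions = gm[keep], positions[keep]
        derived, classes, delflag = derived[keep], classes[keep], delflag[keep]
    return gm.T.astype(np.uint8).copy(), positions, derived, classes, delflag


# --- forward engine ---------------------------------------------------------


class _ForwardPopulation:
    """Mutable forward-simulation state (one population, one contig)."""

    def __init__(self, cfg, rng, ref, effect, pop, positions, derived, classes,
                 delflag=None):
        self.cfg = cfg
        self.rng = rng
        self.ref = ref
        self.effect = effect
        self.pop = pop  # (N, M) uint8
        self.positions = positions.astype(np.int64)
        self.derived = derived.astype(np.uint8)
        self.classes = classes.astype(np.int8)
        if delflag is None:
            delflag = self.classes == CLS_NONSYN
        self.delflag = np.asarray(delflag, dtype=bool)
        self.N = pop.shape[0]
        self.ben_col: Optional[int] = None
        self.reseed_count = 0
        self._refresh_caches()

    # -- caches --------------------------------------------------------------

    def _refresh_caches(self):
        self.order = np.argsort(self.positions, kind="stable")
        self.sorted_pos = self.positions[self.order]
        self.del_cols = np.nonzero(self.delflag)[0]

    @property
    def M(self) -> int:
        return self.pop.shape[1]

    # -- per-generation dynamics --------------------------------------------

    def fitness(self) -> np.ndarray:
        w = np.ones(self.N)
        if self.cfg.s_D > 0 and self.del_cols.size:
            counts = self.pop[:, self.del_cols].sum(axis=1, dtype=np.int64)
            w *= np.power(1.0 - self.cfg.s_D, counts)
        if self.ben_col is not None and self.cfg.s_B > 0:
            w *= 1.0 + self.cfg.s_B * self.pop[:, self.ben_col]
        return w

    def step(self):
        rng = self.rng
        w = self.fitness()
        cw = np.cumsum(w)
        parents = np.searchsorted(cw, rng.random(self.N) * cw[-1], side="right")
        parents[parents == self.N] = self.N - 1  # guard fp rounding
        prev = self.pop
        pop = prev[parents]

        # HGT: tract replacement from a random donor of the parent generation
        if self.cfg.rho > 0 and self.M:
            recipients = np.nonzero(rng.random(self.N) < self.cfg.rho)[0]
            for i in recipients:
                donor = rng.integers(self.N)
                start = rng.integers(self.cfg.L)
                length = rng.geometric(1.0 / self.cfg.tract_mean)
                a = np.searchsorted(self.sorted_pos, start)
                b = np.searchsorted(self.sorted_pos, start + length)
                if b > a:
                    cols = self.order[a:b]
                    pop[i, cols] = prev[donor, cols]
        self.pop = pop
        self._mutate()

    def _mutate(self):
        cfg, rng = self.cfg, self.rng
        if cfg.mu <= 0:
            return
        n_new = rng.poisson(cfg.mu * cfg.L * self.N)
        if n_new == 0:
            return
        pos = rng.integers(0, cfg.L, size=n_new)
        pos = np.unique(pos)
        # one segregating mutation per site (recurrent hits are ignored)
        pos = pos[~np.isin(pos, self.positions)]
        if pos.size == 0:
            return
        alt = ((self.ref[pos] + 1 + rng.integers(0, 3, size=pos.size)) % 4).astype(
            np.uint8
        )
        cls = self.effect[pos, alt]
        flag = (cls == CLS_NONSYN) & (
            rng.random(pos.size) < cfg.nonsyn_deleterious_fraction
        )
        carriers = rng.integers(0, self.N, size=pos.size)
        block = np.zeros((self.N, pos.size), dtype=np.uint8)
        block[carriers, np.arange(pos.size)] = 1
        self.pop = np.concatenate([self.pop, block], axis=1)
        self.positions = np.concatenate([self.positions, pos])
        self.derived = np.concatenate([self.derived, alt])
        self.classes = np.concatenate([self.classes, cls])
        self.delflag = np.concatenate([self.delflag, flag])
        self._refresh_caches()

    def prune(self):
        """Drop fixed and lost mutations (the beneficial column is kept)."""
        counts = self.pop.sum(axis=0, dtype=np.int64)
        keep = (counts > 0) & (counts < self.N)
        if self.ben_col is not None:
            keep[self.ben_col] = True
        if keep.all():
            return
        kept_idx = np.nonzero(keep)[0]
        if self.ben_col is not None:
            self.ben_col = int(np.searchsorted(kept_idx, self.ben_col))
        self.pop = self.pop[:, keep]
        self.positions = self.positions[keep]
        self.derived = self.derived[keep]
        self.classes = self.classes[keep]
        self.delflag = self.delflag[keep]
        self._refresh_caches()

    def resize(self, new_N: int):
        rng = self.rng
        if new_N <= self.N:
            rows = rng.choice(self.N, size=new_N, replace=False)
        else:
            rows = rng.integers(0, self.N, size=new_N)
        self.pop = self.pop[rows]
        self.N = new_N

    # -- sweep bookkeeping ---------------------------------------------------

    def introduce_beneficial(self, position: int, allele: int):
        col = np.zeros((self.N, 1), dtype=np.uint8)
        col[self.rng.integers(self.N), 0] = 1
        self.pop = np.concatenate([self.pop, col], axis=1)
        self.positions = np.concatenate([self.positions, [position]])
        self.derived = np.concatenate(
            [self.derived, np.array([allele], dtype=np.uint8)]
        )
        self.classes = np.concatenate(
            [self.classes, np.array([CLS_BENEFICIAL], dtype=np.int8)]
        )
        self.delflag = np.concatenate([self.delflag, [False]])
        self.ben_col = self.M - 1
        self._refresh_caches()

    def beneficial_count(self) -> int:
        if self.ben_col is None:
            return 0
        return int(self.pop[:, self.ben_col].sum())

    def reseed_beneficial(self):
        self.reseed_count += 1
        if self.reseed_count > self.cfg.establishment_attempts:
            raise ConditioningError(
                f"beneficial allele failed to establish within "
                f"{self.cfg.establishment_attempts} re-seeding attempts"
            )
        self.pop[self.rng.integers(self.N), self.ben_col] = 1


def _pick_sweep_site(effect: np.ndarray, L: int) -> tuple[int, int]:
    """Nearest position to the genome midpoint admitting a NONSYN change."""
    center = L // 2
    for off in range(L // 2):
        for p in (center - off, center + off):
            if 0 <= p < L:
                alts = np.nonzero(effect[p] == CLS_NONSYN)[0]
                if alts.size:
                    return p, int(alts[0])
    raise UsageError("genome admits no non-synonymous change")  # pragma: no cover


# --- top-level simulate -----------------------------------------------------

_PRUNE_EVERY = 16


def simulate(cfg: SimulationConfig, contig_id: str = "contig_1") -> SimulationResult:
    """Run one forward simulation and sample haplotypes with full truth.

    Deterministic given ``cfg`` (all randomness flows from ``cfg.seed``).
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_anc, s_mut, s_fwd, s_ref = [
        int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(4)
    ]
    ref_rng = np.random.default_rng(s_ref)
    rng = np.random.default_rng(s_fwd)

    ref, genes = build_reference_genome(cfg, ref_rng, contig_id)
    effect = mutation_effect_table(ref, genes)
    pop0, positions, derived, classes, delflag = _initial_population(
        cfg, (s_anc, s_mut), rng, ref, effect
    )
    state = _ForwardPopulation(
        cfg, rng, ref, effect, pop0, positions, derived, classes, delflag
    )

    demography = sorted(cfg.demography)
    demo_i = 0
    sweep_gen = cfg.sweep_origin_generation
    sweep_active = False
    sweep_pos = sweep_alt = None
    gen = 0

    def maybe_resize():
        nonlocal demo_i
        while demo_i < len(demography) and demography[demo_i][0] <= gen:
            state.resize(int(demography[demo_i][1]))
            demo_i += 1

    end_burn = max(cfg.burn_in_generations, sweep_gen or 0)
    sweep_start = 0
    while True:
        maybe_resize()
        if sweep_gen is not None and not sweep_active and gen >= sweep_gen:
            sweep_pos, sweep_alt = _pick_sweep_site(effect, cfg.L)
            state.introduce_beneficial(sweep_pos, sweep_alt)
            sweep_active = True
            sweep_start = gen
        if sweep_active:
            cnt = state.beneficial_count()
            if cnt == 0:
                state.reseed_beneficial()
            elif cnt / state.N >= cfg.sweep_target_frequency:
                break
            if gen - sweep_start >= cfg.sweep_generation_cap:
                logger.warning(
                    "sweep cap reached at frequency %.3f", cnt / state.N
                )
                break
        elif gen >= end_burn:
            break
        state.step()
        gen += 1
        if gen % _PRUNE_EVERY == 0:
            state.prune()

    state.prune()

    # --- sample and assemble outputs ---------------------------------------
    n_sample = min(cfg.sample_size, state.N)
    rows = rng.choice(state.N, size=n_sample, replace=False)
    sub = state.pop[rows]
    matrix = np.tile(ref, (n_sample, 1))
    r_idx, c_idx = np.nonzero(sub)
    matrix[r_idx, state.positions[c_idx]] = state.derived[c_idx]

    aln = HaplotypeAlignment(
        contig_id=contig_id,
        matrix=matrix,
        haplotype_ids=[f"hap_{i + 1:04d}" for i in range(n_sample)],
    )
    pop_freq = state.pop.sum(axis=0) / state.N
    samp_freq = sub.sum(axis=0) / n_sample
    truth = pd.DataFrame(
        {
            "position": state.positions,
            "effect_class": CLASS_NAMES[state.classes],
            "s": np.select(
                [state.delflag, state.classes == CLS_BENEFICIAL],
                [-cfg.s_D, cfg.s_B],
                0.0,
            ),
            "pop_frequency": pop_freq,
            "sample_frequency": samp_freq,
        }
    ).sort_values("position", ignore_index=True)

    sweep_freq = 0.0
    if sweep_active and state.ben_col is not None:
        sweep_freq = float(pop_freq[state.ben_col])
    return SimulationResult(
        config=cfg,
        alignment=aln,
        genes=genes,
        reference=ref,
        truth=truth,
        sweep_site=sweep_pos if sweep_active and sweep_freq > 0 else None,
        sweep_frequency=sweep_freq,
    )


# --- scenario suites --------------------------------------------------------

SCENARIOS = (
    "neutral",
    "purifying_only",
    "sweep_grid",
    "contraction",
    "low_recombination",
)

#: full-scale baseline shared by all scenarios
BASE_CONFIG = SimulationConfig(
    Ne=10_000,
    mu=1.5e-7,
    rho=2.0e-3,
    tract_mean=3_000.0,
    burn_in_generations=1_000,
)

_SELECTED_BURN_IN = 2_000  # a few 1/s_D at the paper's s_D once rescaled

SWEEP_GRID_S_B = (0.0, 1e-3, 1e-2, 1e-1)
SWEEP_GRID_S_D = (0.0, 1e-4, 1e-3, 1e-2)


def rescale(cfg: SimulationConfig, scale: float) -> SimulationConfig:
    """Desk-scale a configuration keeping Ne*s, Ne*mu*L and Ne*rho fixed.

    Population size and generation counts shrink by ``scale``; per-generation
    rates and selection coefficients grow by ``1/scale``.
    """
    if not (0 < scale <= 1):
        raise UsageError("scale must be in (0, 1]")
    return replace(
        cfg,
        Ne=max(2, round(cfg.Ne * scale)),
        mu=cfg.mu / scale,
        rho=cfg.rho / scale,
        s_D=cfg.s_D / scale,
        s_B=cfg.s_B / scale,
        burn_in_generations=round(cfg.burn_in_generations * scale),
        sweep_origin_generation=(
            None
            if cfg.sweep_origin_generation is None
            else round(cfg.sweep_origin_generation * scale)
        ),
        sweep_generation_cap=max(200, round(cfg.sweep_generation_cap * scale)),
        demography=[(round(g * scale), max(2, round(n * scale))) for g, n in cfg.demography],
    )


def scenario_suite(
    name: str,
    scale: float = 1.0,
    n_replicates: int = 1,
    base_seed: int = 0,
) -> list[SimulationConfig]:
    """Deterministic configuration lists for the validation scenarios.

    ``scale`` rescales every config for desk runs (see :func:`rescale`);
    seeds are distinct and derived from ``base_seed``.
    """
    if name not in SCENARIOS:
        raise UsageError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    base = BASE_CONFIG
    protos: list[SimulationConfig] = []
    if name == "neutral":
        protos = [base]
    elif name == "purifying_only":
        protos = [
            replace(base, s_D=1e-3, burn_in_generations=_SELECTED_BURN_IN)
        ]
    elif name == "contraction":
        protos = [
            replace(
                base,
                burn_in_generations=3_000,
                demography=[(2_000, base.Ne // 10)],
            )
        ]
    elif name == "low_recombination":
        protos = [replace(base, rho=base.rho / 10)]
    elif name == "sweep_grid":
        for s_b in SWEEP_GRID_S_B:
            for s_d in SWEEP_GRID_S_D:
                protos.append(
                    replace(
                        base,
                        s_D=s_d,
                        s_B=s_b,
                        burn_in_generations=_SELECTED_BURN_IN,
                        sweep_origin_generation=(
                            _SELECTED_BURN_IN if s_b > 0 else None
                        ),
                    )
                )
    configs = []
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(
        len(protos) * n_replicates
    )]
    k = 0
    for proto in protos:
        for _ in range(n_replicates):
            configs.append(replace(rescale(proto, scale), seed=seeds[k]))
            k += 1
    return configs
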