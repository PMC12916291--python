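"""Alignment/annotation input, SNV extraction and SYN/NONSYN classification.

The substrate of every LD quantity in this package is a haplotype alignment
(one phased sequence per strain) plus gene models giving reading frames.
This module reads both from standard formats (multi-FASTA, GFF3), extracts
biallelic single-nucleotide variants, and classifies each variant as
synonymous or non-synonymous by codon translation under the standard genetic
code.  Sites whose codon context is itself polymorphic are classified OTHER
and excluded from the N/S stratified curves: the synonymous/non-synonymous
dichotomy presumes an unambiguous single-site amino-acid effect.

Coordinates are 0-based half-open internally; GFF3 is converted at the
boundary (1-based inclusive on disk).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentFormatError,
    CoordinateError,
    DuplicateIdentifierError,
    EmptyInputError,
)
from .types import (
    COMPLEMENT,
    FIRST_MISSING_CODE,
    GeneModel,
    HaplotypeAlignment,
    NONSYN,
    OTHER,
    SYN,
    decode_sequence,
    empty_site_table,
    encode_sequence,
)

logger = logging.getLogger(__name__)

# --- the standard genetic code as a 64-entry lookup -------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"

#: amino acid (one letter, '*' for stop) for codon index 16*b0 + 4*b1 + b2
CODON_AA = np.zeros(64, dtype="<U1")
for _i0, _b0 in enumerate(_BASES):
    for _i1, _b1 in enumerate(_BASES):
        for _i2, _b2 in enumerate(_BASES):
            _codon = _b0 + _b1 + _b2
            _idx = 16 * _i0 + 4 * _i1 + _i2
            if _codon in _STANDARD_TABLE.stop_codons:
                CODON_AA[_idx] = "*"
            else:
                CODON_AA[_idx] = _STANDARD_TABLE.forward_table[_codon]


def translate_codon(codes: Sequence[int]) -> str:
    """Amino acid for a codon given as three nucleotide codes (stop = '*')."""
    b0, b1, b2 = codes
    if max(b0, b1, b2) >= FIRST_MISSING_CODE:
        raise ValueError("codon contains missing data")
    return CODON_AA[16 * b0 + 4 * b1 + b2]


# --- alignment I/O ----------------------------------------------------------


def load_alignment(path, contig_id: Optional[str] = None) -> HaplotypeAlignment:
    """Read a multi-FASTA haplotype alignment.

    All records must have identical length; lowercase is upper-cased and any
    symbol outside ACGT- is mapped to N (missing).

    Parameters
    ----------
    path
        FASTA file with one record per haplotype.
    contig_id
        Name of the contig the alignment covers; defaults to the file stem.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DuplicateIdentifierError(f"duplicate record identifiers in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"records in {path} have unequal lengths: {sorted(lengths)}"
        )
    matrix = np.vstack([encode_sequence(str(r.seq)) for r in records])
    if contig_id is None:
        import os

        contig_id = os.path.splitext(os.path.basename(str(path)))[0]
    return HaplotypeAlignment(contig_id=contig_id, matrix=matrix, haplotype_ids=ids)


def write_alignment(aln: HaplotypeAlignment, path) -> None:
    """Write a haplotype alignment as multi-FASTA."""
    records = [
        SeqRecord(Seq(decode_sequence(row)), id=hid, description="")
        for hid, row in zip(aln.haplotype_ids, aln.matrix)
    ]
    SeqIO.write(records, str(path), "fasta")


# --- gene model I/O (GFF3) --------------------------------------------------

_GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def load_genes(path, feature_types: Iterable[str] = ("gene", "CDS")) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    ``gene`` and ``CDS`` features are accepted; when both describe the same ID
    the CDS wins (it carries the phase).  GFF3 1-based inclusive coordinates
    are converted to the library's 0-based half-open convention; the CDS
    ``phase`` column becomes the frame offset.
    """
    df = pd.read_csv(
        str(path),
        sep="\t",
        comment="#",
        names=_GFF_COLUMNS,
        dtype={"seqid": str, "type": str, "strand": str, "phase": str},
    )
    if df.empty:
        raise EmptyInputError(f"no features in {path}")
    df = df[df["type"].isin(set(feature_types))]
    genes: dict[str, GeneModel] = {}
    cds_ids: set[str] = set()
    for _, row in df.iterrows():
        attrs = dict(
            item.split("=", 1) for item in str(row["attributes"]).split(";") if "=" in item
        )
        gene_id = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name")
        if gene_id is None:
            gene_id = f"{row['seqid']}:{row['start']}-{row['end']}"
        gene_id = gene_id.removesuffix("_cds")
        phase = row["phase"]
        frame = int(phase) if str(phase).isdigit() else 0
        model = GeneModel(
            gene_id=gene_id,
            contig_id=str(row["seqid"]),
            start=int(row["start"]) - 1,
            end=int(row["end"]),
            strand=str(row["strand"]) if str(row["strand"]) in "+-" else "+",
            frame_offset=frame,
        )
        is_cds = row["type"] == "CDS"
        if gene_id not in genes or (is_cds and gene_id not in cds_ids):
            genes[gene_id] = model
        if is_cds:
            cds_ids.add(gene_id)
    return list(genes.values())


def write_genes(genes: Sequence[GeneModel], path, source: str = "ildscan") -> None:
    """Write gene models as GFF3 (CDS features, 1-based inclusive)."""
    with open(str(path), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig_id}\t{source}\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t{g.frame_offset}\t{attrs}\n"
            )


# --- annotation index -------------------------------------------------------


class AnnotationIndex:
    """Per-position codon bookkeeping for one contig.

    For every position inside a complete codon of some gene this records the
    gene, the genomic start of its codon, and the gene strand, enabling
    vectorized classification of many variants at once.  Overlapping genes are
    resolved in favour of the later one in the input list.
    """

    def __init__(self, genes: Sequence[GeneModel], length: int):
        self.length = length
        self.gene_index = np.full(length, -1, dtype=np.int32)
        self.codon_start = np.full(length, -1, dtype=np.int64)
        self.is_reverse = np.zeros(length, dtype=bool)
        self.genes = list(genes)
        for gi, g in enumerate(self.genes):
            if g.end > length:
                raise CoordinateError(
                    f"gene {g.gene_id} extends past contig length {length}"
                )
            if g.strand == "+":
                first = g.start + g.frame_offset
                n_codons = (g.end - first) // 3
                if n_codons <= 0:
                    continue
                pos = np.arange(first, first + 3 * n_codons)
                cstart = first + 3 * ((pos - first) // 3)
            else:
                last = g.end - 1 - g.frame_offset  # 5' base on the - strand
                n_codons = (last + 1 - g.start) // 3
                if n_codons <= 0:
                    continue
                pos = np.arange(last - 3 * n_codons + 1, last + 1)
                # codon anchored from the 3' (genomic high) side
                cstart = last - 3 * ((last - pos) // 3) - 2
            self.gene_index[pos] = gi
            self.codon_start[pos] = cstart
            self.is_reverse[pos] = g.strand == "-"


def _column_consensus(aln: HaplotypeAlignment):
    """Per-column base counts, called counts, monomorphism flag and consensus."""
    m = aln.matrix
    counts = np.empty((4, aln.length), dtype=np.int32)
    for code in range(4):
        counts[code] = (m == code).sum(axis=0)
    n_called = counts.sum(axis=0)
    n_distinct = (counts > 0).sum(axis=0)
    consensus = counts.argmax(axis=0).astype(np.uint8)
    mono = (n_distinct == 1) & (n_called > 0)
    return counts, n_called, mono, consensus


def classify_sites(
    aln: HaplotypeAlignment,
    positions: np.ndarray,
    allele_codes: np.ndarray,
    genes: Sequence[GeneModel],
    *,
    _index: Optional[AnnotationIndex] = None,
    _consensus: Optional[tuple] = None,
) -> np.ndarray:
    """Classify many biallelic sites as SYN / NONSYN / OTHER at once.

    ``allele_codes`` is ``(n, 2)`` nucleotide codes for the two alleles at
    each position.  A site is SYN/NONSYN only when it sits inside a complete
    codon of a gene and the two flanking codon positions are monomorphic
    across haplotypes; everything else (intergenic, incomplete codon,
    polymorphic codon context) is OTHER.
    """
    positions = np.asarray(positions, dtype=np.int64)
    allele_codes = np.asarray(allele_codes, dtype=np.uint8).reshape(-1, 2)
    if positions.size and (positions.min() < 0 or positions.max() >= aln.length):
        raise CoordinateError("position outside contig")
    index = _index if _index is not None else AnnotationIndex(genes, aln.length)
    _, _, mono, consensus = (
        _consensus if _consensus is not None else _column_consensus(aln)
    )

    out = np.full(positions.shape, OTHER, dtype="<U6")
    in_gene = index.gene_index[positions] >= 0
    if not in_gene.any():
        return out

    idx = np.nonzero(in_gene)[0]
    pos = positions[idx]
    cstart = index.codon_start[pos]
    offset = (pos - cstart).astype(np.int64)  # 0, 1 or 2 within the genomic codon
    codon_pos = cstart[:, None] + np.arange(3)[None, :]  # (n, 3)

    # flanking codon positions must be monomorphic with a called consensus
    flank_ok = np.ones(len(idx), dtype=bool)
    for k in range(3):
        is_focal = offset == k
        flank_ok &= is_focal | mono[codon_pos[:, k]]

    codon = consensus[codon_pos].astype(np.int64)  # (n, 3) consensus codon
    rows = np.arange(len(idx))
    aa = np.empty((len(idx), 2), dtype="<U1")
    for a in range(2):
        cod = codon.copy()
        cod[rows, offset] = allele_codes[idx, a]
        rev = index.is_reverse[pos]
        if rev.any():
            rc = COMPLEMENT[cod[rev][:, ::-1]].astype(np.int64)
            cod[rev] = rc
        aa[:, a] = CODON_AA[16 * cod[:, 0] + 4 * cod[:, 1] + cod[:, 2]]

    syn = aa[:, 0] == aa[:, 1]
    cls = np.where(syn, SYN, NONSYN)
    cls[~flank_ok] = OTHER
    out[idx] = cls
    return out


def classify_site(
    aln: HaplotypeAlignment,
    position: int,
    alleles: tuple[str, str],
    genes: Sequence[GeneModel],
) -> str:
    """Classify one biallelic site; see :func:`classify_sites`."""
    codes = np.array(
        [[encode_sequence(alleles[0])[0], encode_sequence(alleles[1])[0]]]
    )
    return classify_sites(aln, np.array([position]), codes, genes)[0]


# --- SNV calling ------------------------------------------------------------


def call_snvs(
    aln: HaplotypeAlignment,
    genes: Sequence[GeneModel],
    min_called_fraction: float = 0.9,
) -> pd.DataFrame:
    """Extract biallelic SNVs from an alignment and classify them.

    A column is retained when exactly two distinct non-missing nucleotides
    segregate and at least ``min_called_fraction`` of haplotypes carry a
    called (non-missing, non-gap) base.  The minor-allele frequency is
    computed over called haplotypes only.  Returns a SiteTable DataFrame
    (columns ``position, major, minor, maf, func_class, n_called``).
    """
    n = aln.n_haplotypes
    counts, n_called, mono, consensus = _column_consensus(aln)
    n_distinct = (counts > 0).sum(axis=0)
    enough_called = n_called >= min_called_fraction * n
    biallelic = n_distinct == 2
    keep = biallelic & enough_called
    n_excluded = int(((n_distinct >= 2) & ~keep).sum())
    if n_excluded:
        logger.info("call_snvs: excluded %d polymorphic columns", n_excluded)
    positions = np.nonzero(keep)[0]
    if positions.size == 0:
        return empty_site_table()

    col = counts[:, positions]  # (4, k)
    order = np.argsort(col, axis=0)
    major = order[-1].astype(np.uint8)
    minor = order[-2].astype(np.uint8)
    minor_count = col[minor, np.arange(len(positions))]
    called = n_called[positions]
    maf = minor_count / called

    allele_codes = np.stack([major, minor], axis=1)
    index = AnnotationIndex(genes, aln.length)
    func = classify_sites(
        aln,
        positions,
        allele_codes,
        genes,
        _index=index,
        _consensus=(counts, n_called, mono, consensus),
    )
    bases = np.array(list("ACGT"))
    return pd.DataFrame(
        {
            "position": positions.astype(np.int64),
            "major": bases[major],
            "minor": bases[minor],
            "maf": maf,
            "func_class": func,
            "n_called": called.astype(np.int64),
        }
    )


def write_site_table(sites: pd.DataFrame, path) -> None:
    """Serialize a SiteTable as a tab-separated file with header."""
    sites.to_csv(str(path), sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    """Read a SiteTable written by :func:`write_site_table`."""
    return pd.read_csv(str(path), sep="\t")
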