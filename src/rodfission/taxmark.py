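"""Genome-based taxonomic markers: 16S identity, rank thresholds, POCP.

Pairwise percent identity is computed from a multiple alignment with an
explicit column convention: columns where both sequences carry a gap are
skipped, terminal-gap overhangs are skipped, and internal gap-vs-base
columns count as mismatches (configurable).  Identities are judged against
published 16S rRNA rank-delineation thresholds (genus 94.5%, family 86.5%,
order 82.0%, inclusive lower bounds).

POCP (percentage of conserved proteins) counts a query as conserved when it
has at least one hit with e-value < 1e-5, identity > 40% and alignable
length > 50% of the query; POCP = (C1 + C2) / (T1 + T2) x 100 over the two
reciprocal searches.

Genome feature arithmetic derives genes/Mb, protein-coding genes/Mb and the
hypothetical-protein percentage from per-genome annotation counts, with
half-up integer rounding, plus pairwise genome-size differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from rodfission.errors import FormatError, ValidationError

GAP = "-"


@dataclass(frozen=True)
class RankThresholds:
    """16S rRNA % identity thresholds for rank delineation (inclusive)."""

    genus: float = 94.5
    family: float = 86.5
    order: float = 82.0

    def __post_init__(self) -> None:
        if not (self.genus > self.family > self.order):
            raise ValidationError("thresholds must satisfy genus > family > order")


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a BLAST-style tabular search."""

    query_id: str
    subject_id: str
    evalue: float
    percent_identity: float
    alignment_length: int
    query_length: int

    def __post_init__(self) -> None:
        if self.alignment_length <= 0 or self.query_length <= 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: "
                                  "lengths must be positive")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError("percent_identity outside [0, 100]")


@dataclass(frozen=True)
class GenomeAnnotationSummary:
    """Per-genome annotation counts (Table-1-style rows)."""

    strain_id: str
    genome_size: int
    total_genes: int
    protein_coding_genes: int
    hypothetical_proteins: int

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValidationError(f"{self.strain_id}: genome size must be positive")
        if self.protein_coding_genes > self.total_genes:
            raise ValidationError(f"{self.strain_id}: protein-coding > total genes")
        if self.hypothetical_proteins > self.protein_coding_genes:
            raise ValidationError(f"{self.strain_id}: hypothetical > protein-coding")


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise % identity matrix with a 100 diagonal."""

    taxa: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValidationError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValidationError("diagonal must be exactly 100")
        if v.min() < 0 or v.max() > 100:
            raise ValidationError("values outside [0, 100]")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _terminal_gap_mask(seq: str) -> np.ndarray:
    """True on leading/trailing gap columns of one row."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gap = arr == GAP.encode()
    mask = np.zeros(len(seq), dtype=bool)
    nz = np.flatnonzero(~is_gap)
    if len(nz) == 0:
        mask[:] = True
        return mask
    mask[: nz[0]] = True
    mask[nz[-1] + 1:] = True
    return mask


def pairwise_identity(a: str, b: str, internal_gap: str = "mismatch") -> float:
    """Percent identity between two aligned rows.

    Mutual-gap columns and columns inside either row's terminal-gap
    overhang are skipped; internal gap-vs-base columns count as mismatches
    (``internal_gap="mismatch"``) or are skipped (``"skip"``).
    """
    if len(a) != len(b):
        raise FormatError("aligned rows differ in length")
    if internal_gap not in ("mismatch", "skip"):
        raise ValidationError(f"unknown internal_gap policy: {internal_gap!r}")
    aa = np.frombuffer(a.upper().encode(), dtype="S1")
    bb = np.frombuffer(b.upper().encode(), dtype="S1")
    gap = GAP.encode()
    skip = _terminal_gap_mask(a) | _terminal_gap_mask(b)
    skip |= (aa == gap) & (bb == gap)
    if internal_gap == "skip":
        skip |= (aa == gap) | (bb == gap)
    keep = ~skip
    n = int(keep.sum())
    if n == 0:
        raise FormatError("no comparable columns between the two rows")
    matches = int(((aa == bb) & keep & (aa != gap)).sum())
    return 100.0 * matches / n


def pairwise_identity_matrix(
    sequences: dict | Sequence[tuple[str, str]],
    internal_gap: str = "mismatch",
) -> SimilarityMatrix:
    """Pairwise % identity matrix from an equal-length multiple alignment."""
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if not items:
        raise FormatError("empty alignment")
    taxa = [t for t, _ in items]
    rows = [s for _, s in items]
    n0 = len(rows[0])
    if any(len(r) != n0 for r in rows):
        raise FormatError("ragged alignment: rows differ in length")
    n = len(taxa)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pairwise_identity(
                rows[i], rows[j], internal_gap
            )
    return SimilarityMatrix(taxa=taxa, values=values)


def read_aligned_fasta(path) -> dict:
    """Read an aligned FASTA into an ordered {name: row} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def delineate_rank(similarity: float,
                   thresholds: Optional[RankThresholds] = None) -> str:
    """Taxonomic verdict for a pairwise 16S % identity.

    Inclusive lower bounds: a value exactly at a threshold counts as at or
    above it.
    """
    thresholds = thresholds or RankThresholds()
    if not (0.0 <= similarity <= 100.0):
        raise ValidationError(f"similarity {similarity} outside [0, 100]")
    if similarity >= thresholds.genus:
        return "same genus"
    if similarity >= thresholds.family:
        return "novel genus, same family"
    if similarity >= thresholds.order:
        return "novel family, same order"
    return "novel order"


@dataclass
class PocpCutoffs:
    """Conservation cutoffs of the POCP definition."""

    max_evalue: float = 1e-5
    min_identity: float = 40.0
    min_alignable_fraction: float = 0.5


def _conserved_queries(hits: Iterable[AlignmentHit], cutoffs: PocpCutoffs) -> set:
    conserved = set()
    for h in hits:
        if (h.evalue < cutoffs.max_evalue
                and h.percent_identity > cutoffs.min_identity
                and h.alignment_length > cutoffs.min_alignable_fraction * h.query_length):
            conserved.add(h.query_id)
    return conserved


def compute_pocp(hits_ab: Sequence[AlignmentHit], hits_ba: Sequence[AlignmentHit],
                 n_a: int, n_b: int,
                 cutoffs: Optional[PocpCutoffs] = None) -> float:
    """Percentage of conserved proteins between proteomes A (size n_a) and B.

    POCP = (C1 + C2) / (T1 + T2) x 100, where C1/C2 are the numbers of
    queries with at least one conserving hit in each direction.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValidationError("proteome sizes must be positive")
    cutoffs = cutoffs or PocpCutoffs()
    c1 = len(_conserved_queries(hits_ab, cutoffs))
    c2 = len(_conserved_queries(hits_ba, cutoffs))
    if c1 > n_a or c2 > n_b:
        raise FormatError("more conserved queries than proteome size")
    return 100.0 * (c1 + c2) / (n_a + n_b)


BLAST_OUTFMT6_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bit_score",
]


def read_blast_tabular(path, query_lengths: dict) -> list[AlignmentHit]:
    """Read 12-column BLAST outfmt-6 hits, joining query lengths from a sidecar.

    ``query_lengths`` maps query id to its sequence length; a hit whose
    query is missing from the map is a format error.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_OUTFMT6_COLUMNS,
                     comment="#")
    hits = []
    for r in df.itertuples(index=False):
        qid = str(r.query_id)
        if qid not in query_lengths:
            raise FormatError(f"hit references unknown query {qid!r}")
        hits.append(
            AlignmentHit(
                query_id=qid, subject_id=str(r.subject_id),
                evalue=float(r.evalue),
                percent_identity=float(r.percent_identity),
                alignment_length=int(r.alignment_length),
                query_length=int(query_lengths[qid]),
            )
        )
    return hits


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf."""
    return int(np.floor(x + 0.5))


def genome_feature_summary(
    summaries: Sequence[GenomeAnnotationSummary],
) -> pd.DataFrame:
    """Derived per-strain feature table plus pairwise size differences.

    Genes/Mb and protein-coding genes/Mb divide counts by the genome size
    in Mb; the hypothetical-protein percentage divides by the number of
    protein-coding genes; all three are rounded half-up to integers.
    """
    if not summaries:
        raise ValidationError("genome_feature_summary: no summaries")
    rows = []
    for s in summaries:
        mb = s.genome_size / 1e6
        rows.append(
            {
                "strain_id": s.strain_id,
                "genome_size_bp": s.genome_size,
                "total_genes": s.total_genes,
                "protein_coding_genes": s.protein_coding_genes,
                "hypothetical_proteins": s.hypothetical_proteins,
                "genes_per_mb": round_half_up(s.total_genes / mb),
                "protein_coding_per_mb": round_half_up(s.protein_coding_genes / mb),
                "hypothetical_pct": round_half_up(
                    100.0 * s.hypothetical_proteins / s.protein_coding_genes
                ),
            }
        )
    return pd.DataFrame(rows)


def genome_size_differences(
    summaries: Sequence[GenomeAnnotationSummary],
) -> pd.DataFrame:
    """Pairwise genome-size differences in bp (first minus second)."""
    rows = []
    for i, a in enumerate(summaries):
        for b in summaries[i + 1:]:
            rows.append(
                {"strain_a": a.strain_id, "strain_b": b.strain_id,
                 "size_difference_bp": a.genome_size - b.genome_size}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published per-genome annotation counts for the characterized members of
# the phylum Gemmatimonadota and the two novel isolates (inputs to the
# feature arithmetic; the derived columns are recomputed, never stored).

REFERENCE_GENOME_SUMMARIES = [
    GenomeAnnotationSummary("Strain 318T", 3_257_781, 2967, 2907, 631),
    GenomeAnnotationSummary("Strain 138", 3_260_361, 2969, 2909, 631),
    GenomeAnnotationSummary("Gemmatimonas aurantiaca T-27T", 4_636_964, 3998, 3936, 804),
    GenomeAnnotationSummary("Gemmatirosa kalamazoonensis KBS708T", 7_479_215, 6447, 6323, 1499),
    GenomeAnnotationSummary("Roseisolibacter agri AW1220T", 5_928_727, 5074, 5005, 3041),
    GenomeAnnotationSummary("Longimicrobium terrae CB-286315T", 6_784_420, 5641, 5502, 1661),
]
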