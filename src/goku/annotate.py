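"""Simplified ORF calling and coding-context classification.

A longest-ORF greedy caller with two published constraints — minimum gene
length 110 bp and maximum inter-gene overlap 50 bp — stands in for a full
interpolated-Markov-model gene finder: the downstream consumers (the
coding-context filter of the dif-motif scan and the gene-order check of the
prophage miner) need coordinates and roles, not per-gene likelihood scores.

ORF length convention: the stop codon is INCLUDED, so the shortest callable
gene at the 110 bp default is a start codon plus 36 further codons.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .core_io import Interval, SequenceRecord, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}

ROLES = ("VP1", "VP2", "VP3", "VP4", "VP5", "VP8")

NON_CODING = "non_coding"
CODING_INTERNAL = "coding_internal"
CODING_VP4_NTERM = "coding_VP4_Nterm"
CODING_GENE_EDGE = "coding_gene_edge"


@dataclass(frozen=True)
class AnnotationConfig:
    min_gene_len: int = 110        # bp, stop codon included
    max_overlap: int = 50          # bp, between accepted calls
    start_codons: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})
    n_term_window: int = 90        # bp quantifying a gene "N-terminus"/edge

    def __post_init__(self):
        if self.min_gene_len <= 9:
            raise ValueError("min_gene_len must exceed a start + stop codon")
        if self.max_overlap >= self.min_gene_len:
            raise ValueError("max_overlap must be smaller than min_gene_len")


@dataclass(frozen=True)
class GeneCall:
    """An accepted ORF. ``frame`` is start position mod 3 on the + image."""

    location: Interval
    role: str = "unknown"
    frame: int = 0
    role_score: float = 0.0
    role_shared: bool = False  # another call carries the same role


def _enumerate_strand_orfs(seq: str, n: int, circular: bool,
                           cfg: AnnotationConfig) -> list[tuple[int, int]]:
    """All start->stop ORFs on the + strand of ``seq`` as (start, end) 0-based
    half-open, end after the stop codon. For circular records ``seq`` is the
    doubled sequence and candidates are reported with start < n, length <= n.
    """
    scan_len = len(seq)
    out: list[tuple[int, int]] = []
    for f in range(3):
        starts: list[int] = []
        for i in range(f, scan_len - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                end = i + 3
                for s in starts:
                    length = end - s
                    if length < cfg.min_gene_len or length > (n if circular else scan_len):
                        continue
                    if s >= n:
                        continue
                    out.append((s, end))
                starts = []
            elif codon in cfg.start_codons:
                starts.append(i)
    return out


def enumerate_orfs(record: SequenceRecord, cfg: AnnotationConfig) -> list[GeneCall]:
    """Every start->stop ORF on both strands (origin-wrapping if circular),
    unfiltered except for the minimum-length rule.
    """
    n = len(record)
    fwd = record.seq + (record.seq if record.is_circular else "")
    rev = revcomp(record.seq)
    rev_scan = rev + (rev if record.is_circular else "")

    calls: list[GeneCall] = []
    seen: set[tuple[int, int, str]] = set()
    for s, e in _enumerate_strand_orfs(fwd, n, record.is_circular, cfg):
        iv = Interval(record.id, s, e, "+")
        key = (s % n, (e - s), "+")
        if key not in seen:
            seen.add(key)
            calls.append(GeneCall(iv, frame=s % 3))
    for s, e in _enumerate_strand_orfs(rev_scan, n, record.is_circular, cfg):
        # map from revcomp coordinates back to forward coordinates
        start_fwd = (n - e) % n if record.is_circular else n - e
        iv = Interval(record.id, start_fwd, start_fwd + (e - s), "-")
        key = (start_fwd % n, (e - s), "-")
        if key not in seen:
            seen.add(key)
            calls.append(GeneCall(iv, frame=s % 3))
    return calls


def _norm_overlap(a: Interval, b: Interval, n: int, circular: bool) -> int:
    """Overlap in bp, accounting for origin-wrapping on circular contigs."""
    if not circular:
        return a.overlap(b)
    best = 0
    for da in (0, -n, n):
        aa = Interval(a.contig_id, max(a.start + da, -10 * n) + 10 * n,
                      a.end + da + 10 * n, a.strand)
        best = max(best, aa.overlap(
            Interval(b.contig_id, b.start + 10 * n, b.end + 10 * n, b.strand)))
    return best


def greedy_select(candidates: list[GeneCall], n: int, circular: bool,
                  cfg: AnnotationConfig) -> list[GeneCall]:
    """Greedy acceptance by decreasing length (ties: leftmost start, then +
    strand), rejecting candidates overlapping an accepted call by more than
    ``max_overlap``.
    """
    ordered = sorted(
        candidates,
        key=lambda g: (-len(g.location), g.location.start, g.location.strand != "+"),
    )
    accepted: list[GeneCall] = []
    for cand in ordered:
        if all(
            _norm_overlap(cand.location, a.location, n, circular) <= cfg.max_overlap
            for a in accepted
        ):
            accepted.append(cand)
    accepted.sort(key=lambda g: (g.location.start, g.location.end))
    return accepted


def find_orfs(record: SequenceRecord, cfg: AnnotationConfig | None = None) -> list[GeneCall]:
    """Call genes: enumerate all ORFs, then greedy-filter by length/overlap."""
    cfg = cfg or AnnotationConfig()
    return greedy_select(enumerate_orfs(record, cfg), len(record),
                         record.is_circular, cfg)


def translate_call(record: SequenceRecord, call: GeneCall) -> str:
    """Protein sequence of a gene call, stop codon stripped."""
    from .core_io import circular_slice

    nt = circular_slice(record, call.location.start, call.location.end)
    if call.location.strand == "-":
        nt = revcomp(nt)
    aa = str(Seq(nt).translate(table=11))
    return aa[:-1] if aa.endswith("*") else aa


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _self_score(aligner: PairwiseAligner, seq: str) -> float:
    matrix = aligner.substitution_matrix
    return sum(matrix[c, c] for c in seq)


def assign_roles(
    record: SequenceRecord,
    genes: list[GeneCall],
    references: list[tuple[str, str]],
    min_score_frac: float = 0.5,
) -> list[GeneCall]:
    """Label gene calls with the role of their best-matching reference protein.

    A call gets the role of the highest-scoring reference (local alignment,
    BLOSUM62) if the score reaches ``min_score_frac`` of the smaller of the
    two self-scores; otherwise it stays ``unknown``. Multiple calls sharing a
    role are flagged via ``role_shared``.
    """
    if not references:
        raise ValueError("empty reference list")
    aligner = _protein_aligner()
    for _role, ref in references:
        bad = set(ref) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ValueError(f"invalid amino acids in reference: {sorted(bad)}")
    ref_self = {role: _self_score(aligner, ref) for role, ref in references}

    out: list[GeneCall] = []
    for g in genes:
        prot = translate_call(record, g)
        prot_clean = prot.replace("*", "X")
        self_p = _self_score(aligner, prot.replace("*", "").replace("X", "")) or 1.0
        best_role, best_score = "unknown", 0.0
        for role, ref in references:
            score = aligner.score(prot_clean.replace("X", ""), ref)
            norm = score / max(1.0, min(self_p, ref_self[role]))
            if norm > best_score:
                best_role, best_score = role, norm
        if best_score < min_score_frac:
            best_role = "unknown"
        out.append(GeneCall(g.location, best_role, g.frame, round(best_score, 4)))

    counts: dict[str, int] = {}
    for g in out:
        if g.role != "unknown":
            counts[g.role] = counts.get(g.role, 0) + 1
    return [
        GeneCall(g.location, g.role, g.frame, g.role_score,
                 role_shared=counts.get(g.role, 0) > 1)
        for g in out
    ]


def coding_context(
    pos: Interval,
    genes: list[GeneCall],
    cfg: AnnotationConfig | None = None,
    contig_len: int | None = None,
    circular: bool = False,
) -> str:
    """Classify an interval against gene calls.

    Returns one of ``non_coding`` (overlaps no gene), ``coding_VP4_Nterm``
    (every gene overlap lies within the first ``n_term_window`` bp, in gene
    orientation, of a VP4 gene), ``coding_gene_edge`` (confined within the
    window of any gene's 5' or 3' end), else ``coding_internal``. Total: every
    interval receives exactly one label.
    """
    cfg = cfg or AnnotationConfig()
    if genes and any(g.location.contig_id != pos.contig_id for g in genes):
        raise ValueError("interval and gene calls are on different contigs")
    n = contig_len or (max((g.location.end for g in genes), default=pos.end) + 1)

    overlapping = [
        g for g in genes if _norm_overlap(pos, g.location, n, circular) > 0
    ]
    if not overlapping:
        return NON_CODING

    def within_window(g: GeneCall, five_prime: bool) -> bool:
        loc = g.location
        if (loc.strand == "+") == five_prime:
            win = Interval(loc.contig_id, loc.start,
                           min(loc.end, loc.start + cfg.n_term_window), loc.strand)
        else:
            win = Interval(loc.contig_id, max(loc.start, loc.end - cfg.n_term_window),
                           loc.end, loc.strand)
        return _norm_overlap(pos, win, n, circular) == _norm_overlap(pos, loc, n, circular)

    if all(g.role == "VP4" and within_window(g, five_prime=True) for g in overlapping):
        return CODING_VP4_NTERM
    if all(within_window(g, five_prime=True) or within_window(g, five_prime=False)
           for g in overlapping):
        return CODING_GENE_EDGE
    return CODING_INTERNAL
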