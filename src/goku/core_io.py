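"""Sequence and interval data model, circular-sequence utilities, and flat-file I/O.

Everything downstream (simulation, mining, motif scanning, comparative assays)
moves data around as :class:`SequenceRecord` and :class:`Interval` objects.
Internal coordinates are 0-based, half-open throughout; GFF3 (1-based,
inclusive) and BED (0-based, half-open) conventions are converted exactly at
the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")

#: Chromosomal dif site of Escherichia coli K-12 (XerC arm | spacer | XerD arm).
#: Shipped as an overridable default; every operation accepts another grammar.
CANONICAL_DIF_ECOLI = "GGTGCGCATAATGTATATTATGTTAAAT"

#: Header token marking a circular sequence in FASTA descriptions.
CIRCULAR_TAG = "[circular]"


class FormatError(ValueError):
    """Malformed input file or sequence."""


class TopologyError(ValueError):
    """Operation requires a different topology (e.g. wraparound on linear)."""


class AmbiguousAnchorError(ValueError):
    """Rotation anchor occurs more than once."""

    def __init__(self, anchor: str, positions: list[int]):
        self.anchor = anchor
        self.positions = positions
        super().__init__(
            f"anchor {anchor!r} occurs {len(positions)} times at {positions}"
        )


def _validate_seq(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise FormatError(f"{name}: empty sequence")
    bad = next((i for i, c in enumerate(seq) if c not in ALPHABET), None)
    if bad is not None:
        raise FormatError(
            f"{name}: invalid character {seq[bad]!r} at position {bad}"
        )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with linear or circular topology."""

    id: str
    seq: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self):
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")
        _validate_seq(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a contig.

    On circular contigs ``end`` may exceed the contig length to represent an
    origin-spanning feature; the normalized form has ``start < length``.
    """

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def normalized(self, contig_len: int) -> "Interval":
        """Shift start into [0, contig_len); keeps length."""
        s = self.start % contig_len
        return replace(self, start=s, end=s + len(self))

    def overlap(self, other: "Interval") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class DifGrammar:
    """Fixed-width dif-site grammar: XerC arm + central spacer + XerD arm.

    The default is the 28-bp arrangement (11 + 6 + 11) of enterobacterial
    chromosomes, with the E. coli canonical sequence.
    """

    xerC_arm_len: int = 11
    spacer_len: int = 6
    xerD_arm_len: int = 11
    canonical_seq: str = CANONICAL_DIF_ECOLI

    def __post_init__(self):
        _validate_seq(self.canonical_seq, "canonical_seq")
        if len(self.canonical_seq) != self.total_len:
            raise ValueError(
                f"canonical_seq length {len(self.canonical_seq)} != "
                f"grammar width {self.total_len}"
            )

    @property
    def total_len(self) -> int:
        return self.xerC_arm_len + self.spacer_len + self.xerD_arm_len

    def decompose(self, seq: str) -> tuple[str, str, str]:
        """Split a grammar-width sequence into (XerC arm, spacer, XerD arm)."""
        if len(seq) != self.total_len:
            raise ValueError(f"expected {self.total_len} bp, got {len(seq)}")
        a = self.xerC_arm_len
        b = a + self.spacer_len
        return seq[:a], seq[a:b], seq[b:]

    def component_mismatches(self, seq: str) -> tuple[int, int, int]:
        """Per-component Hamming distances vs the canonical sequence.

        N mismatches everything, including another N.
        """
        qc, qs, qd = self.decompose(seq.upper())
        cc, cs, cd = self.decompose(self.canonical_seq)
        return (_hamming(qc, cc), _hamming(qs, cs), _hamming(qd, cd))


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


# DifSite classes
BACTERIAL_LIKE = "bacterial_like"
PHAGE_LIKE = "phage_like"
PARTIAL_C_MISSING = "partial_C_missing"
PARTIAL_D_MISSING = "partial_D_missing"
NON_SITE = "non_site"


@dataclass(frozen=True)
class DifSite:
    """A grammar-width site with per-component mismatch counts and a class."""

    seq: str
    location: Interval
    xerC_mismatches: int
    spacer_mismatches: int
    xerD_mismatches: int
    site_class: str

    @property
    def total_mismatches(self) -> int:
        return self.xerC_mismatches + self.spacer_mismatches + self.xerD_mismatches


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    _validate_seq(seq)
    return seq.translate(_COMP)[::-1]


def circular_slice(record: SequenceRecord, start: int, end: int) -> str:
    """Bases ``start..end-1``, indices modulo length on circular records.

    Result length is always ``end - start``. Requesting an origin-spanning
    slice of a linear record raises :class:`TopologyError`.
    """
    if end <= start:
        raise ValueError(f"bad slice [{start}, {end})")
    n = len(record)
    if not record.is_circular:
        if start < 0 or end > n:
            raise TopologyError(
                f"slice [{start}, {end}) spans beyond linear record "
                f"{record.id!r} of length {n}"
            )
        return record.seq[start:end]
    if end - start <= n:
        s = start % n
        doubled = record.seq + record.seq
        return doubled[s : s + (end - start)]
    return "".join(record.seq[i % n] for i in range(start, end))


def _booth_least_rotation(s: str) -> int:
    """Index of the lexicographically minimal rotation (Booth's algorithm)."""
    s2 = s + s
    n = len(s2)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def find_occurrences(record: SequenceRecord, query: str) -> list[tuple[int, str]]:
    """All (start, strand) occurrences of ``query``; wraps origin if circular.

    Starts are in [0, len(record)) on the forward coordinate system.
    """
    n = len(record)
    hay = record.seq + (record.seq[: len(query) - 1] if record.is_circular else "")
    out = []
    for q, strand in ((query, "+"), (revcomp(query), "-")):
        i = hay.find(q)
        while i != -1:
            if i < n:
                out.append((i, strand))
            i = hay.find(q, i + 1)
    if query == revcomp(query):  # palindromic query: one hit per position
        out = sorted({(p, "+") for p, _ in out})
    return sorted(out)


def canonical_rotation(
    record: SequenceRecord, anchor: str | None = None
) -> SequenceRecord:
    """Deterministic canonical form of a circular record.

    With a unique anchor (either strand) the record is rotated (and
    reverse-complemented if needed) so the anchor starts at position 0 on the
    forward strand. Otherwise the lexicographically minimal rotation of the
    forward sequence is used. Idempotent and rotation-invariant.
    """
    if not record.is_circular:
        raise TopologyError(f"record {record.id!r} is not circular")
    n = len(record)
    if anchor is not None:
        occ = find_occurrences(record, anchor)
        if len(occ) > 1:
            raise AmbiguousAnchorError(anchor, [p for p, _ in occ])
        if len(occ) == 1:
            pos, strand = occ[0]
            seq = record.seq
            if strand == "-":
                # put the anchor's + image at position 0 after revcomp
                seq = revcomp(seq)
                pos = (n - pos - len(anchor)) % n
            rotated = seq[pos:] + seq[:pos]
            return replace(record, seq=rotated)
    k = _booth_least_rotation(record.seq)
    return replace(record, seq=record.seq[k:] + record.seq[:k])


def rotate(record: SequenceRecord, k: int) -> SequenceRecord:
    """Rotate a circular record left by k positions."""
    if not record.is_circular:
        raise TopologyError(f"record {record.id!r} is not circular")
    k %= len(record)
    return replace(record, seq=record.seq[k:] + record.seq[:k])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, circular_tag: str = CIRCULAR_TAG) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords.

    Sequences are uppercased, U is mapped to T, and any character outside
    {A,C,G,T,N} is rejected with its position. Topology defaults to linear
    unless the header description carries ``circular_tag``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        topology = "circular" if circular_tag in rec.description else "linear"
        _validate_seq(seq, rec.id)
        records.append(SequenceRecord(rec.id, seq, topology))
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    circular_tag: str = CIRCULAR_TAG,
    width: int = 70,
) -> None:
    """Write records to FASTA, tagging circular ones in the description."""
    with open(path, "w") as fh:
        for r in records:
            desc = f" {circular_tag}" if r.is_circular else ""
            fh.write(f">{r.id}{desc}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / BED / TSV emitters and round-trip readers
# ---------------------------------------------------------------------------

def interval_to_gff3(iv: Interval) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return iv.start + 1, iv.end


def gff3_to_interval(contig: str, start1: int, end1: int, strand: str) -> Interval:
    return Interval(contig, start1 - 1, end1, strand)


def write_gff3(features: Sequence[tuple[Interval, str, dict]], path: str | Path) -> None:
    """Write (interval, type, attributes) features as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype, attrs in features:
            s1, e1 = interval_to_gff3(iv)
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{iv.contig_id}\tgoku\t{ftype}\t{s1}\t{e1}\t.\t{iv.strand}\t.\t{attr_s}\n"
            )


def read_gff3(path: str | Path) -> list[tuple[Interval, str, dict]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c, _src, ftype, s1, e1, _sc, strand, _ph, attrs = line.rstrip("\n").split("\t")
            ad = {}
            if attrs != ".":
                for kv in attrs.split(";"):
                    k, _, v = kv.partition("=")
                    ad[k] = v
            out.append((gff3_to_interval(c, int(s1), int(e1), strand), ftype, ad))
    return out


def write_bed(intervals: Sequence[tuple[Interval, str, float]], path: str | Path) -> None:
    """Write (interval, name, score) rows as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[Interval, str, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append((Interval(c, int(s), int(e), strand), name, float(score)))
    return out


def write_outputs(calls, outdir: str | Path, formats: set[str] | None = None) -> dict[str, Path]:
    """Serialize a collection of prophage calls to GFF3 + TSV + FASTA.

    ``calls`` is a sequence of objects with the ProphageCall surface
    (host_id, region, upstream_dif, downstream_dif, genes, excised).
    Returns the mapping of format name to written path. Empty call lists
    produce valid, header-only files.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    formats = formats or {"gff3", "tsv", "fasta"}
    written: dict[str, Path] = {}

    if "gff3" in formats:
        feats: list[tuple[Interval, str, dict]] = []
        for i, c in enumerate(calls):
            pid = f"prophage_{i}"
            feats.append((c.region, "prophage", {"ID": pid}))
            for site, which in ((c.upstream_dif, "upstream"), (c.downstream_dif, "downstream")):
                feats.append(
                    (site.location, "dif_site",
                     {"Parent": pid, "position": which, "class": site.site_class})
                )
            for g in c.genes:
                feats.append((g.location, "gene", {"Parent": pid, "role": g.role}))
        p = outdir / "prophages.gff3"
        write_gff3(feats, p)
        written["gff3"] = p

    if "tsv" in formats:
        rows = []
        for c in calls:
            rows.append(
                {
                    "host_id": c.host_id,
                    "start": c.region.start,
                    "end": c.region.end,
                    "length": len(c.region),
                    "upstream_class": c.upstream_dif.site_class,
                    "downstream_class": c.downstream_dif.site_class,
                    "n_genes": len(c.genes),
                    "gene_roles": ",".join(g.role for g in c.genes),
                }
            )
        p = outdir / "prophages.tsv"
        pd.DataFrame(
            rows,
            columns=["host_id", "start", "end", "length", "upstream_class",
                     "downstream_class", "n_genes", "gene_roles"],
        ).to_csv(p, sep="\t", index=False)
        written["tsv"] = p

    if "fasta" in formats:
        p = outdir / "excised.fasta"
        write_fasta([c.excised for c in calls], p)
        written["fasta"] = p

    return written


def write_hits(hits, outdir: str | Path, prefix: str = "dif_hits") -> dict[str, Path]:
    """Write dif-scan hits as BED + TSV (score, identity, context, status)."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed_rows = [(h.location, h.status, h.score) for h in hits]
    bed_path = outdir / f"{prefix}.bed"
    write_bed(bed_rows, bed_path)
    tsv_path = outdir / f"{prefix}.tsv"
    pd.DataFrame(
        [
            {
                "contig": h.location.contig_id,
                "start": h.location.start,
                "end": h.location.end,
                "strand": h.location.strand,
                "score": h.score,
                "best_identity": h.best_identity,
                "context": h.context,
                "status": h.status,
                "reject_reason": h.reject_reason,
            }
            for h in hits
        ],
        columns=["contig", "start", "end", "strand", "score", "best_identity",
                 "context", "status", "reject_reason"],
    ).to_csv(tsv_path, sep="\t", index=False)
    return {"bed": bed_path, "tsv": tsv_path}
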