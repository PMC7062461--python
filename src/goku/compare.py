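"""Comparative statistics and diagnostics: rotation-aware ANI, >95%-ANI clade
clustering, per-column identity profiles of alignments, and in-silico PCR.

ANI between two circular genomes is computed from a single end-to-end
global alignment after rotation-normalizing one genome onto the other (the
second genome, doubled, is searched for the best infix placement of the
first, on either strand). Genomes here are short (<5 kb), so one exact
alignment replaces fragment-based ANI estimators. Identity is matches over
aligned columns, terminal gaps excluded.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .core_io import Interval, SequenceRecord, revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ANIMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric percent identities, diagonal 100

    def __post_init__(self):
        v = self.values
        assert v.shape == (len(self.ids), len(self.ids))


@dataclass(frozen=True)
class IdentityProfile:
    """Per-alignment-column mean pairwise identity in [0,1]; NaN = no valid
    (gap-free) pair at that column."""

    columns: np.ndarray
    window: int = 1


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd: str
    rev: str
    max_product: int = 10_000
    max_mismatch: int = 0  # 3'-terminal base must match regardless

    def __post_init__(self):
        if len(self.fwd) < 15 or len(self.rev) < 15:
            raise ValueError("primers must be at least 15 nt")


def _cigar_identity(cigar: str) -> float:
    """Matches / aligned columns from an extended cigar, terminal gaps
    excluded."""
    ops = _CIGAR_RE.findall(cigar)
    # strip leading/trailing indel runs (end-gap-free identity)
    while ops and ops[0][1] in "ID":
        ops = ops[1:]
    while ops and ops[-1][1] in "ID":
        ops = ops[:-1]
    matches = sum(int(n) for n, op in ops if op == "=")
    columns = sum(int(n) for n, op in ops)
    return matches / columns if columns else 0.0


def _best_rotation(a: str, b: str) -> str:
    """Rotate/orient circular sequence ``b`` to its best placement against
    ``a`` (infix search of ``a`` in the doubled ``b``, both strands)."""
    best_seq, best_dist = b, None
    for cand in (b, revcomp(b)):
        res = edlib.align(a, cand + cand, mode="HW", task="locations")
        if res["editDistance"] == -1 or not res["locations"]:
            continue
        start = res["locations"][0][0] % len(cand)
        rotated = cand[start:] + cand[:start]
        if best_dist is None or res["editDistance"] < best_dist:
            best_seq, best_dist = rotated, res["editDistance"]
    return best_seq


def pairwise_ani(a: SequenceRecord, b: SequenceRecord) -> float:
    """Percent identity from one global alignment of rotation-normalized
    genomes; symmetric by construction (arguments are ordered canonically
    before the single alignment, so ani(a,b) is computed exactly once)."""
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    if a.is_circular != b.is_circular:
        raise ValueError("both records must share a topology")
    if (b.id, b.seq) < (a.id, a.seq):
        a, b = b, a
    sb = _best_rotation(a.seq, b.seq) if a.is_circular else b.seq
    res = edlib.align(a.seq, sb, mode="NW", task="path")
    return 100.0 * _cigar_identity(res["cigar"])


def ani_matrix(records: list[SequenceRecord]) -> ANIMatrix:
    n = len(records)
    vals = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        vals[i, j] = vals[j, i] = pairwise_ani(records[i], records[j])
    return ANIMatrix(tuple(r.id for r in records), vals)


SINGLETON = "singleton"


def cluster_clades(m: ANIMatrix, threshold: float = 95.0) -> dict[str, str]:
    """Single-linkage components of the graph {ANI > threshold}.

    Multi-member components are labelled A, B, ... by decreasing size (ties:
    lexicographically smallest member id); singletons are labelled as such.
    """
    n = len(m.ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if m.values[i, j] > threshold:
            parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = sorted(
        (sorted(members) for members in comps.values()),
        key=lambda g: (-len(g), min(m.ids[i] for i in g)),
    )
    labels: dict[str, str] = {}
    letter = 0
    for g in groups:
        if len(g) == 1:
            labels[m.ids[g[0]]] = SINGLETON
        else:
            labels.update({m.ids[i]: _letter_label(letter) for i in g})
            letter += 1
    return labels


def _letter_label(i: int) -> str:
    out = ""
    while True:
        out = chr(ord("A") + i % 26) + out
        i = i // 26 - 1
        if i < 0:
            return out


def identity_profile(rows: list[str], window: int = 1) -> IdentityProfile:
    """Mean pairwise identity per alignment column.

    Pairs with a gap in either member are excluded at that column; N never
    matches. Columns with no valid pair are NaN. ``window`` > 1 applies a
    centered moving average over defined columns.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 aligned sequences")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("ragged alignment")
    arr = np.array([list(r.upper()) for r in rows])
    cols = np.full(L, np.nan)
    for j in range(L):
        col = arr[:, j]
        residues = col[col != "-"]
        m = len(residues)
        total = m * (m - 1) // 2
        if total == 0:
            continue
        same = 0
        for base in "ACGT":
            k = int((residues == base).sum())
            same += k * (k - 1) // 2
        cols[j] = same / total
    if window > 1:
        cols = (
            pd.Series(cols)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return IdentityProfile(cols, window)


def _primer_sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where ``primer`` anneals to the + strand of
    ``template`` (3'-terminal base must match exactly)."""
    n, k = len(template), len(primer)
    if n < k:
        return []
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(t, k)
    mism = (win != p).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [int(i) for i in hits if template[i + k - 1] == primer[-1]]


def insilico_pcr(template: SequenceRecord, primers: PrimerPair
                 ) -> list[tuple[Interval, int]]:
    """Predicted amplicons: (interval, size), size inclusive of both primers.

    One primer anneals to the + strand, the other (as its reverse
    complement) downstream on the same strand; both primer assignments are
    tried. Circular templates also yield origin-crossing products. Products
    longer than ``max_product`` are suppressed.
    """
    n = len(template)
    circular = template.is_circular
    hay = template.seq + (template.seq[: primers.max_product] if circular else "")
    out: dict[tuple[int, int], tuple[Interval, int]] = {}
    for left, right in ((primers.fwd, primers.rev), (primers.rev, primers.fwd)):
        left_sites = [p for p in _primer_sites(hay, left, primers.max_mismatch)
                      if p < n]
        right_rc = revcomp(right)
        right_sites = _primer_sites(hay, right_rc, primers.max_mismatch)
        for p in left_sites:
            for q in right_sites:
                end = q + len(right_rc)
                size = end - p
                if size < len(left) + len(right) or size > primers.max_product:
                    continue
                if circular and size > n:
                    continue
                start = p % n
                out.setdefault((start, size), (Interval(template.id, start, start + size), size))
    return sorted(out.values(), key=lambda t: (t[0].start, t[1]))


GENOTYPES = ("integrated", "circular_carrier", "empty")


def genotype_bands(
    population: list[tuple[SequenceRecord, str]],
    assays: list[PrimerPair],
) -> pd.DataFrame:
    """Expected amplicon sizes per genotype across assays, with the mixture
    fraction of the population producing each band.

    Returns a tidy frame: assay, size, genotypes (comma-joined provenance),
    fraction (share of population members yielding the band).
    """
    for _rec, label in population:
        if label not in GENOTYPES:
            raise ValueError(f"unknown genotype label {label!r}")
    rows: list[dict] = []
    total = len(population)
    if total == 0:
        return pd.DataFrame(columns=["assay", "size", "genotypes", "fraction"])
    bands: dict[tuple[str, int], list[str]] = {}
    for rec, label in population:
        for assay in assays:
            for _iv, size in insilico_pcr(rec, assay):
                bands.setdefault((assay.name, size), []).append(label)
    for (assay_name, size), labels in sorted(bands.items()):
        rows.append(
            {
                "assay": assay_name,
                "size": size,
                "genotypes": ",".join(sorted(set(labels))),
                "fraction": len(labels) / total,
            }
        )
    return pd.DataFrame(rows, columns=["assay", "size", "genotypes", "fraction"])


def read_primers_tsv(path) -> list[PrimerPair]:
    """Primer TSV schema: name, fwd, rev, max_product."""
    df = pd.read_csv(path, sep="\t")
    return [
        PrimerPair(str(r["name"]), str(r["fwd"]).upper(), str(r["rev"]).upper(),
                   int(r.get("max_product", 10_000)))
        for _, r in df.iterrows()
    ]
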