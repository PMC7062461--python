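"""Synthetic hosts, phages, integrations and MAG sets, with a ground-truth
oracle for every planted feature.

The generator emulates the genome architecture the analysis assumes: host
chromosomes carrying a single 28-bp dif site; circular phage genomes of
4047-4692 bp with six genes in the order VP4, VP5, VP3, VP1, VP2, VP8 and a
phage-type dif (conserved XerC arm, divergent spacer/XerD arm) in the
VP8-VP4 intergenic gap, so that the integrated prophage reads VP4..VP8
between the two boundary difs; and MAG sets with dif-like motifs planted in
non-coding gaps, in the VP4 N-terminal window, or mid-gene (negative
controls), plus decoy near-motifs of 10-14 bp identity to the canonical dif.

Background composition is i.i.d. at the configured GC; there is no
codon-usage realism — the pipeline's operators depend on exact-match and
motif structure, not on realistic composition. One explicit generator object
derived from the config seed drives all sampling; emitted FASTA is
byte-identical across runs of the same seed.

Two construction guarantees make the ground truth a usable oracle:
every phage-type dif or planted motif carries at least two substitutions
(so it can never be mistaken for, or be identical to, the bacterial site),
and intergenic gaps are rejection-sampled until the ORF caller recovers the
six planted genes exactly (an in-frame stop codon is pinned immediately
upstream of each gene start).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotate import (
    CODING_INTERNAL,
    CODING_VP4_NTERM,
    NON_CODING,
    AnnotationConfig,
    GeneCall,
    find_orfs,
)
from .core_io import (
    BACTERIAL_LIKE,
    PHAGE_LIKE,
    DifGrammar,
    DifSite,
    Interval,
    SequenceRecord,
    revcomp,
)
from .miner import HostState, MinerConfig, classify_dif, integrate
from .refs import GENE_ORDER, reference_proteins

_BASES = np.array(list("ACGT"))

# codons per amino acid, standard bacterial code (stop codons excluded)
_CODONS: dict[str, list[str]] = {}
_B = "TCAG"
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE):
    if _aa == "*":
        continue
    _codon = _B[_i // 16] + _B[(_i // 4) % 4] + _B[_i % 4]
    _CODONS.setdefault(_aa, []).append(_codon)
STOPS = ("TAA", "TAG", "TGA")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    host_len: int = 100_000
    phage_len_range: tuple[int, int] = (4047, 4692)
    gene_order: tuple[str, ...] = GENE_ORDER
    phage_dif_spacer_mut: float = 0.3   # per-base substitution in spacer+XerD arm
    bacterial_dif_mut_max: int = 1
    mag_count: int = 9
    decoy_repeat_count: int = 4          # decoys planted per MAG
    coding_plant_fraction: float = 0.5   # planted motifs placed in coding contexts
    mag_motif_fraction: float = 0.75     # MAGs that carry a planted motif
    gc: float = 0.5
    protein_mut: float = 0.02            # aa substitution rate vs reference proteins

    def __post_init__(self):
        lo, hi = self.phage_len_range
        if not (3500 <= lo <= hi <= 6000):
            raise ConfigError("phage_len_range must lie within [3500, 6000]")
        for p in (self.phage_dif_spacer_mut, self.coding_plant_fraction,
                  self.mag_motif_fraction, self.gc, self.protein_mut):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted features keyed by record id — the oracle for recovery tests."""

    host_dif: dict[str, DifSite] = field(default_factory=dict)
    phage_dif: dict[str, DifSite] = field(default_factory=dict)
    genes: dict[str, list[GeneCall]] = field(default_factory=dict)
    prophage: dict[str, Interval] = field(default_factory=dict)
    upstream_dif: dict[str, DifSite] = field(default_factory=dict)
    downstream_dif: dict[str, DifSite] = field(default_factory=dict)
    mag_motifs: dict[str, list[tuple[Interval, str, str]]] = field(default_factory=dict)
    decoys: dict[str, list[tuple[Interval, str]]] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        for name in ("host_dif", "phage_dif", "genes", "prophage",
                     "upstream_dif", "downstream_dif", "mag_motifs", "decoys"):
            getattr(self, name).update(getattr(other, name))
        return self

    def verify(self, records: dict[str, SequenceRecord]) -> None:
        """Check the re-extraction invariant: every recorded feature sequence
        equals the emitted record's sequence at the recorded coordinates."""
        def extract(rid: str, iv: Interval) -> str:
            seq = records[rid].seq[iv.start : iv.end]
            return revcomp(seq) if iv.strand == "-" else seq

        for mapping in (self.host_dif, self.phage_dif,
                        self.upstream_dif, self.downstream_dif):
            for rid, site in mapping.items():
                if rid in records and extract(rid, site.location) != site.seq:
                    raise AssertionError(f"dif re-extraction failed for {rid}")
        for rid, motifs in self.mag_motifs.items():
            for iv, _ctx, seq in motifs:
                if extract(rid, iv) != seq:
                    raise AssertionError(f"motif re-extraction failed for {rid}")
        for rid, decs in self.decoys.items():
            for iv, seq in decs:
                if extract(rid, iv) != seq:
                    raise AssertionError(f"decoy re-extraction failed for {rid}")

    def to_json(self, path: str | Path) -> None:
        def site(s: DifSite) -> dict:
            return {
                "seq": s.seq,
                "start": s.location.start,
                "end": s.location.end,
                "strand": s.location.strand,
                "class": s.site_class,
                "mismatches": [s.xerC_mismatches, s.spacer_mismatches,
                               s.xerD_mismatches],
            }

        payload = {
            "host_dif": {k: site(v) for k, v in self.host_dif.items()},
            "phage_dif": {k: site(v) for k, v in self.phage_dif.items()},
            "prophage": {
                k: {"start": v.start, "end": v.end} for k, v in self.prophage.items()
            },
            "upstream_dif": {k: site(v) for k, v in self.upstream_dif.items()},
            "downstream_dif": {k: site(v) for k, v in self.downstream_dif.items()},
            "genes": {
                k: [
                    {"role": g.role, "start": g.location.start,
                     "end": g.location.end, "strand": g.location.strand}
                    for g in v
                ]
                for k, v in self.genes.items()
            },
            "mag_motifs": {
                k: [{"start": iv.start, "end": iv.end, "context": ctx, "seq": seq}
                    for iv, ctx, seq in v]
                for k, v in self.mag_motifs.items()
            },
            "decoys": {
                k: [{"start": iv.start, "end": iv.end, "seq": seq}
                    for iv, seq in v]
                for k, v in self.decoys.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    out = list(seq)
    for i in positions:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _bacterial_dif(rng: np.random.Generator, grammar: DifGrammar,
                   max_mm: int) -> str:
    k = int(rng.integers(0, max_mm + 1))
    pos = rng.choice(grammar.total_len, size=k, replace=False) if k else np.array([], int)
    return _mutate(rng, grammar.canonical_seq, pos)


def _phage_dif(rng: np.random.Generator, grammar: DifGrammar, rate: float,
               max_total_mm: int = 13) -> str:
    """Canonical XerC arm + spacer/XerD arm mutated at ``rate``; resampled
    until the site carries 2..``max_total_mm`` substitutions (phage-type:
    never bacterial-like, never identical to the host site, and always
    >= 15 bp identical to canonical at the default grammar width)."""
    w = grammar.total_len
    a = grammar.xerC_arm_len
    for _ in range(1000):
        mask = rng.random(w - a) < rate
        pos = np.nonzero(mask)[0] + a
        if 2 <= len(pos) <= max_total_mm:
            return _mutate(rng, grammar.canonical_seq, pos)
    raise ConfigError("could not sample a phage-type dif; check mutation rate")


def _dif_17mer_unique(seq: str, dif_start: int, dif_len: int, seed_len: int = 17) -> bool:
    """True when every seed-length window of the planted dif occurs exactly
    once in seq (forward) and never on the reverse strand."""
    for off in range(dif_len - seed_len + 1):
        kmer = seq[dif_start + off : dif_start + off + seed_len]
        if seq.count(kmer) != 1 or kmer in revcomp(seq):
            return False
    return True


def make_host(cfg: SimConfig, rng: np.random.Generator | None = None,
              grammar: DifGrammar | None = None,
              record_id: str = "host") -> tuple[SequenceRecord, GroundTruth]:
    """Linear host chromosome with exactly one planted dif site within
    ``bacterial_dif_mut_max`` substitutions of canonical; no other exact
    17-mer of the dif neighbourhood occurs anywhere else (rejection-sampled).
    """
    grammar = grammar or DifGrammar()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    w = grammar.total_len
    if cfg.host_len < 10 * w:
        raise ConfigError(f"host_len must be at least {10 * w}")
    margin = max(w, cfg.host_len // 6)
    for _ in range(100):
        background = _random_bases(rng, cfg.host_len, cfg.gc)
        dif = _bacterial_dif(rng, grammar, cfg.bacterial_dif_mut_max)
        pos = int(rng.integers(margin, cfg.host_len - margin - w))
        seq = background[:pos] + dif + background[pos + w :]
        if _dif_17mer_unique(seq, pos, w):
            site = classify_dif(dif, grammar, None, Interval(record_id, pos, pos + w))
            assert site.site_class == BACTERIAL_LIKE
            truth = GroundTruth(host_dif={record_id: site})
            return SequenceRecord(record_id, seq, "linear"), truth
    raise ConfigError("could not plant a unique dif site; host too repetitive")


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = ["ATG"]  # initial M always ATG so translation round-trips
    for aa in protein[1:]:
        codons.append(rng.choice(_CODONS[aa]))
    codons.append(rng.choice(STOPS))
    return "".join(codons)


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != out[i]])
    return "".join(out)


@dataclass
class _PhageLayout:
    seq: str
    genes: list[GeneCall]          # forward strand, layout coordinates
    gaps: list[tuple[int, int]]    # usable gap interiors (pinned stop excluded)
    dif_interval: Interval | None
    dif_seq: str | None


def _assemble_phage(cfg: SimConfig, rng: np.random.Generator,
                    grammar: DifGrammar, record_id: str,
                    include_dif: bool) -> _PhageLayout:
    refs = reference_proteins()
    order = cfg.gene_order
    w = grammar.total_len
    target = int(rng.integers(cfg.phage_len_range[0], cfg.phage_len_range[1] + 1))

    proteins = {r: _mutate_protein(rng, refs[r], cfg.protein_mut) for r in order}
    gene_nt = {r: 3 * len(proteins[r]) + 3 for r in order}
    total_genes = sum(gene_nt.values())
    n_gaps = len(order)
    min_gap = 12                      # room for the pinned stop + spacing
    dif_gap_idx = len(order) - 1      # gap after the last gene (VP8 -> VP4)
    budget = target - total_genes - n_gaps * min_gap - (w if include_dif else 0)
    if budget < 0:
        raise ConfigError("gene lengths incompatible with target genome length")
    extra = rng.multinomial(budget, np.full(n_gaps, 1 / n_gaps))

    parts: list[str] = []
    genes: list[GeneCall] = []
    gaps: list[tuple[int, int]] = []
    dif_iv: Interval | None = None
    dif_seq: str | None = None
    pos = 0
    for i, role in enumerate(order):
        nt = _back_translate(rng, proteins[role])
        genes.append(
            GeneCall(Interval(record_id, pos, pos + len(nt), "+"), role, pos % 3)
        )
        parts.append(nt)
        pos += len(nt)

        gap_len = min_gap + int(extra[i])
        if include_dif and i == dif_gap_idx:
            dif_seq = _phage_dif(rng, grammar, cfg.phage_dif_spacer_mut)
            a_len = int(rng.integers(3, gap_len - 6))
            b_len = gap_len - 3 - a_len
            gap = (_random_bases(rng, a_len, cfg.gc) + dif_seq
                   + _random_bases(rng, b_len, cfg.gc) + "TAA")
            dif_iv = Interval(record_id, pos + a_len, pos + a_len + w)
            gaps.append((pos + a_len + w, pos + len(gap) - 3))
        else:
            gap = _random_bases(rng, gap_len - 3, cfg.gc) + "TAA"
            gaps.append((pos, pos + gap_len - 3))
        parts.append(gap)
        pos += len(gap)
    return _PhageLayout("".join(parts), genes, gaps, dif_iv, dif_seq)


def _orfs_recover_genes(record: SequenceRecord, genes: list[GeneCall]) -> bool:
    called = {(g.location.start, g.location.end, g.location.strand)
              for g in find_orfs(record, AnnotationConfig())}
    return all(
        (g.location.start, g.location.end, g.location.strand) in called
        for g in genes
    )


def make_phage(cfg: SimConfig, rng: np.random.Generator | None = None,
               grammar: DifGrammar | None = None,
               record_id: str = "phage") -> tuple[SequenceRecord, GroundTruth]:
    """Circular phage genome with the six-gene arrangement and one phage-type
    dif in the VP8->VP4 intergenic gap; all features recorded; gaps
    rejection-sampled until the ORF caller recovers all six genes exactly."""
    grammar = grammar or DifGrammar()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    for _ in range(60):
        layout = _assemble_phage(cfg, rng, grammar, record_id, include_dif=True)
        record = SequenceRecord(record_id, layout.seq, "circular")
        if not _dif_17mer_unique(layout.seq, layout.dif_interval.start,
                                 grammar.total_len):
            continue
        if _orfs_recover_genes(record, layout.genes):
            site = classify_dif(layout.dif_seq, grammar, None, layout.dif_interval)
            assert site.site_class == PHAGE_LIKE
            truth = GroundTruth(
                phage_dif={record_id: site},
                genes={record_id: layout.genes},
            )
            return record, truth
    raise ConfigError("could not assemble a phage with recoverable genes")


def plant_integration(
    host: SequenceRecord,
    phage: SequenceRecord,
    truth: GroundTruth,
    grammar: DifGrammar | None = None,
    cfg: MinerConfig | None = None,
) -> tuple[SequenceRecord, GroundTruth]:
    """Integrate ``phage`` downstream of the host dif (delegating to the
    miner's integration arithmetic — single implementation) and extend the
    ground truth with the prophage interval, both boundary difs and the gene
    coordinates inside the integrated chromosome."""
    grammar = grammar or DifGrammar()
    outcome = integrate(host, phage, HostState(), grammar, cfg,
                        phage_dif=truth.phage_dif[phage.id])
    if not outcome.ok:
        raise ConfigError(f"planting failed: {outcome.refusal_reason}")
    rec = outcome.integrated
    w = grammar.total_len
    host_dif = truth.host_dif[host.id]
    insert_at = host_dif.location.end
    plen = len(phage)
    region = Interval(rec.id, insert_at, insert_at + plen)

    phage_dif = truth.phage_dif[phage.id]
    break_at = phage_dif.location.end  # linearization point, phage coords

    def map_pos(p: int) -> int:
        return insert_at + (p - break_at) % plen

    genes = [
        GeneCall(
            Interval(rec.id, map_pos(g.location.start),
                     map_pos(g.location.start) + len(g.location), g.location.strand),
            g.role, g.frame,
        )
        for g in truth.genes.get(phage.id, [])
    ]
    new = GroundTruth(
        prophage={rec.id: region},
        upstream_dif={rec.id: replace(host_dif, location=replace(
            host_dif.location, contig_id=rec.id))},
        downstream_dif={rec.id: replace(phage_dif, location=Interval(
            rec.id, region.end - w, region.end))},
        genes={rec.id: sorted(genes, key=lambda g: g.location.start)},
    )
    truth.merge(new)
    return rec, truth


def _has_stop_free_frame(motif: str) -> bool:
    """True if some codon phase of the motif contains no stop codon among its
    fully-contained codons — a necessary condition for in-gene planting."""
    for shift in range(3):
        codons = [motif[i : i + 3] for i in range(shift, len(motif) - 2, 3)]
        if not any(c in STOPS for c in codons):
            return True
    return False


def _decoy_motif(rng: np.random.Generator, grammar: DifGrammar,
                 avoid: list[str] = ()) -> str:
    """Near-motif with exactly 10-14 bp identity to the canonical dif and at
    most 14 bp identity (either orientation) to every motif in ``avoid`` —
    so only the identity rule, never chance, separates decoys from planted
    motifs."""
    w = grammar.total_len
    for _ in range(200):
        identity = int(rng.integers(10, 15))
        pos = rng.choice(w, size=w - identity, replace=False)
        decoy = _mutate(rng, grammar.canonical_seq, pos)
        rc = revcomp(decoy)
        if all(
            sum(a == b for a, b in zip(img, m)) <= 14
            for m in avoid
            for img in (decoy, rc)
        ):
            return decoy
    raise ConfigError("could not sample a decoy satisfying identity bounds")


def _plant_in_gene(rng: np.random.Generator, seq: str, gene: GeneCall,
                   motif: str, window: tuple[int, int]) -> tuple[str, int] | None:
    """Overwrite ``motif`` at a random in-gene offset within ``window``
    (relative to gene start); returns (new_seq, start) if the gene still
    translates openly (start codon intact, no in-frame stop introduced)."""
    g = gene.location
    lo, hi = window
    hi = min(hi, len(g) - len(motif) - 3)
    if hi <= lo:
        return None
    for _ in range(30):
        off = int(rng.integers(lo, hi + 1))
        start = g.start + off
        cand = seq[: start] + motif + seq[start + len(motif) :]
        body = cand[g.start : g.end]
        codons = [body[i : i + 3] for i in range(0, len(body) - 3, 3)]
        if body[:3] == "ATG" and body[-3:] in STOPS and \
                not any(c in STOPS for c in codons):
            return cand, start
    return None


def make_mag_set(cfg: SimConfig, rng: np.random.Generator | None = None,
                 grammar: DifGrammar | None = None,
                 id_prefix: str = "mag") -> tuple[list[SequenceRecord], GroundTruth]:
    """Circular MAGs with synthetic gene complements; a configured fraction
    carries a dif-like motif planted (a) in a non-coding gap, (b) inside the
    first 90 bp of the VP4 ORF, or (c) mid-gene (negative control that only
    the coding-context filter removes); decoy near-motifs of 10-14 bp
    identity are scattered through the gaps of every MAG."""
    grammar = grammar or DifGrammar()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    w = grammar.total_len

    n_mot = round(cfg.mag_count * cfg.mag_motif_fraction)
    n_cod = round(n_mot * cfg.coding_plant_fraction)
    contexts = ([CODING_VP4_NTERM] * ((n_cod + 1) // 2)
                + [CODING_INTERNAL] * (n_cod // 2)
                + [NON_CODING] * (n_mot - n_cod)
                + [None] * (cfg.mag_count - n_mot))

    # pre-draw all planted motifs so decoys can be constrained against the
    # entire planted family, not just the motifs drawn so far; coding-context
    # motifs must carry a stop-free codon phase or they could never sit
    # inside an intact gene
    motifs_by_mag: dict[int, str] = {}
    for i, ctx in enumerate(contexts):
        if ctx is None:
            continue
        for _ in range(200):
            m = _phage_dif(rng, grammar, cfg.phage_dif_spacer_mut)
            if ctx == NON_CODING or _has_stop_free_frame(m):
                motifs_by_mag[i] = m
                break
        else:
            raise ConfigError("could not draw a plantable coding-context motif")
    planted_family = [grammar.canonical_seq, *motifs_by_mag.values()]

    records: list[SequenceRecord] = []
    truth = GroundTruth()
    for i, ctx in enumerate(contexts):
        rid = f"{id_prefix}{i:03d}"
        for _attempt in range(60):
            layout = _assemble_phage(cfg, rng, grammar, rid, include_dif=False)
            seq = layout.seq
            planted: list[tuple[Interval, str, str]] = []
            decoys: list[tuple[Interval, str]] = []
            gaps = list(layout.gaps)
            rng.shuffle(gaps)
            ok = True

            if ctx is not None:
                motif = motifs_by_mag[i]
                if ctx == NON_CODING:
                    gap = next(((a, b) for a, b in gaps if b - a >= w + 4), None)
                    if gap is None:
                        ok = False
                    else:
                        gaps.remove(gap)
                        start = int(rng.integers(gap[0] + 2, gap[1] - w - 1))
                        seq = seq[:start] + motif + seq[start + w :]
                        planted.append((Interval(rid, start, start + w), ctx, motif))
                else:
                    role = "VP4" if ctx == CODING_VP4_NTERM else "VP1"
                    gene = next(g for g in layout.genes if g.role == role)
                    window = (3, 90 - w) if ctx == CODING_VP4_NTERM else \
                        (120, len(gene.location) - 150)
                    res = _plant_in_gene(rng, seq, gene, motif, window)
                    if res is None:
                        ok = False
                    else:
                        seq, start = res
                        planted.append((Interval(rid, start, start + w), ctx, motif))

            if ok:
                for _d in range(cfg.decoy_repeat_count):
                    gap = next(((a, b) for a, b in gaps if b - a >= w + 4), None)
                    if gap is None:
                        break
                    gaps.remove(gap)
                    decoy = _decoy_motif(rng, grammar, planted_family)
                    start = int(rng.integers(gap[0] + 2, gap[1] - w - 1))
                    seq = seq[:start] + decoy + seq[start + w :]
                    decoys.append((Interval(rid, start, start + w), decoy))

            record = SequenceRecord(rid, seq, "circular")
            if ok and _orfs_recover_genes(record, layout.genes):
                records.append(record)
                truth.genes[rid] = layout.genes
                truth.mag_motifs[rid] = planted
                truth.decoys[rid] = decoys
                break
        else:
            raise ConfigError(f"could not assemble MAG {rid}")
    return records, truth


def delete_dif_arm(
    phage: SequenceRecord,
    truth: GroundTruth,
    which: str,
    grammar: DifGrammar | None = None,
) -> tuple[SequenceRecord, DifSite]:
    """Engineer a dif deletion construct: remove the XerC arm ("C"), the
    XerD arm ("D") or the whole site ("CD") from the phage genome. Returns
    the modified record and the construct's site descriptor (class
    partial_C_missing / partial_D_missing / non_site)."""
    from .miner import partial_dif_site

    grammar = grammar or DifGrammar()
    site = truth.phage_dif[phage.id]
    s, e = site.location.start, site.location.end
    a = grammar.xerC_arm_len
    d0 = e - grammar.xerD_arm_len
    if which == "C":
        new_seq = phage.seq[:s] + phage.seq[s + a :]
        remnant = site.seq[a:]
    elif which == "D":
        new_seq = phage.seq[:d0] + phage.seq[e:]
        remnant = site.seq[: site.location.end - site.location.start
                           - grammar.xerD_arm_len]
    elif which == "CD":
        new_seq = phage.seq[:s] + phage.seq[e:]
        remnant = ""
    else:
        raise ValueError("which must be 'C', 'D' or 'CD'")
    rec = SequenceRecord(f"{phage.id}_ddif{which}", new_seq, "circular")
    loc = Interval(rec.id, s, max(s + 1, s + len(remnant)))
    construct = partial_dif_site(remnant, which, grammar, loc)
    return rec, construct


def simulate_all(cfg: SimConfig, outdir: str | Path | None = None,
                 n_hosts: int = 1, grammar: DifGrammar | None = None
                 ) -> tuple[dict[str, list[SequenceRecord]], GroundTruth]:
    """Generate hosts, phages, integrated chromosomes and a MAG set under one
    seed; optionally write hosts/phages/integrated/mags FASTA plus the
    ground-truth JSON to ``outdir``."""
    from .core_io import write_fasta

    grammar = grammar or DifGrammar()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    hosts, phages, integrated = [], [], []
    for i in range(n_hosts):
        host, t1 = make_host(cfg, rng, grammar, record_id=f"host{i:03d}")
        phage, t2 = make_phage(cfg, rng, grammar, record_id=f"phage{i:03d}")
        truth.merge(t1).merge(t2)
        rec, truth = plant_integration(host, phage, truth, grammar)
        hosts.append(host)
        phages.append(phage)
        integrated.append(rec)
    mags, t3 = make_mag_set(cfg, rng, grammar)
    truth.merge(t3)
    out = {"hosts": hosts, "phages": phages, "integrated": integrated, "mags": mags}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, records in out.items():
            write_fasta(records, outdir / f"{name}.fasta")
        truth.to_json(outdir / "truth.json")
    return out, truth
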