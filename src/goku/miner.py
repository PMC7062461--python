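"""Prophage discovery, boundary detection, excision and integration modelling.

The discovery chain per genome is: translated homology search for the major
capsid protein (VP1) -> exact-repeat search for shared >=17-mers in the 5 kb
flanks of the capsid locus (the attachment-site direct repeat left by
dif-mediated integration) -> dif-grammar classification of the repeat copies
-> excision of the circular replicative-form genome.

Integration is modelled as strictly XerC/XerD-dependent: both recombinases
must be active and the phage must present an intact, phage-like dif site
(conserved XerC arm, both arms present). The phage genome is linearized at
its dif and inserted immediately downstream (3') of the bacterial dif, which
is left unchanged — so the prophage region runs from the first base after
the bacterial dif through the last base of the phage dif, and excision takes
the phage dif along while the bacterial site stays behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotate import AnnotationConfig, GeneCall, assign_roles, find_orfs
from .core_io import (
    BACTERIAL_LIKE,
    NON_SITE,
    PARTIAL_C_MISSING,
    PARTIAL_D_MISSING,
    PHAGE_LIKE,
    DifGrammar,
    DifSite,
    Interval,
    SequenceRecord,
    circular_slice,
    revcomp,
)
from . import difscan


class ProphageRejected(Exception):
    """A candidate boundary pair failed validation."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class AmbiguousBoundaryError(ProphageRejected):
    """Both repeat copies are bacterial-like and identical: the excision
    direction is undecidable."""


@dataclass(frozen=True)
class MinerConfig:
    flank_len: int = 5000          # bp searched either side of the capsid locus
    repeat_seed_len: int = 17      # exact shared k-mer seeding the repeat search
    capsid_score_min: float = 100.0  # raw BLOSUM62 local-alignment score
    bacterial_dif_max_mm: int = 1
    xerC_arm_max_mm: int = 2
    seed_kmer: int = 5             # protein k-mer for alignment seeding
    pwm_fallback_threshold: float | None = None  # score floor for fallback hits
    #                                              (None = 0.0 bits; permissive,
    #                                              grammar ranking does the work)

    def __post_init__(self):
        if self.repeat_seed_len > self.flank_len:
            raise ValueError("repeat_seed_len must not exceed flank_len")


@dataclass(frozen=True)
class HostState:
    """Recombinase availability of the infected host.

    ``xerD_complementable`` mirrors the observed asymmetry that plasmid
    complementation restores a xerC deletion but not a xerD deletion; it is a
    configurable flag, not a mechanistic claim.
    """

    xerC_active: bool = True
    xerD_active: bool = True

    @staticmethod
    def from_genotype(
        xerC_deleted: bool = False,
        xerD_deleted: bool = False,
        plasmid: str | None = None,   # None | "xerC" | "xerD"
        induced: bool = False,
        xerD_complementable: bool = False,
    ) -> "HostState":
        xerC = not xerC_deleted
        xerD = not xerD_deleted
        if plasmid == "xerC" and induced:
            xerC = True
        if plasmid == "xerD" and induced and xerD_complementable:
            xerD = True
        return HostState(xerC_active=xerC, xerD_active=xerD)


@dataclass(frozen=True)
class ProphageCall:
    host_id: str
    region: Interval               # first base after upstream dif .. last base of downstream dif
    upstream_dif: DifSite
    downstream_dif: DifSite
    genes: tuple[GeneCall, ...]
    excised: SequenceRecord


@dataclass(frozen=True)
class IntegrationOutcome:
    """Result of an integration attempt: a genome or a typed refusal."""

    integrated: SequenceRecord | None = None
    refusal_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.integrated is not None


def classify_dif(seq: str, grammar: DifGrammar | None = None,
                 cfg: MinerConfig | None = None,
                 location: Interval | None = None) -> DifSite:
    """Classify a grammar-width sequence against the canonical dif.

    bacterial_like: total mismatches <= ``bacterial_dif_max_mm`` (the "at
    most one nucleotide" rule). phage_like: XerC arm within
    ``xerC_arm_max_mm`` of canonical while the spacer/XerD arm may diverge.
    Anything else is non_site. (The partial_* classes describe engineered
    arm deletions and are produced by :func:`partial_dif_site`.)
    """
    grammar = grammar or DifGrammar()
    cfg = cfg or MinerConfig()
    mc, ms, md = grammar.component_mismatches(seq)
    total = mc + ms + md
    if total <= cfg.bacterial_dif_max_mm:
        site_class = BACTERIAL_LIKE
    elif mc <= cfg.xerC_arm_max_mm:
        site_class = PHAGE_LIKE
    else:
        site_class = NON_SITE
    loc = location or Interval("query", 0, grammar.total_len)
    return DifSite(seq.upper(), loc, mc, ms, md, site_class)


def partial_dif_site(seq: str, missing_arm: str,
                     grammar: DifGrammar | None = None,
                     location: Interval | None = None) -> DifSite:
    """Describe an engineered dif with a deleted/disabled arm ("C", "D" or
    "CD"); used to model the deletion constructs."""
    grammar = grammar or DifGrammar()
    loc = location or Interval("construct", 0, max(1, len(seq)))
    if missing_arm == "C":
        cls = PARTIAL_C_MISSING
    elif missing_arm == "D":
        cls = PARTIAL_D_MISSING
    else:
        cls = NON_SITE
    w = grammar.total_len
    padded = (seq.upper() + "N" * w)[:w]
    mc, ms, md = grammar.component_mismatches(padded)
    return DifSite(seq.upper(), loc, mc, ms, md, cls)


# ---------------------------------------------------------------------------
# capsid homology search
# ---------------------------------------------------------------------------

_FRAME_CACHE_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _translate_frame(nt: str) -> str:
    from Bio.Seq import Seq

    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate(table=11))


def find_capsid_loci(record: SequenceRecord, query: str,
                     cfg: MinerConfig | None = None) -> list[Interval]:
    """Translated, seeded local-alignment search for the capsid query.

    Six-frame translation; shared protein k-mers seed banded windows that are
    aligned with affine-gap local alignment (BLOSUM62); windows scoring >=
    ``capsid_score_min`` are mapped back to nucleotide coordinates. Returns
    the best non-overlapping loci sorted by position.
    """
    cfg = cfg or MinerConfig()
    query = query.upper()
    bad = set(query) - _FRAME_CACHE_AA
    if bad:
        raise ValueError(f"invalid residues in query: {sorted(bad)}")
    if len(query) < 50:
        raise ValueError("query must be at least 50 aa")

    from .annotate import _protein_aligner

    aligner = _protein_aligner()
    k = cfg.seed_kmer
    qkmers: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        qkmers.setdefault(query[i : i + k], []).append(i)

    candidates: list[tuple[float, Interval]] = []
    n = len(record)
    for strand in "+-":
        base = record.seq if strand == "+" else revcomp(record.seq)
        for f in range(3):
            prot = _translate_frame(base[f:])
            # seed diagonals
            diags: dict[int, list[int]] = {}
            for i in range(len(prot) - k + 1):
                for qpos in qkmers.get(prot[i : i + k], ()):
                    d = i - qpos
                    diags.setdefault(d // 25, []).append(i)
            # merge neighbouring diagonal buckets into alignment windows
            windows: list[tuple[int, int]] = []
            for bucket, positions in sorted(diags.items()):
                lo = max(0, min(positions) - len(query))
                hi = min(len(prot), max(positions) + len(query) + k)
                if windows and lo <= windows[-1][1]:
                    windows[-1] = (windows[-1][0], max(windows[-1][1], hi))
                else:
                    windows.append((lo, hi))
            for lo, hi in windows:
                sub = prot[lo:hi].replace("*", "X")
                sub_clean = sub.replace("X", "A")  # X never in BLOSUM keys here
                score = aligner.score(sub_clean, query)
                if score < cfg.capsid_score_min:
                    continue
                aln = aligner.align(sub_clean, query)[0]
                t0 = int(aln.aligned[0][0][0]) + lo
                t1 = int(aln.aligned[0][-1][1]) + lo
                nt_start = f + 3 * t0
                nt_end = f + 3 * t1
                if strand == "-":
                    nt_start, nt_end = n - nt_end, n - nt_start
                candidates.append(
                    (float(score), Interval(record.id, nt_start, nt_end, strand))
                )
    # best-per-region, non-overlapping
    candidates.sort(key=lambda t: (-t[0], t[1].start))
    loci: list[Interval] = []
    for _score, iv in candidates:
        if all(iv.overlap(acc) == 0 for acc in loci):
            loci.append(iv)
    loci.sort(key=lambda iv: iv.start)
    return loci


# ---------------------------------------------------------------------------
# flanking repeat search
# ---------------------------------------------------------------------------

def find_flanking_repeats(
    record: SequenceRecord,
    locus: Interval,
    cfg: MinerConfig | None = None,
    grammar: DifGrammar | None = None,
) -> list[tuple[Interval, Interval]]:
    """Maximal exact repeats with one copy in the upstream and one in the
    downstream flank of ``locus``, seeded by shared ``repeat_seed_len``-mers
    in the same orientation.

    Ranked by (1) longer extended match, (2) smaller enclosed interval,
    (3) leftmost upstream copy. Dif-PWM fallback pairs (best same-strand dif
    hits of the two flanks, ranked by summed score) are appended after the
    exact pairs: the shared dif core can be shorter than the seed length when
    the phage spacer/XerD arm has diverged, in which case no exact repeat
    marks the true boundary.
    """
    cfg = cfg or MinerConfig()
    grammar = grammar or DifGrammar()
    n = len(record)
    up_lo = max(0, locus.start - cfg.flank_len)
    up_hi = locus.start
    dn_lo = locus.end
    dn_hi = min(n, locus.end + cfg.flank_len)
    up = record.seq[up_lo:up_hi]
    dn = record.seq[dn_lo:dn_hi]
    k = cfg.repeat_seed_len

    up_kmers: dict[str, list[int]] = {}
    for i in range(len(up) - k + 1):
        up_kmers.setdefault(up[i : i + k], []).append(i)

    pairs: set[tuple[int, int, int]] = set()  # (up_start_abs, dn_start_abs, length)
    for j in range(len(dn) - k + 1):
        kmer = dn[j : j + k]
        for i in up_kmers.get(kmer, ()):
            a, b, ln = _extend_match(record.seq, up_lo + i, dn_lo + j, k,
                                     up_lo, up_hi, dn_lo, dn_hi)
            pairs.add((a, b, ln))

    ranked = sorted(
        pairs,
        key=lambda p: (-p[2], (p[1] + p[2]) - p[0], p[0]),
    )
    out = [
        (Interval(record.id, a, a + ln), Interval(record.id, b, b + ln))
        for a, b, ln in ranked
    ]

    # PWM fallback pairs: same-strand dif hits of the two flanks. A diverged
    # phage dif can score barely above background, so the floor is permissive
    # and the ranking prefers grammar-plausible pairs (bacterial-like
    # upstream, intact XerC arm downstream) before raw score.
    pwm = difscan.build_pwm([grammar.canonical_seq], grammar)
    floor = (cfg.pwm_fallback_threshold
             if cfg.pwm_fallback_threshold is not None else 0.0)
    scfg = difscan.ScanConfig(floor_threshold=floor)
    fallback: list[tuple[tuple, Interval, Interval]] = []
    if up and dn:
        up_hits = difscan.scan(SequenceRecord(record.id, up, "linear"), pwm, scfg)
        dn_hits = difscan.scan(SequenceRecord(record.id, dn, "linear"), pwm, scfg)
        for hu in up_hits:
            su = classify_dif(hu.seq, grammar, cfg)
            for hd in dn_hits:
                if hu.location.strand != hd.location.strand:
                    continue
                sd = classify_dif(hd.seq, grammar, cfg)
                strand = hu.location.strand
                # in dif orientation, the chromosomal (bacterial-like) copy
                # precedes the phage copy: on + that is the left flank, on -
                # the right flank
                bact, phg = (su, sd) if strand == "+" else (sd, su)
                if bact.site_class != BACTERIAL_LIKE:
                    continue
                iu = Interval(record.id, up_lo + hu.location.start,
                              up_lo + hu.location.end, strand)
                idn = Interval(record.id, dn_lo + hd.location.start,
                               dn_lo + hd.location.end, strand)
                rank = (
                    phg.xerC_mismatches,               # conserved XerC arm first
                    -(hu.score + hd.score),
                )
                fallback.append((rank, iu, idn))
    fallback.sort(key=lambda t: (t[0], t[1].start, t[2].start))
    out.extend((iu, idn) for _r, iu, idn in fallback)
    return out


def _extend_match(seq: str, i: int, j: int, k: int,
                  up_lo: int, up_hi: int, dn_lo: int, dn_hi: int
                  ) -> tuple[int, int, int]:
    """Extend an exact seed at absolute positions i/j to the maximal exact
    match whose copies stay inside their windows."""
    left = 0
    while (i - left - 1 >= up_lo and j - left - 1 >= dn_lo
           and seq[i - left - 1] == seq[j - left - 1]):
        left += 1
    right = 0
    while (i + k + right < up_hi and j + k + right < dn_hi
           and seq[i + k + right] == seq[j + k + right]):
        right += 1
    return i - left, j - left, k + left + right


# ---------------------------------------------------------------------------
# calling and excision
# ---------------------------------------------------------------------------

def _best_dif_window(seq: str, center_start: int, center_end: int,
                     grammar: DifGrammar, pwm=None) -> int:
    """Best grammar-width window start overlapping [center_start, center_end)
    by canonical-PWM score (ties: leftmost)."""
    w = grammar.total_len
    if pwm is None:
        pwm = difscan.build_pwm([grammar.canonical_seq], grammar)
    a, b = center_end - w, center_start  # copy inside window vs window inside copy
    lo = max(0, min(a, b))
    hi = min(len(seq) - w, max(a, b))
    if hi < lo:
        hi = lo
    best, best_score = lo, -np.inf
    for s in range(lo, hi + 1):
        sc = pwm.score_seq(seq[s : s + w])
        if sc > best_score:
            best, best_score = s, sc
    return best


def call_prophage(
    record: SequenceRecord,
    locus: Interval,
    pair: tuple[Interval, Interval],
    grammar: DifGrammar | None = None,
    cfg: MinerConfig | None = None,
    references: list[tuple[str, str]] | None = None,
    annotation_cfg: AnnotationConfig | None = None,
) -> ProphageCall:
    """Turn a repeat pair into a validated prophage call.

    The repeat copies are positionally homologous, so the grammar window is
    located once on the upstream copy (canonical-PWM best placement) and the
    same offset is applied to the downstream copy. The upstream site must be
    bacterial-like; the region spans from the end of the upstream dif through
    the end of the downstream dif; genes are annotated on the excised genome.
    """
    grammar = grammar or DifGrammar()
    cfg = cfg or MinerConfig()
    w = grammar.total_len
    up_iv, dn_iv = pair
    if up_iv.strand == "-" or dn_iv.strand == "-":
        raise ProphageRejected(
            "minus-oriented boundary pair; flip the contig and re-call"
        )
    pwm = difscan.build_pwm([grammar.canonical_seq], grammar)

    up_start = _best_dif_window(record.seq, up_iv.start, up_iv.end, grammar, pwm)
    offset = up_start - up_iv.start
    dn_start = dn_iv.start + offset
    if dn_start < 0 or dn_start + w > len(record):
        raise ProphageRejected("downstream dif window out of bounds")

    up_seq = record.seq[up_start : up_start + w]
    dn_seq = record.seq[dn_start : dn_start + w]
    up_site = classify_dif(up_seq, grammar, cfg,
                           Interval(record.id, up_start, up_start + w))
    dn_site = classify_dif(dn_seq, grammar, cfg,
                           Interval(record.id, dn_start, dn_start + w))

    if up_site.site_class == BACTERIAL_LIKE and dn_site.site_class == BACTERIAL_LIKE \
            and up_seq == dn_seq:
        raise AmbiguousBoundaryError(
            "both boundary copies are bacterial-like and identical"
        )
    if up_site.site_class != BACTERIAL_LIKE:
        raise ProphageRejected(
            f"upstream boundary is {up_site.site_class}, not {BACTERIAL_LIKE}"
        )
    if dn_site.site_class not in (PHAGE_LIKE, BACTERIAL_LIKE):
        raise ProphageRejected(
            f"downstream boundary is {dn_site.site_class}"
        )

    region = Interval(record.id, up_start + w, dn_start + w)
    excised = SequenceRecord(
        f"{record.id}|prophage_{region.start}_{region.end}",
        record.seq[region.start : region.end],
        "circular",
    )
    genes = find_orfs(excised, annotation_cfg)
    if references:
        genes = assign_roles(excised, genes, references)
    return ProphageCall(record.id, region, up_site, dn_site, tuple(genes), excised)


def excise(record: SequenceRecord, call: ProphageCall
           ) -> tuple[SequenceRecord, SequenceRecord]:
    """Excise the called region: the circular replicative-form phage genome
    (phage dif once, bacterial dif zero times) and the restored host with the
    bacterial dif left unchanged. Lengths are conserved."""
    region = call.region
    if region.end > len(record) or region.start < 0:
        raise ValueError("region out of bounds")
    phage_seq = record.seq[region.start : region.end]
    if region.strand == "-":  # call was made on the flipped contig
        phage_seq = revcomp(phage_seq)
    phage = SequenceRecord(call.excised.id, phage_seq, "circular")
    host = SequenceRecord(f"{record.id}|restored",
                          record.seq[: region.start] + record.seq[region.end :],
                          record.topology)
    return phage, host


def find_dif_sites(record: SequenceRecord, grammar: DifGrammar | None = None,
                   max_mm: int = 1) -> list[DifSite]:
    """All grammar-width windows within ``max_mm`` total mismatches of the
    canonical sequence, both strands (origin-wrapping on circular records)."""
    grammar = grammar or DifGrammar()
    w = grammar.total_len
    n = len(record)
    hay = record.seq + (record.seq[: w - 1] if record.is_circular else "")
    sites: list[DifSite] = []
    for strand in "+-":
        target = grammar.canonical_seq if strand == "+" else revcomp(grammar.canonical_seq)
        enc_t = np.frombuffer(target.encode(), dtype=np.uint8)
        enc = np.frombuffer(hay.encode(), dtype=np.uint8)
        if len(enc) < w:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        mism = (windows != enc_t).sum(axis=1)
        # N mismatches everything including itself
        nmask = (windows == ord("N")).sum(axis=1)
        mism = np.maximum(mism, nmask)
        for i in np.nonzero(mism <= max_mm)[0]:
            start = int(i)
            if start >= n:
                continue
            seq = hay[start : start + w]
            if strand == "-":
                seq = revcomp(seq)
            sites.append(
                classify_dif(seq, grammar, None,
                             Interval(record.id, start, start + w, strand))
            )
    # a palindrome-ish canonical can match both strands at one position
    uniq: dict[tuple[int, str], DifSite] = {}
    for s in sites:
        uniq.setdefault((s.location.start, s.location.strand), s)
    return sorted(uniq.values(), key=lambda s: (s.location.start, s.location.strand))


def locate_phage_dif(phage: SequenceRecord, grammar: DifGrammar | None = None,
                     cfg: MinerConfig | None = None) -> DifSite | None:
    """Best dif-grammar site on a phage genome (both strands), or None if
    nothing classifies as a site."""
    grammar = grammar or DifGrammar()
    cfg = cfg or MinerConfig()
    pwm = difscan.build_pwm([grammar.canonical_seq], grammar)
    # score floor keeps chance XerC-arm look-alikes from masquerading as sites
    thr = difscan.threshold_for_fpr(pwm, null_fpr=0.05)
    scfg = difscan.ScanConfig(floor_threshold=thr)
    hits = difscan.scan(phage, pwm, scfg)
    for h in hits:  # sorted by score descending
        site = classify_dif(h.seq, grammar, cfg, h.location)
        if site.site_class in (BACTERIAL_LIKE, PHAGE_LIKE):
            return site
    return None


def integrate(
    host: SequenceRecord,
    phage: SequenceRecord,
    host_state: HostState | None = None,
    grammar: DifGrammar | None = None,
    cfg: MinerConfig | None = None,
    phage_dif: DifSite | None = None,
) -> IntegrationOutcome:
    """Attempt XerC/XerD-mediated integration of a circular phage genome.

    Refuses (typed, with reason) unless both recombinases are active and the
    phage dif is intact and phage-like (or bacterial-like; both arms present,
    XerC arm within tolerance). On success the phage is linearized at its dif
    and inserted immediately downstream of the host dif, which remains
    unchanged; the phage dif becomes the downstream prophage boundary,
    co-oriented with the bacterial dif.
    """
    host_state = host_state or HostState()
    grammar = grammar or DifGrammar()
    cfg = cfg or MinerConfig()
    if not phage.is_circular:
        raise ValueError("phage genome must be circular")

    host_sites = [s for s in find_dif_sites(host, grammar, cfg.bacterial_dif_max_mm)
                  if s.site_class == BACTERIAL_LIKE]
    if len(host_sites) != 1:
        raise ValueError(
            f"host must carry exactly one bacterial-like dif site, found {len(host_sites)}"
        )
    host_dif = host_sites[0]

    if not host_state.xerC_active:
        return IntegrationOutcome(refusal_reason="xerC_inactive")
    if not host_state.xerD_active:
        return IntegrationOutcome(refusal_reason="xerD_inactive")

    site = phage_dif if phage_dif is not None else locate_phage_dif(phage, grammar, cfg)
    if site is None:
        return IntegrationOutcome(refusal_reason="no_phage_dif")
    if site.site_class in (PARTIAL_C_MISSING, PARTIAL_D_MISSING, NON_SITE):
        return IntegrationOutcome(refusal_reason=f"phage_dif_{site.site_class}")

    w = grammar.total_len
    # orient the phage so its dif reads on + and rotate it to END with the dif
    oriented = phage if site.location.strand == "+" else \
        replace(phage, seq=revcomp(phage.seq))
    if site.location.strand == "+":
        dif_start = site.location.start
    else:
        dif_start = (len(phage) - site.location.start - w) % len(phage)
    lin = circular_slice(oriented, dif_start + w, dif_start + w + len(phage))

    hd = host_dif.location
    if hd.strand == "-":
        # normalize: flip the host image so its dif reads on +
        flipped = revcomp(host.seq)
        insert_at = len(host) - hd.start
        new_seq = flipped[:insert_at] + lin + flipped[insert_at:]
    else:
        insert_at = hd.end
        new_seq = host.seq[:insert_at] + lin + host.seq[insert_at:]
    integrated = SequenceRecord(f"{host.id}|{phage.id}", new_seq, host.topology)
    return IntegrationOutcome(integrated=integrated)


def mine(
    genomes: list[SequenceRecord],
    query: str,
    grammar: DifGrammar | None = None,
    cfg: MinerConfig | None = None,
    references: list[tuple[str, str]] | None = None,
    annotation_cfg: AnnotationConfig | None = None,
) -> tuple[list[ProphageCall], list[tuple[str, str]]]:
    """End-to-end discovery: loci -> repeats -> calls -> excision, per
    genome. Returns (calls, rejection log of (genome id, reason))."""
    grammar = grammar or DifGrammar()
    cfg = cfg or MinerConfig()
    calls: list[ProphageCall] = []
    rejections: list[tuple[str, str]] = []
    for orig in genomes:
        for orig_locus in find_capsid_loci(orig, query, cfg):
            # prophages found on the - strand are mined on the flipped contig
            # and the call is mapped back to forward coordinates
            if orig_locus.strand == "-":
                n = len(orig)
                record = replace(orig, seq=revcomp(orig.seq))
                locus = Interval(orig.id, n - orig_locus.end,
                                 n - orig_locus.start, "+")
            else:
                record, locus = orig, orig_locus
            pairs = find_flanking_repeats(record, locus, cfg, grammar)
            if not pairs:
                rejections.append((record.id, "no boundary repeat pair"))
                continue
            called = False
            for pair in pairs:
                try:
                    call = call_prophage(record, locus, pair, grammar, cfg,
                                         references, annotation_cfg)
                except ProphageRejected as exc:
                    rejections.append((record.id, exc.reason))
                    continue
                if orig_locus.strand == "-":
                    call = _flip_call(call, len(orig))
                if any(c.host_id == call.host_id and
                       c.region.overlap(call.region) > 0 for c in calls):
                    called = True
                    break
                calls.append(call)
                called = True
                break
            if not called:
                rejections.append((record.id, "no valid boundary pair"))
    return calls, rejections


def _flip_interval(iv: Interval, n: int) -> Interval:
    strand = "-" if iv.strand == "+" else "+"
    return Interval(iv.contig_id, n - iv.end, n - iv.start, strand)


def _flip_call(call: ProphageCall, n: int) -> ProphageCall:
    """Map a call made on the reverse-complemented contig back to forward
    coordinates. The excised genome stays gene-oriented; dif semantics
    (upstream = bacterial, downstream = phage, in dif orientation) are kept.
    """
    return ProphageCall(
        call.host_id,
        _flip_interval(call.region, n),
        replace(call.upstream_dif, location=_flip_interval(call.upstream_dif.location, n)),
        replace(call.downstream_dif, location=_flip_interval(call.downstream_dif.location, n)),
        call.genes,
        call.excised,
    )
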