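"""PWM-based dif-motif discovery with iterative search and context filtering.

dif sites are fixed-length (28 bp by default) and ungapped, so an ungapped
position weight matrix over the grammar width is used as the motif model:
per-column log2-odds of base probability (counts + pseudocount) against a
background composition. The primary score threshold can be calibrated
analytically from the exact null score distribution (dynamic-programming
convolution of per-column score distributions) to a configured expected
false-hit rate per 5 kb of scanned sequence.

Sub-threshold hits are rescued as "potential" motifs when they share at least
``min_identity`` positionally identical bases with a confirmed motif and fall
in a non-coding region — or inside the N-terminal window of a VP4 gene, the
one coding context where integration is tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotate import (
    CODING_VP4_NTERM,
    NON_CODING,
    AnnotationConfig,
    GeneCall,
    coding_context,
)
from .core_io import DifGrammar, Interval, SequenceRecord, revcomp

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

CONFIRMED = "confirmed"
POTENTIAL = "potential"
REJECTED = "rejected"


@dataclass(frozen=True)
class ScanConfig:
    min_identity: int = 15            # bp identical to a confirmed motif
    primary_threshold: float | str = "auto"
    null_fpr: float = 0.05            # expected false hits per 5 kb (both strands)
    max_rounds: int = 10
    floor_threshold: float = 0.0      # minimum log-odds score to report at all
    shifted_identity: bool = False    # allow positional shifts in the 15-bp rule


@dataclass(frozen=True)
class ScanHit:
    location: Interval
    score: float
    seq: str
    best_identity: int = 0
    context: str = ""
    status: str = ""
    reject_reason: str = ""


@dataclass(frozen=True)
class PWMModel:
    """Per-column log2-odds matrix over {A,C,G,T}."""

    matrix: np.ndarray                 # (width, 4) log2-odds
    probs: np.ndarray                  # (width, 4) column probabilities
    pseudocount: float
    background: np.ndarray             # (4,)
    training_ids: tuple[str, ...] = ()

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def score_seq(self, seq: str) -> float:
        if len(seq) != self.width:
            raise ValueError(f"expected {self.width} bp, got {len(seq)}")
        total = 0.0
        for j, c in enumerate(seq.upper()):
            i = _BASE_INDEX.get(c)
            # N scores as the worst base in that column (conservative)
            total += self.matrix[j].min() if i is None else self.matrix[j, i]
        return float(total)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.matrix, axis=1))

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


def build_pwm(
    motifs: list[str],
    grammar: DifGrammar | None = None,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    training_ids: tuple[str, ...] = (),
) -> PWMModel:
    """Column counts + pseudocount -> probabilities -> log2-odds vs background."""
    grammar = grammar or DifGrammar()
    width = grammar.total_len
    if not motifs:
        raise ValueError("need at least one training motif")
    for m in motifs:
        if len(m) != width:
            raise ValueError(f"motif {m!r} is not grammar width {width}")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    counts = np.zeros((width, 4))
    for m in motifs:
        for j, c in enumerate(m.upper()):
            i = _BASE_INDEX.get(c)
            if i is None:  # N contributes equally to all bases
                counts[j] += 0.25
            else:
                counts[j, i] += 1
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    matrix = np.log2(probs / bg)
    return PWMModel(matrix, probs, pseudocount, bg, tuple(training_ids))


def threshold_for_fpr(
    pwm: PWMModel, null_fpr: float = 0.05, per_bp: int = 5000, precision: float = 0.01
) -> float:
    """Smallest score t with (expected null hits in ``per_bp`` bp, both
    strands) <= ``null_fpr``, from the exact i.i.d.-background score
    distribution computed by convolution on a discretized score grid.
    """
    q = np.round(pwm.matrix / precision).astype(int)  # (width, 4)
    cur = np.zeros(1)
    cur[0] = 1.0
    cur_lo = 0
    for j in range(pwm.width):
        nxt_lo = cur_lo + int(q[j].min())
        nxt_hi = cur_lo + len(cur) - 1 + int(q[j].max())
        nxt = np.zeros(nxt_hi - nxt_lo + 1)
        for b in range(4):
            shift = q[j, b]
            start = cur_lo + shift - nxt_lo
            nxt[start : start + len(cur)] += pwm.background[b] * cur
        cur, cur_lo = nxt, nxt_lo
    tail = np.cumsum(cur[::-1])[::-1]  # P(score >= s) on the grid
    n_tests = 2 * per_bp  # both strands
    target = null_fpr / n_tests
    idx = np.argmax(tail <= target) if (tail <= target).any() else len(tail) - 1
    return (cur_lo + idx) * precision


def resolve_threshold(pwm: PWMModel, cfg: ScanConfig) -> float:
    if cfg.primary_threshold == "auto":
        return threshold_for_fpr(pwm, cfg.null_fpr)
    return float(cfg.primary_threshold)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(seq: str, pwm: PWMModel) -> np.ndarray:
    """Score of every width-window of ``seq`` (N = worst base per column)."""
    w = pwm.width
    enc = _encode(seq)
    if len(enc) < w:
        return np.zeros(0)
    ext = np.concatenate([pwm.matrix, pwm.matrix.min(axis=1, keepdims=True)], axis=1)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    return ext[np.arange(w)[None, :], windows].sum(axis=1)


def scan(record: SequenceRecord, pwm: PWMModel, cfg: ScanConfig | None = None) -> list[ScanHit]:
    """Score every position on both strands (wrapping the origin on circular
    records); report hits >= ``floor_threshold``, overlapping same-strand hits
    resolved to the local maximum, sorted by score descending.
    """
    cfg = cfg or ScanConfig()
    w = pwm.width
    n = len(record)
    fwd = record.seq + (record.seq[: w - 1] if record.is_circular else "")
    raw: list[ScanHit] = []
    for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
        scores = np.round(_window_scores(seq, pwm), 6)
        for i in np.nonzero(scores >= cfg.floor_threshold)[0]:
            if strand == "+":
                start = int(i)
            else:
                start = len(seq) - w - int(i)
            if start >= n:
                continue
            raw.append(
                ScanHit(
                    Interval(record.id, start, start + w, strand),
                    # rounded so ties sort identically regardless of
                    # floating-point summation order
                    round(float(scores[i]), 6),
                    seq[i : i + w] if strand == "-" else fwd[start : start + w],
                )
            )
    # non-maximum suppression among same-strand overlapping hits;
    # ties: higher score, then + strand, then leftmost
    raw.sort(key=lambda h: (-h.score, h.location.strand != "+", h.location.start))
    kept: list[ScanHit] = []
    for h in raw:
        if all(
            h.location.strand != k.location.strand
            or _circ_overlap(h.location, k.location, n, record.is_circular) == 0
            for k in kept
        ):
            kept.append(h)
    return kept


def _circ_overlap(a: Interval, b: Interval, n: int, circular: bool) -> int:
    if not circular:
        return a.overlap(b)
    best = 0
    for d in (-n, 0, n):
        shifted = Interval(a.contig_id, a.start + d + 2 * n, a.end + d + 2 * n, a.strand)
        best = max(best, shifted.overlap(
            Interval(b.contig_id, b.start + 2 * n, b.end + 2 * n, b.strand)))
    return best


def frame_identity(a: str, b: str) -> int:
    """Positionally identical bases in the grammar frame (no shifts)."""
    return sum(1 for x, y in zip(a, b) if x == y and x in _BASE_INDEX)


def shifted_identity(a: str, b: str, min_overlap: int = 15) -> int:
    """Max identical bases over all relative shifts (both directions)."""
    best = 0
    w = len(a)
    for off in range(-(w - min_overlap), w - min_overlap + 1):
        if off >= 0:
            best = max(best, frame_identity(a[off:], b))
        else:
            best = max(best, frame_identity(a, b[-off:]))
    return best


def best_identity(seq: str, confirmed: list[str], cfg: ScanConfig) -> int:
    if not confirmed:
        return 0
    fn = (lambda a, b: shifted_identity(a, b, cfg.min_identity)) if cfg.shifted_identity \
        else frame_identity
    return max(fn(seq, m) for m in confirmed)


def filter_hits(
    hits: list[ScanHit],
    genes: list[GeneCall],
    confirmed: list[str],
    cfg: ScanConfig | None = None,
    annotation_cfg: AnnotationConfig | None = None,
    primary_threshold: float | None = None,
    contig_len: int | None = None,
    circular: bool = False,
) -> list[ScanHit]:
    """Assign confirmed/potential/rejected status; never alters coordinates
    or scores.

    The coding-context rule dominates: hits inside coding regions are
    rejected regardless of score, except those in the VP4 N-terminal window
    (where integration can preserve the gene via a nearby alternative
    start). Surviving hits are confirmed when score >= primary threshold,
    or rescued as potential when >= ``min_identity`` bases are identical to
    a confirmed motif.
    """
    cfg = cfg or ScanConfig()
    annotation_cfg = annotation_cfg or AnnotationConfig()
    if primary_threshold is None:
        if cfg.primary_threshold == "auto":
            raise ValueError("primary_threshold must be resolved before filtering")
        primary_threshold = float(cfg.primary_threshold)
    out: list[ScanHit] = []
    for h in hits:
        ctx = coding_context(h.location, genes, annotation_cfg,
                             contig_len=contig_len, circular=circular)
        ident = best_identity(h.seq, confirmed, cfg)
        if ctx not in (NON_CODING, CODING_VP4_NTERM):
            status, reason = REJECTED, ctx
        elif h.score >= primary_threshold:
            status, reason = CONFIRMED, ""
        elif ident >= cfg.min_identity:
            status, reason = POTENTIAL, ""
        else:
            status, reason = REJECTED, f"identity_{ident}_below_{cfg.min_identity}"
        out.append(replace(h, best_identity=ident, context=ctx,
                           status=status, reject_reason=reason))
    return out


@dataclass
class RoundLog:
    round: int
    training_size: int
    new_motifs: int
    mags_with_hits: int


@dataclass
class IterativeSearchResult:
    motifs: list[str]                     # final training set (seeds + found)
    hits: dict[str, list[ScanHit]]        # accepted hits per MAG id
    rounds: list[RoundLog] = field(default_factory=list)


def iterative_search(
    mags: list[SequenceRecord],
    seed_motifs: list[str],
    genes_per_mag: dict[str, list[GeneCall]],
    grammar: DifGrammar | None = None,
    cfg: ScanConfig | None = None,
    annotation_cfg: AnnotationConfig | None = None,
) -> IterativeSearchResult:
    """Rounds of build_pwm -> scan -> filter. Stops when no new MAG gains a
    hit or after ``max_rounds``. Deterministic.

    Only confirmed-status motifs (the seeds plus hits clearing the primary
    threshold) serve as identity references and rejoin the training set:
    feeding the potential class back would let chance 15/28-identity windows
    bootstrap themselves into the model. Potential hits are reported, not
    recycled.
    """
    grammar = grammar or DifGrammar()
    cfg = cfg or ScanConfig()
    annotation_cfg = annotation_cfg or AnnotationConfig()
    training = list(dict.fromkeys(m.upper() for m in seed_motifs))
    if not training:
        raise ValueError("need at least one seed motif")

    result = IterativeSearchResult(motifs=training, hits={})
    mags_with_hits: set[str] = set()
    for rnd in range(1, cfg.max_rounds + 1):
        pwm = build_pwm(training, grammar, training_ids=(f"round{rnd}",))
        thr = resolve_threshold(pwm, cfg)
        new_motifs: list[str] = []
        hits_now: dict[str, list[ScanHit]] = {}
        for mag in mags:
            hits = scan(mag, pwm, cfg)
            filtered = filter_hits(
                hits, genes_per_mag.get(mag.id, []), training, cfg,
                annotation_cfg, primary_threshold=thr,
                contig_len=len(mag), circular=mag.is_circular,
            )
            hits_now[mag.id] = filtered
            for h in filtered:
                if h.status == CONFIRMED and h.seq not in training \
                        and h.seq not in new_motifs:
                    new_motifs.append(h.seq)
        now_with = {m for m, hs in hits_now.items()
                    if any(h.status in (CONFIRMED, POTENTIAL) for h in hs)}
        result.hits = hits_now
        result.rounds.append(
            RoundLog(rnd, len(training), len(new_motifs), len(now_with))
        )
        if now_with <= mags_with_hits:
            break
        mags_with_hits = now_with
        training.extend(new_motifs)
        result.motifs = training
    return result
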