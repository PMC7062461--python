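"""Independent brute-force oracles used by the validation suites.

These deliberately re-derive each quantity with naive loops, sharing no code
with the production implementations they check.
"""

import itertools

import numpy as np

from goku.annotate import STOP_CODONS, AnnotationConfig
from goku.core_io import SequenceRecord, revcomp


def oracle_scan(record, pwm, cfg):
    """Per-position PWM scorer with the same N rule, NMS and tie-breaks."""
    w = pwm.width
    n = len(record)
    ext = record.seq + (record.seq[: w - 1] if record.is_circular else "")
    raw = []
    for strand in "+-":
        hay = ext if strand == "+" else revcomp(ext)
        for i in range(len(hay) - w + 1):
            window = hay[i : i + w]
            score = 0.0
            for j, c in enumerate(window):
                k = "ACGT".find(c)
                score += pwm.matrix[j].min() if k < 0 else pwm.matrix[j, k]
            start = i if strand == "+" else len(hay) - w - i
            if start < n and round(score, 6) >= cfg.floor_threshold:
                raw.append((round(score, 6), start, strand))
    raw.sort(key=lambda t: (-t[0], t[2] != "+", t[1]))
    kept = []
    for score, start, strand in raw:
        clash = False
        for _s2, st2, sd2 in kept:
            if sd2 != strand:
                continue
            if _circular_overlap(start, start + w, st2, st2 + w, n,
                                 record.is_circular) > 0:
                clash = True
                break
        if not clash:
            kept.append((score, start, strand))
    return kept


def _circular_overlap(a0, a1, b0, b1, n, circular):
    if not circular:
        return max(0, min(a1, b1) - max(a0, b0))
    return max(
        max(0, min(a1 + d, b1) - max(a0 + d, b0)) for d in (-n, 0, n)
    )


def oracle_find_orfs(record: SequenceRecord, cfg: AnnotationConfig):
    """Enumerate all start->stop ORFs then greedy-filter (linear records)."""
    n = len(record)
    cands = []
    for strand in "+-":
        s = record.seq if strand == "+" else revcomp(record.seq)
        for f in range(3):
            starts = []
            for i in range(f, n - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    for st in starts:
                        if i + 3 - st >= cfg.min_gene_len:
                            cands.append((st, i + 3, strand))
                    starts = []
                elif codon in cfg.start_codons:
                    starts.append(i)
    mapped = []
    for st, en, strand in cands:
        if strand == "-":
            st, en = n - en, n - st
        mapped.append((st, en, strand))
    ordered = sorted(mapped, key=lambda g: (-(g[1] - g[0]), g[0], g[2] != "+"))
    accepted = []
    for c in ordered:
        ok = True
        for a in accepted:
            ov = max(0, min(c[1], a[1]) - max(c[0], a[0]))
            if ov > cfg.max_overlap:
                ok = False
                break
        if ok:
            accepted.append(c)
    return sorted(accepted, key=lambda g: (g[0], g[1]))


def oracle_components(ids, vals, threshold):
    """Connected components of {ANI > threshold} by transitive expansion."""
    n = len(ids)
    comp = {i: {i} for i in range(n)}
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if vals[i, j] > threshold and not comp[i] >= comp[j]:
                    comp[i] |= comp[j]
                    for k in list(comp[i]):
                        comp[k] = comp[i]
                    changed = True
    return {frozenset(ids[i] for i in g)
            for g in {frozenset(v) for v in comp.values()}}


def oracle_profile(rows):
    """Exhaustive pair loop for the per-column identity profile."""
    ncol = len(rows[0])
    out = np.full(ncol, np.nan)
    for j in range(ncol):
        same = total = 0
        for a, b in itertools.combinations(range(len(rows)), 2):
            x, y = rows[a][j], rows[b][j]
            if x == "-" or y == "-":
                continue
            total += 1
            same += (x == y) and x in "ACGT"
        if total:
            out[j] = same / total
    return out
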