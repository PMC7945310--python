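"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected result from first principles,
sharing no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_enumerate(refs, editor, pam_class):
    """Test every (strand, PAM position, offset) triple exhaustively.

    Returns a sorted list of (contig, fwd_start0, strand, spacer, pam,
    target_offset) applying the rules: editable base (C/A) at protospacer
    positions 4-8, matching PAM, minimal offset per base, one guide per
    protospacer at the minimal offset of its selected bases, N-containing
    candidates skipped.
    """
    base = "C" if editor == "CBE" else "A"
    plen = 3 if pam_class == "NGG" else 2

    def pam_ok(p):
        if len(p) != plen or "N" in p:
            return False
        return p[1:] == "GG" if pam_class == "NGG" else p[1] == "G"

    per_base = {}
    for contig, fwd in refs.items():
        for strand, seq in (("+", fwd), ("-", rc(fwd))):
            for pam_start in range(20, len(seq) - plen + 1):
                proto = seq[pam_start - 20 : pam_start]
                pam = seq[pam_start : pam_start + plen]
                if not pam_ok(pam) or "N" in proto:
                    continue
                for off in range(4, 9):
                    if proto[off - 1] != base:
                        continue
                    key = (contig, strand, pam_start - 20 + off - 1)
                    cur = per_base.get(key)
                    if cur is None or off < cur[1]:
                        per_base[key] = (pam_start - 20, off)
    per_proto = {}
    for (contig, strand, _b), (start, off) in per_base.items():
        key = (contig, strand, start)
        if key not in per_proto or off < per_proto[key]:
            per_proto[key] = off
    out = []
    for (contig, strand, start), off in per_proto.items():
        seq = refs[contig] if strand == "+" else rc(refs[contig])
        spacer = seq[start : start + 20]
        pam = seq[start + 20 : start + 20 + plen]
        fwd_start = start if strand == "+" else len(seq) - start - 20
        out.append((contig, fwd_start, strand, spacer, pam, off))
    return sorted(out)


def brute_unique(spacer, refs, pam_class):
    """Count spacer occurrences followed by a valid PAM on both strands."""
    plen = 3 if pam_class == "NGG" else 2
    n = 0
    for fwd in refs.values():
        for seq in (fwd, rc(fwd)):
            for i in range(len(seq) - 20 - plen + 1):
                if seq[i : i + 20] != spacer:
                    continue
                pam = seq[i + 20 : i + 20 + plen]
                ok = pam[1:] == "GG" if pam_class == "NGG" else pam[1] == "G"
                if ok and "N" not in pam:
                    n += 1
    return n


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def fisher_exact_p(a, b, c, d):
    """Two-sided Fisher exact p by direct hypergeometric summation."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    p_obs = pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def jaro_reference(a, b):
    """Direct evaluation of the Jaro formula (independent coding)."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    win = max(0, max(len(a), len(b)) // 2 - 1)
    ma, mb = [], []
    used = [False] * len(b)
    for i, ch in enumerate(a):
        for j in range(max(0, i - win), min(len(b), i + win + 1)):
            if not used[j] and b[j] == ch:
                used[j] = True
                ma.append((i, ch))
                mb.append(j)
                break
    m = len(ma)
    if m == 0:
        return 0.0
    b_matched = [b[j] for j in sorted(mb)]
    t = sum(1 for (_, ch), bc in zip(ma, b_matched) if ch != bc) / 2
    return (m / len(a) + m / len(b) + (m - t) / m) / 3


def fk_recount(read_outcomes_edited, read_outcomes_control, key):
    """Brute-force f_k from per-read outcome lists.

    ``read_outcomes_edited`` is a list per edited sample of lists of
    outcome keys (one per assigned read, including "unedited"/"other");
    controls likewise.  Mirrors the published formula with clamping.
    """
    h_vals = []
    for sample in read_outcomes_control:
        d = len(sample)
        if d > 0:
            h_vals.append(sum(1 for k in sample if k == key) / d)
    h = sum(h_vals) / len(h_vals) if h_vals else 0.0
    vals = []
    for sample in read_outcomes_edited:
        d = len(sample)
        if d == 0:
            continue
        r = sum(1 for k in sample if k == key)
        vals.append(min(1.0, max(0.0, (r - d * h) / (d - d * h))))
    return sum(vals) / len(vals)


def grid_cutoff(posterior, lo, hi, threshold, n=2_000_001):
    """Dense-grid location of the rightmost crossing of the threshold.

    ``posterior`` must accept a vector of scores.
    """
    import numpy as np

    x = np.linspace(lo, hi, n)
    above = np.flatnonzero(posterior(x) > threshold)
    return float(x[above[-1]]) if above.size else None
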