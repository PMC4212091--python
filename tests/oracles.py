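"""Independent brute-force oracles the tests compare the package against.

Each oracle is deliberately naive — exhaustive scans, direct formulas,
whole-chromosome string splicing — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

BIG = 10 ** 6


# ---------------------------------------------------------------------------
# exhaustive sliding banded edit-distance scan (mapper oracle)
# ---------------------------------------------------------------------------

def sliding_scan(read: str, ref: str, k: int) -> np.ndarray:
    """Anchored-start semi-global edit distance d(p) for every 0-based
    start p in ref, vectorized over p with a band of +-k on the number
    of consumed reference characters.  Values above k are not exact
    (band truncation), which is irrelevant for hit finding."""
    L, m = len(read), len(ref)
    big = np.int16(30000)
    refi = np.frombuffer(ref.encode(), dtype=np.uint8)
    readi = np.frombuffer(read.encode(), dtype=np.uint8)
    W = 2 * k + 1
    D = np.full((W, m), big, dtype=np.int16)
    D[k] = 0
    for o in range(k + 1, W):
        D[o] = o - k  # leading reference-only consumption
    Dn = np.empty((W, m), dtype=np.int16)
    tmp = np.empty(m, dtype=np.int16)
    for i in range(1, L + 1):
        Dn.fill(big)
        c = readi[i - 1]
        for o in range(W):
            t = i + o - k  # reference chars consumed
            if t < 0:
                continue
            row = Dn[o]
            if o + 1 < W:
                np.add(D[o + 1], 1, out=row)  # read insertion
            if t >= 1:
                end = m - (t - 1) if t > 1 else m
                if end <= 0:
                    continue
                mis = refi[t - 1 : t - 1 + end] != c
                np.add(D[o][:end], mis, out=tmp[:end])  # match / mismatch
                np.minimum(row[:end], tmp[:end], out=row[:end])
                if o - 1 >= 0:
                    np.add(Dn[o - 1][:end], 1, out=tmp[:end])  # ref deletion
                    np.minimum(row[:end], tmp[:end], out=row[:end])
        D, Dn = Dn, D
    return D.min(axis=0)


def scan_best_hits(read: str, ref: str, k: int) -> tuple[int | None, set[int]]:
    """(best distance, set of 1-based best start positions) or (None, {})."""
    d = sliding_scan(read, ref, k)
    dmin = int(d.min())
    if dmin > k:
        return None, set()
    return dmin, {int(p) + 1 for p in np.flatnonzero(d == dmin)}


# ---------------------------------------------------------------------------
# whole-chromosome haplotype splicing + naive read enumeration
# ---------------------------------------------------------------------------

def apply_haplotype(seq: str, variants, alleles):
    """Splice chosen alleles into a contig.

    Returns (hap_seq, ref2hap, hap2ref): ref2hap[p] is the 0-based
    haplotype index of the first aligned base at-or-after reference
    position p (1-based); hap2ref[i] the reference position of
    haplotype base i (inserted bases carry their anchor position).
    """
    out: list[str] = []
    ref2hap = [0] * (len(seq) + 2)
    hap2ref: list[int] = []
    cur = 1
    for v, a in sorted(zip(variants, alleles), key=lambda t: t[0].pos):
        for p in range(cur, v.pos):
            ref2hap[p] = len(out)
            hap2ref.append(p)
            out.append(seq[p - 1])
        chosen = v.alt_seq if a else v.ref_seq
        ref2hap[v.pos] = len(out)
        for ch in chosen:
            hap2ref.append(v.pos)
            out.append(ch)
        for p in range(v.pos + 1, v.pos + len(v.ref_seq)):
            ref2hap[p] = len(out)
        cur = v.pos + len(v.ref_seq)
    for p in range(cur, len(seq) + 1):
        ref2hap[p] = len(out)
        hap2ref.append(p)
        out.append(seq[p - 1])
    return "".join(out), ref2hap, hap2ref


def brute_force_read_set(panel, reference, read_len: int):
    """Every (focal, contig, origin, signature, allele, sequence) tuple,
    enumerated from whole-chromosome haplotype splices of every
    distinct panel row (plus the all-reference row)."""
    result = set()
    rows = {tuple(int(x) for x in r) for r in panel.haplotypes}
    rows.add(tuple([0] * len(panel.variants)))
    for focal_idx, focal in enumerate(panel.variants):
        seq = reference[focal.contig]
        for row in rows:
            hapseq, r2h, h2r = apply_haplotype(seq, panel.variants, row)
            for s in range(1, len(seq) - read_len + 2):
                if not (s <= focal.end and s + read_len - 1 >= focal.pos):
                    continue
                h = r2h[s]
                read = hapseq[h : h + read_len]
                if len(read) < read_len:
                    continue
                sig = []
                for v, a in zip(panel.variants, row):
                    if v.contig != focal.contig:
                        continue
                    fs = r2h[v.pos]
                    fe = fs + len(v.alt_seq if a else v.ref_seq) - 1
                    if (fs <= h + read_len - 1 and fe >= h) or v.vid == focal.vid:
                        sig.append("RA"[a])
                result.add(
                    (focal.vid, focal.contig, h2r[h], "".join(sig), "RA"[row[focal_idx]], read)
                )
    return result


# ---------------------------------------------------------------------------
# exact-test oracles
# ---------------------------------------------------------------------------

def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact P by exhaustive hypergeometric enumeration
    with exact integer arithmetic (R-style relative tolerance)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    pmf = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        pmf[x] = math.comb(r1, x) * math.comb(r2, c1 - x)
    obs = pmf[a]
    cutoff = obs + obs * 1e-7
    return sum(v for v in pmf.values() if v <= cutoff) / denom


def mannwhitney_u(x, y) -> float:
    """U statistic for x by direct pair counting with half-ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
    return u


def mannwhitney_p_normal(x, y) -> float:
    """Two-sided normal-approximation P with tie correction and
    continuity correction, from the brute-force U."""
    n1, n2 = len(x), len(y)
    u = mannwhitney_u(x, y)
    mu = n1 * n2 / 2.0
    allv = list(x) + list(y)
    n = n1 + n2
    ties = {}
    for v in allv:
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t ** 3 - t for t in ties.values())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return 1.0
    from scipy.stats import norm

    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    return float(2 * norm.sf(z))


def midranks(v) -> list[float]:
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = r
        i = j + 1
    return ranks


def spearman_midrank(x, y) -> float:
    """Spearman rho as the Pearson correlation of midranks, written out."""
    rx, ry = midranks(x), midranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    if vx == 0 or vy == 0:
        return math.nan
    return cov / math.sqrt(vx * vy)
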