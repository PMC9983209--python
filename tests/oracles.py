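"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is deliberately naive (pure-Python dynamic programming,
exhaustive scans, closed-form statistics) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def sw_align(a: str, b: str, match=1, mismatch=-2, gap=-2):
    """Plain Smith-Waterman, full matrices, python lists.

    Returns (identity, coverage_a, coverage_b) with identity =
    matches / alignment columns (gaps counted).
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]  # 0 stop, 1 diag, 2 up, 3 left
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cand = [(0, 0), (H[i - 1][j - 1] + s, 1), (H[i - 1][j] + gap, 2), (H[i][j - 1] + gap, 3)]
            # prefer diag, then up, then left on ties (order below)
            h = max(c for c, _ in cand)
            for c, p in ((H[i - 1][j - 1] + s, 1), (H[i - 1][j] + gap, 2), (H[i][j - 1] + gap, 3), (0, 0)):
                if c == h:
                    H[i][j], P[i][j] = h, p if h > 0 else 0
                    break
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return 0.0, 0.0, 0.0
    i, j, matches, cols = bi, bj, 0, 0
    while P[i][j] != 0:
        cols += 1
        if P[i][j] == 1:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif P[i][j] == 2:
            i -= 1
        else:
            j -= 1
    return matches / cols, (bi - i) / n, (bj - j) / m


def sw_identity_best_strand(a: str, b: str):
    fwd = sw_align(a, b)
    rev = sw_align(a, revcomp(b))
    return max(fwd, rev, key=lambda t: t[0])


def edlib_identity(a: str, b: str, mode: str = "NW") -> float:
    """Identity = matches / alignment columns from edlib's extended CIGAR."""
    import edlib
    import re

    res = edlib.align(a, b, mode=mode, task="path")
    ops = re.findall(r"(\d+)([=XIDM])", res["cigar"])
    cols = sum(int(n) for n, _ in ops)
    matches = sum(int(n) for n, op in ops if op == "=")
    return matches / cols


def exact_jaccard(seq_a: str, seq_b: str, k: int) -> float:
    """Exact Jaccard over canonical k-mer sets built with python strings."""

    def kmers(s: str) -> set[str]:
        out = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) <= {"A", "C", "G", "T"}:
                out.add(min(km, revcomp(km)))
        return out

    A, B = kmers(seq_a), kmers(seq_b)
    return len(A & B) / len(A | B) if A | B else 0.0


def n50_bruteforce(lengths) -> int:
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= total / 2:
            return l
    raise ValueError("empty")


STOPS = {"TAA", "TAG", "TGA"}
TABLE = {}  # codon -> aa, built lazily from Biopython below


def orf_scan(contig: str, min_aa: int = 100, require_start: bool = True):
    """Exhaustive six-frame ORF scan; returns set of (strand, start, end)
    forward-strand half-open coordinates."""
    out = set()
    L = len(contig)
    for strand, seq in ((1, contig), (-1, revcomp(contig))):
        for frame in range(3):
            codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
            seg_start = 0  # codon index where current stop-free segment starts
            i = 0
            while i <= len(codons):
                if i == len(codons) or codons[i] in STOPS:
                    has_stop = i < len(codons)
                    seg = codons[seg_start:i]
                    first = None
                    if require_start:
                        for ci, c in enumerate(seg):
                            if c == "ATG":
                                first = ci
                                break
                    else:
                        first = 0 if seg else None
                    if first is not None and len(seg) - first >= min_aa:
                        s_nt = frame + 3 * (seg_start + first)
                        e_nt = frame + 3 * i + (3 if has_stop else 0)
                        if strand == 1:
                            out.add((1, s_nt, e_nt))
                        else:
                            out.add((-1, L - e_nt, L - s_nt))
                    seg_start = i + 1
                i += 1
    return out


def window_trim(quals, window: int, threshold: float) -> int:
    """First cut position per the sliding-window rule (exhaustive scan);
    returns len(quals) when no window fails."""
    for i in range(0, len(quals) - window + 1):
        if sum(quals[i : i + window]) / window < threshold:
            return i
    return len(quals)


def welch_formula(a, b):
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    se2 = va / len(a) + vb / len(b)
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    return t, df


def ols_normal_equations(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(u * v for u, v in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
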