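"""Independent brute-force oracles used to verify the implementation.

These deliberately share no code with the package: a full Gotoh dynamic
program for local alignment scores, an exhaustive offset scan for read
placement, a window enumeration for the mismatch-cluster rule, an exact
hypergeometric enumeration for the two-sided Fisher test, and a literal
Benjamini-Hochberg step-up.
"""

from math import comb


def sw_local_score(a, b, match=1.0, mismatch=-2.0, gap_open=-5.0, gap_extend=-2.0):
    """Best local alignment score by full affine-gap DP (Gotoh).

    A gap of length L costs gap_open + (L-1)*gap_extend; N scores 0
    against anything.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == "N" or b[j - 1] == "N":
                s = 0.0
            elif a[i - 1] == b[j - 1]:
                s = match
            else:
                s = mismatch
            M[i][j] = s + max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def scan_placements(gene_seq, read_seq, max_mismatches=2):
    """Every ungapped placement with ≤ max_mismatches, both orientations."""
    hits = []
    L = len(read_seq)
    for reverse in (False, True):
        placed = rc(read_seq) if reverse else read_seq
        for start in range(len(gene_seq) - L + 1):
            offs = [
                i
                for i in range(L)
                if placed[i] != gene_seq[start + i]
                or placed[i] == "N"
                or gene_seq[start + i] == "N"
            ]
            if len(offs) <= max_mismatches:
                hits.append((start, reverse, tuple(offs)))
    return sorted(hits)


def cluster_retained(columns, min_run=4):
    """Retained A-G columns by exhaustive window enumeration.

    ``columns`` is a string over {E, M, X}: E an A-G mismatch column, M an
    exact match, X anything else (gap, other mismatch, N).  A column is
    retained iff some window bounded by E columns contains ≥ min_run E
    columns and nothing but E and M.
    """
    n = len(columns)
    retained = set()
    for i in range(n):
        if columns[i] != "E":
            continue
        for j in range(i, n):
            if columns[j] != "E":
                continue
            window = columns[i : j + 1]
            if "X" in window:
                break
            if window.count("E") >= min_run:
                retained.update(k for k in range(i, j + 1) if columns[k] == "E")
    return retained


def fisher_two_sided(a, b, c, d):
    """Exact two-sided Fisher p by enumerating tables with fixed margins.

    Sums the probabilities of every table whose hypergeometric likelihood
    does not exceed the observed table's (minimum-likelihood rule).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def bh_adjust(pvalues):
    """Literal Benjamini-Hochberg step-up in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj
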