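"""Independent brute-force oracles used to check the alignment-backed code.

These are deliberately naive pure-Python dynamic programs, written against
the same scoring convention as the package (match +1, mismatch -1, gap of
length L costs 4 + (L-1), 'N' never matches) but sharing no code with it.
"""

from __future__ import annotations

NEG = float("-inf")

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -4.0  # cost of a length-1 gap
GAP_EXTEND = -1.0


def _sub(a: str, b: str) -> float:
    return MATCH if (a == b and a != "N") else MISMATCH


def local_align_score(query: str, target: str) -> float:
    """Smith-Waterman with affine gaps; best local score (0 if none positive)."""
    n, m = len(query), len(target)
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]  # ends in a match/mismatch
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (query base)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (target base)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = diag + _sub(query[i - 1], target[j - 1])
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def global_align_score(a: str, b: str) -> float:
    """Needleman-Wunsch with affine gaps; end-to-end score."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(
                M[i - 1][j] + GAP_OPEN,
                X[i - 1][j] + GAP_EXTEND,
                Y[i - 1][j] + GAP_OPEN,
            )
            Y[i][j] = max(
                M[i][j - 1] + GAP_OPEN,
                Y[i][j - 1] + GAP_EXTEND,
                X[i][j - 1] + GAP_OPEN,
            )
            M[i][j] = (
                max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                + _sub(a[i - 1], b[j - 1])
            )
    return max(M[n][m], X[n][m], Y[n][m])


def longest_common_substring_scan(a: str, b: str) -> int:
    """Length of the longest exact common substring by exhaustive scan."""
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            piece = a[i:j]
            if "N" in piece:
                break
            if piece in b:
                best = j - i
            else:
                break
    return best


def best_d_call(cdr3: str, d_genes: dict[str, str], min_run: int) -> str | None:
    """Exhaustive-scan D assignment: longest run wins, ties to smallest name."""
    best_run, best_name = 0, None
    for name in sorted(d_genes):
        run = longest_common_substring_scan(cdr3, d_genes[name])
        if run > best_run:
            best_run, best_name = run, name
    if best_run < min_run:
        return None
    return best_name


def gapped_codon_start(gapped: str, codon: int) -> int | None:
    """Brute-force ungapped position of the first base of a gapped codon:
    walk the gapped string counting letters."""
    target_cols = range(3 * (codon - 1), 3 * codon)
    if len(gapped) < 3 * codon:
        return None
    if any(gapped[c] == "." for c in target_cols):
        return None
    count = 0
    for col, ch in enumerate(gapped):
        if col == 3 * (codon - 1):
            return count
        if ch != ".":
            count += 1
    return None
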