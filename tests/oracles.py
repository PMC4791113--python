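"""Independent reference implementations used only by the tests."""

from flds.classify import GAP, MATCH, MISMATCH


def oracle_identity(a: str, b: str) -> float:
    """Textbook Needleman-Wunsch with free end gaps, plain triple loop.

    Same scoring and deterministic tie-breaks as the production code but an
    entirely independent implementation (no vectorization, no shared code).
    """
    if (len(a), a) > (len(b), b):  # same canonical order as the library
        a, b = b, a
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + GAP, H[i][j - 1] + GAP)
    best, bi, bj = None, 0, 0
    for j in range(m + 1):
        if best is None or H[n][j] > best:
            best, bi, bj = H[n][j], n, j
    for i in range(n + 1):
        if H[i][m] > best:
            best, bi, bj = H[i][m], i, m
    i, j, matches, cols = bi, bj, 0, 0
    while i > 0 and j > 0:
        s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += s == MATCH
            i -= 1
            j -= 1
        elif H[i][j] == H[i - 1][j] + GAP:
            i -= 1
        else:
            j -= 1
        cols += 1
    return 100.0 * matches / cols if cols else 0.0
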