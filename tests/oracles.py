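"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: guide enumeration is a
regex scan, alignment scoring is a from-scratch Gotoh DP, and the read
classification rule is re-stated as a literal decision table.
"""

from __future__ import annotations

import re

import numpy as np

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def enumerate_guides_oracle(seq: str, variant_offset: int | None = None,
                            require_overlap: bool = False,
                            strands: str = "both") -> list[tuple]:
    """Regex/loop NGG scan on both strands.

    Returns tuples (protospacer, pam, strand, start, end) with 1-based
    inclusive top-strand protospacer spans, sorted by (start, strand).
    """
    out = []
    if strands in ("top", "both"):
        for m in re.finditer(r"(?=[ACGT]GG)", seq):
            i = m.start()
            if i >= 20:
                out.append((seq[i - 20:i], seq[i:i + 3], "+", i - 19, i))
    if strands in ("bottom", "both"):
        rc = revcomp(seq)
        n = len(seq)
        for m in re.finditer(r"(?=[ACGT]GG)", rc):
            i = m.start()  # 0-based on the reverse complement
            if i >= 20:
                # protospacer on rc is rc[i-20:i]; map to top-strand span
                start = n - i + 1
                end = n - (i - 20)
                out.append((rc[i - 20:i], rc[i:i + 3], "-", start, end))
    if require_overlap:
        if variant_offset is None:
            raise ValueError("need variant offset")
        out = [g for g in out if g[3] <= variant_offset <= g[4]]
    out.sort(key=lambda g: (g[3], g[2]))
    return out


def gotoh_fitting_score(ref: str, read: str, match: float = 2.0,
                        mismatch: float = 3.0, gap_open: float = 6.0,
                        gap_extend: float = 1.0) -> float:
    """Optimal fitting-alignment score by explicit Gotoh DP.

    The read must be consumed entirely; reference flanks outside the read are
    free.  A gap of length k costs gap_open + (k - 1) * gap_extend; gaps in
    the reference at the read's ends are penalized like internal ones.
    """
    n, m = len(ref), len(read)
    NEG = -1e18
    q = np.frombuffer(read.encode(), dtype=np.uint8)
    M = np.full(m + 1, NEG)
    X = np.full(m + 1, NEG)
    Y = np.full(m + 1, NEG)
    M[0] = 0.0
    X[0] = 0.0
    if m >= 1:
        Y[1:] = -(gap_open + np.arange(m) * gap_extend)
    best = max(M[m], Y[m])
    ks = np.arange(m + 1)
    for i in range(1, n + 1):
        r = ord(ref[i - 1])
        sub = np.where(q == r, match, -mismatch)
        M_new = np.full(m + 1, NEG)
        M_new[1:] = sub + np.maximum(np.maximum(M[:-1], X[:-1]), Y[:-1])
        M_new[0] = 0.0
        X_new = np.maximum(np.maximum(M - gap_open, Y - gap_open),
                           X - gap_extend)
        X_new[0] = 0.0
        c = np.maximum(M_new, X_new) - gap_open + ks * gap_extend
        run = np.maximum.accumulate(c)
        Y_new = np.full(m + 1, NEG)
        Y_new[1:] = run[:-1] - ks[1:] * gap_extend + gap_extend
        M, X, Y = M_new, X_new, Y_new
        best = max(best, M[m], Y[m])
    return float(best)


def classify_oracle(marker: str | None, net_indel_len: int,
                    has_indel: bool) -> str:
    """Literal restatement of the allele-specific classification rule."""
    if marker is None or marker == "other":
        return "discarded"
    if marker == "wt":
        return "wt"
    # mutant-marker read
    if not has_indel:
        return "mutant_unedited"
    L = net_indel_len
    if L != 0 and 1 <= abs(L) <= 8 and L % 3 != 0:
        return "mutant_edited"
    return "mutant_excluded"
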