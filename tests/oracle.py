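"""Brute-force reference for iterated non-intersecting local alignment.

Enumerates every colinear pairing of columns (each a strictly increasing
row subset matched to a strictly increasing column subset of equal size),
scores it as sum of cell scores minus gap * (skipped rows + skipped columns
between consecutive pairs), and extracts alignments best-first, forbidding
previously used cells — the declumping semantics of suboptimal local
alignment.  Exponential; only for matrices up to ~8x8.
"""

from __future__ import annotations

from itertools import combinations


def enumerate_pairings(m: int, n: int):
    for k in range(1, min(m, n) + 1):
        for rows in combinations(range(m), k):
            for cols in combinations(range(n), k):
                yield tuple(zip(rows, cols))


def score_pairing(seq, S, gap: float) -> float:
    sc = sum(S[i, j] for i, j in seq)
    for (i1, j1), (i2, j2) in zip(seq, seq[1:]):
        sc -= gap * ((i2 - i1 - 1) + (j2 - j1 - 1))
    return sc


def oracle_alignments(S, gap: float, min_score: float, max_alignments: int = 1000):
    """All non-intersecting local alignments with score strictly above
    ``min_score``, extracted greedily best-first; cell exclusion applies to
    positively scoring (homologous) pairs — mismatch pairs carry no signal
    and their placement between fixed homologous pairs is cost-equivalent.
    Returns a list of (score, homologous-pair tuple) sorted by (-score, start).
    """
    m, n = S.shape
    seqs = list(enumerate_pairings(m, n))
    scores = [score_pairing(seq, S, gap) for seq in seqs]
    pos = [tuple(c for c in seq if S[c] > 0) for seq in seqs]
    masked: set = set()
    out = []
    while len(out) < max_alignments:
        best = None
        for seq, sc, ps in zip(seqs, scores, pos):
            if any(c in masked for c in ps):
                continue
            key = (-sc, seq[0][0], seq[0][1])
            if best is None or key < best[0]:
                best = (key, seq, sc, ps)
        if best is None or best[2] <= min_score + 1e-9:
            break
        out.append((best[2], best[3]))
        masked.update(best[3])
    out.sort(key=lambda t: (-t[0],) + (t[1][0] if t[1] else (0, 0)))
    return out
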