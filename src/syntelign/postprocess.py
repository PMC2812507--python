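"""RSB reduction, assembly-boundary flagging, and interval enrichment.

Overlapping CSMs (alignments sharing at least one gene) form components; the
representative syntenic block (RSB) of a component is the member spanning the
largest total genomic region — the non-redundant unit for counting conserved
synteny.  A block touching the first or last gene of a contig is flagged,
since it may end prematurely because of an assembly boundary rather than a
rearrangement.

``region_enrichment_test`` is the generic randomized-interval statistic:
observed feature overlaps are compared against repeatedly re-placing the same
number of equally sized intervals uniformly on the contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GeneOrder, ValidationError


@dataclass(slots=True)
class RSB:
    """Representative syntenic block of one overlap component."""

    representative: object          # GeneAlignment (or compatible record)
    members: list
    span_total: int
    at_contig_end: bool = False


def compute_rsbs(csms: list) -> list[RSB]:
    """Group overlapping CSMs (shared genes) and pick per component the
    member with maximal total span (ties: higher score, then input order).

    Members only need ``gene_ids()``, ``span_total()`` and ``score``; the
    CSMs are expected in score-rank order.
    """
    parent = list(range(len(csms)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    owner: dict[str, int] = {}
    for i, al in enumerate(csms):
        for g in al.gene_ids():
            if g in owner:
                union(owner[g], i)
            else:
                owner[g] = i
    comps: dict[int, list[int]] = {}
    for i in range(len(csms)):
        comps.setdefault(find(i), []).append(i)
    rsbs = []
    for root in sorted(comps):
        idxs = comps[root]
        best = min(idxs, key=lambda i: (-csms[i].span_total(), -csms[i].score, i))
        rsbs.append(RSB(
            representative=csms[best],
            members=[csms[i] for i in idxs],
            span_total=csms[best].span_total(),
        ))
    return rsbs


def flag_contig_ends(rsbs: list[RSB], orders: list[GeneOrder]) -> list[RSB]:
    """Set ``at_contig_end`` iff any member gene is the first or last gene of
    its contig."""
    rank_of: dict[str, tuple[int, int]] = {}
    for go in orders:
        n = len(go.genes)
        for g in go.genes:
            rank_of[g.gene_id] = (g.rank, n)
    for rsb in rsbs:
        flag = False
        for al in rsb.members:
            for gid in al.gene_ids():
                if gid not in rank_of:
                    raise ValidationError(f"gene {gid!r} not found in gene orders")
                rank, n = rank_of[gid]
                if rank == 0 or rank == n - 1:
                    flag = True
        rsb.at_contig_end = flag
    return rsbs


def region_enrichment_test(
    features: list[tuple[str, int, int]],
    blocks: list[tuple[str, int, int]],
    contig_sizes: dict[str, int],
    n_samples: int = 1000,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Randomization test for enrichment of features inside blocks.

    Counts features overlapping any block, then repeatedly places
    ``len(blocks)`` random intervals of the same lengths uniformly on the
    contigs (placement probability proportional to placeable length) and
    recounts.  Returns (observed, expected, p) with the add-one estimator

        p = (1 + #{replicates >= observed}) / (n_samples + 1),

    so p is never 0 and p = 1 under saturation.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    for name, s, e in list(features) + list(blocks):
        if name not in contig_sizes:
            raise ValidationError(f"interval on unknown contig {name!r}")
        if s < 0 or e > contig_sizes[name] or s >= e:
            raise ValidationError(
                f"interval {name}:{s}-{e} exceeds contig bounds"
            )
    contigs = sorted(contig_sizes)
    cindex = {c: k for k, c in enumerate(contigs)}
    sizes = np.array([contig_sizes[c] for c in contigs], dtype=np.int64)
    fstart: dict[int, np.ndarray] = {}
    fend: dict[int, np.ndarray] = {}
    for k in range(len(contigs)):
        fs = [(s, e) for (c, s, e) in features if cindex[c] == k]
        fstart[k] = np.array([s for s, _ in fs], dtype=np.int64)
        fend[k] = np.array([e for _, e in fs], dtype=np.int64)

    def count_overlaps(placed):
        hits = {k: np.zeros(len(fstart[k]), dtype=bool) for k in fstart}
        for k, s, e in placed:
            hits[k] |= (fstart[k] < e) & (fend[k] > s)
        return int(sum(h.sum() for h in hits.values()))

    observed = count_overlaps(
        [(cindex[c], s, e) for (c, s, e) in blocks]
    )
    rng = np.random.default_rng(seed)
    n_feat = len(features)
    hits = np.zeros((n_samples, n_feat), dtype=bool)
    fcontig = np.array([cindex[c] for (c, _s, _e) in features], dtype=np.int64)
    fs_all = np.array([s for (_c, s, _e) in features], dtype=np.int64)
    fe_all = np.array([e for (_c, _s, e) in features], dtype=np.int64)
    for (_c, bs, be) in blocks:
        L = be - bs
        room = np.maximum(0, sizes - L + 1)
        total = room.sum()
        if total <= 0:
            raise ValidationError(f"no contig can host an interval of {L} bp")
        ks = rng.choice(len(contigs), size=n_samples, p=room / total)
        starts = rng.integers(0, room[ks])
        if n_feat == 0:
            continue
        for k in np.unique(ks):
            rows = ks == k
            cols = fcontig == k
            if not cols.any():
                continue
            s_sub = starts[rows][:, None]
            hits[np.ix_(rows, cols)] |= (
                (fs_all[None, cols] < s_sub + L) & (fe_all[None, cols] > s_sub)
            )
    counts = hits.sum(axis=1)
    expected = float(counts.mean())
    p = (1 + int((counts >= observed).sum())) / (n_samples + 1)
    return observed, expected, p
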