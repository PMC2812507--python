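"""Local profile-profile alignment over the gene alphabet.

Profiles are ordered sequences of columns; a leaf profile holds one genome
contig (one gene per column).  ``local_align_all`` runs Smith-Waterman with
linear gaps over the column-pair sum-of-pairs scores and extracts *all*
non-intersecting local alignments above the (phylogenetically scaled)
threshold, Waterman-Eggert style: best path, mask its positively scoring
(homologous) column pairs, recompute the affected rectangle, repeat.  Two
returned alignments never share a homologous column pair; mismatch columns
carry no signal of their own and are not declumped, which keeps extraction
independent of arbitrary tie-breaking between equal-cost mismatch
placements.  Alignments are returned by decreasing score with deterministic
tie-breaking.

Both relative orientations are handled by aligning against the reversed
(column order flipped, strands flipped) second profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import Gene, GuideTree, HomologyTable, ScoringParams
from .scoring import effective_params, score_matrix

GAP = None  # gap marker in alignment pair lists

_EPS = 1e-9


@dataclass(slots=True)
class Column:
    """One alignment column: species -> (gene, orientation flag)."""

    entries: dict[str, tuple[Gene, int]]
    profile_species: tuple[str, ...] = ()

    def gene_ids(self):
        return [ent[0].gene_id for ent in self.entries.values()]


class Profile:
    """Ordered columns over a fixed species set.

    ``origin`` is a hashable provenance tag (e.g. ``('leaf', species, contig)``
    or a merged-alignment label) used for deterministic ordering and caching.
    """

    __slots__ = ("species", "columns", "origin", "score", "_arrays")

    def __init__(self, species, columns, origin, score=0.0):
        self.species = tuple(species)
        self.columns = list(columns)
        for col in self.columns:
            col.profile_species = self.species
        self.origin = origin
        self.score = score
        self._arrays = {}

    def __len__(self):
        return len(self.columns)

    def cache_key(self):
        return (self.origin, len(self.columns))

    def species_arrays(self, sp: str, hom: HomologyTable):
        """Per-species (gene index, orientation flag) arrays over columns.

        Gap columns get index -1 and flag 0; genes unknown to the homology
        table also get index -1 (they can never match).
        """
        key = (sp, id(hom))
        cached = self._arrays.get(key)
        if cached is not None:
            return cached
        n = len(self.columns)
        idx = np.full(n, -1, dtype=np.int64)
        flags = np.zeros(n, dtype=np.int64)
        for k, col in enumerate(self.columns):
            ent = col.entries.get(sp)
            if ent is not None:
                g, f = ent
                idx[k] = hom.gene_index(g.gene_id)
                flags[k] = f
        self._arrays[key] = (idx, flags)
        return idx, flags

    def reverse(self) -> "Profile":
        """Reversed column order with all orientation flags flipped."""
        cols = [
            Column({sp: (g, -f) for sp, (g, f) in col.entries.items()})
            for col in reversed(self.columns)
        ]
        return Profile(self.species, cols, ("rev", self.origin), self.score)


def leaf_profile(order) -> Profile:
    """Trivial single-genome profile: one column per gene, flag = strand."""
    cols = [Column({order.species: (g, g.strand)}) for g in order.genes]
    return Profile((order.species,), cols, ("leaf", order.species, order.contig))


class GeneAlignment:
    """One local alignment between two profiles (a CSM when multi-species).

    ``pairs`` holds (indexA, indexB) with ``None`` for gaps; indices refer to
    ``profileA``/``profileB`` as aligned — for a reverse-orientation alignment
    ``profileB`` is the reversed profile object.  Non-gap indices strictly
    increase along both profiles.
    """

    __slots__ = ("profileA", "profileB", "pairs", "score", "orientation",
                 "column_scores", "_gene_ids", "_aligned_gene_ids", "_merged")

    def __init__(self, profileA, profileB, pairs, score, orientation,
                 column_scores=None):
        self.profileA = profileA
        self.profileB = profileB
        self.pairs = pairs
        self.score = score
        self.orientation = orientation
        self.column_scores = column_scores
        self._gene_ids = None
        self._aligned_gene_ids = None
        self._merged = None

    @property
    def start(self):
        i = next(p[0] for p in self.pairs if p[0] is not None)
        j = next(p[1] for p in self.pairs if p[1] is not None)
        return (i, j)

    @property
    def n_match_columns(self) -> int:
        return sum(1 for i, j in self.pairs if i is not None and j is not None)

    def species_set(self) -> set[str]:
        return set(self.profileA.species) | set(self.profileB.species)

    def _columns_of_pair(self, i, j):
        cols = []
        if i is not None:
            cols.append(self.profileA.columns[i])
        if j is not None:
            cols.append(self.profileB.columns[j])
        return cols

    def gene_ids(self) -> frozenset:
        """All genes appearing in any column of the alignment."""
        if self._gene_ids is None:
            ids = []
            for i, j in self.pairs:
                for col in self._columns_of_pair(i, j):
                    ids.extend(col.gene_ids())
            self._gene_ids = frozenset(ids)
        return self._gene_ids

    def aligned_gene_ids(self) -> frozenset:
        """Genes in columns where both profiles are present (the genes the
        alignment actually pairs; genes skipped by gap columns excluded)."""
        if self._aligned_gene_ids is None:
            ids = []
            for i, j in self.pairs:
                if i is not None and j is not None:
                    ids.extend(self.profileA.columns[i].gene_ids())
                    ids.extend(self.profileB.columns[j].gene_ids())
            self._aligned_gene_ids = frozenset(ids)
        return self._aligned_gene_ids

    def genes(self):
        for i, j in self.pairs:
            for col in self._columns_of_pair(i, j):
                for g, _f in col.entries.values():
                    yield g

    def spans(self) -> dict[tuple[str, str], tuple[int, int]]:
        """Per (species, contig): (min start, max end) over member genes."""
        spans: dict[tuple[str, str], tuple[int, int]] = {}
        for g in self.genes():
            key = (g.species, g.contig)
            cur = spans.get(key)
            if cur is None:
                spans[key] = (g.start, g.end)
            else:
                spans[key] = (min(cur[0], g.start), max(cur[1], g.end))
        return spans

    def span_total(self) -> int:
        return sum(hi - lo for lo, hi in self.spans().values())

    def merged(self) -> Profile:
        if self._merged is None:
            self._merged = merge_alignment(self)
        return self._merged

    def merged_columns(self):
        return self.merged().columns

    def sort_key(self):
        i, j = self.start
        return (-self.score, self.profileA.origin, self.profileB.origin, i, j)


def merge_alignment(al: GeneAlignment) -> Profile:
    """Union profile of an alignment: one column per pair; a gap on one side
    leaves that side's species gapped."""
    spA = set(al.profileA.species)
    spB = set(al.profileB.species)
    if spA & spB:
        raise ValueError("cannot merge profiles with overlapping species sets")
    cols = []
    for i, j in al.pairs:
        entries: dict[str, tuple[Gene, int]] = {}
        if i is not None:
            entries.update(al.profileA.columns[i].entries)
        if j is not None:
            entries.update(al.profileB.columns[j].entries)
        cols.append(Column(entries))
    return Profile(
        al.profileA.species + al.profileB.species,
        cols,
        ("merged", al.profileA.origin, al.profileB.origin, al.start),
        al.score,
    )


@njit(cache=False)
def _fill_rect(H, S, diagok, gap, i0, j0):  # pragma: no cover - numba kernel
    m, n = S.shape
    for i in range(i0, m):
        for j in range(j0, n):
            v = 0.0
            if diagok[i, j]:
                t = H[i, j] + S[i, j]
                if t > v:
                    v = t
            t = H[i, j + 1] - gap
            if t > v:
                v = t
            t = H[i + 1, j] - gap
            if t > v:
                v = t
            H[i + 1, j + 1] = v


def _traceback(H, S, diagok, gap, i, j):
    """Follow the best path ending at cell (i, j); returns (pairs, cells,
    column score contributions)."""
    pairs = []
    scores = []
    cells = []
    while i >= 0 and j >= 0 and H[i + 1, j + 1] > _EPS:
        v = H[i + 1, j + 1]
        if diagok[i, j] and abs(v - (H[i, j] + S[i, j])) <= _EPS:
            pairs.append((i, j))
            scores.append(S[i, j])
            cells.append((i, j))
            i -= 1
            j -= 1
        elif abs(v - (H[i, j + 1] - gap)) <= _EPS:
            pairs.append((i, GAP))
            scores.append(-gap)
            i -= 1
        elif abs(v - (H[i + 1, j] - gap)) <= _EPS:
            pairs.append((GAP, j))
            scores.append(-gap)
            j -= 1
        else:  # numerical inconsistency; should not happen
            raise AssertionError("traceback failed to reproduce DP value")
    pairs.reverse()
    scores.reverse()
    return pairs, cells, scores


def local_align_all(
    A: Profile,
    B: Profile,
    hom: HomologyTable,
    tree: GuideTree,
    params: ScoringParams,
    orientation: str = "forward",
    cache: dict | None = None,
) -> list[GeneAlignment]:
    """All non-intersecting local alignments of A vs B above threshold.

    Iterated Waterman-Eggert extraction: the best path is reported, its
    aligned column pairs are forbidden, and the DP is recomputed on the
    affected down-right rectangle; extraction stops when the best remaining
    score is not strictly above the scaled threshold or ``max_alignments`` is
    reached.  Results are sorted by decreasing score, ties by start indices.
    """
    if len(A) == 0 or len(B) == 0:
        return []
    if set(A.species) & set(B.species):
        raise ValueError("profiles must have disjoint species sets")
    eff = effective_params(params, set(A.species), set(B.species), tree)
    S = score_matrix(A, B, hom, tree, params, cache=cache)
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    diagok = np.ones((m, n), dtype=np.bool_)
    _fill_rect(H, S, diagok, eff.gap_eff, 0, 0)
    out: list[GeneAlignment] = []
    while len(out) < params.max_alignments:
        flat = int(np.argmax(H))
        i, j = divmod(flat, n + 1)
        best = H[i, j]
        if best <= eff.min_score_eff + _EPS:
            break
        pairs, cells, col_scores = _traceback(H, S, diagok, eff.gap_eff, i - 1, j - 1)
        cells = [(ci, cj) for ci, cj in cells if S[ci, cj] > 0]
        if not cells:  # a path above a non-negative threshold has a positive cell
            raise AssertionError("extracted path has no homologous column pair")
        for ci, cj in cells:
            diagok[ci, cj] = False
        out.append(
            GeneAlignment(A, B, pairs, float(best), orientation, col_scores)
        )
        i0 = min(c[0] for c in cells)
        j0 = min(c[1] for c in cells)
        _fill_rect(H, S, diagok, eff.gap_eff, i0, j0)
    out.sort(key=lambda al: (-al.score,) + al.start)
    return out


def align_both_orientations(
    A: Profile,
    B: Profile,
    hom: HomologyTable,
    tree: GuideTree,
    params: ScoringParams,
    cache: dict | None = None,
) -> list[GeneAlignment]:
    """Pool of local alignments of A vs B and A vs reversed(B).

    Overlap resolution between the two orientations is deferred to the filter
    stage.
    """
    fwd = local_align_all(A, B, hom, tree, params, "forward", cache)
    rev = local_align_all(A, B.reverse(), hom, tree, params, "reverse", cache)
    return fwd + rev
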