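"""Genome rearrangement simulator, truth blocks, and the benchmark evaluator.

A small ancestral genome (default 1040 genes on 2 chromosomes, one gene
family per gene) is copied twice and each copy is evolved independently by
inversions, translocations, duplications and deletions — a single speciation
event.  No gene is involved in two rearrangement events.  Rearrangement sites
are additionally kept mutually non-adjacent (no surviving gene may end up
with both of its ancestral adjacencies broken, counting contig ends), so
every perfect colinear block spans at least two genes; event sizes start at
two genes for the same reason (a one-gene inversion or copy would create an
unrecoverable one-gene block at the benchmark's minimum alignment length).

Truth: perfect colinear blocks are maximal chains of same-family gene pairs
(one gene per descendant) that sit at consecutive positions in both genomes
with a consistent relative orientation; duplicated copies chain against the
other genome's originals and form paralogous blocks of their own.  Blocks are
extracted from the recorded gene identities and re-verified by an independent
colinearity/maximality/coverage check.

Homology emission: self bitscore 1000 for every gene, 500 for every within-
family pair (orthologs and paralogs).

Evaluation follows the benchmark protocol: sensitivity is the fraction of
blocks whose genes (both genomes) all occur in a single alignment;
specificity is the fraction of genes in aligned (non-gap) columns of the
reported alignments that lie in some block.  Neither measure checks
colinearity of the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Gene, GeneOrder, GuideTree, HomologyTable
from .progressive import progressive_align

#: parameter grid of the published benchmark (both gap and mismatch)
BENCHMARK_GRID = (0.1, 0.5, 1.0, 2.0, 3.0, 5.0, 20.0)

KINDS = ("inversion", "translocation", "duplication", "deletion")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True, slots=True)
class SimEvent:
    kind: str
    source: tuple[str, int, int]          # (contig, start rank, length in genes)
    target: tuple[str, int] | None = None  # (contig, insertion rank)


@dataclass(slots=True)
class TrueBlock:
    """One perfect colinear block: chained (gene in genome 1, gene in genome 2)
    pairs, consecutive in both genomes with consistent orientation."""

    pairs: list[tuple[str, str]]

    @property
    def gene_ids(self) -> frozenset:
        return frozenset(g for pair in self.pairs for g in pair)

    def __len__(self):
        return len(self.pairs)


@dataclass(slots=True)
class SimHistory:
    ancestor: list[GeneOrder]
    species: tuple[str, str]
    events: tuple[list[SimEvent], list[SimEvent]]
    descendants: tuple[list[GeneOrder], list[GeneOrder]]
    family_of: dict[str, int]


# --------------------------------------------------------------------------
# internal genome representation during evolution

class _SGene:
    __slots__ = ("anc", "family", "iid", "strand")

    def __init__(self, anc, family, iid, strand):
        self.anc = anc          # global ancestral index, -1 for duplication copies
        self.family = family
        self.iid = iid
        self.strand = strand


class _SimState:
    """Bookkeeping shared across both branches.

    ``touched`` holds ancestral indices / copy ids already used by an event;
    ``broken`` holds ancestral adjacencies (identified by their left gene's
    global index) severed on either branch; ``deleted`` holds ancestral genes
    removed on either branch.
    """

    def __init__(self, contig_lo, contig_hi):
        self.touched: set = set()
        self.broken: set[int] = set()
        self.deleted: set[int] = set()
        self.copy_serial = 0
        self._lo = contig_lo  # anc index -> first index of its ancestral contig
        self._hi = contig_hi  # anc index -> one-past-last index

    def untouched(self, g: _SGene) -> bool:
        key = g.anc if g.anc >= 0 else g.iid
        return key not in self.touched

    def mark(self, g: _SGene) -> None:
        self.touched.add(g.anc if g.anc >= 0 else g.iid)

    def adjacency(self, left: _SGene | None, right: _SGene | None) -> int | None:
        """Ancestral adjacency id severed by separating ``left``/``right``,
        or None if the current adjacency is not an intact ancestral one."""
        if left is None or right is None:
            return None
        if left.anc < 0 or right.anc < 0:
            return None
        if right.anc != left.anc + 1 or self._hi[left.anc] != self._hi[right.anc]:
            return None
        if left.anc in self.broken:
            return None
        return left.anc

    def islanded(self, e: int, broken: set[int]) -> bool:
        """Would ancestral gene ``e`` end up with both adjacencies broken
        (contig ends count as broken)?"""
        left_ok = e - 1 >= self._lo[e] and (e - 1) not in broken
        right_ok = e + 1 < self._hi[e] and e not in broken
        return not left_ok and not right_ok


def _ancestor_layout(n_genes: int, n_contigs: int, rng) -> tuple[list[int], np.ndarray]:
    if n_contigs < 1 or n_genes < n_contigs:
        raise ValueError("need n_genes >= n_contigs >= 1")
    base, extra = divmod(n_genes, n_contigs)
    sizes = [base + (1 if c < extra else 0) for c in range(n_contigs)]
    strands = np.where(rng.integers(0, 2, size=n_genes) == 1, 1, -1)
    return sizes, strands


def _coords(rank: int) -> tuple[int, int]:
    # synthetic coordinates: 500 bp genes at 1000 bp spacing
    return 1000 * rank, 1000 * rank + 500


def generate_ancestor(n_genes: int, n_contigs: int, seed) -> list[GeneOrder]:
    """Ancestral genome: genes spread as evenly as possible over contigs, one
    family per gene, random strands; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    sizes, strands = _ancestor_layout(n_genes, n_contigs, rng)
    orders = []
    idx = 0
    for c, size in enumerate(sizes):
        genes = []
        for r in range(size):
            start, end = _coords(r)
            genes.append(Gene(
                gene_id=f"anc.g{idx:04d}", species="anc", contig=f"chr{c + 1}",
                start=start, end=end, strand=int(strands[idx]), rank=r,
            ))
            idx += 1
        orders.append(GeneOrder(species="anc", contig=f"chr{c + 1}", genes=genes))
    return orders


def _branch_from_ancestor(ancestor: list[GeneOrder], species: str):
    contigs, offset = [], 0
    for go in ancestor:
        contigs.append([
            _SGene(offset + g.rank, offset + g.rank,
                   f"{species}.g{offset + g.rank:04d}", g.strand)
            for g in go.genes
        ])
        offset += len(go.genes)
    return [go.contig for go in ancestor], contigs


def _contig_bounds(ancestor: list[GeneOrder]):
    n = sum(len(go) for go in ancestor)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    off = 0
    for go in ancestor:
        lo[off:off + len(go)] = off
        hi[off:off + len(go)] = off + len(go)
        off += len(go)
    return lo, hi


def _propose_and_apply(contig_names, contigs, kind, size, rng, state):
    """Try to place and apply one event; returns a SimEvent or None on reject."""
    ci = int(rng.integers(len(contigs)))
    contig = contigs[ci]
    if len(contig) < size or (kind == "deletion" and len(contig) - size < 1):
        return None
    s = int(rng.integers(0, len(contig) - size + 1))
    run = contig[s:s + size]
    if not all(state.untouched(g) for g in run):
        return None
    if kind != "deletion":
        # the run must be ancestrally intact: original genes, consecutive,
        # with no internal adjacency already broken by the other branch —
        # otherwise its image in the other genome is fragmented and the
        # rearranged/copied run would split into sub-blocks (possibly of a
        # single gene, which no minimum-length-2 alignment can recover)
        for g1, g2 in zip(run, run[1:]):
            if (g1.anc < 0 or g2.anc < 0 or g2.anc != g1.anc + 1
                    or state._hi[g1.anc] != state._hi[g2.anc]
                    or g1.anc in state.broken):
                return None

    newly: list[int] = []

    def sever(left, right):
        a = state.adjacency(left, right)
        if a is not None and a not in newly:
            newly.append(a)

    if kind in ("inversion", "translocation", "deletion"):
        sever(contig[s - 1] if s > 0 else None, run[0])
        sever(run[-1], contig[s + size] if s + size < len(contig) else None)

    target = None
    tc = p = None
    if kind in ("translocation", "duplication"):
        lengths = [len(c) for c in contigs]
        if kind == "translocation":
            lengths[ci] -= size
        tc = int(rng.integers(len(contigs)))
        p = int(rng.integers(0, lengths[tc] + 1))
        if kind == "translocation" and tc == ci and p == s:
            return None  # would restore the original location
        dest = contigs[tc] if kind == "duplication" else (
            contigs[tc] if tc != ci else contig[:s] + contig[s + size:]
        )
        left = dest[p - 1] if p > 0 else None
        right = dest[p] if p < len(dest) else None
        for flank in (left, right):
            if flank is not None and not state.untouched(flank):
                return None  # keep insertions away from rearranged material
        sever(left, right)
        target = (contig_names[tc], p)

    deleting = {g.anc for g in run if g.anc >= 0} if kind == "deletion" else set()
    cand = state.broken | set(newly)
    for a in newly:
        for e in (a, a + 1):
            if e in state.deleted or e in deleting:
                continue
            if state.islanded(e, cand):
                return None  # would create an unrecoverable one-gene block

    # ---- apply ----
    for g in run:
        state.mark(g)
    state.broken |= set(newly)
    if kind == "inversion":
        inv = [_SGene(g.anc, g.family, g.iid, -g.strand) for g in reversed(run)]
        contig[s:s + size] = inv
    elif kind == "deletion":
        state.deleted |= deleting
        del contig[s:s + size]
    elif kind == "translocation":
        del contig[s:s + size]
        contigs[tc].insert(p, None)  # placeholder to splice
        contigs[tc][p:p + 1] = run
    elif kind == "duplication":
        species = run[0].iid.split(".")[0]
        copies = []
        for g in run:
            state.copy_serial += 1
            cp = _SGene(-1, g.family, f"{g.iid}.c{state.copy_serial}", g.strand)
            state.mark(cp)
            copies.append(cp)
        contigs[tc][p:p] = copies
    return SimEvent(kind, (contig_names[ci], s, size), target)


def _evolve_branch(contig_names, contigs, n_events, size_range, kind_weights,
                   rng, state) -> list[SimEvent]:
    if kind_weights is None:
        weights = np.full(len(KINDS), 1.0 / len(KINDS))
    else:
        weights = np.asarray([kind_weights.get(k, 0.0) for k in KINDS], dtype=float)
        weights = weights / weights.sum()
    events: list[SimEvent] = []
    rejections = 0
    while len(events) < n_events:
        if rejections >= 1000:
            raise SimulationError(
                f"could not place event {len(events) + 1}/{n_events} after 1000 "
                f"consecutive rejections (genome too small or too constrained)"
            )
        kind = KINDS[int(rng.choice(len(KINDS), p=weights))]
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        ev = _propose_and_apply(contig_names, contigs, kind, size, rng, state)
        if ev is None:
            rejections += 1
        else:
            rejections = 0
            events.append(ev)
    return events


def _to_gene_orders(species, contig_names, contigs) -> list[GeneOrder]:
    orders = []
    for name, contig in zip(contig_names, contigs):
        genes = []
        for r, sg in enumerate(contig):
            start, end = _coords(r)
            genes.append(Gene(
                gene_id=sg.iid, species=species, contig=name,
                start=start, end=end, strand=sg.strand, rank=r,
            ))
        orders.append(GeneOrder(species=species, contig=name, genes=genes))
    return orders


def evolve(genome: list[GeneOrder], n_events: int, size_range=(2, 10),
           kind_weights=None, seed=0, state: _SimState | None = None,
           rng=None) -> tuple[list[GeneOrder], list[SimEvent]]:
    """Apply ``n_events`` random rearrangements to one genome copy.

    The input genome is treated as the ancestral reference (each gene one
    family).  Returns the rearranged genome (same gene ids; duplication
    copies suffixed ``.c<k>``) and the event list.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = _contig_bounds(genome)
    if state is None:
        state = _SimState(lo, hi)
    contig_names = [go.contig for go in genome]
    contigs, offset = [], 0
    for go in genome:
        contigs.append([
            _SGene(offset + g.rank, offset + g.rank, g.gene_id, g.strand)
            for g in go.genes
        ])
        offset += len(go.genes)
    events = _evolve_branch(contig_names, contigs, n_events, size_range,
                            kind_weights, rng, state)
    species = genome[0].species if genome else "genome"
    return _to_gene_orders(species, contig_names, contigs), events


def simulate_pair(n_genes=1040, n_contigs=2, n_events=25, size_range=(2, 10),
                  kind_weights=None, seed=0, species=("S1", "S2")) -> SimHistory:
    """One speciation: generate an ancestor and evolve two descendants.

    The no-double-event and breakpoint-separation constraints are enforced
    jointly across both branches.
    """
    rng = np.random.default_rng(seed)
    ancestor = generate_ancestor(n_genes, n_contigs, rng)
    lo, hi = _contig_bounds(ancestor)
    state = _SimState(lo, hi)
    descendants, all_events = [], []
    family_of: dict[str, int] = {}
    for sp in species:
        contig_names, contigs = _branch_from_ancestor(ancestor, sp)
        events = _evolve_branch(contig_names, contigs, n_events, size_range,
                                kind_weights, rng, state)
        orders = _to_gene_orders(sp, contig_names, contigs)
        for contig in contigs:
            for sg in contig:
                family_of[sg.iid] = sg.family
        descendants.append(orders)
        all_events.append(events)
    return SimHistory(
        ancestor=ancestor,
        species=tuple(species),
        events=(all_events[0], all_events[1]),
        descendants=(descendants[0], descendants[1]),
        family_of=family_of,
    )


# --------------------------------------------------------------------------
# truth blocks

def _genome_tables(orders: list[GeneOrder]):
    """Position/strand lookup and per-contig id sequences for one genome."""
    pos: dict[str, tuple[str, int, int]] = {}
    seq: dict[str, list[str]] = {}
    for go in orders:
        ids = [g.gene_id for g in go.genes]
        seq[go.contig] = ids
        for g in go.genes:
            pos[g.gene_id] = (go.contig, g.rank, g.strand)
    return pos, seq


def extract_true_blocks(history: SimHistory) -> list[TrueBlock]:
    """All maximal perfect colinear blocks of the descendant pair.

    A pair (x, y), x in genome 1 and y in genome 2 of the same family, chains
    to (x', y') when x' directly follows x, y' is the gene at y's position
    + rel (rel = strand(x)*strand(y)) on y's contig, the two form a
    same-family pair, and their orientation product equals rel.  Blocks are
    the maximal chains; every same-family cross pair belongs to exactly one.
    """
    d1, d2 = history.descendants
    fam = history.family_of
    pos1, seq1 = _genome_tables(d1)
    pos2, seq2 = _genome_tables(d2)
    by_fam_2: dict[int, list[str]] = {}
    for y in pos2:
        by_fam_2.setdefault(fam[y], []).append(y)
    pairs = [
        (x, y)
        for x in sorted(pos1)
        for y in sorted(by_fam_2.get(fam[x], ()))
    ]

    def successor(x, y):
        c1, r1, s1 = pos1[x]
        c2, r2, s2 = pos2[y]
        rel = s1 * s2
        row1 = seq1[c1]
        if r1 + 1 >= len(row1):
            return None
        nx = row1[r1 + 1]
        r2n = r2 + rel
        row2 = seq2[c2]
        if not (0 <= r2n < len(row2)):
            return None
        ny = row2[r2n]
        if fam[nx] != fam[ny]:
            return None
        if pos1[nx][2] * pos2[ny][2] != rel:
            return None
        return (nx, ny)

    succ = {p: successor(*p) for p in pairs}
    has_pred = {q for q in succ.values() if q is not None}
    blocks = []
    visited = set()
    for p in pairs:
        if p in has_pred or p in visited:
            continue
        chain = []
        q = p
        while q is not None and q not in visited:
            visited.add(q)
            chain.append(q)
            q = succ[q]
        blocks.append(TrueBlock(chain))
    leftover = [p for p in pairs if p not in visited]
    if leftover:  # cycles are impossible; convergent chains indicate a bug
        raise SimulationError(f"unchained pairs remain: {leftover[:3]}...")
    return blocks


def verify_true_blocks(history: SimHistory, blocks: list[TrueBlock]) -> None:
    """Independent brute-force check of a block decomposition.

    Verifies per-block colinearity (consecutive positions in both genomes,
    constant direction, consistent orientation, matching families),
    maximality at both ends, and that the blocks exactly cover all
    same-family cross pairs.  Raises AssertionError on any violation.
    """
    d1, d2 = history.descendants
    fam = history.family_of
    pos1, seq1 = _genome_tables(d1)
    pos2, seq2 = _genome_tables(d2)

    def pair_ok(x, y):
        return fam[x] == fam[y]

    def chainable(a, b):
        (x, y), (xn, yn) = a, b
        c1, r1, s1 = pos1[x]
        c2, r2, s2 = pos2[y]
        c1n, r1n, s1n = pos1[xn]
        c2n, r2n, s2n = pos2[yn]
        rel = s1 * s2
        return (
            c1n == c1 and r1n == r1 + 1
            and c2n == c2 and r2n == r2 + rel
            and s1n * s2n == rel
        )

    seen = set()
    for blk in blocks:
        assert len(blk.pairs) >= 1, "empty block"
        for x, y in blk.pairs:
            assert pair_ok(x, y), f"pair ({x}, {y}) is not a family pair"
            assert (x, y) not in seen, f"pair ({x}, {y}) in two blocks"
            seen.add((x, y))
        for a, b in zip(blk.pairs, blk.pairs[1:]):
            assert chainable(a, b), f"pairs {a} -> {b} are not colinear"
        # maximality: no extension on either side
        x0, y0 = blk.pairs[0]
        for cand in _extension_candidates(x0, y0, pos1, seq1, pos2, seq2, fam,
                                          forward=False):
            assert not chainable(cand, (x0, y0)), f"block extendable left by {cand}"
        xe, ye = blk.pairs[-1]
        for cand in _extension_candidates(xe, ye, pos1, seq1, pos2, seq2, fam,
                                          forward=True):
            assert not chainable((xe, ye), cand), f"block extendable right by {cand}"
    by_fam_2: dict[int, list[str]] = {}
    for y in pos2:
        by_fam_2.setdefault(fam[y], []).append(y)
    all_pairs = {
        (x, y) for x in pos1 for y in by_fam_2.get(fam[x], ())
    }
    assert seen == all_pairs, "blocks do not cover the family pairs exactly"


def _extension_candidates(x, y, pos1, seq1, pos2, seq2, fam, forward):
    c1, r1, _ = pos1[x]
    c2, r2, _ = pos2[y]
    step = 1 if forward else -1
    row1, row2 = seq1[c1], seq2[c2]
    if not (0 <= r1 + step < len(row1)):
        return
    xn = row1[r1 + step]
    for d in (-1, 1):
        if 0 <= r2 + d < len(row2):
            yn = row2[r2 + d]
            if fam.get(xn) == fam.get(yn):
                yield (xn, yn)


def emit_homology(history: SimHistory) -> HomologyTable:
    """Self bitscore 1000 for every descendant gene; 500 for every
    within-family pair (orthologs and paralogs)."""
    table = HomologyTable()
    by_fam: dict[int, list[str]] = {}
    for orders in history.descendants:
        for go in orders:
            for g in go.genes:
                table.add(g.gene_id, g.gene_id, 1000.0)
                by_fam.setdefault(history.family_of[g.gene_id], []).append(g.gene_id)
    for members in by_fam.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                table.add(a, b, 500.0)
    return table


# --------------------------------------------------------------------------
# evaluation and benchmark

def evaluate(alignments, blocks: list[TrueBlock]) -> tuple[float, float]:
    """(sensitivity, specificity) of predicted alignments against truth blocks.

    A block counts as recovered iff all its genes (both genomes) occur in a
    single alignment.  Specificity is the fraction of genes in aligned
    (non-gap) columns that lie in some block.  With no alignments the result
    is (0.0, 1.0); colinearity of the prediction is not checked.
    """
    aligned_sets = [al.aligned_gene_ids() for al in alignments]
    if blocks:
        recovered = sum(
            1 for blk in blocks
            if any(blk.gene_ids <= s for s in aligned_sets)
        )
        sensitivity = recovered / len(blocks)
    else:
        sensitivity = 1.0
    union: set = set()
    for s in aligned_sets:
        union |= s
    if not union:
        return (0.0 if blocks else 1.0, 1.0)
    block_genes: set = set()
    for blk in blocks:
        block_genes |= blk.gene_ids
    specificity = len(union & block_genes) / len(union)
    return sensitivity, specificity


def pair_tree(species=("S1", "S2")) -> GuideTree:
    """Cherry guide tree at zero distance for pairwise benchmark runs."""
    return GuideTree.from_newick(f"({species[0]}:0.0,{species[1]}:0.0);")


def run_pair(history: SimHistory, params, tree=None, cache=None):
    """Run the full alignment pipeline on one simulated pair; returns the
    root CSM list."""
    if tree is None:
        tree = pair_tree(history.species)
    genomes = [go for orders in history.descendants for go in orders]
    hom = emit_homology(history)
    results = progressive_align(genomes, hom, tree, params, cache=cache)
    return results[tree.root_label].csms


def run_benchmark(
    n_replicates=20,
    gap_values=BENCHMARK_GRID,
    mismatch_values=BENCHMARK_GRID,
    seed=0,
    n_genes=1040,
    n_contigs=2,
    n_events=25,
    size_range=(2, 10),
    min_score=1.0,
    min_length=2,
    max_alignments=1000,
    gene_coverage=4,
    progress=False,
) -> pd.DataFrame:
    """Sensitivity/specificity over replicate genome pairs and a
    gap x mismatch parameter grid.

    Returns one row per (replicate, gap, mismatch) with the evaluation
    scores; deterministic given the seed.
    """
    from .model import ScoringParams

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    rows = []
    for r, rep_seed in enumerate(rep_seeds):
        history = simulate_pair(
            n_genes=n_genes, n_contigs=n_contigs, n_events=n_events,
            size_range=size_range, seed=int(rep_seed),
        )
        blocks = extract_true_blocks(history)
        tree = pair_tree(history.species)
        hom = emit_homology(history)
        genomes = [go for orders in history.descendants for go in orders]
        cache: dict = {}
        for gap in gap_values:
            for mm in mismatch_values:
                params = ScoringParams(
                    mismatch=mm, gap=gap, min_score=min_score,
                    max_alignments=max_alignments, gene_coverage=gene_coverage,
                    min_length=min_length,
                )
                results = progressive_align(genomes, hom, tree, params, cache=cache)
                csms = results[tree.root_label].csms
                sens, spec = evaluate(csms, blocks)
                rows.append({
                    "replicate": r, "gap": gap, "mismatch": mm,
                    "sensitivity": sens, "specificity": spec,
                    "n_alignments": len(csms), "n_blocks": len(blocks),
                })
        if progress:
            print(f"replicate {r + 1}/{n_replicates} done", flush=True)
    return pd.DataFrame(rows)


def benchmark_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-gap medians over all mismatch values and replicates (the box
    semantics of the published benchmark figure)."""
    return (
        df.groupby("gap")[["sensitivity", "specificity"]]
        .median()
        .rename(columns={"sensitivity": "median_sensitivity",
                         "specificity": "median_specificity"})
        .reset_index()
    )
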