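"""Shared builders for tiny gene orders, homology tables and trees."""

from __future__ import annotations

import numpy as np
import pytest

from syntelign.model import GeneOrder, GuideTree, HomologyTable, build_gene_order
from syntelign.pairwise import leaf_profile


def make_order(species: str, contig: str, genes) -> GeneOrder:
    """genes: list of (gene_id, strand); synthetic 500 bp genes, 1 kb apart."""
    recs = [
        (gid, 1000 * i, 1000 * i + 500, strand)
        for i, (gid, strand) in enumerate(genes)
    ]
    return build_gene_order(species, contig, recs)


def make_hom(pairs, selves=None, self_score=1000.0) -> HomologyTable:
    """pairs: (a, b, bitscore); selves default to every gene in pairs."""
    t = HomologyTable()
    seen = set()
    for a, b, s in pairs:
        t.add(a, b, s)
        seen.update((a, b))
    for g in (selves if selves is not None else sorted(seen)):
        t.add(g, g, self_score)
    return t


def zero_tree(*species) -> GuideTree:
    """Caterpillar tree with all branch lengths 0 (phylo factor 1)."""
    nw = species[0] + ":0"
    for sp in species[1:]:
        nw = f"({nw},{sp}:0):0"
    return GuideTree.from_newick(nw + ";")


@pytest.fixture
def cherry_tree():
    return GuideTree.from_newick("(A:0.0,B:0.0);")


def random_instance(rng, max_len=8):
    """Random pair of leaf profiles + homology with continuous bitscores.

    Returns (profileA, profileB, hom, S) where S is the score matrix computed
    directly from the definition (match_scale 2, clamped normalized bitscore,
    distance 0) for an independently supplied mismatch penalty of 1 unit —
    callers rescale the mismatch part themselves.
    """
    m = int(rng.integers(2, max_len + 1))
    n = int(rng.integers(2, max_len + 1))
    sa = [int(s) for s in rng.choice([-1, 1], size=m)]
    sb = [int(s) for s in rng.choice([-1, 1], size=n)]
    A = make_order("A", "c1", [(f"a{i}", sa[i]) for i in range(m)])
    B = make_order("B", "c1", [(f"b{j}", sb[j]) for j in range(n)])
    hom = HomologyTable()
    bs = np.zeros((m, n))
    for i in range(m):
        hom.add(f"a{i}", f"a{i}", 1000.0)
    for j in range(n):
        hom.add(f"b{j}", f"b{j}", 1000.0)
    for i in range(m):
        for j in range(n):
            if rng.random() < 0.35:
                bs[i, j] = float(rng.uniform(200, 990))
                hom.add(f"a{i}", f"b{j}", bs[i, j])
    match = np.where(bs > 0, 2.0 * np.minimum(1.0, 2.0 * bs / 2000.0), 0.0)
    consistent = np.equal.outer(sa, sb)
    return leaf_profile(A), leaf_profile(B), hom, match, consistent
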