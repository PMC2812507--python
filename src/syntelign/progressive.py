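"""Progressive alignment along the guide tree with the filter cascade.

Leaves hold one trivial profile per contig.  At every internal node, every
profile of the left child is aligned against every profile of the right child
in both orientations; the pooled alignments are filtered (greedy unique /
gene-coverage / alignment-count / minimum-length filters) and the survivors
are merged into the node's profiles.  Only retained alignment regions
propagate upward — all other sequence regions of the children are discarded,
so a region must be conserved at every intermediate node to reach the root.

Each filtered alignment is a CSM: a conserved syntenic region over the
species under that node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import GeneOrder, GuideTree, HomologyTable, ScoringParams
from .pairwise import GeneAlignment, Profile, align_both_orientations, leaf_profile

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class NodeResult:
    """Profiles and retained alignments (CSMs) at one guide-tree node."""

    node: str
    profiles: list[Profile]
    csms: list[GeneAlignment] = field(default_factory=list)


def filter_alignments(pool: list[GeneAlignment], params: ScoringParams) -> list[GeneAlignment]:
    """Greedy score-ordered filtering of an alignment pool.

    Processing by decreasing score (deterministic tie-break), an alignment is
    retained if its gene set is disjoint from every previously retained
    alignment's gene set; overlapping alignments are additionally retained
    while fewer than ``max_alignments`` have been kept and every one of their
    genes occurred fewer than ``gene_coverage`` times among higher-scoring
    retained alignments (these carry paralogous conserved synteny).  Finally
    alignments with fewer than ``min_length`` aligned column pairs are
    dropped.

    The retained set does not depend on the input order of ``pool``.
    """
    ordered = sorted(pool, key=lambda al: al.sort_key())
    kept: list[GeneAlignment] = []
    coverage: dict[str, int] = {}
    for al in ordered:
        genes = al.gene_ids()
        overlapping = any(g in coverage for g in genes)
        if overlapping:
            if len(kept) >= params.max_alignments:
                continue
            if any(coverage.get(g, 0) >= params.gene_coverage for g in genes):
                continue
        kept.append(al)
        for g in genes:
            coverage[g] = coverage.get(g, 0) + 1
    return [al for al in kept if al.n_match_columns >= params.min_length]


def progressive_align(
    genomes: list[GeneOrder],
    hom: HomologyTable,
    tree: GuideTree,
    params: ScoringParams,
    cache: dict | None = None,
) -> dict[str, NodeResult]:
    """Bottom-up progressive alignment; returns a NodeResult per tree node.

    ``cache`` optionally memoizes mismatch-independent score-matrix
    components across calls that reuse profiles with identical origins
    (parameter sweeps); results are identical with or without it.
    """
    by_species: dict[str, list[GeneOrder]] = {}
    for go in genomes:
        by_species.setdefault(go.species, []).append(go)
    tree_leaves = set(tree.leaves)
    for sp in by_species:
        if sp not in tree_leaves:
            raise ValueError(f"species {sp!r} has gene orders but is not in the guide tree")
    results: dict[str, NodeResult] = {}
    for sp in tree_leaves:
        orders = by_species.get(sp, [])
        if not orders:
            raise ValueError(f"guide-tree leaf {sp!r} has no gene orders")
        profiles = [leaf_profile(go) for go in sorted(orders, key=lambda g: g.contig)]
        results[sp] = NodeResult(node=sp, profiles=profiles)

    for label, left, right, _lleaf, _rleaf in tree.postorder_internal():
        pool: list[GeneAlignment] = []
        for pa in results[left].profiles:
            for pb in results[right].profiles:
                pool.extend(
                    align_both_orientations(pa, pb, hom, tree, params, cache=cache)
                )
        kept = filter_alignments(pool, params)
        profiles = [al.merged() for al in kept]
        results[label] = NodeResult(node=label, profiles=profiles, csms=kept)
        logger.info(
            "node %s: pooled %d alignments over %d x %d profiles, retained %d",
            label, len(pool), len(results[left].profiles),
            len(results[right].profiles), len(kept),
        )
    return results


def csms_at_node(results: dict[str, NodeResult], node: str) -> list[GeneAlignment]:
    """Retained alignments of one node (empty at leaves)."""
    try:
        return list(results[node].csms)
    except KeyError:
        raise KeyError(f"no node {node!r} in progressive results")
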