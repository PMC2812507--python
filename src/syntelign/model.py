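"""Core domain types: genes, gene orders, homology tables, guide trees, parameters.

A genome is modelled as a set of contigs, each a linear sequence of genes
ordered by start coordinate.  Homology between genes is given by BLASTP
bitscores (consumed, never computed here).  A rooted species tree with branch
lengths supplies the phylogenetic distances that weight all alignment scores.

Coordinates are 0-based, half-open throughout (BED convention); GFF3 input is
converted on read.  Strand is encoded as +1/-1.
"""

from __future__ import annotations


from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import sparse


class ValidationError(ValueError):
    """Raised when input data violates a documented contract."""


@dataclass(frozen=True, slots=True)
class Gene:
    """One annotated gene.

    ``rank`` is the 0-based position of the gene in its contig's gene order
    (genes sorted by start; ties broken by end, then gene_id).
    """

    gene_id: str
    species: str
    contig: str
    start: int
    end: int
    strand: int
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in (1, -1):
            raise ValidationError(f"gene {self.gene_id}: strand must be +1 or -1")


@dataclass(slots=True)
class GeneOrder:
    """An ordered gene sequence on one contig of one species."""

    species: str
    contig: str
    genes: list[Gene]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def build_gene_order(species: str, contig: str, records) -> GeneOrder:
    """Assemble a GeneOrder from unranked (gene_id, start, end, strand) records.

    Records are sorted by (start, end, gene_id) and ranks assigned 0..n-1.
    """
    recs = sorted(records, key=lambda r: (r[1], r[2], r[0]))
    genes = [
        Gene(gene_id=g, species=species, contig=contig, start=s, end=e,
             strand=st, rank=i)
        for i, (g, s, e, st) in enumerate(recs)
    ]
    return GeneOrder(species=species, contig=contig, genes=genes)


@dataclass(frozen=True, slots=True)
class ScoringParams:
    """Alignment parameters.

    mismatch, gap and min_score are base values; during alignment of two
    profiles they are scaled by the phylogenetic factor of the mean
    cross-species distance (see :mod:`syntelign.scoring`).
    """

    mismatch: float = 0.3
    gap: float = 0.3
    min_score: float = 2.0
    max_alignments: int = 1000
    gene_coverage: int = 2
    min_length: int = 2
    match_scale: float = 2.0

    def __post_init__(self) -> None:
        for name in ("mismatch", "gap", "min_score", "match_scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and non-negative")
        for name in ("max_alignments", "gene_coverage", "min_length"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")


class HomologyTable:
    """Sparse symmetric map (gene_id, gene_id) -> bitscore.

    Conflicting asymmetric entries are resolved by maximum on load (BLAST
    reciprocal scores differ; max is order independent).  An absent pair means
    "no homology".  Self scores are required for any gene that participates in
    a cross pair; the normalized score of a pair is

        2 * bs(a, b) / (bs(a, a) + bs(b, b)),  clamped to [0, 1].
    """

    def __init__(self, pairs=None):
        self._scores: dict[tuple[str, str], float] = {}
        self._index: dict[str, int] = {}
        self._norm_csr = None
        if pairs is not None:
            for a, b, s in pairs:
                self.add(a, b, s)

    def add(self, a: str, b: str, score: float) -> None:
        if score < 0:
            raise ValidationError(f"negative bitscore for pair ({a}, {b}): {score}")
        key = (a, b) if a <= b else (b, a)
        prev = self._scores.get(key)
        if prev is None or score > prev:
            self._scores[key] = float(score)
        self._norm_csr = None

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        key = (a, b) if a <= b else (b, a)
        return self._scores.get(key, default)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self._scores

    def self_score(self, a: str) -> float:
        s = self._scores.get((a, a))
        if s is None or s <= 0:
            raise ValidationError(
                f"gene {a} participates in a homologous pair but has no "
                f"positive self score"
            )
        return s

    def normalized(self, a: str, b: str) -> float:
        """Clamped normalized bitscore of a homologous pair (0 if absent)."""
        bs = self.get(a, b)
        if bs is None:
            return 0.0
        return min(1.0, max(0.0, 2.0 * bs / (self.self_score(a) + self.self_score(b))))

    def gene_index(self, gene_id: str) -> int:
        """Integer index of a gene for matrix lookups; -1 if unknown to the table."""
        self._ensure_matrix()
        return self._index.get(gene_id, -1)

    @property
    def n_indexed(self) -> int:
        self._ensure_matrix()
        return len(self._index)

    def _ensure_matrix(self):
        if self._norm_csr is not None:
            return
        ids = sorted({g for pair in self._scores for g in pair})
        self._index = {g: i for i, g in enumerate(ids)}
        n = len(ids)
        rows, cols, vals = [], [], []
        for (a, b), _ in self._scores.items():
            if a == b:
                continue
            v = self.normalized(a, b)
            if v <= 0:
                continue
            ia, ib = self._index[a], self._index[b]
            rows.extend((ia, ib))
            cols.extend((ib, ia))
            vals.extend((v, v))
        # row/col n is a zero "dummy" used for gap entries in fancy indexing
        self._norm_csr = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n + 1, n + 1), dtype=np.float64
        )

    def normalized_matrix(self) -> sparse.csr_matrix:
        """CSR matrix of clamped normalized scores, with one trailing zero
        dummy row/column (index ``n_indexed``) for gap placeholders."""
        self._ensure_matrix()
        return self._norm_csr

    def items(self):
        return self._scores.items()

    def __len__(self) -> int:
        return len(self._scores)


@dataclass(frozen=True, slots=True)
class EffectiveParams:
    """ScoringParams scaled by the phylogenetic factor for one profile pair."""

    mismatch_eff: float
    gap_eff: float
    min_score_eff: float
    mean_distance: float
    factor: float


class GuideTree:
    """Rooted species tree with branch lengths; supplies patristic distances.

    Multifurcations are resolved to binary left-to-right at construction with
    zero-length edges.  Missing branch lengths are read as 0.  Internal nodes
    receive deterministic labels ``node_<k>`` in postorder unless already
    labelled.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.resolve_polytomies(limit=2, update_bipartitions=False)
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
            elif edge.length < 0:
                raise ValidationError("negative branch length in guide tree")
        self._tree = tree
        k = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node._sa_label = node.taxon.label if node.taxon else node.label
                if node._sa_label is None:
                    raise ValidationError("unlabelled leaf in guide tree")
            else:
                node._sa_label = node.label or f"node_{k}"
                k += 1
        leaves = [n._sa_label for n in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValidationError("duplicate leaf labels in guide tree")
        self._leaves = leaves
        self._dist = self._patristic()

    @classmethod
    def from_newick(cls, newick: str) -> "GuideTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "GuideTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _patristic(self) -> dict[tuple[str, str], float]:
        # depth of every node from root, then LCA-free pairwise sums per leaf pair
        depth: dict[int, float] = {}
        for node in self._tree.preorder_node_iter():
            p = node.parent_node
            depth[id(node)] = (depth[id(p)] if p else 0.0) + (node.edge.length or 0.0)
        dist: dict[tuple[str, str], float] = {}
        leaf_nodes = list(self._tree.leaf_node_iter())
        # ancestor sets for LCA
        anc: dict[int, list] = {}
        for lf in leaf_nodes:
            chain = []
            n = lf
            while n is not None:
                chain.append(n)
                n = n.parent_node
            anc[id(lf)] = chain
        for i, a in enumerate(leaf_nodes):
            dist[(a._sa_label, a._sa_label)] = 0.0
            seta = {id(n) for n in anc[id(a)]}
            for b in leaf_nodes[i + 1:]:
                lca = next(n for n in anc[id(b)] if id(n) in seta)
                d = depth[id(a)] + depth[id(b)] - 2.0 * depth[id(lca)]
                dist[(a._sa_label, b._sa_label)] = d
                dist[(b._sa_label, a._sa_label)] = d
        return dist

    @property
    def leaves(self) -> list[str]:
        return list(self._leaves)

    def distance(self, s1: str, s2: str) -> float:
        try:
            return self._dist[(s1, s2)]
        except KeyError:
            missing = s1 if s1 not in self._leaves else s2
            raise KeyError(f"species {missing!r} is not a leaf of the guide tree")

    def postorder_internal(self):
        """Yield (label, left_child_label, right_child_label, is_child_leaf flags)
        for every internal node in postorder."""
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                continue
            ch = node.child_nodes()
            assert len(ch) == 2, "guide tree must be binary after resolution"
            yield (
                node._sa_label,
                ch[0]._sa_label,
                ch[1]._sa_label,
                ch[0].is_leaf(),
                ch[1].is_leaf(),
            )

    @property
    def root_label(self) -> str:
        return self._tree.seed_node._sa_label

    def leaf_species_under(self, label: str) -> set[str]:
        """Leaf labels below (and including) the node with the given label."""
        for node in self._tree.postorder_node_iter():
            if node._sa_label == label:
                if node.is_leaf():
                    return {label}
                return {lf._sa_label for lf in node.leaf_iter()}
        raise KeyError(f"no node labelled {label!r} in guide tree")


def tree_distance(tree: GuideTree, s1: str, s2: str) -> float:
    """Patristic distance between two leaf species of the guide tree."""
    return tree.distance(s1, s2)
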