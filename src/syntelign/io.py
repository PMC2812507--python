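"""Readers and writers for gene orders, homology tables, trees and block output.

Formats
-------
Gene orders
    6-column TSV: species, contig, start, end, strand, gene_id (0-based
    half-open coordinates, strand ``+``/``-`` or ``+1``/``-1``; an optional
    header line is detected and skipped), or GFF3 (``gene`` features with an
    ``ID`` attribute; 1-based closed coordinates converted on read; one
    species per file, given by the ``species`` argument).
Homology
    3-column TSV: gene_a, gene_b, bitscore.
Guide tree
    Newick with branch lengths.
Blocks
    One BED file per species (0-based half-open, ``block_<k>`` ids ordered by
    score rank) plus ``blocks.txt`` listing the aligned gene columns of every
    block.
"""

from __future__ import annotations

import os
from collections import defaultdict

import pandas as pd

from .model import GeneOrder, GuideTree, HomologyTable, ValidationError, build_gene_order

_STRANDS = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}


def _parse_strand(token: str, where: str) -> int:
    try:
        return _STRANDS[token]
    except KeyError:
        raise ValidationError(f"{where}: strand must be +/- (got {token!r})")


def read_gene_orders(path, format: str = "tsv", species: str | None = None) -> list[GeneOrder]:
    """Read gene annotations into one GeneOrder per (species, contig).

    Ranks are assigned by start order (ties: end, then gene_id).  Duplicate
    gene ids within a file are rejected.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "gff3":
        if species is None:
            raise ValidationError("GFF3 input requires an explicit species name")
        return _read_gff3(path, species)
    raise ValidationError(f"unknown gene-order format {format!r}")


def _read_tsv(path) -> list[GeneOrder]:
    by_key: dict[tuple[str, str], list] = defaultdict(list)
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValidationError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            sp, contig, start, end, strand, gid = fields
            try:
                s, e = int(start), int(end)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates")
            st = _parse_strand(strand, f"{path}:{lineno}")
            if gid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            by_key[(sp, contig)].append((gid, s, e, st))
    return [
        build_gene_order(sp, contig, recs)
        for (sp, contig), recs in sorted(by_key.items())
    ]


def _read_gff3(path, species: str) -> list[GeneOrder]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_key: dict[tuple[str, str], list] = defaultdict(list)
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise ValidationError(f"{path}: duplicate gene id {gid!r}")
        seen.add(gid)
        if feat.strand not in ("+", "-"):
            raise ValidationError(
                f"{path}: gene {gid!r} has no strand; strand is required"
            )
        # GFF3 is 1-based closed: convert to 0-based half-open
        by_key[(species, feat.seqid)].append(
            (gid, feat.start - 1, feat.end, 1 if feat.strand == "+" else -1)
        )
    return [
        build_gene_order(sp, contig, recs)
        for (sp, contig), recs in sorted(by_key.items())
    ]


def write_gene_orders(orders: list[GeneOrder], path) -> None:
    """Write gene orders as the 6-column TSV (with header)."""
    with open(path, "w") as fh:
        fh.write("species\tcontig\tstart\tend\tstrand\tgene_id\n")
        for go in orders:
            for g in go.genes:
                fh.write(
                    f"{g.species}\t{g.contig}\t{g.start}\t{g.end}\t"
                    f"{'+' if g.strand > 0 else '-'}\t{g.gene_id}\n"
                )


def read_homology(path) -> HomologyTable:
    """Read a 3-column TSV (gene_a, gene_b, bitscore) into a HomologyTable."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["gene_a", "gene_b", "bitscore"],
        dtype={"gene_a": str, "gene_b": str},
    )
    # drop a header row if present
    first = df.iloc[0]["bitscore"] if len(df) else None
    if first is not None and not _is_number(first):
        df = df.iloc[1:]
    df["bitscore"] = df["bitscore"].astype(float)
    if (df["bitscore"] < 0).any():
        bad = df[df["bitscore"] < 0].iloc[0]
        raise ValidationError(
            f"{path}: negative bitscore for pair ({bad.gene_a}, {bad.gene_b})"
        )
    table = HomologyTable()
    for a, b, s in df.itertuples(index=False):
        table.add(a, b, s)
    return table


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_homology(table: HomologyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tbitscore\n")
        for (a, b), s in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{s:g}\n")


def read_tree(path) -> GuideTree:
    try:
        return GuideTree.from_file(path)
    except ValidationError:
        raise
    except Exception as exc:  # dendropy parse errors
        raise ValidationError(f"cannot parse guide tree {path}: {exc}") from exc


def write_blocks(alignments, out_dir) -> dict[str, str]:
    """Write per-species BED files and a ``blocks.txt`` column listing.

    ``alignments`` is a list of GeneAlignment in score-rank order; block ids
    are ``block_1`` .. ``block_n`` in that order.  Returns a map of written
    file names.  Empty input yields header-only outputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    species_rows: dict[str, list] = defaultdict(list)
    written = {}
    txt_path = os.path.join(out_dir, "blocks.txt")
    with open(txt_path, "w") as txt:
        txt.write("# block\tscore\torientation\tspecies\tcolumns\n")
        for k, al in enumerate(alignments, start=1):
            bid = f"block_{k}"
            for (sp, contig), (lo, hi) in sorted(al.spans().items()):
                species_rows[sp].append((contig, lo, hi, bid))
            sps = sorted(al.species_set())
            txt.write(
                f"## {bid} score={al.score:.6g} orientation={al.orientation} "
                f"species={','.join(sps)}\n"
            )
            for col in al.merged_columns():
                cells = []
                for sp in sps:
                    ent = col.entries.get(sp)
                    cells.append("." if ent is None else ent[0].gene_id)
                txt.write("\t".join(cells) + "\n")
    written["blocks.txt"] = txt_path
    for sp in sorted(species_rows) if species_rows else []:
        p = os.path.join(out_dir, f"{sp}.blocks.bed")
        with open(p, "w") as fh:
            for contig, lo, hi, bid in species_rows[sp]:
                fh.write(f"{contig}\t{lo}\t{hi}\t{bid}\n")
        written[f"{sp}.blocks.bed"] = p
    return written


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read a BED3/BED4 file as (contig, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >=3 BED columns")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, size = line.split("\t")[:2]
            sizes[name] = int(size)
    return sizes


def read_block_genes(path) -> list[tuple[str, float, list[str]]]:
    """Parse ``blocks.txt`` back into (block_id, score, gene_ids) records."""
    blocks = []
    current: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("## "):
                head = line[3:].split()
                bid = head[0]
                score = float(next(t for t in head if t.startswith("score=")).split("=")[1])
                current = []
                blocks.append((bid, score, current))
            elif line.startswith("#") or not line:
                continue
            elif current is not None:
                current.extend(g for g in line.split("\t") if g != ".")
    return blocks
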