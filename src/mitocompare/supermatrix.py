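"""Amino-acid supermatrix construction and root-to-tip rate contrasts.

Protein-coding genes are translated with the invertebrate mitochondrial
code (NCBI table 5), individually aligned amino-acid matrices are
trimmed to their unambiguously aligned blocks with the published
Gblocks default rules, concatenated into a partitioned supermatrix, and
per-lineage substitution rates are read off a tree as the branch-length
path from the most recent common ancestor of the two focal clades to
each tip.

Alignment itself is an external input — this module starts at aligned
matrices; tree inference is likewise out of scope, trees arrive as
rooted Newick with branch lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio.Data import CodonTable

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]


class SupermatrixError(ValueError):
    pass


@dataclass
class GeneAlignment:
    """One gene's aligned amino-acid matrix (gap character ``-``)."""

    gene_key: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise SupermatrixError(f"{self.gene_key}: taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise SupermatrixError(f"{self.gene_key}: duplicate taxon label")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise SupermatrixError(f"{self.gene_key}: ragged alignment {widths}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class BlockMask:
    gene_key: str
    kept_columns: tuple[int, ...]

    def __post_init__(self):
        self.kept_columns = tuple(sorted(self.kept_columns))


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]  # (gene_key, start, end) half-open

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class CladeRateSummary:
    """MRCA-to-tip path lengths per taxon with per-clade aggregates."""

    per_tip: list[tuple[str, str, float]]       # (taxon, clade, root_to_tip)
    per_clade: dict[str, tuple[float, float, int]] = field(default_factory=dict)

    def rates_of(self, clade: str) -> list[float]:
        return [r for _, c, r in self.per_tip if c == clade]


# --------------------------------------------------------------------------
# Translation (NCBI table 5)
# --------------------------------------------------------------------------

def translate_mito(cds: str, frame: int = 0, allow_internal_stops: bool = False) -> str:
    """Translate a mitochondrial CDS with the invertebrate code (table 5).

    Table-5 particulars: ATA -> M, TGA -> W, AGA/AGG -> S.  A trailing
    incomplete codon (1-2 nt, the polyadenylation-completed stop
    convention) is dropped with a warning; a terminal stop codon is
    removed; an internal stop raises unless ``allow_internal_stops``
    (then it becomes ``X``).
    """
    if frame != 0:
        cds = cds[frame:]
    if len(cds) < 3:
        raise SupermatrixError(f"CDS shorter than one codon: {len(cds)} nt")
    cds = cds.upper().replace("U", "T")
    tail = len(cds) % 3
    if tail:
        warnings.warn(
            f"dropping {tail} nt trailing incomplete codon "
            "(polyadenylation-completed stop assumed)"
        )
        cds = cds[: len(cds) - tail]
    aa = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _TABLE5.stop_codons:
            if i == n_codons - 1:
                break  # terminal stop stripped
            if allow_internal_stops:
                aa.append("X")
                continue
            raise SupermatrixError(f"internal stop codon {codon} at codon {i}")
        aa.append(_TABLE5.forward_table.get(codon, "X"))
    return "".join(aa)


# --------------------------------------------------------------------------
# Conserved-block selection (Gblocks default rules)
# --------------------------------------------------------------------------

@dataclass
class BlockParams:
    """The published Gblocks defaults, restated as explicit thresholds."""

    min_conserved_frac: float = 0.5    # conserved: > N/2 rows share a residue
    min_flank_frac: float = 0.85       # highly conserved: >= ceil(0.85*N)
    max_nonconserved_run: int = 8      # longer runs are removed outright
    min_block_len: int = 10            # after trimming to highly conserved flanks
    allow_gaps: bool = False           # default: any gap makes a column nonconserved


def select_blocks(aln: GeneAlignment, params: BlockParams | None = None) -> BlockMask:
    """Column mask of unambiguously aligned blocks, Gblocks-default style.

    With ``N`` rows a column is *conserved* when one residue occurs in at
    least ``floor(N/2) + 1`` rows and *highly conserved* when one occurs
    in at least ``ceil(0.85 * N)``; any gap makes a column nonconserved.
    Maximal runs of more than 8 contiguous nonconserved columns are
    removed; the remaining segments are trimmed so both flanks are
    highly conserved columns, and survive only at length >= 10.
    """
    params = params or BlockParams()
    n = len(aln.rows)
    if n < 4:
        raise SupermatrixError(
            f"{aln.gene_key}: need >=4 rows for consensus thresholds, got {n}"
        )
    width = aln.width
    conserved_min = math.floor(n * params.min_conserved_frac) + 1
    flank_min = math.ceil(n * params.min_flank_frac)

    status = []  # 0 nonconserved, 1 conserved, 2 highly conserved
    is_gap = [False] * width
    for col in range(width):
        column = [row[col] for row in aln.rows]
        if not params.allow_gaps and "-" in column:
            status.append(0)
            is_gap[col] = True
            continue
        top = max(column.count(r) for r in set(column) if r != "-")
        if top >= flank_min:
            status.append(2)
        elif top >= conserved_min:
            status.append(1)
        else:
            status.append(0)

    # remove long nonconserved runs
    removed = [False] * width
    col = 0
    while col < width:
        if status[col] == 0:
            run_start = col
            while col < width and status[col] == 0:
                col += 1
            if col - run_start > params.max_nonconserved_run:
                for c in range(run_start, col):
                    removed[c] = True
        else:
            col += 1
    # nonconserved columns at the alignment edges can never sit inside a
    # flanked block either
    kept: list[int] = []
    seg_start = 0
    for col in range(width + 1):
        boundary = col == width or removed[col]
        if not boundary:
            continue
        seg = list(range(seg_start, col))
        seg_start = col + 1
        if not seg:
            continue
        # trim to highly conserved flanks
        while seg and status[seg[0]] != 2:
            seg.pop(0)
        while seg and status[seg[-1]] != 2:
            seg.pop()
        if len(seg) >= params.min_block_len:
            # gap columns participate in run/flank logic but are never kept
            kept.extend(c for c in seg if not is_gap[c])
    return BlockMask(aln.gene_key, tuple(kept))


# --------------------------------------------------------------------------
# Concatenation
# --------------------------------------------------------------------------

def concatenate(
    alns: Sequence[tuple[GeneAlignment, BlockMask]],
    taxon_union_policy: str = "gap_fill",
) -> Supermatrix:
    """Concatenate masked gene alignments into a partitioned supermatrix.

    ``gap_fill`` (default) unions the taxa and fills missing genes with
    gaps; ``intersect`` keeps only taxa present in every gene.
    """
    if not alns:
        raise SupermatrixError("no gene alignments to concatenate")
    if taxon_union_policy not in ("gap_fill", "intersect"):
        raise SupermatrixError(f"unknown policy {taxon_union_policy!r}")
    taxa_sets = [set(a.taxa) for a, _ in alns]
    if taxon_union_policy == "gap_fill":
        taxa = sorted(set().union(*taxa_sets))
    else:
        common = set.intersection(*taxa_sets)
        taxa = sorted(common)
        if not taxa:
            raise SupermatrixError("no taxa shared by all genes under 'intersect'")
    rows = {t: [] for t in taxa}
    partitions = []
    offset = 0
    for aln, mask in alns:
        if aln.gene_key != mask.gene_key:
            raise SupermatrixError(
                f"mask {mask.gene_key} applied to alignment {aln.gene_key}"
            )
        cols = mask.kept_columns
        by_taxon = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            if t in by_taxon:
                row = by_taxon[t]
                rows[t].append("".join(row[c] for c in cols))
            else:
                rows[t].append("-" * len(cols))
        partitions.append((aln.gene_key, offset, offset + len(cols)))
        offset += len(cols)
    return Supermatrix(
        taxa=taxa, rows=["".join(rows[t]) for t in taxa], partitions=partitions
    )


# --------------------------------------------------------------------------
# Root-to-tip rates
# --------------------------------------------------------------------------

def root_to_tip_rates(
    tree: "dendropy.Tree | str | Path",
    clade_map: dict[str, str],
    mrca_of: tuple[str, str],
) -> CladeRateSummary:
    """Per-tip branch-length distance from the MRCA of two named clades.

    The reference node is the most recent common ancestor of the union
    of all tips assigned to the two named clades; each tip's rate proxy
    is the sum of branch lengths on the node-to-tip path.  Clade means
    and standard deviations cover the two named clades only (outgroup
    tips are reported per-tip but excluded from aggregates).
    """
    t = _as_tree(tree)
    label_of = {}
    for leaf in t.leaf_node_iter():
        label_of[leaf.taxon.label] = leaf
    missing = [tx for tx in clade_map if tx not in label_of]
    if missing:
        raise SupermatrixError(f"clade_map taxa absent from tree: {missing}")
    focal = [
        tx for tx, cl in clade_map.items() if cl in mrca_of
    ]
    if not focal:
        raise SupermatrixError(f"no tips assigned to clades {mrca_of}")
    mrca = t.mrca(taxa=[label_of[tx].taxon for tx in focal])
    if mrca.is_leaf():
        raise SupermatrixError("MRCA of the named clades is a tip")

    def path_length(leaf) -> float:
        total = 0.0
        node = leaf
        while node is not mrca:
            if node.edge.length is None:
                raise SupermatrixError(
                    f"missing branch length on edge above {node.taxon.label if node.taxon else 'internal node'}"
                )
            total += node.edge.length
            node = node.parent_node
            if node is None:
                raise SupermatrixError(
                    f"tip {leaf.taxon.label} is not a descendant of the MRCA"
                )
        return total

    per_tip = []
    for tx, cl in sorted(clade_map.items()):
        leaf = label_of[tx]
        if cl in mrca_of:
            d = path_length(leaf)
        else:
            d = float("nan")  # outgroup: not on the focal subtree in general
        per_tip.append((tx, cl, d))
    summary = CladeRateSummary(per_tip=per_tip)
    for clade in mrca_of:
        vals = summary.rates_of(clade)
        if vals:
            mean = sum(vals) / len(vals)
            sd = (
                math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
                if len(vals) > 1
                else 0.0
            )
            summary.per_clade[clade] = (mean, sd, len(vals))
    return summary


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" not in text and Path(text).exists():
        t = dendropy.Tree.get(path=text, schema="newick")
    else:
        t = dendropy.Tree.get(data=text, schema="newick")
    t.is_rooted = True
    return t


# --------------------------------------------------------------------------
# File formats
# --------------------------------------------------------------------------

def read_alignment_fasta(path: str | Path, gene_key: str) -> GeneAlignment:
    from Bio import SeqIO

    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    return GeneAlignment(gene_key, taxa, rows)


def write_alignment_fasta(aln: GeneAlignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{r}\n")


def write_partition_file(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition text, 1-based inclusive coordinates."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene, start, end in sm.partitions:
            fh.write(f"GENE, {gene} = {start + 1}-{end}\n")


def read_partition_file(path: str | Path) -> list[tuple[str, int, int]]:
    parts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            _, rest = line.split(",", 1)
            name, span = rest.split("=")
            lo, hi = span.strip().split("-")
            parts.append((name.strip(), int(lo) - 1, int(hi)))
    return parts
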