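"""Reading, writing and normalizing annotated mitochondrial genomes.

Coordinates are 0-based half-open on the forward strand throughout;
GenBank 1-based closed coordinates are converted on read.  Features
crossing the sequence origin of a circular genome carry
``wraps_origin`` (stored with ``start >= end``); intergenic-region
(IGR) logic internally rotates the genome so that no feature wraps.

The gene vocabulary is the canonical bilaterian mitochondrial set:
13 protein-coding genes (the wood-borer dataset lacks *atp8*),
22 tRNA isoacceptors (leucine and serine each split in two) and the
two rRNAs ``rrnS``/``rrnL``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

PCG_KEYS = frozenset({
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
})
TRNA_KEYS = frozenset(
    {f"trn{a}" for a in "ACDEFGHIKMNPQRTVWY"}
    | {"trnL1", "trnL2", "trnS1", "trnS2"}
)
RRNA_KEYS = frozenset({"rrnS", "rrnL"})
ALL_GENE_KEYS = PCG_KEYS | TRNA_KEYS | RRNA_KEYS

#: genes expected in this study's mitogenomes (atp8 undetected in both families)
EXPECTED_ABSENT = frozenset({"atp8"})

CLADES = ("Teredinidae", "Xylophagaidae", "outgroup")


class MitoError(ValueError):
    """Base error for malformed genome or annotation input."""


class UnknownGeneNameError(MitoError):
    """A gene name could not be mapped to the closed vocabulary."""


@dataclass
class MitoGenome:
    """A circular mitochondrial genome with identity metadata."""

    record_id: str
    sequence: str
    taxon_label: str = ""
    clade: str = "outgroup"
    circular: bool = True
    accession: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise MitoError(
                f"{self.record_id}: sequence contains non-ACGTN symbols {sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def gc_percent(self) -> float:
        s = self.sequence
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return 100.0 * (s.count("G") + s.count("C")) / acgt

    def rotated(self, offset: int) -> "MitoGenome":
        """Return the genome linearized starting at ``offset`` (circular rotation)."""
        off = offset % self.length_bp
        return replace(self, sequence=self.sequence[off:] + self.sequence[:off])


@dataclass
class GeneFeature:
    """One annotated gene on a mitogenome.

    ``start``/``end`` are 0-based half-open; a feature with
    ``wraps_origin`` stores ``start >= end`` and spans
    ``[start, L) + [0, end)``.
    """

    gene_key: str
    feature_class: str  # PCG | tRNA | rRNA | unknown
    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False
    copy_index: int = 1
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise MitoError(f"{self.gene_key}: strand must be '+' or '-'")
        if self.copy_index < 1:
            raise MitoError(f"{self.gene_key}: copy_index must be >= 1")
        if not self.wraps_origin and not self.start < self.end:
            raise MitoError(
                f"{self.gene_key}: start {self.start} !< end {self.end} "
                "(non-wrapping feature)"
            )

    def length_on(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.end
        return self.end - self.start


@dataclass
class Igr:
    """An intergenic region labelled by its flanking genes in genome order."""

    label: str
    start: int
    end: int  # may be < start when the IGR wraps the origin

    def length_on(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start
        return genome_length - self.start + self.end


@dataclass
class AnnotationSet:
    """All gene features of one record, sorted by start, plus derived IGRs."""

    record_id: str
    features: list[GeneFeature] = field(default_factory=list)
    igrs: list[Igr] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))

    def of_class(self, classes: Iterable[str]) -> list[GeneFeature]:
        wanted = set(classes)
        return [f for f in self.features if f.feature_class in wanted]


# --------------------------------------------------------------------------
# Gene-name normalization
# --------------------------------------------------------------------------

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

_SYNONYMS = {
    # cytochrome oxidase subunits
    "coi": "cox1", "co1": "cox1", "cox1": "cox1", "coxi": "cox1",
    "coii": "cox2", "co2": "cox2", "cox2": "cox2", "coxii": "cox2",
    "coiii": "cox3", "co3": "cox3", "cox3": "cox3", "coxiii": "cox3",
    # cytochrome b
    "cob": "cob", "cytb": "cob", "cyb": "cob", "cob/cytb": "cob",
    # ATP synthase
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    # NADH dehydrogenase
    **{f"nd{i}": f"nad{i}" for i in (1, 2, 3, 5, 6)},
    **{f"nad{i}": f"nad{i}" for i in (1, 2, 3, 5, 6)},
    **{f"nadh{i}": f"nad{i}" for i in (1, 2, 3, 5, 6)},
    "nd4": "nad4", "nad4": "nad4", "nadh4": "nad4",
    "nd4l": "nad4l", "nad4l": "nad4l", "nadh4l": "nad4l",
    # rRNAs
    "12s": "rrnS", "srrna": "rrnS", "s-rrna": "rrnS", "rrns": "rrnS",
    "12srrna": "rrnS", "rns": "rrnS", "mtssu": "rrnS",
    "16s": "rrnL", "lrrna": "rrnL", "l-rrna": "rrnL", "rrnl": "rrnL",
    "16srrna": "rrnL", "rnl": "rrnL", "mtlsu": "rrnL",
}

# anticodon families that split leucine and serine tRNAs
_LEU_SER_CODONS = {
    ("L", "uur"): "trnL2", ("L", "uaa"): "trnL2", ("L", "taa"): "trnL2",
    ("L", "cun"): "trnL1", ("L", "uag"): "trnL1", ("L", "tag"): "trnL1",
    ("S", "ucn"): "trnS2", ("S", "uga"): "trnS2", ("S", "tga"): "trnS2",
    ("S", "agn"): "trnS1", ("S", "agy"): "trnS1", ("S", "ucu"): "trnS1",
    ("S", "gcu"): "trnS1", ("S", "gct"): "trnS1",
}


def _classify_key(key: str) -> str:
    if key in PCG_KEYS:
        return "PCG"
    if key in TRNA_KEYS:
        return "tRNA"
    if key in RRNA_KEYS:
        return "rRNA"
    raise UnknownGeneNameError(key)


def normalize_gene_name(raw: str) -> tuple[str, str]:
    """Map an annotation-dialect gene name to ``(gene_key, feature_class)``.

    Handles the common MITOS/GenBank synonym families case-insensitively:
    ``COI``/``COX1`` -> ``cox1``, ``CYTB`` -> ``cob``, ``ND4`` -> ``nad4``,
    ``12S``/``s-rRNA`` -> ``rrnS``, ``16S``/``l-rRNA`` -> ``rrnL``, and
    tRNA names in ``trnX``, ``tRNA-Xxx`` or ``tRNA-Leu(UUR)`` style with
    the leucine/serine isoacceptors kept distinct.

    Raises
    ------
    UnknownGeneNameError
        if the name cannot be mapped; the caller decides whether to keep
        the feature as class ``unknown`` or reject it.
    """
    if not raw or not raw.strip():
        raise UnknownGeneNameError("empty gene name")
    s = raw.strip()
    low = s.lower()

    # paren-annotated anticodon, e.g. tRNA-Leu(UUR) / trnL(uag)
    paren = re.match(r"^(.*?)\(([^)]+)\)$", low)
    codon = None
    if paren:
        low, codon = paren.group(1).strip(), paren.group(2).strip()

    compact = re.sub(r"[\s_\-]+", "", low)

    # tRNA forms
    m = re.match(r"^(?:trn|trna)([a-z])([12])?$", compact)
    if m:
        aa = m.group(1).upper()
        num = m.group(2)
        return _trna_key(aa, num, codon, raw)
    m = re.match(r"^trna([a-z]{3})([12])?$", compact)
    if m and m.group(1) in _AA3_TO_1:
        return _trna_key(_AA3_TO_1[m.group(1)], m.group(2), codon, raw)

    if compact in _SYNONYMS:
        key = _SYNONYMS[compact]
        return key, _classify_key(key)
    # exact vocabulary hit with original casing rules (rrnS/rrnL handled above)
    if compact in ALL_GENE_KEYS:
        return compact, _classify_key(compact)
    raise UnknownGeneNameError(raw)


def _trna_key(aa: str, num: str | None, codon: str | None, raw: str) -> tuple[str, str]:
    if aa in ("L", "S"):
        if num in ("1", "2"):
            return f"trn{aa}{num}", "tRNA"
        if codon:
            codon = codon.lower()
            for (a, c), key in _LEU_SER_CODONS.items():
                if a == aa and (codon == c or codon.replace("u", "t") == c):
                    return key, "tRNA"
        raise UnknownGeneNameError(
            f"{raw}: leucine/serine tRNA needs an isoacceptor number or anticodon"
        )
    key = f"trn{aa}"
    if key in TRNA_KEYS:
        return key, "tRNA"
    raise UnknownGeneNameError(raw)


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def _clade_of(taxon_label: str, clade_map: dict[str, str] | None, record_id: str) -> str:
    if clade_map is None:
        return "outgroup"
    for key in (record_id, taxon_label):
        if key in clade_map:
            return clade_map[key]
    return "outgroup"


def read_records(
    path: str | Path,
    format: str = "genbank",
    *,
    clade_map: dict[str, str] | None = None,
    strict_names: bool = False,
) -> list[tuple[MitoGenome, AnnotationSet]]:
    """Read annotated mitogenomes from a GenBank flat file or FASTA + TSV pair.

    For ``format="fasta_plus_table"``, ``path`` is the FASTA file and a
    sibling file with suffix ``.features.tsv`` (header
    ``record_id  gene  class  start  end  strand`` and optional ``quality``)
    must exist; coordinates there are already 0-based half-open.

    Unknown gene names are kept with class ``unknown`` (and excluded from
    gene-order analysis downstream) unless ``strict_names`` is set, in
    which case they raise :class:`UnknownGeneNameError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        pairs = _read_genbank(path, clade_map, strict_names)
    elif format == "fasta_plus_table":
        pairs = _read_fasta_table(path, clade_map, strict_names)
    else:
        raise ValueError(f"unknown format {format!r}")
    for genome, ann in pairs:
        _assign_copy_indices(ann)
        _validate_bounds(genome, ann)
    return pairs


def _validate_bounds(genome: MitoGenome, ann: AnnotationSet) -> None:
    L = genome.length_bp
    for f in ann.features:
        if f.wraps_origin:
            if not (0 <= f.start < L and 0 <= f.end <= L):
                raise MitoError(
                    f"{ann.record_id}:{f.gene_key}: wrapping coordinates out of range"
                )
        elif f.end > L:
            raise MitoError(
                f"{ann.record_id}:{f.gene_key}: end {f.end} exceeds genome "
                f"length {L} and wraps_origin is false"
            )


def _assign_copy_indices(ann: AnnotationSet) -> None:
    seen: dict[str, int] = {}
    for f in ann.features:
        seen[f.gene_key] = seen.get(f.gene_key, 0) + 1
        f.copy_index = seen[f.gene_key]


def _norm_or_unknown(raw: str, strict: bool) -> tuple[str, str]:
    try:
        return normalize_gene_name(raw)
    except UnknownGeneNameError:
        if strict:
            raise
        logger.warning("unmappable gene name %r kept with class 'unknown'", raw)
        return raw, "unknown"


def _read_genbank(path: Path, clade_map, strict: bool):
    pairs = []
    for rec in SeqIO.parse(str(path), "genbank"):
        topo = rec.annotations.get("topology", "circular")
        genome = MitoGenome(
            record_id=rec.id,
            sequence=str(rec.seq),
            taxon_label=rec.annotations.get("organism", rec.description or rec.id),
            clade=_clade_of(rec.annotations.get("organism", ""), clade_map, rec.id),
            circular=(topo != "linear"),
            accession=rec.id,
        )
        feats = []
        for sf in rec.features:
            if sf.type not in ("CDS", "tRNA", "rRNA"):
                continue
            name = (
                sf.qualifiers.get("gene", [None])[0]
                or sf.qualifiers.get("product", [None])[0]
            )
            if name is None:
                continue
            key, cls = _norm_or_unknown(name, strict)
            start = int(sf.location.start)  # Biopython is already 0-based half-open
            end = int(sf.location.end)
            strand = "-" if sf.location.strand == -1 else "+"
            wraps = False
            if len(sf.location.parts) > 1:  # compound location crossing the origin
                p0, p1 = sf.location.parts[0], sf.location.parts[-1]
                if int(p0.end) == len(rec.seq) and int(p1.start) == 0:
                    start, end, wraps = int(p0.start), int(p1.end), True
            feats.append(GeneFeature(key, cls, start, end, strand, wraps_origin=wraps))
        pairs.append((genome, AnnotationSet(rec.id, feats)))
    return pairs


_TSV_COLUMNS = ("record_id", "gene", "class", "start", "end", "strand")


def _table_path(fasta_path: Path) -> Path:
    return fasta_path.parent / (fasta_path.stem + ".features.tsv")


def _read_fasta_table(path: Path, clade_map, strict: bool):
    table = _table_path(path)
    if not table.exists():
        raise FileNotFoundError(f"feature table {table} not found next to {path}")
    by_record: dict[str, list[GeneFeature]] = {}
    with open(table, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[: len(_TSV_COLUMNS)]) != _TSV_COLUMNS:
            raise MitoError(f"{table}: bad header {header!r}")
        has_quality = "quality" in header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(_TSV_COLUMNS):
                raise MitoError(f"{table}:{lineno}: expected >=6 columns")
            rid, gene, cls, start_s, end_s, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise MitoError(
                    f"{table}:{lineno}: malformed coordinates {start_s!r}/{end_s!r}"
                ) from exc
            key, norm_cls = _norm_or_unknown(gene, strict)
            if norm_cls == "unknown" and cls in ("PCG", "tRNA", "rRNA"):
                norm_cls = cls  # class inferred from the table for unknown names
            quality = None
            if has_quality and len(parts) > 6 and parts[6] not in ("", "NA"):
                quality = float(parts[6])
            wraps = start >= end
            by_record.setdefault(rid, []).append(
                GeneFeature(key, norm_cls, start, end, strand,
                            wraps_origin=wraps, quality=quality)
            )
    pairs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = rec.description.split(maxsplit=1)[1] if " " in rec.description else rec.id
        genome = MitoGenome(
            record_id=rec.id,
            sequence=str(rec.seq),
            taxon_label=taxon,
            clade=_clade_of(taxon, clade_map, rec.id),
        )
        pairs.append((genome, AnnotationSet(rec.id, by_record.get(rec.id, []))))
    return pairs


def write_records(
    pairs: Sequence[tuple[MitoGenome, AnnotationSet]],
    fasta_path: str | Path,
) -> Path:
    """Write genomes to FASTA plus the sibling ``.features.tsv`` table.

    Inverse of :func:`read_records` with ``format="fasta_plus_table"``.
    Returns the feature-table path.
    """
    fasta_path = Path(fasta_path)
    fasta_path.parent.mkdir(parents=True, exist_ok=True)
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for genome, _ in pairs:
            fh.write(f">{genome.record_id} {genome.taxon_label}\n")
            for i in range(0, genome.length_bp, 70):
                fh.write(genome.sequence[i : i + 70] + "\n")
    table = _table_path(fasta_path)
    with open(table, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS + ("quality",)) + "\n")
        for genome, ann in pairs:
            for f in ann.features:
                q = "" if f.quality is None else repr(f.quality)
                fh.write(
                    f"{ann.record_id}\t{f.gene_key}\t{f.feature_class}\t"
                    f"{f.start}\t{f.end}\t{f.strand}\t{q}\n"
                )
    return table


# --------------------------------------------------------------------------
# Gene order and intergenic regions
# --------------------------------------------------------------------------

def extract_gene_order(
    ann: AnnotationSet,
    classes: Iterable[str] = ("PCG",),
    duplicate_policy: str = "best",
):
    """Derive the circular signed gene order for the requested feature classes.

    Genes are listed by start position; the sign is the strand.  Under
    ``duplicate_policy="best"`` only the copy with the best (lowest)
    quality score is kept — ties broken by longest, then smallest start —
    and dropped copies are logged.  ``duplicate_policy="error"`` raises on
    any duplicate.  Features with class ``unknown`` never enter the order.
    """
    from mitocompare.gene_order import SignedGeneOrder  # local import; no cycle at module load

    wanted = set(classes)
    feats = [f for f in ann.features if f.feature_class in wanted
             and f.feature_class != "unknown"]
    if not feats:
        raise MitoError(f"{ann.record_id}: no features left after class filter {wanted}")

    by_key: dict[str, list[GeneFeature]] = {}
    for f in feats:
        by_key.setdefault(f.gene_key, []).append(f)
    keep: list[GeneFeature] = []
    for key, copies in by_key.items():
        if len(copies) == 1:
            keep.append(copies[0])
            continue
        if duplicate_policy == "error":
            raise MitoError(f"{ann.record_id}: duplicate gene {key}")
        if any(c.quality is None for c in copies):
            logger.warning(
                "%s: duplicate %s without quality scores; keeping longest",
                ann.record_id, key,
            )
            best = sorted(copies, key=lambda c: (-(c.end - c.start), c.start))[0]
        else:
            best = sorted(
                copies, key=lambda c: (c.quality, -(c.end - c.start), c.start)
            )[0]
        for c in copies:
            if c is not best:
                logger.info("%s: dropped duplicate %s copy at %d", ann.record_id,
                            key, c.start)
        keep.append(best)
    keep.sort(key=lambda f: (f.start, f.end))
    elements = [(f.gene_key if f.strand == "+" else "-" + f.gene_key) for f in keep]
    return SignedGeneOrder(record_id=ann.record_id, elements=elements, circular=True)


def _rotation_offset(ann: AnnotationSet) -> int:
    """Offset such that after rotation no feature wraps the origin."""
    for f in ann.features:
        if f.wraps_origin:
            return f.start
    return 0


def _truncate_overlaps(feats: list[GeneFeature], L: int) -> list[tuple[str, int, int]]:
    """Midpoint-truncated (gene_key, start, end) intervals; input non-wrapping, sorted."""
    out: list[list] = []
    for f in feats:
        out.append([f.gene_key, f.start, f.end])
    changed = True
    while changed:
        changed = False
        out.sort(key=lambda t: (t[1], t[2]))
        for i in range(len(out) - 1):
            a, b = out[i], out[i + 1]
            if b[1] < a[2]:  # overlap
                mid = (b[1] + a[2]) // 2
                a[2], b[1] = mid, mid
                changed = True
        out = [t for t in out if t[2] > t[1]]
    return [tuple(t) for t in out]


def compute_igrs(ann: AnnotationSet, genome: MitoGenome) -> AnnotationSet:
    """Fill ``ann.igrs`` with the intergenic regions around the circle.

    Overlapping annotations are truncated at the overlap midpoint for
    this purpose only (original coordinates are preserved); IGRs then
    partition every unannotated position.  Labels read
    ``"geneA-geneB"`` in genome order; zero-length gaps are omitted.
    Wrapping features are handled by computing on a rotated
    linearization and mapping coordinates back.
    """
    L = genome.length_bp
    if not ann.features:
        ann.igrs = []
        return ann
    off = _rotation_offset(ann)

    rotated: list[GeneFeature] = []
    for f in ann.features:
        if f.wraps_origin:
            start = (f.start - off) % L
            end = start + f.length_on(L)
        else:
            start = (f.start - off) % L
            end = start + (f.end - f.start)
        if end > L:
            raise MitoError(
                f"{ann.record_id}: feature {f.gene_key} still wraps after rotation"
            )
        rotated.append(replace(f, start=start, end=end, wraps_origin=False))
    rotated.sort(key=lambda f: (f.start, f.end))
    spans = _truncate_overlaps(rotated, L)

    igrs: list[Igr] = []
    for i, (key, _s, e) in enumerate(spans):
        nxt_key, nxt_s, _ = spans[(i + 1) % len(spans)]
        gap_start, gap_end = e, (nxt_s if i + 1 < len(spans) else nxt_s + L)
        if gap_end - gap_start <= 0:
            continue
        start0 = (gap_start + off) % L
        end0 = (gap_end + off) % L
        igrs.append(Igr(label=f"{key}-{nxt_key}", start=start0, end=end0))
    ann.igrs = igrs
    return ann


def coding_coverage(ann: AnnotationSet, genome: MitoGenome) -> int:
    """Number of positions covered by any feature, overlaps counted once."""
    L = genome.length_bp
    if not ann.features:
        return 0
    off = _rotation_offset(ann)
    rotated = []
    for f in ann.features:
        start = (f.start - off) % L
        rotated.append(replace(f, start=start, end=start + f.length_on(L),
                               wraps_origin=False))
    rotated.sort(key=lambda f: (f.start, f.end))
    return sum(e - s for _, s, e in _truncate_overlaps(rotated, L))
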