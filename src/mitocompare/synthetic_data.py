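"""Synthetic two-clade mitogenome studies with full ground truth.

The generator emulates the geometry of a shallow-water/deep-sea
wood-borer comparison: 26 + 16 taxa in two sister clades plus an
outgroup; circular ~14.5–18.6 kb genomes carrying 12 protein-coding
genes, 22 tRNAs and 2 rRNAs all on one strand; one clade with a frozen
protein-coding gene order (tRNA-only repositioning allowed) and a
sister clade accumulating planted rearrangements; clade-specific GC
content (40.7% vs 38.5% by default); a ~1.4-fold clade contrast in
amino-acid substitution rate (2.17 vs 1.55 MRCA-to-tip subs/site, with
a 2.36/1.86 subclade split inside the fast clade); and planted
replication-origin signals — a base-composition skew switch plus a
T-rich-loop hairpin — in chosen intergenic regions, absent for OriL in
the slow clade.

Substitution model: per-branch Poisson substitution counts at a
configurable fraction of free-to-vary sites, uniform amino-acid
exchange — rate contrasts, not substitution realism, are the target.
The emitted "estimated" tree carries realized substitution densities
as branch lengths, emulating a well-estimated tree without
re-implementing tree inference.  Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from mitocompare.gene_order import (
    RearrangementEvent,
    SignedGeneOrder,
    apply_event,
    classify_single_event,
    orders_equivalent,
    tdrl_reachable,
)
from mitocompare.mito_io import AnnotationSet, GeneFeature, MitoGenome, write_records
from mitocompare.supermatrix import GeneAlignment, _TABLE5

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: ancestral gene order used for the conserved clade; OriH sits downstream of
#: cob (cob–trnM–trnC–rrnL neighborhood) and OriL downstream of cox1
#: (cox1–trnT–nad4), mirroring the conserved arrangements of the real study.
ANCESTRAL_ORDER: tuple[str, ...] = (
    "cox1", "trnT", "nad4", "nad4l", "nad5", "trnF", "trnH", "nad6",
    "nad3", "trnA", "trnS2", "nad1", "trnV", "trnL1", "trnL2", "rrnS",
    "trnI", "cox3", "trnW", "trnE", "trnG", "cox2", "trnR", "atp6",
    "trnN", "trnP", "trnK", "nad2", "trnQ", "trnD", "trnY", "cob",
    "trnM", "trnC", "rrnL", "trnS1",
)

#: relative protein lengths (realistic animal-mitogenome proportions)
PCG_WEIGHTS = {
    "cox1": 515, "nad5": 570, "nad4": 459, "cob": 380, "nad2": 340,
    "nad1": 325, "cox3": 260, "cox2": 230, "atp6": 225, "nad6": 165,
    "nad3": 115, "nad4l": 96,
}

RNA_LENGTHS = {"rrnS": 700, "rrnL": 950}
TRNA_LENGTH = 65


@dataclass
class SimulationConfig:
    """Study geometry and signal strengths; defaults are the study conditions."""

    seed: int = 0
    n_teredinid_like: int = 26
    n_xylophagaid_like: int = 16
    n_outgroup: int = 3
    rate_ratio: float = 1.4
    base_rate: float = 1.55            # slow-clade MRCA-to-tip subs/site
    subclade_split: tuple[int, int] = (16, 10)   # fast-clade subclade sizes
    subclade_rate_ratio: float = 1.27  # fast vs slow subclade inside clade A
    rate_noise_sd: float = 0.06        # geometric-diffusion rate noise (log-sd per unit time)
    gc_means: tuple[float, float] = (40.7, 38.5)  # percent, per clade
    gc_sds: tuple[float, float] = (1.2, 1.5)
    genome_size_range: tuple[int, int] = (14_450, 18_624)
    n_pcg: int = 12
    n_trna: int = 22
    n_rrna: int = 2
    supermatrix_target_width: int = 4_135
    variable_site_fraction: float = 0.30
    pcg_event_rate: float = 0.25       # clade-B events per branch (Poisson mean)
    trna_event_rate: float = 0.10      # tRNA-only transpositions, both clades
    # all observed genomes stay on one strand, so the study generator plants
    # strand-preserving events only; orientation-changing kinds are exercised
    # by plant_events in accuracy studies
    event_kind_weights: dict = field(
        default_factory=lambda: {"transposition": 0.8, "tdrl": 0.2}
    )
    ori_plant: dict = field(
        default_factory=lambda: {
            "Teredinidae": {"OriH": "cob", "OriL": "cox1"},
            "Xylophagaidae": {"OriH": "cob", "OriL": None},
        }
    )
    ori_igr_reserve: int = 300         # bp guaranteed for planted-origin IGRs
    gap_fraction: float = 0.0          # optional alignment gap injection

    def clade_rates(self) -> tuple[float, float]:
        return (self.base_rate * self.rate_ratio, self.base_rate)

    def gene_lengths(self) -> dict[str, int]:
        """Amino-acid length per gene, summing to the supermatrix target width."""
        total_w = sum(PCG_WEIGHTS.values())
        lengths = {
            g: max(30, round(self.supermatrix_target_width * w / total_w))
            for g, w in PCG_WEIGHTS.items()
        }
        # fix rounding drift on the longest gene
        drift = self.supermatrix_target_width - sum(lengths.values())
        lengths["nad5"] += drift
        return lengths


# --------------------------------------------------------------------------
# Tree simulation
# --------------------------------------------------------------------------

@dataclass
class SimNode:
    name: str
    age: float
    children: list["SimNode"] = field(default_factory=list)
    clade: str = ""
    time_len: float = 0.0      # edge above this node, time units
    rate: float = 0.0          # subs/site per time unit on the edge above
    subs_len: float = 0.0      # expected substitutions/site on the edge above
    realized_len: float = 0.0  # realized substitution density (filled later)

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["SimNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def tips(self) -> list["SimNode"]:
        return [n for n in self.walk() if n.is_leaf()]

    def newick(self, attr: str = "subs_len") -> str:
        def fmt(node: SimNode) -> str:
            length = getattr(node, attr)
            if node.is_leaf():
                return f"{node.name}:{length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def _build_ultrametric(names: list[str], age: float, rng: np.random.Generator) -> SimNode:
    if len(names) == 1:
        return SimNode(name=names[0], age=0.0)
    node = SimNode(name="", age=age)
    k = int(rng.integers(1, len(names)))
    for part in (names[:k], names[k:]):
        child_age = 0.0 if len(part) == 1 else age * rng.uniform(0.5, 0.9)
        child = _build_ultrametric(part, child_age, rng)
        child.time_len = age - child.age
        node.children.append(child)
    return node


def simulate_tree(config: SimulationConfig) -> SimNode:
    """Rooted time tree: two sister clades plus an outgroup.

    The family MRCA sits at age 1.0; per-edge substitution rates apply
    the clade contrast (clade A = ``base_rate * rate_ratio``, clade B =
    ``base_rate``) with an additional subclade split inside clade A and
    mean-one lognormal per-branch noise.  Expected clade mean
    MRCA-to-tip distances are therefore ``rate_ratio`` apart.
    """
    if config.n_teredinid_like < 2 or config.n_xylophagaid_like < 2:
        raise ValueError("need >=2 taxa per clade")
    rng = np.random.default_rng([config.seed, 11])
    ter = [f"T{i + 1:02d}" for i in range(config.n_teredinid_like)]
    xyl = [f"X{i + 1:02d}" for i in range(config.n_xylophagaid_like)]
    out = [f"OUT{i + 1}" for i in range(config.n_outgroup)]

    n1, n2 = config.subclade_split
    n1 = min(n1, len(ter) - 1) or 1
    sub1, sub2 = ter[:n1], ter[n1:]
    a_root = SimNode(name="", age=rng.uniform(0.6, 0.8))
    for part in (sub1, sub2):
        child_age = 0.0 if len(part) == 1 else a_root.age * rng.uniform(0.6, 0.9)
        child = _build_ultrametric(part, child_age, rng)
        child.time_len = a_root.age - child.age
        a_root.children.append(child)
    b_root = _build_ultrametric(xyl, rng.uniform(0.6, 0.8), rng)

    ingroup = SimNode(name="", age=1.0)
    a_root.time_len = ingroup.age - a_root.age
    b_root.time_len = ingroup.age - b_root.age
    ingroup.children = [a_root, b_root]

    root = SimNode(name="root", age=1.3)
    ingroup.time_len = root.age - ingroup.age
    og_rng = np.random.default_rng([config.seed, 12])
    og = _build_ultrametric(out, 0.0 if len(out) == 1 else 0.9, og_rng)
    og.time_len = root.age - og.age
    root.children = [ingroup, og]

    rate_a, rate_b = config.clade_rates()
    # subclade rates normalized so the clade-A mean stays rate_a
    f1 = len(sub1) / len(ter)
    norm = 1.0 / (f1 * config.subclade_rate_ratio + (1 - f1))
    sub_rates = (rate_a * norm * config.subclade_rate_ratio, rate_a * norm)

    def assign(node: SimNode, clade: str, rate: float) -> None:
        node.clade = clade
        node.rate = rate
        for c in node.children:
            assign(c, clade, rate)

    assign(a_root, "Teredinidae", rate_a)
    for child, r in zip(a_root.children, sub_rates):
        assign(child, "Teredinidae", r)
        child.rate = r
    assign(b_root, "Xylophagaidae", rate_b)
    assign(og, "outgroup", rate_b)
    ingroup.clade = "ingroup"
    ingroup.rate = rate_b

    noise_rng = np.random.default_rng([config.seed, 13])
    for node in root.walk():
        if node is root:
            continue
        # mean-one lognormal with variance proportional to branch duration,
        # so deep shared branches perturb clade means only mildly while
        # per-tip spread stays realistic
        s = config.rate_noise_sd * math.sqrt(max(node.time_len, 0.0))
        noise = math.exp(noise_rng.normal(0.0, s) - s**2 / 2.0)
        node.subs_len = node.time_len * node.rate * noise
    return root


def clade_map_of(tree: SimNode) -> dict[str, str]:
    return {tip.name: tip.clade for tip in tree.tips()}


def subclade_map_of(tree: SimNode, config: SimulationConfig) -> dict[str, str]:
    n1 = config.subclade_split[0]
    out = {}
    for tip in tree.tips():
        if tip.clade != "Teredinidae":
            continue
        idx = int(tip.name[1:])
        out[tip.name] = "subclade1" if idx <= n1 else "subclade2"
    return out


# --------------------------------------------------------------------------
# Sequence evolution
# --------------------------------------------------------------------------

@dataclass
class SequenceEvolution:
    alignments: dict[str, GeneAlignment]          # per gene, all taxa
    cds_aa: dict[str, dict[str, str]]             # taxon -> gene -> aa string
    variable_sites: dict[str, list[int]]          # per gene, free-to-vary columns
    substituted_columns: dict[str, set[int]]      # per gene, columns actually hit
    total_width: int


def evolve_sequences(tree: SimNode, config: SimulationConfig) -> SequenceEvolution:
    """Evolve per-gene amino-acid sequences down the tree.

    Each branch draws Poisson(subs_len * gene_length) substitution
    events targeting the gene's free-to-vary sites with uniform
    replacement; ``realized_len`` on every edge records the realized
    substitution density, later used as the estimated branch length.
    Zero-length branches leave sequences identical to their parent.
    """
    rng = np.random.default_rng([config.seed, 21])
    lengths = config.gene_lengths()
    genes = sorted(lengths)
    total_width = sum(lengths.values())

    root_seq = {
        g: rng.integers(0, 20, size=lengths[g]).astype(np.uint8) for g in genes
    }
    variable_sites = {
        g: sorted(
            rng.choice(
                lengths[g],
                size=max(1, int(round(lengths[g] * config.variable_site_fraction))),
                replace=False,
            ).tolist()
        )
        for g in genes
    }
    var_arrays = {g: np.asarray(v) for g, v in variable_sites.items()}
    substituted: dict[str, set[int]] = {g: set() for g in genes}

    tip_seqs: dict[str, dict[str, np.ndarray]] = {}

    def descend(node: SimNode, seqs: dict[str, np.ndarray]) -> None:
        if node.time_len > 0 or node.subs_len > 0:
            events_total = 0
            for g in genes:
                lam = node.subs_len * lengths[g]
                n_events = int(rng.poisson(lam)) if lam > 0 else 0
                events_total += n_events
                if n_events:
                    seq = seqs[g].copy()
                    sites = rng.choice(var_arrays[g], size=n_events, replace=True)
                    for s in sites:
                        old = seq[s]
                        new = int(rng.integers(0, 19))
                        if new >= old:
                            new += 1
                        seq[s] = new
                        substituted[g].add(int(s))
                    seqs = {**seqs, g: seq}
            node.realized_len = events_total / total_width
        else:
            node.realized_len = 0.0
        if node.is_leaf():
            tip_seqs[node.name] = seqs
        for c in node.children:
            descend(c, seqs)

    for c in tree.children:
        descend(c, root_seq)

    taxa = sorted(tip_seqs)
    alignments = {}
    cds_aa: dict[str, dict[str, str]] = {t: {} for t in taxa}
    gap_rng = np.random.default_rng([config.seed, 22])
    for g in genes:
        rows = []
        for t in taxa:
            aa = "".join(AA_ALPHABET[v] for v in tip_seqs[t][g])
            cds_aa[t][g] = aa
            rows.append(aa)
        if config.gap_fraction > 0:
            rows = _inject_gap_runs(rows, config.gap_fraction, gap_rng)
        alignments[g] = GeneAlignment(g, list(taxa), rows)
    return SequenceEvolution(
        alignments=alignments,
        cds_aa=cds_aa,
        variable_sites=variable_sites,
        substituted_columns=substituted,
        total_width=total_width,
    )


def _inject_gap_runs(rows: list[str], fraction: float, rng) -> list[str]:
    width = len(rows[0])
    n_runs = max(1, int(round(fraction * width / 12)))
    rows = [list(r) for r in rows]
    for _ in range(n_runs):
        taxon = int(rng.integers(0, len(rows)))
        start = int(rng.integers(0, max(1, width - 12)))
        for c in range(start, min(width, start + 12)):
            rows[taxon][c] = "-"
    return ["".join(r) for r in rows]


# --------------------------------------------------------------------------
# Gene-order evolution
# --------------------------------------------------------------------------

@dataclass
class PlantedEvent:
    branch: str
    kind: str
    event: RearrangementEvent
    scope: str  # "pcg" (touches protein-coding genes) or "trna"


def _random_event(
    order: SignedGeneOrder,
    rng: np.random.Generator,
    kinds: Sequence[str],
    weights: Sequence[float],
    trna_only: bool = False,
    max_block: int = 3,
) -> Optional[RearrangementEvent]:
    n = len(order)
    elems = order.elements
    kind = str(rng.choice(list(kinds), p=np.asarray(weights) / np.sum(weights)))
    for _ in range(50):
        if kind == "tdrl":
            if trna_only:
                kind = "transposition"
                continue
            k = int(rng.integers(2, 5))
            picks = rng.choice(np.arange(1, n), size=k, replace=False)
            pattern = [0] * n
            for p in picks:
                pattern[int(p)] = 1
            ev = RearrangementEvent("tdrl", kept_pattern=tuple(pattern))
        else:
            blen = int(rng.integers(1, max_block + 1))
            i = int(rng.integers(1, n - blen + 1))  # never move the anchor at 0
            j = i + blen - 1
            if trna_only and any(
                not elems[t].lstrip("-").startswith("trn") for t in range(i, j + 1)
            ):
                continue
            if kind == "reversal":
                ev = RearrangementEvent("reversal", segment=(i, j))
            else:
                k = int(rng.integers(1, n - blen + 1))
                if k == i:
                    continue
                ev = RearrangementEvent(kind, segment=(i, j), insert_at=k)
        derived = apply_event(order, ev)
        if not orders_equivalent(order, derived):
            return ev
    return None


def plant_events(
    order: SignedGeneOrder,
    n_events: int,
    rng: np.random.Generator,
    kinds: Sequence[str] = ("transposition", "reversal", "reverse_transposition", "tdrl"),
    weights: Sequence[float] = (0.5, 0.2, 0.15, 0.15),
    max_block: int = 3,
) -> tuple[SignedGeneOrder, list[RearrangementEvent]]:
    """Plant ``n_events`` independent events on a gene order.

    Independence is enforced directly: the composed result must not be
    reachable in fewer events (checked against single-event
    classification and one-step TDRL reachability for ``n_events == 2``),
    so the planted count is the true parsimony cost.  At most one TDRL
    is planted per scenario — two stacked whole-genome TDRLs are not
    identifiable at small depth and are vanishingly rare per branch.
    """
    for _attempt in range(200):
        cur = order
        events = []
        used_tdrl = False
        ok = True
        for _ in range(n_events):
            ks, ws = list(kinds), list(weights)
            if used_tdrl and "tdrl" in ks:
                ws = [w if k != "tdrl" else 0.0 for k, w in zip(ks, ws)]
            ev = _random_event(cur, rng, ks, ws, max_block=max_block)
            if ev is None:
                ok = False
                break
            if ev.kind == "tdrl":
                used_tdrl = True
            events.append(ev)
            cur = apply_event(cur, ev)
        if not ok:
            continue
        if orders_equivalent(order, cur):
            continue
        if n_events >= 2:
            if classify_single_event(order, cur) is not None:
                continue
            if tdrl_reachable(order, cur)[0]:
                continue
        return cur, events
    raise RuntimeError("could not plant independent events")


def evolve_gene_orders(
    tree: SimNode, config: SimulationConfig
) -> tuple[dict[str, SignedGeneOrder], list[PlantedEvent]]:
    """Evolve full 36-gene orders down the tree.

    Clade-A branches receive tRNA-only transpositions (their
    protein-coding order stays frozen); clade-B branches additionally
    draw strand-preserving PCG events (transpositions and TDRLs) at the
    configured Poisson rate.  Every event is logged with the branch it
    occurred on.
    """
    rng = np.random.default_rng([config.seed, 31])
    log: list[PlantedEvent] = []
    orders: dict[str, SignedGeneOrder] = {}
    counter = {"n": 0}

    def branch_id(node: SimNode) -> str:
        counter["n"] += 1
        return node.name or f"branch{counter['n']:03d}"

    kinds = sorted(config.event_kind_weights)
    weights = [config.event_kind_weights[k] for k in kinds]

    def descend(node: SimNode, order: SignedGeneOrder) -> None:
        bid = branch_id(node)
        if node.clade in ("Teredinidae", "Xylophagaidae", "outgroup"):
            n_trna = rng.poisson(config.trna_event_rate * max(node.time_len, 0.0))
            for _ in range(int(n_trna)):
                ev = _random_event(
                    order, rng, ["transposition"], [1.0], trna_only=True
                )
                if ev is not None:
                    order = apply_event(order, ev)
                    log.append(PlantedEvent(bid, ev.kind, ev, "trna"))
            if node.clade == "Xylophagaidae":
                n_pcg = rng.poisson(config.pcg_event_rate * max(node.time_len, 0.0))
                for _ in range(int(n_pcg)):
                    ev = _random_event(order, rng, kinds, weights)
                    if ev is not None:
                        order = apply_event(order, ev)
                        log.append(PlantedEvent(bid, ev.kind, ev, "pcg"))
        if node.is_leaf():
            orders[node.name] = SignedGeneOrder(node.name, order.elements)
        for c in node.children:
            descend(c, order)

    ancestral = SignedGeneOrder("ancestor", ANCESTRAL_ORDER)
    for c in tree.children:
        descend(c, ancestral)
    return orders, log


# --------------------------------------------------------------------------
# Genome synthesis
# --------------------------------------------------------------------------

_BACK_TABLE: dict[str, tuple[list[str], list[str]]] = {}


def _back_table() -> dict[str, tuple[list[str], list[str]]]:
    if not _BACK_TABLE:
        by_aa: dict[str, list[str]] = {}
        for codon, aa in _TABLE5.forward_table.items():
            by_aa.setdefault(aa, []).append(codon)
        for aa, codons in by_aa.items():
            gc_end = sorted(c for c in codons if c[2] in "GC")
            at_end = sorted(c for c in codons if c[2] in "AT")
            _BACK_TABLE[aa] = (gc_end, at_end)
    return _BACK_TABLE


def _back_translate(aa: str, gc3: float, rng: np.random.Generator) -> str:
    table = _back_table()
    out = []
    for res in aa:
        gc_end, at_end = table[res]
        use_gc = rng.random() < gc3
        pool = gc_end if (use_gc and gc_end) or not at_end else at_end
        out.append(pool[int(rng.integers(0, len(pool)))])
    out.append("TAA")
    return "".join(out)


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Skew-balanced random DNA: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


_HAIRPIN_ARM = "GCGGACGTCGCC"  # 12 bp stem arm, GC-rich
_HAIRPIN_LOOP = "TTTTTTTT"


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _planted_igr(n: int, kind: str, gc: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """IGR carrying a skew switch plus a T-rich hairpin at its center.

    OriH: C-rich upstream, G-rich downstream (a GC-walk minimum);
    OriL: mirrored (a GC-walk maximum).  Returns (sequence, switch offset).
    """
    half = n // 2
    rich, lean = 0.48, 0.02  # strong one-letter excess, A/T balanced
    if kind == "OriH":
        p_up = [(1 - rich - lean) / 2, rich, lean, (1 - rich - lean) / 2]
    else:
        p_up = [(1 - rich - lean) / 2, lean, rich, (1 - rich - lean) / 2]
    p_down = [p_up[0], p_up[2], p_up[1], p_up[3]]
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = np.concatenate([
        rng.choice(acgt, size=half, p=np.asarray(p_up) / sum(p_up)),
        rng.choice(acgt, size=n - half, p=np.asarray(p_down) / sum(p_down)),
    ])
    hairpin = _HAIRPIN_ARM + _HAIRPIN_LOOP + _revcomp(_HAIRPIN_ARM)
    hp = np.frombuffer(hairpin.encode(), dtype=np.uint8)
    # hairpin sits beside the switch so the skew contrast stays undiluted
    pos = min(max(0, half + 40 - len(hp) // 2), n - len(hp))
    seq[pos : pos + len(hp)] = hp
    return seq, half


def synthesize_genomes(
    orders: dict[str, SignedGeneOrder],
    sequences: SequenceEvolution,
    config: SimulationConfig,
    clade_map: dict[str, str],
) -> tuple[list[tuple[MitoGenome, AnnotationSet]], dict[str, dict]]:
    """Assemble annotated genomes from gene orders and evolved CDSs.

    Genes are laid on the plus strand in each taxon's order, separated
    by IGRs sized to hit a per-taxon target genome size drawn from the
    configured range (clamped below at gene content plus the planted-IGR
    reserve); per-taxon GC targets are clade mean + Gaussian noise,
    realized through third-codon-position bias and the free (RNA + IGR)
    base composition.  Planted origin IGRs receive a composition switch
    and a T-rich hairpin; the truth log records their labels and
    positions.  Returns (records, ori_truth).
    """
    rng = np.random.default_rng([config.seed, 41])
    records = []
    ori_truth: dict[str, dict] = {}
    lo, hi = config.genome_size_range
    lengths = config.gene_lengths()

    for taxon in sorted(orders):
        order = orders[taxon]
        clade = clade_map.get(taxon, "outgroup")
        ci = 0 if clade == "Teredinidae" else 1
        gc_target = rng.normal(config.gc_means[min(ci, 1)], config.gc_sds[min(ci, 1)]) / 100.0
        gc_target = float(np.clip(gc_target, 0.15, 0.7))

        plant = dict(config.ori_plant.get(clade, {}))
        plant_after: dict[str, str] = {}
        for kind in ("OriH", "OriL"):
            gene = plant.get(kind)
            if gene:
                plant_after[gene] = kind

        # per-gene nucleotide sequences
        gene_nt: dict[str, str] = {}
        keys = [e.lstrip("-") for e in order.elements]
        for key in keys:
            if key in PCG_WEIGHTS:
                gene_nt[key] = _back_translate(
                    sequences.cds_aa[taxon][key], gc_target, rng
                )
            elif key in RNA_LENGTHS:
                gene_nt[key] = _random_dna(RNA_LENGTHS[key], gc_target, rng).tobytes().decode()
            else:
                gene_nt[key] = _random_dna(TRNA_LENGTH, gc_target, rng).tobytes().decode()
        coding_total = sum(len(s) for s in gene_nt.values())

        n_gaps = len(keys)
        reserved = {
            i: config.ori_igr_reserve
            for i, key in enumerate(keys)
            if key in plant_after
        }
        min_size = coding_total + sum(reserved.values()) + n_gaps
        if hi < min_size:
            raise ValueError(
                f"genome_size_range max {hi} below gene content {min_size}"
            )
        target = int(rng.integers(max(lo, min_size), hi + 1))
        spare = target - coding_total - sum(reserved.values())
        alloc = rng.multinomial(spare, np.ones(n_gaps) / n_gaps)
        igr_sizes = [int(alloc[i]) + reserved.get(i, 0) for i in range(n_gaps)]

        # free-composition GC solved so the whole genome hits its target
        pcg_nt = "".join(gene_nt[k] for k in keys if k in PCG_WEIGHTS)
        pcg_gc = pcg_nt.count("G") + pcg_nt.count("C")
        rna_len = sum(len(gene_nt[k]) for k in keys if k not in PCG_WEIGHTS)
        free_len = rna_len + sum(igr_sizes)
        q = (gc_target * target - pcg_gc) / max(free_len, 1)
        q = float(np.clip(q, 0.05, 0.9))
        for key in keys:  # regenerate RNA genes at the solved composition
            if key in RNA_LENGTHS:
                gene_nt[key] = _random_dna(RNA_LENGTHS[key], q, rng).tobytes().decode()
            elif key not in PCG_WEIGHTS:
                gene_nt[key] = _random_dna(TRNA_LENGTH, q, rng).tobytes().decode()

        parts: list[str] = []
        feats: list[GeneFeature] = []
        pos = 0
        taxon_ori: dict[str, dict] = {}
        for i, elem in enumerate(order.elements):
            key = elem.lstrip("-")
            strand = "-" if elem.startswith("-") else "+"
            seq = gene_nt[key]
            if strand == "-":
                seq = _revcomp(seq)
            cls = (
                "PCG" if key in PCG_WEIGHTS
                else "rRNA" if key in RNA_LENGTHS
                else "tRNA"
            )
            feats.append(GeneFeature(key, cls, pos, pos + len(seq), strand))
            parts.append(seq)
            pos += len(seq)
            glen = igr_sizes[i]
            if glen <= 0:
                continue
            if key in plant_after and glen >= 2 * config.ori_igr_reserve // 3:
                kind = plant_after[key]
                igr_seq, switch = _planted_igr(glen, kind, q, rng)
                next_key = order.elements[(i + 1) % len(order.elements)].lstrip("-")
                taxon_ori[kind] = {
                    "igr_label": f"{key}-{next_key}",
                    "position": pos + switch,
                }
                parts.append(igr_seq.tobytes().decode())
            else:
                parts.append(_random_dna(glen, q, rng).tobytes().decode())
            pos += glen
        genome = MitoGenome(
            record_id=taxon,
            sequence="".join(parts),
            taxon_label=taxon,
            clade=clade,
        )
        for kind in ("OriH", "OriL"):
            taxon_ori.setdefault(kind, {"igr_label": "ND", "position": None})
        ori_truth[taxon] = taxon_ori
        records.append((genome, AnnotationSet(taxon, feats)))
    return records, ori_truth


# --------------------------------------------------------------------------
# Full-study orchestration
# --------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: SimulationConfig
    tree: SimNode
    clade_map: dict[str, str]
    subclade_map: dict[str, str]
    records: list[tuple[MitoGenome, AnnotationSet]]
    alignments: dict[str, GeneAlignment]
    orders: dict[str, SignedGeneOrder]
    event_log: list[PlantedEvent]
    ori_truth: dict[str, dict]
    sequences: SequenceEvolution

    @property
    def estimated_tree_newick(self) -> str:
        return self.tree.newick("realized_len")

    @property
    def true_tree_newick(self) -> str:
        return self.tree.newick("subs_len")


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete two-clade study with ground truth."""
    tree = simulate_tree(config)
    cmap = clade_map_of(tree)
    sequences = evolve_sequences(tree, config)
    orders, log = evolve_gene_orders(tree, config)
    records, ori_truth = synthesize_genomes(orders, sequences, config, cmap)
    return SyntheticStudy(
        config=config,
        tree=tree,
        clade_map=cmap,
        subclade_map=subclade_map_of(tree, config),
        records=records,
        alignments=sequences.alignments,
        orders=orders,
        event_log=log,
        ori_truth=ori_truth,
        sequences=sequences,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Emit the study bundle as plain-text files (FASTA/TSV/Newick/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_records(study.records, outdir / "genomes.fasta")
    from mitocompare.supermatrix import write_alignment_fasta

    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for gene, aln in sorted(study.alignments.items()):
        write_alignment_fasta(aln, aln_dir / f"{gene}.faa")
    (outdir / "tree_estimated.nwk").write_text(study.estimated_tree_newick + "\n")
    (outdir / "tree_true.nwk").write_text(study.true_tree_newick + "\n")
    with open(outdir / "clades.tsv", "w", encoding="utf-8") as fh:
        fh.write("record_id\tclade\n")
        for t, c in sorted(study.clade_map.items()):
            fh.write(f"{t}\t{c}\n")
    truth = {
        "seed": study.config.seed,
        "ori": study.ori_truth,
        "events": [
            {
                "branch": e.branch,
                "kind": e.kind,
                "scope": e.scope,
                "segment": e.event.segment,
                "insert_at": e.event.insert_at,
                "kept_pattern": e.event.kept_pattern,
            }
            for e in study.event_log
        ],
        "orders": {t: list(o.elements) for t, o in sorted(study.orders.items())},
        "variable_sites": study.sequences.variable_sites,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return outdir
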