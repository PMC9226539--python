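# Methods

This note documents the models and procedures `mitocompare` implements,
the tunable parameters that matter, and the design decisions taken where
the problem left genuine freedom. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Signed circular gene orders and rearrangement inference

A genome's gene order is a signed circular permutation of gene keys
(sign = strand). Orders are compared up to rotation **and** reflection:
the linearization anchor (default `cox1`, positive) is an artifact of
how a circular molecule is written down. `canonicalize` reflects the
order first if the anchor is on the minus strand, then rotates it to
the front.

**Breakpoint distance.** Adjacencies are signed circular pairs
`(u, v)`, identified with `(-v, -u)` under reflection; the distance is
the number of adjacencies of one order absent from the other. It is
symmetric, zero exactly on rotation/reflection equivalence, and a
single event changes at most three adjacencies, so `ceil(bd/3)` lower
bounds any scenario cost built from reversals and transpositions.

**Event model.** Four event classes, matching the vocabulary of
common-interval tools such as CRex: reversal (block inverted in place,
signs flip), transposition (block excised and reinserted),
reverse transposition (both), and whole-genome tandem
duplication–random loss (TDRL). TDRL is modelled classically: the whole
circle is duplicated in tandem and one copy of each gene is lost, so an
applied TDRL is fully described by a 0/1 `kept_pattern` (which copy
each gene survives in) and its result is the copy-0 genes in source
order followed by the copy-1 genes. Segmental TDRL is out of scope.

The classes overlap (every transposition is a TDRL; a reverse
transposition of a sign-symmetric block equals a reversal), so
classification uses the fixed priority
`reversal > transposition > reverse_transposition > tdrl` — the more
specific, orientation-aware explanation is preferred and output is
deterministic.

**Single-event classification** is direct rather than enumerative: the
mismatch window between the two orders admits only O(n) candidate
reversals and O(n) candidate block splits for (reverse) transpositions,
each verified by application; TDRL reachability in one step is a
prefix/suffix monotonicity test on source positions. If direct
detection fails on the given linearization, all rotations and the
reflection of the target are retried, so events that move the anchor
are still found.

**`tdrl_reachable`** answers the one-step question in its general form:
the target must be partitionable into at most two disjoint
subsequences, each in the source's relative order, and TDRL never
changes orientation. A greedy best-fit assignment into increasing
subsequences (optimal by the patience-sorting/Dilworth argument)
produces the witness; the test suite checks it against exhaustive
2-coloring for every permutation up to n = 7.

**Scenario search** is iterative-deepening DFS with unit event costs,
deterministic candidate order (kind priority, then leftmost then
shortest segment, then insertion point), and pruning by the breakpoint
bound on non-TDRL branches. Because TDRL candidates are exponential to
enumerate (2^n kept patterns), TDRLs are detected only as the **first**
event (via an inverse step from the target, depth 2) or the **last**
event (via the terminal classification) of a scenario. Consequences:
a TDRL strictly interior to a ≥3-event scenario can make a pair
"unresolved", and `optimal_flag` is claimed only when the shallower
depths were exhausted without bound-pruning. The default `max_depth`
is 4; deeper exhaustive search at n = 12 is not attempted, and an
unresolved pair reports its breakpoint lower bound instead of a guess.

**Ancestral order proposal** is parsimony-among-observed: the extant
order minimizing the summed scenario cost to all others (unresolved
pairs contribute their lower bound), ties broken toward the order
shared by most records, then the smallest record id. This is a
heuristic, not a median-genome solver; with one clade frozen and the
other a few events away it returns the frozen order.

## 2. Replication-origin prediction

Replication origins in animal mitogenomes co-locate with abrupt
changes in strand composition bias and with stable hairpins whose loop
is T-rich. Both signals are scored explicitly; a manual skew-graphing plus
fold-inspection workflow is replaced by a
deterministic procedure.

**DNA walks.** `walk_gc[i]` is cumulative #G − #C over the first `i`
bases (likewise `walk_at`); N contributes 0. The slope-contrast series
`delta(p)` is the mean per-base skew of the following `window` bases
minus that of the preceding `window` bases (circular), with
`window = 100` bp — wide enough to average codon-level noise, narrow
enough to localize an origin within a typical intergenic region (IGR).
All walk computations run on an anchor-gene-rotated linearization, so
every output is invariant to how the deposited sequence was rotated.

**Inflection detection.** An extremum of the cumulative walk is a peak
of `|delta|`; candidates are local maxima of `|delta|` under
non-maximum suppression (radius = `window`), scored as
`|delta| / (sqrt(2/window) * sd(per-base skew))` — the contrast in
units of the sampling spread a composition-homogeneous genome would
show. (An earlier formulation located extrema via sign changes of
`delta`; those occur ~`window` bp away from the extremum and
mislocalize the switch, hence the peak-based definition.)

**Hairpin scan.** All maximal inverted repeats with stem ≥ 10 bp,
≤ 2 mismatched pairs and loop 3–30 nt, scored by the integer pair
count `2·GC + 1·AT − mismatches`. No nearest-neighbor thermodynamics:
the score only ranks candidates, and determinism matters more than
kcal/mol here. Only hairpins whose loop is ≥ 60% T count as origin
evidence — loop T-richness, not stem stability, is what separates
origin hairpins from the inverted repeats any AT-rich genome contains
by chance.

**Calls.** Candidates are inflections inside an IGR (or within
`window` bp, snapped); each IGR contributes only its dominant
inflection, because a composition switch inside an origin IGR also
produces weaker opposite-polarity steps at the IGR's edges which must
not double-report. The composite score is

    composite = 0.25 * inflection_score
              + 1.00 * min(best_stability / 20, 1)   (T-rich hairpins only)
              + 1.00 * loop_T_fraction

and a side is called when its best candidate reaches 2.0, else "ND".
The inflection weight comes from an extreme-value argument: the
genome-wide maximum of the null contrast is ~3.5–4.5 sd for a 15–19 kb
genome, so a composition step alone must not clear the threshold — a
call requires hairpin corroboration. By default candidates at GC-walk
minima compete for OriH and maxima for OriL; which polarity marks OriH
is a configuration option (`orih_polarity`) because the convention
depends on which strand was deposited.

All thresholds (`window`, `min_stem`, loop bounds, mismatches,
`t_rich_min`, weights, call threshold) are fields of `OriParams`.

## 3. Supermatrix and rates

**Translation** uses NCBI table 5 (invertebrate mitochondrial):
ATA→M, TGA→W, AGA/AGG→S. A 1–2 nt trailing remainder is dropped with a
warning (polyadenylation-completed stop convention), a terminal stop is
stripped, and an internal stop is an error unless explicitly allowed
(then "X") — silent read-through would mask annotation errors.

**Block selection** restates the published Gblocks defaults as an
explicit contract. With N rows: a column is *conserved* if one residue
occurs in ≥ floor(N/2)+1 rows, *highly conserved* if ≥ ceil(0.85·N);
any gap makes a column nonconserved, and gap columns are never kept.
Maximal runs of > 8 contiguous nonconserved columns are removed;
remaining segments are trimmed so both flanks are highly conserved and
survive only at length ≥ 10. Fewer than 4 rows is an error: the
majority thresholds are meaningless below that.

**Concatenation** gap-fills taxa missing a gene (default) or
intersects taxa; partitions are emitted and round-trip through a
RAxML-style partition file (1-based inclusive on disk).

**Rates.** Alignment and tree inference are inputs, not computations:
the package consumes aligned matrices and rooted Newick trees with
branch lengths. The per-tip rate proxy is the branch-length path from
the MRCA of the two focal clades to the tip; clade aggregates cover
the two focal clades only. Clade means are compared with Welch's
two-sample *t*-test (a paired test is undefined for unequal group
sizes; Student's pooled test is available as a switch), Bonferroni
factor = number of properties tested in the call (default property set:
genome size, GC%, rate). Subclade contrasts use the Kruskal–Wallis
*H*-test with tie correction and the χ² approximation.

**Percent coding** counts positions covered by any annotated feature
(PCG + rRNA + tRNA) once, after truncating overlapping annotations at
the overlap midpoint — so percent noncoding equals the IGR fraction
and the two always sum to 100.

## 4. The synthetic-data generator

The generator produces the study the analyses assume, with every
planted signal logged:

- **Geometry**: 26 + 16 taxa in two sister clades plus a 3-taxon
  outgroup; circular genomes drawn from 14,450–18,624 bp (clamped
  below at actual gene content, ~15.6 kb at the default supermatrix
  width); 12 PCGs + 22 tRNAs + 2 rRNAs, all plus-strand; no atp8.
- **Tree**: random ultrametric topologies per clade under a fixed-age
  family MRCA (age 1.0); the fast clade splits into 16 + 10 subclades.
  Substitution rates per branch: fast clade `base_rate × rate_ratio`
  (default 1.55 × 1.4 ≈ 2.17 subs/site root-to-tip), slow clade
  `base_rate`, with a 1.27-fold subclade contrast inside the fast
  clade normalized to keep the clade mean. Branch-rate noise is a
  mean-one lognormal whose log-sd grows as sqrt(branch time)
  (log-sd 0.06 per unit time) — a geometric-diffusion choice made
  once from a variance budget: i.i.d. per-branch noise concentrates on
  the two clade stems and makes the clade-ratio estimate swing far
  more than the 10% recovery tolerance, while the diffusion form keeps
  per-tip spread realistic and clade means stable.
- **Sequences**: uniform amino-acid exchange with per-branch Poisson
  substitution counts restricted to a free-to-vary 30% of sites. This
  is deliberately not an empirical substitution model: the study's
  target is rate *contrasts*, and a uniform process is analytically
  checkable. The emitted "estimated" tree carries realized per-branch
  substitution densities (events / width) as branch lengths — an
  idealized well-estimated ML tree, since tree inference is out of
  scope. Per-gene lengths follow realistic animal-mitogenome
  proportions scaled to a 4,135-column target.
- **Gene orders**: the slow clade keeps the ancestral protein-coding
  order (tRNA-only transpositions allowed, Poisson 0.1/branch-time);
  fast-clade branches additionally draw strand-preserving PCG events
  (transpositions 0.8 / TDRLs 0.2, Poisson 0.25/branch-time). Only
  strand-preserving kinds are planted because every observed genome in
  the motivating system is single-strand; reversals and reverse
  transpositions are exercised by `plant_events` in the accuracy
  studies. `plant_events` enforces event independence directly — the
  composed result must not be reachable in fewer events — so the
  planted count is the true parsimony cost, and plants at most one
  TDRL per scenario (stacked whole-genome TDRLs are outside the
  search's documented scope).
- **Composition**: per-taxon GC targets are clade mean ± Gaussian
  (defaults 40.7% / 38.5%, sd 1.2 / 1.5), realized through
  third-codon-position bias and the free (RNA + IGR) composition
  solved per genome. The spreads are chosen so the GC contrast carries
  the significance structure the study design calls for under
  Welch + Bonferroni; the wider spreads of the real tables would leave
  that contrast underpowered at these sample sizes. All random
  sequence is G/C- and A/T-balanced so signal-free genomes are
  genuinely skew-free.
- **Origins**: planted origin IGRs (reserved ≥ 300 bp) carry a strong
  composition switch (±0.46 G−C per base, halves mirrored; OriH as a
  GC-walk minimum, OriL as a maximum) plus a 12 bp-stem, 8×T-loop
  hairpin placed beside the switch. The slow clade gets OriH
  (downstream of cob) and OriL (downstream of cox1); the fast clade
  OriH only — its OriL truth is "ND". Truth labels record the actual
  flanking genes, so tRNA repositioning changes the label exactly as
  it would in real annotations.

Everything is deterministic under `SimulationConfig.seed`; the bundle
(FASTA, feature TSV, per-gene alignments, Newick, ground-truth JSON)
is byte-identical across reruns.

**What passing tests do and do not show.** The generator has uniform
exchangeability, no indels by default, no selection, no compositional
strand asymmetry outside planted origins, and genuinely conserved
sites are perfectly conserved. Success on it demonstrates the
*machinery* — oracle exactness, parsimony, signal recovery, the
statistical pipeline — not robustness to alignment error, saturation,
heterotachy, or annotation noise in real data.

## 5. Numerical and interface choices

- Coordinates are 0-based half-open on the forward strand everywhere;
  GenBank input converts on read. Features crossing the sequence
  origin are stored with `wraps_origin` and handled by rotation.
- Overlapping annotations are truncated at the overlap midpoint for
  coverage/IGR purposes only; original coordinates are preserved.
- Unknown gene names are kept with class `unknown` and excluded from
  gene-order analysis (`strict_names` turns them into errors).
- Problem sizes in the tests and acceptance script — 13-genome
  ori batches (~100 genomes per condition), 500 scenario trials,
  100 significance replicates — were chosen as the smallest sizes at
  which the binomial uncertainty of the measured rates is well inside
  the margins being demonstrated.
- Reports embed seed and config hash; reruns are byte-identical.

## 6. Known limitations

- Scenario search is exact only to `max_depth`, TDRL only at scenario
  ends; costs beyond that are lower bounds, and no equivalence with
  CRex's strong-interval-tree output is promised beyond the shared
  event vocabulary.
- Hairpin stability is a pair count, not free energy; candidate
  ranking can differ from a thermodynamic fold.
- The rate stage trusts the input tree; branch-length estimation error
  propagates directly into the per-tip rates.
- `compare_families` treats genomes as independent observations, as
  the motivating analysis did; no phylogenetic correction (PGLS or
  independent contrasts) is applied.
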