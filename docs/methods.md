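# Methods

This note documents the models and procedures implemented in `panbgc`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the conventional workflow leaves
the details to external tools.

## Problem setting

Collections of closely related bacterial genomes (the motivating case:
*Xenorhabdus* and *Photorhabdus*, two genera of insect-pathogenic symbionts)
carry dozens of natural-product biosynthetic gene clusters (BGCs) per
genome. Two complementary decompositions expose their structure: a
**pangenome** view (which gene families are shared by all, some, or one
genome) and a **similarity network** view (which BGCs belong to the same
gene cluster family, GCF, and which GCFs match experimentally characterised
reference clusters). `panbgc` implements both and their integration as one
deterministic pipeline.

## Homology groups

Pairwise protein similarity is exact global alignment identity
(Needleman–Wunsch; match +1, mismatch −1, linear gap −1; identity =
identical aligned positions / alignment length). Traceback ties are broken
diagonal > up > left, which pins a unique optimal alignment and makes the
reported identity well defined. At desk scale (hundreds to a few thousand
proteins) the O(n²·L²) cost is affordable and removes any dependence on an
external search binary. A BLAST-like seeding prescreen (skip pairs sharing
no exact 4-mer) is on by default in the all-vs-all stage: two unrelated
random proteins essentially never share a 4-mer, while family members at
the divergence levels considered here essentially always do. It can be
disabled (`prescreen_kmer=None`) to recover the literal
edge-iff-identity≥threshold contract on adversarial inputs.

Edges below `min_similarity` (default 0.35, the conventional
protein-homology twilight-zone floor) are dropped. Markov clustering then
runs per connected component on the dense column-stochastic matrix with
self-loops (loop weight = max incident weight, 1.0 for isolated nodes):
expansion (matrix square), inflation (elementwise power, default **8**, the
aggressive family-splitting setting used in pangenomics), column
renormalisation, pruning of entries < 1e−5, to convergence (max-norm
difference < 1e−6, cap 200 iterations; hitting the cap emits a warning and
the current partition, recorded in provenance). Clusters are read off
attractor rows; a node on several attractors goes to the attractor holding
the most of its column mass, ties to the lowest node index, and mutually
owning attractors merge. Node order is lexicographic gene id throughout, so
results are platform-stable.

## Pangenome bins, homogeneity, trees

A homology group in all *N* genomes is **core**, in exactly one (for
*N* > 1) **singleton**, otherwise **accessory**; with a single-genome
collection everything is core. Single-copy core groups additionally require
one gene per genome and pass two index filters whose exact formulas are our
reconstruction (the upstream pangenomics tooling publishes only threshold
values, not formulas):

- **Functional homogeneity** — over all alignment columns and unordered
  sequence pairs with both residues non-gap, the fraction of pairs sharing
  a chemical class under the fixed partition hydrophobic AVLIMC / aromatic
  FWY / polar STNQ / positive KRH / negative DE / special GP. Groups with
  FH > 0.9 are *excluded*: near-identical groups carry no phylogenetic
  signal.
- **Geometric homogeneity** — 1 − (mean pairwise Hamming distance between
  gap/non-gap masks)/L; the filter requires GH = 1, i.e. congruent gap
  structure (trivially true for the generator's ungapped families).

Groups of equal-length members are treated as trivially aligned; an
unequal-length pair is globally aligned, and larger unequal groups use a
longest-member star alignment — full multiple alignment is deliberately out
of scope.

Genome trees: (1) mean per-site difference fraction over scg groups,
Jukes–Cantor corrected (protein form *d* = −(19/20)·ln(1 − 20*p*/19),
saturating at *p* = 19/20; nucleotide form available), then UPGMA;
(2) Jaccard distance between genome presence/absence columns, then UPGMA.
UPGMA uses size-weighted average updates, heights = half the merge
distance (so the output is ultrametric by construction), and breaks ties on
the lexicographically smallest label pair. An all-zero genome column sits
at distance 1 from everything (logged). Whether the original interactive
workflow used Jaccard or another metric for its dendrogram is not
published; Jaccard + UPGMA is our documented, configurable choice.

## BGC integration

**Boundary trimming.** A region's boundary is redefined as [start of first
biosynthetic gene, stop of last biosynthetic gene] within the raw interval;
peripheral non-structural genes (transporters, regulators, transposases)
thereby fall outside. Regions with no biosynthetic gene are flagged
untrimmable and dropped with a logged reason. Known false-positive
annotations (e.g. a ribosomal-methylthiolation locus misannotated as a
thiopeptide cluster) are handled by per-genome exclusion lists in the
metadata, or `--exclude` on the command line — never silently.

**Gene linking.** A gene is a biosynthetic gene (BG) iff its interval is
fully contained in a trimmed boundary on the same contig ("fell within" is
read as full containment: partially overlapping edge genes are exactly the
peripheral genes the boundary rule excludes). Strand is carried but ignored
by containment. Regions on one contig must not overlap.

**Conserved runs.** Genes are taken in positional order per contig; a run
is a maximal stretch of same-bin BGs tolerating up to `max_gap` (default 1)
intervening non-qualifying genes; runs shorter than `min_run` (default 3)
are discarded. Runs from different genomes are linked into one conserved
cluster when their homology-group signatures share an ordered common
subsequence (forward or reversed, tolerating local strand flips) of length
≥ `min_run`; a plain set-overlap mode is available. A cluster is reported
when it spans ≥ `min_genome_fraction` (default 1.0) of the genomes. The
defaults replace what was a manual spreadsheet-sorting step in conventional
practice with an explicit, reproducible algorithm; the implicit
consecutiveness parameters of that manual step are not published, so these
defaults are documented choices.

**Prevalence.** Per (GCF, genus): floor(100 · carriers / genus size), as an
integer percent. Truncation is deliberate: the printed convention in this
field reports 28/29 as 96 % and 15/16 as 93 %, both floor values.

## GCF network

Each BGC is an ordered profile of domain families. We use the homology
groups of its member genes as families (the conventional Pfam-domain
content requires HMM scanning, which is out of scope; users may supply
domain columns directly). The composite distance is

d(A,B) = 1 − (0.2·J + 0.05·AI + 0.75·DSS)

with J = Jaccard of family sets; AI = Jaccard of the sets of unordered
adjacent-family pairs (both-empty → 1); DSS = mean representative-sequence
identity over shared families × (shared / total distinct families).
Weights follow the mixed-mode convention of BGC similarity networking and
are configurable. The distance is a bounded semimetric (d(a,a)=0,
symmetric; the triangle inequality is not asserted). Edges with d ≤ cutoff
(default **0.65**) define GCFs as connected components; a sweep over
0.30–0.95 in steps of 0.05 is reported. Reference (MIBiG-like) clusters
join the network after their families are mapped onto the collection's
homology groups by best representative identity (≥ `min_similarity`);
unmatched reference families keep private ids and cannot create spurious
similarity. Components containing only references are not counted as GCFs.

Classification precedence: **fragmented** (contig-edge regions —
incompletely observed) > **known** (component contains a reference, or the
BGC is on a curated experimentally-identified list) > **unknown**. The
summary reports GCF counts both with and without reference connections
(isolated clades = size-≥2 components without references; singletons =
single-member components), since "family count" is ambiguous between the
two conventions.

All percentages and per-genome averages in reports are truncated to
integers, consistent with the prevalence convention.

## Synthetic data generator

The generator emulates the statistical structure of a two-genus, 45-genome
style collection at desk scale. Defaults — chosen once as the study
conditions for all tests and the acceptance script — are: 12 genomes
(7 genus *X* + 5 genus *P*, mirroring a 29:16 two-genus design), 40 core +
60 accessory (presence probability 0.5) + 20 singleton families, protein
length 60 residues, within-family substitution rate 0.05 (each site
independently replaced by a uniformly chosen different residue; no indels),
and three planted GCF templates: a conserved known NRPS (5 structural + 2
peripheral genes, prevalence 1.0 in both genera, emitted as a reference
cluster), a widespread unknown PKS/NRPS hybrid (4+2, prevalence 0.6/0.8)
and a *P*-specific RiPP (3+1, prevalence 0/1.0). Ancestral family sequences
are i.i.d. uniform over the 20 residues, maximising inter-family distance
so that clustering failures are attributable to the algorithm, not the
generator. Genes are laid consecutively (50-bp spacer, one contig per
genome, gene length 3 × protein length); each planted BGC is a consecutive
block with peripherals flanking the structural run, and the raw region
interval spans the whole block so that boundary trimming has real work to
do. Carrier counts per genus are round(prevalence × n); the truth sidecar
records the *realised* fractions and realised bins, which is what the
pipeline must recover.

What the generator does **not** emulate: indels and alignment gaps (an
optional concern the homogeneity indices would exercise), rate
heterogeneity, paralogy, horizontal transfer beyond presence/absence,
nucleotide-level sequence, multi-contig assemblies and contig-edge
truncation (fragmented classification is exercised with hand-built
fixtures), and overlapping or nested regions. Passing recovery tests on
this generator therefore demonstrates the correctness of the pipeline's
logic under its stated model, not robustness to the full messiness of real
assemblies and annotations.

## Numerical and determinism notes

- Every tie-break (MCL node order and attractor resolution, UPGMA label
  pairs, region ordering, representative choice = smallest gene id) is
  lexicographic; identical config + seed gives byte-identical outputs, and
  the provenance manifest stores a SHA-256 per output file.
- MCL column-stochasticity is restored after every inflation and pruning
  step; convergence is max-norm < 1e−6.
- Jukes–Cantor is clamped just below saturation when averaging pushes an
  scg distance past the domain boundary (logged via the clamp, not an
  error, since the mean of valid per-group distances can still saturate).
- Cluster-count monotonicity of MCL in the inflation parameter is checked
  empirically as a soft property (it is folklore, not a theorem).
- The headline dataset-level numbers of the motivating 45-genome study
  (1,000 BGCs, 176 families, class breakdowns) depend on external
  annotation tools and genome downloads and are not reproduced here; the
  acceptance script instead reproduces the collection-level arithmetic
  (truncated prevalence, shares and averages) from the printed counts used
  as inputs, and measures exact planted-structure recovery on the synthetic
  study conditions. Problem sizes there: 12 genomes, ~1,000 genes, ~25
  regions — sizes at which every stage runs in seconds on one CPU.
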