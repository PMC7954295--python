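# Methods

## Statistics

**Pham assignment.** A pham is the unit of gene-content comparison: a set
of genes whose proteins are related at the amino-acid level. Relatedness
is decided per pair by global alignment with free terminal gaps (match
+1, mismatch 0, gap open −2, gap extend −0.5; all configurable through
`AlignmentScoring`). Identity is the fraction of identical columns among
alignment columns between the first and last position where both
sequences are present (terminal overhangs are free and excluded);
coverage is the fraction of the shorter sequence's residues inside that
window. A pair is similar when identity ≥ 35% *and* coverage ≥ 75%, and
phams are the connected components (single linkage) of the similarity
graph. Single linkage was chosen because it matches the "groups of genes
with related sequences" semantics of pham databases and because it has an
exact independent oracle (transitive closure over all pairwise
comparisons), which the tests exercise. The 35/75 defaults sit near
historical pham-pipeline practice; they are parameters, not claims —
exact reproduction of any external database's pham boundaries is not
promised. Identical sequences are collapsed before alignment (trivially
lossless); no other prescreen is applied, because a k-mer bound that is
provably lossless at these thresholds does not exist (above-threshold
pairs can share no k-mer when matching columns are scattered).

Co-optimal alignments are broken deterministically by the underlying
aligner after sorting the two sequences, so identity is symmetric in
argument order; different co-optimal paths can in principle give slightly
different identity values for borderline pairs, which is why the oracle
tests use the same pairwise routine and differ only in the clustering
route.

**GCS / GCD.** With $A$, $B$ the sets of *distinct* phams in two genomes
(a pham duplicated within one genome counts once — "shared genes in
phams" is set language, and this is how gene-content calculators in this
field behave), $s = |A\cap B|$:

$$\mathrm{GCS} = 100\cdot\tfrac12\!\left(\tfrac{s}{|A|} + \tfrac{s}{|B|}\right),\qquad
\mathrm{GCD} = 1 - \mathrm{GCS}/100 .$$

GCS is symmetric, 100 on the diagonal, and for fixed $s$ and $|A|$
strictly decreasing in $|B|$ — the same number of shared genes scores
higher between smaller genomes, a property asserted directly in the
tests because it matters when clustering communities of unequal genome
sizes.

**MaxGCDGap.** The focal phage's GCD values are sorted ascending and a 0
is prepended (its distance to itself); MaxGCDGap is 100× the largest
difference between consecutive values, reported with the phage whose GCD
closes the gap (ties go to the earlier, smaller-GCD gap). Including the
leading gap is a deliberate reading: it is the only one under which an
isolated phage's gap equals its nearest-neighbour GCD and is located
"between" the focal phage and that neighbour. `gap_from_zero=False`
switches to interior gaps only, since published scripts differ on this
point.

**Clustering.** Clusters are connected components of the GCS ≥ threshold
graph (default 35%); labels C1, C2, … are assigned by descending
component size then lexicographically smallest member, so output is
independent of input order. Raising the threshold only ever splits
components (tested). The legacy nucleotide rule (50% identity / 50%
span) is *approximated* by exact-word span coverage: the percentage of
one genome's positions covered by at least one exact 15-mer match
(either strand) to the other. This errs conservative — a pair passing
the real rule has high word coverage, but coverage claims nothing about
alignment identity — and is used only as a screen; the package
deliberately does not reimplement BLAST-style percent identity.

**Dot plots.** Exact word matching (nucleotide word 15, protein word 5,
following common practice for genome/proteome word plots), exhaustive
over all positions, with reverse-complement matches flagged for
nucleotide plots (on by default; a flag disables it since published
plots do not always state the convention). Concatenated plots join
per-phage segments with a word-length run of `#`, a character outside
both alphabets; any window containing it is skipped, which provably
kills cross-boundary words, and the axis segment table lets callers
attribute every block to a phage pair. Output is coordinates (TSV) plus
an optional coarse text raster; no similarity-matrix (grayscale) mode.

**Phylogeny.** Distances are GCD; the tree is standard Saitou–Nei
neighbor joining with two determinism guarantees: Q-criterion ties are
broken by the lexicographically smallest pair of subtree-minimum taxon
names, and negative branch estimates are clamped to zero. On additive
matrices NJ reproduces all pairwise path lengths exactly (tested to
1e-9 against matrices built by random leaf attachment). Split networks
themselves are out of scope; the NEXUS `DISTANCES` export (lower
triangular, labels sanitized to `[A-Za-z0-9_]` with collisions rejected)
preserves the ability to draw one externally from identical input.

**HGT evidence.** For each gene of a focal genome: GC content (N bases
excluded from the denominator; strand-independent), its deviation from
the genome-wide GC, and the number of distinct isolation hosts among
phages carrying its pham (exact string comparison at the granularity the
metadata provides; no taxonomy normalization). The source analyses
report candidate HGT genes by inspection rather than by a stated rule,
so the flag here is an explicit operationalization — flagged iff GC
deviation ≥ `gc_delta` (default 5 points) **or** host count ≥
`host_min` (default 3) — and the full table ranked by (host count desc,
GC deviation desc) is always emitted so users can apply their own cut.

## The synthetic population generator

The generator produces the data regime this analysis exists for, plus
ground truth (`SyntheticTruth`: pham of every gene, generating cluster
of every phage, implanted HGT genes, per-gene GC targets).

*Gene content.* A pham universe holds reference proteins (uniform random
composition, lengths 140–260 aa, leading M). Each genome's gene list is
built from: a pool shared by **all** clusters (`cross_cluster_share`,
default 0.45 of the non-orpham budget), pair-specific extra pools
(`cross_cluster_extra`, default +0.22 between the second cluster and the
focal phage), a within-cluster core (`core_fraction`, 0.30), per-genome
accessory draws, and `orphams_per_genome` (2) fresh private phams.
Shared pools enter as common prefixes, so pairwise shared counts — and
hence GCS — are controlled by construction rather than left to sampling
noise. The default scenario (clusters of 3, 2 and 1 phage of 24–26
genes each) yields focal-phage GCS ≈ 40% against the far cluster and
≈ 60% against the near one: above the 35% parameter everywhere, above
55% for the near cluster, merging all six genomes into one expanded
cluster while two satellite genomes (below) stay singletons.

*Nucleotides.* Proteins are back-translated with `codon_scramble`: at
each position a minimum-GC or maximum-GC synonymous codon (genetic code
table 11; a stop codon is appended), steering the running GC total
toward a target so realized GC tracks any achievable target to within a
few bases; seeds shuffle position order and tie choices, so one protein
has many nucleotide realizations. Each (pham, cluster) pair gets its own
realization: cluster 0 keeps a base realization and every other cluster
re-draws each codon with probability `synonymous_scramble_rate` (default
1.0, i.e. independent realizations). This reproduces the key signature —
protein identity exactly 100% across clusters while nucleotide identity
collapses to the synonymous baseline (exact-word span coverage ≈ 4–5%,
versus ≈ 80% within clusters at the default 1% within-pham amino-acid
divergence). Genomes are genes joined by 10–50 bp random spacers at the
base GC; one gene per genome is placed on the reverse strand. Genome
lengths land near 15–17 kb, inside the range observed for small
actinobacteriophages.

The base GC target is 52%. Uniform-composition random proteins cap the
synonymous-achievable GC near 60–64%, so a base in the low 50s is needed
to leave headroom for implanted +6-point GC offsets; real phage genomes
in this niche run higher (≈ 64%), which the generator does not imitate
because amino-acid composition, not the codon chooser, is the binding
constraint. Unreachable targets are clamped to the nearest achievable
value with a warning.

*HGT implants.* `hgt_implants` entries (slot, GC offset, extra hosts)
modify the focal genome: GC implants re-realize the gene at slot with
the offset target; host implants give the slot a dedicated pham that is
also carried by small "satellite" genomes (9 genes each, otherwise
private phams), one per extra host, each with a distinct isolation-host
string while the whole main community shares one host. Defaults implant
two +6-point genes and two three-host phams, and the evidence table at
default thresholds flags exactly those four.

*Determinism.* Every phage draws from an RNG stream derived from
(master seed, phage index); the universe and per-pham codon realizations
have their own streams. Populations are byte-identical across runs and
extensible without perturbing existing genomes.

*What passing does and does not show.* The generator has no
recombination breakpoints, no temporal evolution, no realistic codon
usage, uniform amino-acid composition and a substitution-matrix-free
mutation model (uniform over the 19 alternatives — recovery tests need
controlled identity, not realism). Recovery results on it demonstrate
that the pipeline's logic is correct under its assumptions, not that the
default thresholds are optimal for any particular real community.

## Numerical and interface choices

- Coordinates are 1-based inclusive in all files (GenBank convention);
  reverse-strand `nucleotide_seq` is the coding-strand (reverse
  complemented) sequence, asserted base-for-base against the genome
  slice on read.
- Translation uses genetic code table 11 with the terminal stop removed.
- GCS is reported to 2 decimals; test comparisons use absolute
  tolerance 0.005. NJ path-length checks use 1e-9; NEXUS round-trips
  1e-12 (values printed at 6 decimals are exact at that scale).
- Degenerate inputs error early and loudly: empty pham profiles (GCS
  undefined), populations of one (no profile), fewer than three taxa
  (no NJ), sequences shorter than the word, all-N sequences.
- Problem sizes in the shipped tests and acceptance script: populations
  of 8 genomes / ~170 genes for the full scenario, 4–6 genomes for unit
  tests, 20-seed sweeps for recovery — sizes at which every stage's
  exhaustive oracle (brute-force closure, brute-force word enumeration)
  is itself cheap to run.

## Known limitations

- Pham boundaries depend on alignment scoring and thresholds; no attempt
  is made to match any versioned external pham database gene-for-gene.
- The legacy nucleotide rule is screened, not computed: span coverage is
  word-exact and conservative.
- The HGT flag is a transparent OR rule over two signals; it is a
  screen, not a test (no codon-usage, tetranucleotide or
  phylogenetic-incongruence evidence).
- Population-scale statistics that depend on large versioned databases
  (thousands of phages) are outside desk scale and are not reproduced;
  the two acceptance checks that need real deposited records run only
  when those records are fetched locally.
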