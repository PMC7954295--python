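# phamflock

Shared-gene-content analysis for bacteriophage genomes.

Phage genomes are mosaics: genes move between phages faster than nucleotide
sequences stay recognisable, so two phages can encode nearly identical
proteins while sharing no alignable DNA. Clustering parameters based on
nucleotide identity (the classic "50% identity over 50% span" rule) then
call such phages *singletons* even when their gene content ties them firmly
to an existing cluster. `phamflock` implements the gene-content route
around this problem for small actinobacteriophage-style communities:

1. **Pham assignment** — group every protein in a population into *phams*
   (families related at the amino-acid level) by single-linkage clustering
   of pairwise global alignments (defaults: identity ≥ 35%, coverage ≥ 75%
   of the shorter protein).
2. **Gene Content Similarity** — for phages with pham sets $A$ and $B$:

   $$\mathrm{GCS}(A,B) = 100\cdot\tfrac12\left(\frac{|A\cap B|}{|A|} + \frac{|A\cap B|}{|B|}\right),
   \qquad \mathrm{GCD} = 1 - \mathrm{GCS}/100 .$$

3. **MaxGCDGap** — sort a focal phage's GCD values ascending, prepend 0,
   and take 100× the largest consecutive gap: a measure of how isolated
   the phage is from the population.
4. **Clustering** — connected components of the GCS ≥ 35% graph, plus a
   conservative exact-word screen for the legacy nucleotide rule.
5. **Dot plots** — Gepard-style exact-word match sets of concatenated
   genomes (word 15) and proteomes (word 5), sentinel-separated so every
   match block is attributable to a phage pair.
6. **Gene-content phylogeny** — neighbor joining on GCD distances and a
   NEXUS `DISTANCES` export loadable by split-network tools.
7. **HGT evidence** — per-gene GC-content deviation and the number of
   distinct isolation hosts represented in each gene's pham.
8. **Synthetic populations** — a generator that emulates the scenario this
   analysis exists for (clusters tied together by shared gene content
   whose nucleotide identity has been erased by synonymous substitution,
   with implanted HGT genes) together with full ground truth, so every
   stage is testable without downloads.

## Worked example

Simulate the default scenario (two clusters of three and two phages, one
focal phage, two HGT "satellite" carriers) and cluster it:

```bash
$ phamflock simulate --seed 17 --out pop
$ phamflock cluster --genomes pop/genomes.fasta --genes pop/genes.tsv \
                    --metadata pop/metadata.tsv --out .
C1      6       Phage1_1,Phage1_2,Phage1_3,Phage2_1,Phage2_2,Phage3_1
C2      1       Satellite1
C3      1       Satellite2
```

All six community phages — including `Phage3_1`, which shares almost no
nucleotide sequence with the others (exact-word span coverage ≈ 4–5%,
far below the legacy 50% rule) — form one expanded cluster at the 35%
gene-content parameter, while the two satellite genomes stay singletons.
The focal phage's dissimilarity profile:

```bash
$ phamflock gcdgap --genomes pop/genomes.fasta --genes pop/genes.tsv \
                   --metadata pop/metadata.tsv --focal Phage3_1
phage,gcd,gap_from_previous
Phage2_1,0.3875,0.3875
Phage2_2,0.4,0.0125
Phage1_1,0.591667,0.191667
...
# MaxGCDGap 38.75% closing at Phage2_1
```

The largest jump in the sorted GCD list is the leading gap from 0 to the
nearest neighbour `Phage2_1` (GCD 0.3875), so MaxGCDGap = 38.75%: the
focal phage is clearly separated from, yet closest to, the second
cluster. `phamflock run --config run.cfg` executes every stage (phams,
GCS/GCD, clustering, tree/NEXUS, dot plots, HGT table) and writes a JSON
manifest; `phamflock hgt --genome Phage3_1 ...` prints the per-gene
evidence table, which in this scenario flags exactly the four implanted
genes (two with +6-point GC offsets, two whose phams span three
isolation hosts).

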