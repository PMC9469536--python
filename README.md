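# mitocompare

Comparative analysis of annotated fungal mitochondrial genomes.

Fungal mitogenomes — circular molecules of roughly 50–150 kb in
basidiomycetes — differ enormously in size between even closely related
species, driven mostly by mobile group I/II introns, intergenic expansion
and repeat accumulation. `mitocompare` takes two or more annotated circular
mitogenomes (GenBank flat files, or FASTA plus a feature table) and produces
the standard battery of comparative statistics used in fungal mitogenomics:

- **Composition & skews** — base composition, AT/GC content, strand
  asymmetries AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C).
- **Region partition & contribution rates** — every nucleotide is assigned
  to exactly one of {protein-coding, intronic, RNA, intergenic}; for a
  genome pair, the contribution of each region class to the total size
  difference is `100 · Δregion / Δgenome`.
- **Codon usage** under the mold mitochondrial genetic code (translation
  table 4, TGA = Trp): start/stop tabulation, codon frequencies and RSCU.
- **Gene evolution** — pairwise global alignment (Needleman–Wunsch/Gotoh
  scoring), Kimura 2-parameter distances
  `d = −½·ln((1−2P−Q)·√(1−2Q))`, and Nei–Gojobori (NG86) Ka/Ks with
  exhaustive mutational-pathway averaging and Jukes–Cantor correction,
  plus a neighbor-joining tree on the concatenated core gene set.
- **Intron position classes (Pcls)** — introns of a host gene (typically
  *cox1*) are named `P<n>` by their insertion site mapped onto a reference
  coding sequence through alignment; introns in the same Pcl are putatively
  orthologous.
- **Repeats** — interspersed repeats by seed-and-extend genome
  self-comparison, a simplified tandem-array detector, and NUMT-like
  fragments shared between mitochondrial and nuclear sequences.
- **Gene order** — circular, strand-aware arrangement comparison: conserved
  backbone (longest common circular subsequence), displaced genes, and
  tRNA doubling events.
- **tRNA variation** — variable sites between homologous tRNAs attributed
  to cloverleaf regions (acceptor stem, D arm, anticodon arm, extra arm,
  T arm).

A first-class synthetic-data generator (`mitocompare.synthetic_data`)
builds realistic annotated mitogenome pairs with planted ground truth —
15 core protein genes, 2 rRNAs, 25 tRNAs, introns at named coding
positions, a 1-bp *nad4L*/*nad5* overlap, repeats, and a mutational
divergence process — so every analysis stage can be verified exactly.

## Worked example

```bash
mitocompare simulate --seed 4 --length 40000 --outdir demo/
mitocompare compare -g demo/sim4A.fa -g demo/sim4B.fa --out demo/report/
```

`demo/report/summary.json` then contains (abridged):

```json
{
 "pair_comparison": {
  "total_size_difference_bp": 4,
  "gc_gap_percent": 1.26,
  "mean_at_percent": 69.94,
  "contribution_rates_percent": {"intergenic": 100.0, "intronic": 0.0, ...}
 },
 "pcl": {"host_gene": "cox1", "n_pcls": 4, "n_introns": 8},
 "gene_order": {"displaced": [], "doubled_in_b": [], "backbone_size": 39},
 "trna": {"total_variable_sites": 59, "n_trnas_variable": 25, "n_trnas_compared": 25}
}
```

Reading: the sister genome is 4 bp longer, entirely due to intergenic
indels (contribution rate 100%); both genomes carry the same four *cox1*
intron position classes; the gene arrangement is fully conserved
(39 genes in the shared backbone, nothing displaced or doubled); and 59
variable sites fell across all 25 tRNAs. The TSV files in the bundle hold
the per-gene, per-codon and per-repeat detail behind these numbers.

Library use mirrors the CLI:

```python
from mitocompare.synthetic_data import SyntheticSpec, generate_genome, diverge
from mitocompare.composition import partition_regions, contribution_rates

spec = SyntheticSpec(seed=4)
a, truth = generate_genome(spec)
b, _ = diverge(a, spec, parent_truth=truth)
report = contribution_rates(partition_regions(a), partition_regions(b))
print(report.total_difference, report.contribution_rates)
```

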