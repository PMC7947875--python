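# microhic

Hi-C analysis of genomes that carry both macrochromosomes and
microchromosomes — the small (<30 Mb in birds, <~50 Mb in non-avian
reptiles), gene-dense chromosomes found across many vertebrate lineages.
`microhic` quantifies how microchromosomes organize in the nucleus from a
binned Hi-C contact matrix:

* **Interchromosomal contact density.** For chromosome *k* with length
  *L<sub>k</sub>* (Mb), the ICF density is
  Σ<sub>j∉k</sub> C<sub>kj</sub> / L<sub>k</sub> — the summed trans contact
  frequency per Mb. Micro vs macro groups are compared by Student's
  *t*-test, and density is regressed on chromosome length (OLS).
* **Observed/expected trans enrichment.** Pairwise trans sums
  O<sub>kl</sub> are compared with a uniform-interaction null,
  E<sub>kl</sub> = T·L<sub>k</sub>L<sub>l</sub> / Σ<sub>m&lt;n</sub>L<sub>m</sub>L<sub>n</sub>
  (T = total trans contacts), and summarized as log₂(O/E) with hierarchical
  clustering of chromosomes over the enrichment rows.
* **A/B compartments from trans contacts.** The leading eigenvector E1 of
  the bin–bin correlation of the trans O/E matrix, with its sign oriented
  so corr(E1, GC) ≥ 0; bins with E1 > 0 are "A" (open, GC-rich), E1 < 0
  "B". Per-chromosome A proportions are compared between classes.
* **3D interpretation by MDS.** Contacts become dissimilarities
  d<sub>ij</sub> = c<sub>ij</sub><sup>−α</sup> and are embedded in 3D by
  SMACOF stress majorization; radial centrality and nearest-neighbor
  territory overlap summarize the geometry up to rigid motion.

Matrix balancing (iterative correction to uniform marginals) removes
per-bin coverage bias before any statistic is computed.

Because real Hi-C maps come with no ground truth, the package includes a
**synthetic-nucleus generator**: chromosomes occupy spherical territories
(macros on a peripheral shell, micros in a central core), bins follow
confined random walks, contacts are sampled from
p<sub>ij</sub> = (d<sub>ij</sub>+d₀)<sup>−γ</sup>·(1+s·[both A]), and a
GC track is tied to the planted A/B labels. Every analysis stage is tested
by recovering what the generator planted.

## Worked example

```bash
python examples/02_trans_enrichment.py
```

prints, for the default synthetic nucleus (two 80 Mb macrochromosomes, six
microchromosomes of 10–20 Mb, 1 Mb bins, 2×10⁶ contacts, seed 1):

```
ICF density, micro vs macro: mean 11266 vs 5269 per Mb (Student t=4.62, p=0.0036)
density-on-length regression slope: -93.5 per Mb of length (p=0.0023)
mean log2 O/E micro-micro: +0.96
mean log2 O/E macro-micro: -0.20
mean log2 O/E macro-macro: -0.47
```

Microchromosomes carry about twice the trans contact density of
macrochromosomes, and micro–micro pairs interact ~2-fold more than the
length-product null predicts while macro–micro pairs are depleted — the
contact signature of microchromosomes clustering in a shared central
nuclear territory. `examples/03_compartments.py` and
`examples/04_embedding_centrality.py` continue the same dataset through
compartment calling (micro mean A proportion 0.90 vs 0.25 on macros,
p = 0.0047; 100% planted-label recovery) and the 3D embedding (micro bins
significantly more central, t = −5.57; micro–micro territory overlap 0.13
vs 0.00 macro–macro).

The same pipeline runs from the shell:

```bash
microhic run --synthetic --outdir report --seed 1      # demo data
microhic run --contacts contacts.txt --chrom-sizes genome.chrom.sizes \
             --gc-bedgraph gc.bedgraph --preset reptile --outdir report
```

`--preset avian` classes chromosomes under 30 Mb as micro; `--preset
reptile` uses 50 Mb. Real inputs are plain text: a chrom.sizes TSV, sparse
contact triplets (global-bin or 7-column genomic form), and a per-bin GC
bedGraph.

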