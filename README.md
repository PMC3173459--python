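# fragtax

Taxonomic classification of short genomic fragments (200–1000 nt) from
metagenomes, by genome composition, by homology evidence, and by hybrids of
the two — together with a leave-one-out clade-exclusion benchmark that
measures how classifiers behave when a fragment's true lineage is missing
from the reference set. A synthetic-data generator makes the entire
pipeline runnable end to end with no external databases.

## The classifiers

**Naive Bayes (NB).** Each reference genome `G_i` is modelled by
Laplace-smoothed conditional probabilities over all `N = 4^n` n-mers,
counted on both strands of all contigs:

    P(w_j | G_i) = (f(w_j|G_i) + 1) / (M_i + N)

where `f(w_j|G_i)` is the occurrence count of n-mer `w_j` and `M_i` the
total number of overlapping n-mers in the genome. With a flat prior over
genomes, a fragment is assigned to the genome maximising the sum of
`ln P(w_j|G_i)` over its overlapping n-mers (default `n = 10`). This is a
*rank-specific* classifier: it always answers with one genome (strain).

**ε-NB.** A *rank-flexible* variant: every genome whose likelihood is
within a factor ε of the maximum (default `ε = 1e5`) joins the candidate
set, and the fragment is assigned to the lowest taxonomic rank (LTR) shared
by the set — unclassified below it. Larger ε trades rank specificity for
confidence.

**NN.** Nearest neighbour by Manhattan distance between n-mer frequency
profiles (default `n = 4`).

**BLAST best hit / LCA.** From 12-column tabular BLAST output: the best-hit
classifier takes the minimum-E-value genome(s) below a threshold (default
`E < 1e-5`), assigning ties to their LTR; the LCA classifier takes the LTR
of all hits within `p%` of the top bit score (default `p = 15`); the
conservative LCA variant pools every hit with `E < 1e-2`.

**NB-BL.** A rank-specific combination, `Score = NB − 12·ln(E) + 4.8` per
genome, with a plain-NB fallback when no hit has `E < 10` and a special
rule for exact-zero E-values.

**Consensus hybrids.** `BLASTN+NB`, `BLASTN+ε-NB`, `LCA+NB`, `LCA+ε-NB`:
the longest common lineage prefix of a homology and a composition
prediction.

## Evaluation

Leave-one-out clade exclusion removes an entire lineage (strain … phylum)
from the training set; fragments from lineages with no sister clade are
dropped. Per lineage `i` with `Z_i = TP_i + FN_i + U_i` fragments the
package reports sensitivity `Sn = TP/Z`, specificity `Sp = TP/(TP+FP)`,
false negative rate `FNr = FN/Z` and unclassified rate `Ur = U/Z`, both
averaged over lineages and pooled ("absolute"). Each fragment is also
categorized against `r`, the deepest rank it shares with any training
genome: *correct rank* (assigned exactly at `r`, inside its lineage),
*correct lineage* (over-specific but contained within `r`), *incorrect*, or
*unclassified at r*.

## Worked example

```sh
fragtax simulate --out world --seed 5 --n-phyla 2 --n-families 2 \
    --n-genera 2 --n-species 2 --genome-length 8000 \
    --fragment-length 200 --fragments-per-species 2
fragtax build-models --genomes world/genomes.fasta \
    --subject-map world/subject_map.tsv -n 6 --out models
fragtax classify --method lca+enb --taxonomy world/taxonomy.tsv \
    --fragments world/fragments.fasta --models models \
    --hits world/hits.tsv --subject-map world/subject_map.tsv \
    --out preds.tsv
fragtax evaluate --predictions preds.tsv --truth world/truth.tsv \
    --taxonomy world/taxonomy.tsv --rank genus --metrics-out metrics.tsv
```

The run logs its parameters to stderr, e.g.

```
[fragtax] cmd=classify method=lca+enb epsilon=100000.0 lca_percent=15.0 evalue_max=1e-05 nn_n=4
[fragtax] cmd=classify fragments=32 out=preds.tsv
```

and `metrics.tsv` ends with the pooled rows (this world has 8 genera of two
species each, two 200 nt fragments per species):

```
lineage	rank	TP	FP	FN	U	Z	Sn	Sp	FNr	Ur
...
<average>	genus	32	0	0	0	32	1.000000	1.000000	0.000000	0.000000
<absolute>	genus	32	0	0	0	32	1.000000	1.000000	0.000000	0.000000
```

Here every fragment's own genome is still in the reference set, so the
conservative hybrid classifies all 32 fragments to the correct genus with
no false positives. Excluding a lineage (see `--excluded-lineage` on
`fragtax evaluate`, or the library's `ExclusionScheme`) is where the
classifiers separate.

The same operations are available as a library:

```python
from fragtax import build_nb_model, nb_classify
from fragtax.simdata import build_world, sample_fragments

world = build_world(seed=1)                      # 36 genomes, 50 kb each
models = [build_nb_model(g, c, 10) for g, c in sorted(world.genomes.items())]
frag = sample_fragments(world.genomes, world.tree, 400, 1, seed=2)[0]
print(nb_classify(models, world.tree, frag.fragment_id, frag.sequence).assigned)
```

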