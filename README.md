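# astrodirac

Rank-conservation network analysis across ordered astrocytoma grades:
Differential Rank Conservation (DIRAC) statistics, template-based
classification, and monotone-gene detection, with a synthetic multi-study
cohort generator that provides planted ground truth for every stage.

## The problem

Transcriptomic signatures for astrocytoma grading (Normal brain, Grade 2,
Grade 3, and primary/secondary glioblastoma) are notoriously fragile: lab
effects across studies swamp biological signal, and patients with the same
grade vary widely gene-by-gene.  Two ideas address this.  First, work on
*within-array ranks*: after replacing each array's intensities by their
relative ranks, any analysis that depends only on orderings is immune to
monotone normalization differences between labs.  Second, move from genes to
*networks*: for a gene set G with m genes, summarize a sample by the binary
vector over all m(m−1)/2 pairs (i, j), i < j, with bit 1 iff
x(g_i) < x(g_j).

Per (network, phenotype) the **rank template** T is the majority bit per
pair across the phenotype's samples; a sample's **rank matching score** is
the fraction of pairs agreeing with T; and the **rank conservation index**

    R(G, φ) = mean over samples s of φ of  score(s; T_{G,φ})   ∈ [1/2, 1]

measures how consistently the network is internally ordered across patients.
Averaging R over all networks gives one global dysregulation estimate per
phenotype — in tumors this falls with increasing grade.  Between two
phenotypes, Δ = R_A − R_B ranks the most *differentially regulated*
networks, with significance from permuting the A/B labels and pooling the
null |Δ| over all networks.  The same templates classify: assign each sample
to the phenotype whose template it matches better (apparent accuracy,
leave-one-out cross-validation, pooled permutation p and FDR).  Orthogonally,
the package finds genes whose mean within-array rank changes *monotonically*
along the grade ladder (Wilcoxon + Bonferroni in every adjacent-grade
comparison, both GBM subtypes required past G3), qualified by 80%-subsampling
robustness and a label-permutation directionality test.

Who this is for: anyone studying rank-based (normalization-free) network
statistics on ordered phenotypes — methodologically minded bioinformaticians,
and anyone needing a fully seeded synthetic multi-grade cohort with planted
dysregulation, planted monotone genes, batch effects, and a probe layer with
present-call masks.

## Worked example

```python
import astrodirac as ad

cfg = ad.SimConfig(
    n_genes=1000,
    samples_per_phenotype={p: 20 for p in ad.PHENOTYPES},
    n_networks=50,
    planted_dysreg=[("NET_007", "pGBM", 90.0)],   # extra noise in one network
    seed=42,
)
networks = ad.generate_networks(cfg)
matrix, labels, probes, truth = ad.generate_cohort(cfg, networks)

ranks = ad.preprocess_probe_layer(probes, labels)       # filter -> collapse -> rank
table = ad.conservation_table(ranks, labels, networks, merge_gbm=True)
for ph in table.phenotypes:
    print(f"{ph:7s} global mean conservation {ad.global_dysregulation(table, ph):.4f}")
f, p = ad.anova_conservation(table)
print(f"one-way ANOVA across phenotypes: F = {f:.1f}, p = {p:.2e}")

res = ad.differential_regulation(ranks, labels, networks, "G3", "pGBM",
                                 n_perm=1000, seed=42)
print(res.table.head(3)[["delta", "direction", "p"]])
```

prints

```
Normal  global mean conservation 0.9885
G2      global mean conservation 0.9847
G3      global mean conservation 0.9810
GBM     global mean conservation 0.9733
one-way ANOVA across phenotypes: F = 43.9, p = 9.85e-22
            delta             direction        p
network                                         
NET_007  0.090354  more conserved in G3  0.00002
NET_027  0.023333  more conserved in G3  0.00752
NET_020  0.018132  more conserved in G3  0.01248
```

Reading this: conservation falls monotonically with grade (the generator's
noise ladder rises with grade), the ANOVA confirms the phenotype means
differ, and the planted network `NET_007` tops the differential-regulation
ranking — less conserved in pGBM, where its extra noise was planted — at the
permutation floor p = 2·10⁻⁵, well clear of the best null network.

The same analyses run from the shell:

```bash
astro-dirac simulate --out demo/ --seed 42
astro-dirac preprocess --probes demo/probes_intensities.tsv \
    --calls demo/probes_calls.tsv --map demo/probes_map.tsv \
    --labels demo/labels.tsv --out demo/rank.tsv
astro-dirac conserve --expression demo/rank.tsv --labels demo/labels.tsv \
    --gmt demo/networks.gmt --out demo/conservation.tsv
astro-dirac all --out demo_full/ --seed 42     # full pipeline + report.md
```

All formats are plain text: expression and conservation tables as TSV, gene
sets as GMT, ground truth and summaries as JSON.

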