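# aneutx

Genomic-imbalance expression analysis for aneuploid transcriptomes.

Changing the copy number of one chromosome arm perturbs expression across the
whole genome, not just on the varied arm. In *Drosophila* trisomies the genes
on the varied arm (*cis*) often show **dosage compensation** (aneuploid/euploid
expression ratio ≈ 1.0) while genes on unvaried arms (*trans*) are subject to
an **inverse dosage effect** (ratio ≈ control_dose/case_dose, i.e. 2/3 in a
trisomy); genes escaping compensation show a proportional **gene dosage
effect** (ratio 1.5). `aneutx` implements the ratio-distribution analysis used
to study how long noncoding RNAs (lncRNAs) and transposable elements (TEs)
respond to this imbalance, for a five-karyotype design — euploid female (CF)
and male (CM) controls, trisomy-2L females/males (2LF/2LM) and metafemales
(XXX) — with three replicates each.

The toolkit covers, module by module:

- **annotation** — GTF parsing and positional classification of lncRNAs
  (lincRNA / intronic / sense / antisense) and TE insertions (intergenic /
  intronic / sense / antisense) against the protein-coding annotation, plus
  transcript length/exon statistics;
- **quantify** — CPM normalization, strict low-count filtering (mean raw
  count > 5), TE insertion→family aggregation and within-TE family shares;
- **imbalance** — per-feature case/control expression ratios
  r_g = mean(CPM_case)/mean(CPM_control), their 0.1-binned
  percentage-frequency distributions split by cis/trans location, analytic
  dosage landmarks {1.0, d, 1/d} for dose ratio d, nearest-landmark (log
  scale) dosage-response classification, distribution peaks, and two-sample
  Kolmogorov–Smirnov comparisons between transcript classes;
- **diffexp** — a Welch-*t* on log2(CPM+1) stand-in for differential
  expression at padj < 0.1 (Benjamini–Hochberg), an ingest hook for external
  DESeq2-layout tables, and Fisher-exact overlap statistics across
  aneuploidies;
- **interactions** — lncRNA–mRNA and TE-family–mRNA co-expression networks
  (|Pearson r| > 0.95, p < 0.05, pairs supported in ≥ 2 aneuploidies) and
  10 kb co-location networks;
- **simulate** — a negative-binomial generator that emulates the full study
  design with planted dosage-response classes and truth tables for recovery
  testing.

## Worked example

Simulate the five-genotype design and examine trisomy-2L females vs euploid
females:

```python
import numpy as np
from aneutx import (SimulationConfig, simulate_dataset, default_karyotypes,
                    filter_low_expression, cpm_normalize, expression_ratio,
                    dosage_landmarks, assign_cis_trans, ks_compare,
                    build_ratio_distribution, find_distribution_peaks)

cfg = SimulationConfig(n_mrna_per_arm=300, n_lncrna_per_arm=80, seed=7)
ds = simulate_dataset(cfg)
k = {x.genotype: x for x in default_karyotypes()}
case, control = k["2LF"], k["CF"]

cpm = cpm_normalize(filter_low_expression(ds.counts, 5.0))
annot = ds.truth[["feature_id", "biotype", "chrom"]].copy()
annot["location"] = assign_cis_trans(annot["chrom"], case, control).to_numpy()
rt = expression_ratio(cpm, ds.counts.samples_for("2LF"),
                      ds.counts.samples_for("CF"), annotation=annot)

for (bt, loc), grp in rt.table.groupby(["biotype", "location"]):
    med = np.median(grp["ratio"])
    peak = find_distribution_peaks(build_ratio_distribution(grp["ratio"])).iloc[0]
    print(f"{bt:15s} {loc:5s} n={len(grp):4d} median={med:.3f} "
          f"peak_bin={peak['bin_center']:.2f}")

lnc = rt.table.query("biotype=='lncRNA' and location=='trans'")["ratio"]
mr = rt.table.query("biotype=='protein_coding' and location=='trans'")["ratio"]
ks = ks_compare(lnc, mr)
print(f"K-S trans lncRNA vs mRNA: D={ks.statistic:.3f} p={ks.p_value:.2e}")
```

prints

```
lncRNA          cis   n=  80 median=0.965 peak_bin=0.65
lncRNA          trans n= 400 median=0.864 peak_bin=0.75
protein_coding  cis   n= 300 median=1.121 peak_bin=1.05
protein_coding  trans n=1500 median=0.970 peak_bin=0.65
K-S trans lncRNA vs mRNA: D=0.134 p=1.96e-05
```

Reading the output: cis mRNAs sit near the compensation landmark 1.0 (the
median above 1 reflects the planted minority with a proportional dosage
effect), cis lncRNAs show a secondary peak near the inverse landmark 0.67,
and trans lncRNAs are shifted significantly further below 1.0 than trans
mRNAs (K-S p ≪ 0.05) — the planted "lncRNAs are more sensitive to the inverse
dosage effect" signature, recovered by the pipeline.

The same stages run from the shell:

```sh
aneutx simulate --out run --seed 7
aneutx classify --out run
aneutx ratios   --out run
aneutx de       --out run
aneutx networks --out run
aneutx report   --out run     # collated JSON + markdown summary
```

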