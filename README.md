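# pbmcnet

Bottom-up construction of transcriptional-network modules from targeted
qRT-PCR panels, with a personalized metagene ("modular index") and
control-vs-patient comparison.

## The problem

Circulating stem/progenitor cells leave a faint transcriptional footprint in
peripheral blood mononuclear cell (PBMC) samples: tens of primitive and
tissue-differentiation marker mRNAs at copy numbers far below what
microarrays detect reliably, but well within reach of targeted qRT-PCR.
Because these markers are co-regulated, their expression organizes into
*modules* of a co-expression network, and the aggregate expression of a
module can track a donor's cardiovascular state (age, arterial stiffness,
central aortic pressure, adiposity) — a candidate blood-borne biomarker of
vascular health. `pbmcnet` implements the full analysis for anyone running
a gene-panel qRT-PCR study of this kind: quantification, network mining,
phenotype validation, metagene construction, and cohort contrasts.

## The method

Starting from a Cq table (genes × subjects) with designated housekeeping
controls:

1. **Relative quantification.** RCN = 2^(−ΔCq) × 100 with
   ΔCq = Cq(target) − Cq(reference), the reference being the per-subject
   *median* Cq of the housekeeping genes (B2M, GAPDH, RPL13 by default).
2. **Co-expression statistics.** All-pairs Pearson r with two-sided
   p-values from the t-transform, one global Bonferroni correction over
   G(G−1)/2 tests, and complete-linkage clustering of z-scored profiles.
3. **Module mining.** Build the graph with an edge wherever |r| > τ
   (τ = 0.7), enumerate all maximal cliques with Bron–Kerbosch (with
   pivoting), then greedily merge overlapping cliques while the union keeps
   edge density ≥ γ **and** mean |r| over all member pairs ≥ α_corr
   (γ = α_corr = 0.8). Every reported module therefore induces a submatrix
   with average |r| above 0.8 by contract. Per-node degree k, clustering
   coefficient C(k), the log–log C(k)-vs-k slope (negative ⇒ hierarchical
   modularity), and hub genes (adjacent to every module member and to a
   neighboring module) are reported per module.
4. **Functional filtering and metagene.** Genes whose RCN correlates
   (unadjusted p < 0.05) with *all* of age, AIx (augmentation index), AoPP
   (aortic pulse pressure) and BMI-in-females form the cardiovascular
   module; its modular index MI(subject) = mean over member genes of the
   z-scored RCN. Internal consistency is summarized by Cronbach's α
   (standardized form α = K·r̄ / (1 + (K−1)·r̄)); α > 0.95 indicates item
   saturation. Radial percent-of-median profiles give per-subject diagrams.
5. **Cohort comparison.** Per-gene percent reduction from cohort medians
   with Mann–Whitney tests, module-level mean ± SD reduction, and structure
   contrasts (module counts, degree ranges, module-fusion flag) between
   control and hypertensive cohorts mined at identical thresholds.

A seeded synthetic-cohort generator (`pbmcnet.simulate`) reproduces the
statistical structure this analysis assumes — two latent-factor modules, a
phenotype-coupled cardiovascular factor, abundant uncoupled leukocyte
genes, and a patient cohort with planted expression reductions and
tightened coupling — so the whole pipeline is testable without any data
download. Real data are ingested as plain Cq/phenotype TSVs.

## Worked example

```python
from pbmcnet import ModuleNetworkModel
from pbmcnet.simulate import default_control_spec, generate_cohort

cq, phenotypes = generate_cohort(default_control_spec(seed=0))
model = ModuleNetworkModel.from_cq(cq, phenotypes=phenotypes)
results = model.fit(tau=0.7, gamma=0.8, alpha_corr=0.8)
print(results.summary())
```

prints

```
Co-expression module network
============================================================
genes: 45   subjects: 26
edge threshold |r| > 0.7, density floor 0.8, mean-|r| floor 0.8
maximal cliques: 11   modules: 2

module 0: size=21 density=1.000 mean|r|=0.920 C(k)~k slope=undefined
  members: ACTA2, ADIPOQ, AFP, ALDH1A1, BGLAP, CD34, CDH5, DES, GATA4, ...
module 1: size=15 density=1.000 mean|r|=0.862 C(k)~k slope=undefined
  members: ABCG2, ALPL, CAV3, CNN1, FSHR, KDR, KIT, NANOG, NES, NKX2-5, ...

functional filter (p < 0.05 for all of age, AIx, AoPP, BMI): 15 genes
  ABCG2, ALPL, CAV3, CNN1, FSHR, KDR, KIT, NANOG, NES, NKX2-5, NOS3,
  NOTCH4, OLR1, POU5F1, TEK

modular index over 15 genes, Cronbach alpha (standardized) = 0.9894
  MI ~ age  : r=-0.859 signed_r2=-0.738 p=0.0000 n=26 [all]
  MI ~ AIx  : r=-0.846 signed_r2=-0.716 p=0.0000 n=26 [all]
  MI ~ AoPP : r=-0.769 signed_r2=-0.591 p=0.0000 n=26 [all]
  MI ~ BMI  : r=+0.951 signed_r2=+0.905 p=0.0000 n=14 [females]
```

Reading this: the miner recovered two gene communities; the 15-gene
cardiovascular module passes the all-four-variables filter; its metagene
falls with age, arterial stiffness and aortic pulse pressure, rises with
BMI among the 14 female subjects, and is statistically saturated
(α = 0.989 > 0.95). `signed_r2` is sign(r)·r², the signed effect-size
convention for these regressions (a literal R² cannot be negative).

The same pipeline is available from the shell:

```bash
pbmcnet simulate --cohort control --seed 0 --out sim/
pbmcnet quantify --cq sim/cq.tsv --refs B2M,GAPDH,RPL13 --out rcn.tsv
pbmcnet network  --rcn rcn.tsv --tau 0.7 --gamma 0.8 --out net/
pbmcnet run-all  --seed 0 --out run/        # all stages + manifest.json
```

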