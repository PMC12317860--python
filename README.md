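# clonekit

Clone, synonym and fingerprint-panel analysis for SNP-genotyped
germplasm collections of clonally propagated crops.

Field collections of tree crops (the motivating case is a lychee
collection of 91 trees carrying 57 cultivar names plus unnamed
accessions) accumulate naming problems over decades of exchange:
**synonymous** cultivars are genetically identical clones held under
different names, **homonymous** cultivars are genetically different
trees sharing one name. Because multiplexed reduced-representation
genotyping never calls clones 100% identical (heterozygote
under-calling, digestion artefacts, somatic "sports"), identifying
clones needs a data-derived distance cutoff rather than exact matching.

From a VCF of biallelic SNPs and a sample → cultivar-name table,
`clonekit`:

1. filters sites (missingness, MAF ≥ 5%, physical thinning);
2. computes the pairwise **p-distance** matrix,
   `d(i,j) = mean |g_i − g_j| / 2` over pairwise-complete dosages;
3. builds a **neighbour-joining** tree (Saitou–Nei with the
   Studier–Keppler criterion `Q(i,j) = (r−2)d(i,j) − R_i − R_j`) with
   site-bootstrap bipartition support;
4. finds *seed groups* — same-named (or known-synonym) sister pairs and
   tight clades with ≤ 2 outsiders — and sets the **clone cutoff** to
   their maximum within-group distance;
5. partitions the collection by **single linkage** at that cutoff into
   clone groups and singletons, then reports synonym sets, homonyms
   and name suggestions for unnamed samples;
6. estimates **admixture** by EM on the binomial likelihood
   `g_il ~ Bin(2, Σ_k q_ik f_kl)` across K = 1…10 with restarts, picking
   K by the **Evanno deltaK** second-difference statistic, and labels
   samples (> 80% membership, F1-like 50/50, BC1-like 25/75);
7. selects a minimal **fingerprinting SNP panel** by greedy set cover
   over sample pairs, reporting per-marker MAF and Botstein PIC
   (`1 − p² − q² − 2p²q²`);
8. optionally tabulates the two-primer **maturity-marker** assay
   (COL307 indel: insertion homozygote = late-maturing, deletion
   homozygote = extremely early, heterozygote = early hybrid).

A synthetic-cohort generator (divergent Balding–Nichols gene pools,
F1/BC1 hybrids, clone groups of 2–9 with genotyping noise, plus a
ground-truth record) makes every stage testable without any downloads.
See `docs/methods.md` for models, parameter choices and limitations.

## Worked example

Simulate a 25-tree collection (two pools at F_ST 0.35, two F1 and two
BC1 hybrids, clone groups of 3 and 4, realistic noise) and run the full
pipeline:

```sh
clonekit run-all --config demo.yaml
```

with `demo.yaml`:

```yaml
outdir: demo_out
seed: 7
bootstrap: 100
admixture: {k_min: 1, k_max: 4, restarts: 3}
simulate:
  k_pools: 2
  fst: 0.35
  n_sites: 2000
  seed: 7
  n_per_pool: [8, 8]
  hybrids: [[0.5, 2], [0.25, 2]]
  clone_groups: [[0, 3], [9, 4]]
  noise: [0.05, 0.005, 0.05]
```

prints the stage summary:

```json
{
  "load":      {"n_samples": 25, "n_sites": 2000},
  "filter":    {"input": 2000, "missingness": 2000, "maf": 1563, "thin": 1563},
  "distance":  {"max": 0.4409, "mean": 0.3268},
  "tree":      {"n_tips": 25, "bootstrap": 100},
  "admixture": {"k_optimal": 2, "loglik": -32375.15, "n_admixed": 4},
  "clones":    {"cutoff": 0.0235, "n_seed_groups": 4, "n_groups": 2,
                "n_clonal_samples": 7, "n_singletons": 18,
                "max_group_size": 4, "n_distinct_genotypes": 20},
  "panel":     {"panel_size": 5, "n_residual_pairs": 0}
}
```

Reading it: 437 of 2,000 sites fell below 5% MAF and were dropped; the
derived clone cutoff 0.0235 sits far below the between-genotype
distances (mean 0.33), so single linkage recovers exactly the two
simulated clone groups (3 + 4 = 7 clonal trees, 20 distinct genotypes
among 25); deltaK picks K = 2 and labels the four hybrids admixed; and
5 SNPs suffice to fingerprint all 25 trees with no residual
indistinguishable pair — genotyping noise leaves even clone copies
separable, just as real collections can fingerprint every tree.
`demo_out/` holds the artifacts: `nj_tree.nwk`, `Q.tsv`, `delta_k.tsv`,
`clone_groups.tsv`, `synonym_sets.tsv`, `homonyms.tsv`,
`unknown_suggestions.tsv`, `core_panel.tsv` and `manifest.json`.

Each stage is also available as its own subcommand (`filter`, `dist`,
`tree`, `clones`, `panel`, `maturity`, `simulate`) for use on real VCF +
metadata inputs, e.g.

```sh
clonekit clones --vcf collection.vcf --meta samples.tsv --out clones.tsv
```

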