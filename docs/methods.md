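# Methods

`clonekit` analyses SNP-genotyped germplasm collections of clonally
propagated crops (the motivating system is a lychee field collection of
91 trees under 57 cultivar names plus unnamed accessions). Its job is to
answer three questions: which trees are clones of one another
(synonymous cultivars and mislabelled or unnamed samples), how ancestry
is structured across the collection's divergent gene pools, and what is
the smallest SNP panel that fingerprints every distinct genotype.

## Genotype representation and site filtering

Genotypes are diploid alternate-allele dosages in {0, 1, 2} with a
reserved missing sentinel, read from biallelic SNP records of a VCF
(multi-allelic and non-SNP records are skipped and counted, never
split). Three site filters are applied in a fixed order:

1. **Missingness** — keep a site iff strictly fewer than `max_missing`
   samples are missing (count mode, the default), or iff the missing
   fraction is at most the threshold (fraction mode). Both modes exist
   because collection-scale studies state thresholds either way; the
   default is the count reading.
2. **MAF** — keep a site iff its folded minor-allele frequency, computed
   on non-missing alleles, is ≥ `min_maf` (default 0.05; a site at
   exactly the threshold is kept). Monomorphic sites are always dropped.
3. **Physical thinning** — greedy left-to-right scan per chromosome:
   keep the first site, then each site at least `thin_bp` from the last
   kept one. This is the standard proxy for LD pruning when no
   population LD estimate is wanted.

The order is load-bearing (thinning outcome depends on which sites
remain), so it is fixed rather than configurable; a constructed fixture
in the tests documents how reordering changes the result.

## Distances and the NJ tree

Pairwise distance is the p-distance on dosages: per shared site
|g_i − g_j| / 2 (so het vs hom = 0.5, opposite homozygotes = 1),
averaged over pairwise-complete sites (pairwise deletion; each pair's
site count is reported). Pairwise deletion was chosen over complete-case
because filtered collection data retain scattered missingness and
complete-case deletion would discard most sites. p-distances are not
guaranteed metric; only symmetry and range are asserted.

Trees are built with neighbour joining (Saitou–Nei agglomeration,
Studier–Keppler Q-criterion, standard two-point branch lengths, final
three-node closed form). Implementation choices:

- **Tie-breaking**: the lexicographically smallest active index pair
  wins. Clone-heavy matrices are full of (near-)zero distances; without
  a deterministic rule the topology would depend on dictionary order of
  floating-point noise.
- **Negative branch lengths** (possible on non-additive input) are
  clamped to zero and logged.
- On additive input the algorithm is exact; the test suite checks
  topology and branch-length recovery to 1e−9 on random additive trees,
  and cross-checks topology against scikit-bio's independent NJ on
  non-additive matrices.

Support values come from site bootstrap: each replicate resamples sites
with replacement to the original count, a replicate tree is built, and
each internal edge of the main tree is labelled with the percentage of
replicates containing the same bipartition. This maps supports onto the
full-data tree rather than building a majority-rule consensus; it is
what collection-scale figures display, and the two differ only in how
low-support conflicts are summarised.

Clade enumeration for the synonymy stage is rooting-independent: both
sides of every internal edge are candidate clades (each side is a clade
under a rooting on that edge). A midpoint-rooting convention was
considered and rejected: when the midpoint falls exactly on a node the
available rooting routine degenerates, and the enumeration below makes
the choice of rooting irrelevant anyway.

## Clone cutoff, clone groups, nomenclature

Clonally propagated trees never genotype 100% identical under
multiplexed reduced-representation sequencing (heterozygote
under-calling at low depth, digestion inconsistencies, somatic
"sports"), so a 0-distance criterion is useless and the cutoff is
derived from the data:

1. **Sister pairs** — cherries whose two tips share a cultivar name or
   a user-declared known-synonym group.
2. **Seed groups** — tight clades holding ≥ 2 same-named (or
   known-synonym) tips with at most `max_extra` (default 2) other
   samples. Per name, the qualifying clade with the most same-named
   tips is chosen, ties resolved toward fewer outsiders, then smaller
   maximum internal distance. Sister pairs are kept as size-2 groups in
   their own right, so a pair and its larger expansion can both
   contribute (mirroring how such groups are reported in practice).
3. **Cutoff** — the maximum over seed groups of the maximum within-group
   pairwise distance. On the motivating collection's reference group maxima
   (0.0651, 0.0442, 0.0413, 0.0564, 0.0482, 0.0482) this yields 0.0651,
   which `scripts/acceptance.py` recomputes.
4. **Clone groups** — single-linkage clustering at the cutoff:
   connected components of the graph with an edge wherever
   d ≤ cutoff. Single linkage (not complete or average) because real
   clonal groups chain through tree-adjacent samples; a brute-force
   reachability oracle verifies the implementation.

Groups are then read against names: a group with ≥ 2 distinct names is
a synonym set; a name spread over ≥ 2 groups/singletons is a homonym;
an unnamed sample grouped with exactly one name gets that name
suggested (two or more: ambiguous). The package deliberately does not
decide which of several homonymous groups "really" owns a name.

## Admixture by EM and deltaK

Ancestry is modelled with the standard unsupervised admixture
likelihood for unlinked biallelic SNPs: dosage g_il ~ Binomial(2, p_il)
with p_il = Σ_k q_ik f_kl, Q the n×K ancestry proportions and F the K×L
ancestral frequencies. Instead of MCMC the model is maximised by EM
(the classic allele-responsibility updates), which is deterministic per
seed and desk-scale. This is the package's central reinterpretation of
Bayesian clustering practice: the likelihood model is identical, and
the Evanno deltaK statistic

    deltaK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K))

transfers with per-restart final log-likelihoods standing in for
per-run posterior means. Only the argmax-K behaviour is comparable to
an MCMC run; no numeric reproduction of MCMC output is claimed.

Numerical choices: Q initialised from a symmetric Dirichlet and F from
jittered observed frequencies (both seeded); F clipped to
[1e−6, 1−1e−6] each iteration; convergence at relative log-likelihood
change < 1e−6 (1e−5 in the pipeline defaults) or 500 (300) iterations;
monotonicity of the trajectory asserted on every run; 5 restarts per K
by default; zero between-run variance makes deltaK undefined at that K
and is flagged, never reported as infinite. Label switching is handled
by greedy least-squares column matching when comparing runs or truth.

Membership labels use a strict > 0.80 max-ancestry threshold
(else "admixed"); with K = 2, ancestry within ±0.02 of 0.5 is F1-like
and within ±0.02 of 0.25/0.75 is BC1-like, mirroring how
early-generation hybrids present in such collections.

## Fingerprinting panel

The panel is a set cover over sample pairs: a pair is distinguished at
a site iff both calls are observed and differ (a panel must never rely
on missingness). The production selector is greedy — repeatedly take
the site covering the most unresolved pairs, ties to the smallest
genomic coordinate — with residual (indistinguishable) pairs reported
rather than treated as failure; exact clones are expected to be
residual. An exhaustive increasing-size subset search (bounded at ~20
sites) serves as the minimality oracle on small instances. Marker
informativeness is reported as folded MAF and Botstein's PIC
(1 − p² − q² − 2p²q², max 0.375 at MAF 0.5).

## Maturity-marker assay

The flowering-time indel near the COL307 gene separates the
late-maturing (insertion, haplotype B) and extremely-early
(deletion, haplotype C) lineages; hybrids are heterozygous. The assay
records two presence/absence amplification flags per sample, and the
call is a pure function of the pair: (B only) → B-homozygote,
(C only) → C-homozygote, (both) → heterozygote, (neither) → failed.
Counts are tabulated and optionally crossed against admixture
membership labels.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- **Pools** — Balding–Nichols divergence: ancestral frequency per site
  uniform on [0.05, 0.95] (bounded away from 0/1 so MAF filtering does
  not degenerate), pool frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) at
  divergence F (two pools at F ≈ 0.3–0.4 by default, matching two
  well-separated domestication gene pools).
- **Samples** — pure founders per pool; hybrids at chosen ancestry
  (50/50 F1-like, 25/75 BC1-like); clone groups of 2–9 samples, each an
  exact copy of its founder before noise; clone groups share the
  founder's cultivar name, with optional deliberate mislabelling
  (synthetic synonyms) and unknown-renaming.
- **Noise** — three rates applied in a fixed order: each heterozygote
  becomes a random homozygote with probability `het_miscall` (0.05
  default — the dominant artefact of low-depth multiplexed
  genotyping), each call shifts ±1 dosage with probability
  `allele_error` (0.005), each call drops out with probability
  `missing` (0.05). The rates are the package's own defaults: no
  quantitative error-rate estimate exists for the motivating data, so
  values typical of reduced-representation genotyping were fixed once.
  A per-site outcome-enumeration oracle in the tests confirms the
  induced within-clone distances match the model.

Every cohort ships a truth record (true Q, true clone partition,
founder genotypes), so recovery tests are exact: clone-partition
recovery is asserted in ≥ 90% of 20 noisy cohorts end-to-end, and EM
recovers pure founders at max-Q > 0.95 and F1 ancestry within ±0.05.

What the generator does **not** emulate: linkage and recombination
(sites are independent, so thinning is exercised only mechanically),
restriction-site dropout structure specific to the library protocol,
read-level errors (noise is applied at the genotype layer), and
name-history confusions beyond random mislabelling. Passing recovery
tests therefore demonstrate correctness of the algorithms under the
stated model, not robustness to every artefact of real field data.

## Problem sizes in tests

Recovery tests use cohorts of 14–60 samples at 2,000–10,000 sites with
20 (clone recovery) or 5 (admixture) replicate seeds, and the pipeline
test runs 20 bootstrap replicates — sizes chosen so the full suite
completes in a few minutes on one CPU while keeping every statistical
check comfortably powered.

## Known limitations

- The deltaK statistic is undefined at the range ends (K must have both
  neighbours) and cannot select K = 1; inspect mean log-likelihoods
  when a single pool is plausible.
- The cutoff derivation requires at least one same-named or
  known-synonym tight group; collections without repeated names need a
  manual cutoff (`--cutoff`).
- Single linkage can chain distinct genotypes through intermediates if
  the cutoff is generous; the seed-group construction keeps the cutoff
  conservative, but a pathological collection could still over-merge.
- p-distances ignore allele-frequency weighting; two samples sharing
  rare alleles are not considered closer than two sharing common ones.
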