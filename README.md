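# mhcdab

Amplicon genotyping and molecular-evolution analysis of MHC class IIB
(*DAB*) genes in cyprinid fish.

Classical MHC class IIB genes of cyprinids fall into two divergent allelic
lineages (*DAB1*-like and *DAB3*-like, putative duplicated loci), and a
single fish can express up to eight distinct alleles — two duplicated
diploid loci per lineage.  Exon 2 (276 bp, 92 codons) encodes the
peptide-binding region and is the target of both strong positive selection
at antigen-binding sites and trans-species polymorphism.  Genotyping such a
multilocus system from pooled amplicon pyrosequencing requires separating
true alleles from PCR artefacts (point substitutions and template-switch
chimeras) without ever knowing how many alleles a fish "should" have.

`mhcdab` implements that whole workflow as one tested pipeline, for
conservation geneticists and molecular ecologists studying multigene MHC
variation in hybridising species:

* **tag design** — 7-bp multiplexing tags with no homopolymer, no tandem
  motif, pairwise Hamming distance ≥ 3; 12 tagged forward × 8 tagged
  reverse primers address a 96-well plate;
* **genotyping** — demultiplexing by dual tags, marker assignment
  (DAB1-like vs DAB3-like), and allele validation by the **maximum
  per-amplicon frequency (MPAF)**: variants below 5 % MPAF that are
  explainable as a 1-bp substitution from, or a single-crossover recombinant
  of, higher-frequency variants in the same amplicon are artefacts;
  variants reaching ≥ 50 % of an amplicon's reads are true alleles;
  frameshifted variants and unreplicated low-frequency singletons are
  excluded.  Validated alleles are named `Pato-`/`Chna-`/`Pctn-DAB*NN` by
  species occurrence;
* **phylogeny** — Jukes–Cantor distances, neighbour joining, bootstrap
  support (1000 replicates by default);
* **selection** — Nei–Gojobori dN/dS with Jukes–Cantor correction,
  partitioned into antigen-binding sites (ABS, from the human DRB1 crystal
  structure) vs non-ABS, with 1000-replicate bootstrap SEs and one-tailed
  Z-tests; maximum-likelihood codon site models M0/M1a/M2a/M3/M7/M8 with
  likelihood-ratio tests and Bayes empirical Bayes identification of
  positively selected sites;
* **gene conversion** — GENECONV-style inner/outer fragment detection with
  permutation significance (10 000 permutations, Bonferroni-corrected
  pairwise tests);
* **population genetics** — presence/absence of each allele as a dominant
  binary locus: variance-component F\_st with 20 000-replicate bootstrap
  CIs, haplotype-frequency F\_st, Weir–Cockerham θ for microsatellites,
  STRUCTURE-like Gibbs admixture inference with Evanno's ΔK and
  CLUMPP-style run alignment, Mantel tests (Spearman, 10 000 permutations)
  and diversity/rarefaction summaries;
* **synthetic data** — a first-class generator for every input (allele
  pools, genotypes, dual-tagged reads with point errors and chimeras,
  microsatellite panels) with complete ground-truth tables, so every stage
  is testable end to end.

## Worked example

Design tags, simulate a two-population cohort with realistic noise, and
genotype it:

```python
import pandas as pd
from mhcdab import tags, simulate, genotyping

cands = tags.enumerate_candidate_tags()          # all valid 7-mers
ts = tags.select_tag_set(cands, min_hamming=3, target_size=40, seed=1)

pool = simulate.generate_allele_pool(n_per_lineage=6, seed=1)
genos = (simulate.simulate_genotypes(pool, 20, species="A", population="orb", seed=1)
         + simulate.simulate_genotypes(pool, 20, species="B", population="all", seed=2))
layout = tags.build_plate_layout(ts, 12, 8, [g.specimen_id for g in genos])
cfg = simulate.ReadSimConfig(coverage=(500, 1200), error_rate=0.01,
                             chimera_fraction=0.05, seed=7)
reads, _truth, amp_truth = simulate.simulate_read_set(genos, pool, layout, cfg)

meta = pd.DataFrame([{"specimen": g.specimen_id, "population": g.population,
                      "species": g.species} for g in genos])
res = genotyping.genotype_cohort(reads, layout, pool.reference_sequences(), meta)
print(res.variant_table.summary["status"].value_counts().to_string())
print(genotyping.summarize_population(res.presence, res.catalog).to_string(index=False))
```

prints

```
status
excluded_singleton       35990
artefact_substitution     5325
artefact_chimera            57
true_allele                 11

group  n_specimens  n_alleles  n_private  n_dab1  n_dab3  alleles_per_specimen_min  alleles_per_specimen_max  alleles_per_specimen_mean  alleles_per_specimen_sd
  all           20          8          5       4       4                         2                         4                       3.45                 0.668954
  orb           20          6          3       2       4                         1                         3                       2.10                 0.700000
```

Of 54 295 simulated reads, the vast majority of distinct sequences are
error singletons or recognised substitution/chimera artefacts; 11 variants
survive validation.  Against the ground truth this is 11 of 12 true alleles
with zero false positives: the one miss is an allele carried by a single
specimen, whose exact sequence reaches only ~6 % of its amplicon's reads
under 1 %/base error and is therefore (correctly, by design) excluded by
the unreplicated-singleton rule — in the lab one would re-amplify that
specimen, which is exactly what the validation scheme prescribes.  The
per-population summary shows species B carrying more alleles per specimen
(mean 3.45 vs 2.10) and both *DAB* lineages, the pattern the expression
weights of the generator emulate.

The same objects flow on into the other stages: the catalog's sequences go
to `phylo.bootstrap_support`, `ng86.partition_rates` (dN/dS by ABS
partition), `CodonSiteModel(...).fit()` → `.lrt()` / `.beb()`,
`geneconv.permutation_significance`, and the presence matrix to
`popgen.fst_binary` / `popgen.admixture_infer`.  The whole chain runs from
one config with the `mhcdab` CLI:

```sh
mhcdab run --config config.yaml      # simulate → genotype → phylo → selection → geneconv → popgen
mhcdab report <run-dir>              # render the summary tables
```

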