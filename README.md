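# phenocomm

Multi-taxonomy 16S profiling and community phenotype indices for
replicated in-vitro gut-community experiments.

When a pooled fecal community is cultured under different supplements —
for example each of the nine major short-chain fatty acids (SCFAs) next
to an unsupplemented control, with four technical replicates each — the
questions are always the same: *which strains and species changed, and
what can the resulting community do metabolically?* `phenocomm`
implements that analysis end to end, starting from denoised amplicon
sequence variants (ASVs) and their count table:

1. **Multi-taxonomy assignment (MTA).** Each ASV is aligned against a
   reference 16S database. With the best fractional identity denoted
   *M*, every reference with identity strictly above the threshold

   τ = M − (1 − M)/4

   is accepted, and the accepted lineages are merged rank-by-rank into
   `/`-joined multi-names (e.g. species `obeum/wexlerae`). Ambiguity is
   kept explicit instead of being resolved by an arbitrary best hit.
2. **Copy-number-corrected abundances.** Relative abundances are divided
   by rrnDB-style mean 16S gene copy numbers at a chosen rank and
   re-closed, removing the multi-copy amplification bias; tables can be
   aggregated to any rank (phylotype, species, genus, …).
3. **Community Phenotype Index (CPI).** A binary phenotype matrix (BPM)
   marks each reference genome 1/0 for a complete metabolic pathway
   (SCFA production, vitamin or amino-acid biosynthesis, …). The
   probability *P* that a taxon carries a phenotype is the mean bit over
   its matching genomes, and per sample

   CPI = 100 × Σ_taxa P(taxon, phenotype) · abundance(taxon)

   — the percentage of community cells predicted to carry the pathway.
4. **Diversity and differential statistics.** Shannon α-diversity,
   Bray–Curtis β-diversity with principal-coordinates ordination,
   >fivefold altered/unaltered classification of taxa against control,
   and an **exact** two-tailed Mann–Whitney test: at 4 vs 4 replicates
   the smallest attainable p is 2/70 ≈ 0.0286, so "P = 0.03" is the
   floor, computed by full enumeration rather than a large-sample
   approximation.

A fully seeded synthetic-experiment generator (strain-level phylotypes
nested in species groups, planted fold-change effects, multinomial or
Dirichlet-multinomial counts) provides ground truth against which every
stage is verified.

## Worked example

```python
from phenocomm import (
    EffectConfig, MultiTaxonomyClassifier, copy_number_renormalize, cpi_matrix,
    differential_table, generate_phenotype_matrix, generate_reference_database,
    probability_table_by_refs, simulate_experiment, summarize_modulation, to_relative,
)

# a synthetic study: 10 species x 3 strains, control + 9 SCFAs x 4 replicates,
# 10-fold fitness reductions planted on 10% of strains per condition
ref_db = generate_reference_database(n_species=10, strains_per_species=3, seed=101)
bpm = generate_phenotype_matrix(ref_db, seed=102)
cfg = EffectConfig(seed=103, depth=100_000, fraction_affected=0.1,
                   multiplier_low=0.1, multiplier_high=0.1)
counts, truth = simulate_experiment(ref_db, cfg)

clf = MultiTaxonomyClassifier().fit(ref_db.sequences, ref_db.lineages)
assignments = clf.predict(ref_db.sequences)
a = assignments["S001.1"]
print(f"ASV S001.1: M={a.max_identity:.3f}, tau={a.threshold:.4f}, "
      f"refs={';'.join(a.accepted_refs)}, species={a.lineage.at('species')}")

rel = to_relative(counts)
names = {t: assignments[t].lineage.at("species") for t in rel.taxon_ids}
corrected = copy_number_renormalize(rel, ref_db.copy_numbers_by_species, names)
cpi, _ = cpi_matrix(corrected, probability_table_by_refs(assignments, bpm))
print(cpi.loc[["control_r1", "butyrate_r1"],
              ["butyrate_production", "B12_biosynthesis"]].round(2))

diff = differential_table(rel.data, counts.metadata, "control")
hit = diff[(diff.direction != "unaltered") & (diff.p < 0.05)].iloc[0]
print(f"{hit.feature} in {hit.condition}: {hit.direction}, "
      f"fold={hit.fold_ratio:.2f}, P={hit.p:.4f}")
print(summarize_modulation(diff).head(3))
```

prints

```
ASV S001.1: M=1.000, tau=1.0000, refs=S001.1, species=sp001
             butyrate_production  B12_biosynthesis
control_r1                 71.96             41.71
butyrate_r1                70.61             44.21
S004.1 in formate: decreased, fold=0.12, P=0.0286
           increased  decreased  altered  unaltered
condition
acetate            0          3        3         27
butyrate           0          3        3         27
formate            0          3        3         27
```

Reading it: every strain's own 16S sequence is its unique best match at
identity 1.0, so the assignment resolves to a single species name; about
72% of control-community cells are predicted butyrate producers; strain
`S004.1` dropped ~8-fold under formate supplementation with the exact
two-tailed Mann–Whitney p at its 4-vs-4 floor (P = 0.0286, i.e. "0.03");
and each condition recovers exactly the three planted fitness reductions
with no false calls among the other 27 strains.

The same pipeline runs from the shell:

```sh
phenocomm simulate --n-species 10 --strains-per-species 3 --seed 101 --outdir data/
phenocomm run --config pipeline.yaml        # assign -> abundance -> phenotype -> diff
```

`run` writes assignment, abundance, diversity, CPI and differential
tables plus a JSON manifest with SHA-256 hashes of every input and
output; reruns over identical inputs are hash-identical.

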