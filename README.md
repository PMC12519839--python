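# mungomhc

Analysis toolkit for multi-locus MHC immunogenetics from amplicon
sequencing, built around the banded mongoose (*Mungos mungo*) study
design: duplicate-typed amplicons of MHC-I exon 2/3 and MHC-II DRB
exon 2, where co-amplifying paralogous loci make genotypes
presence/absence allele sets rather than diploid calls.

It is aimed at wildlife immunogenetics groups who need a tested,
scriptable version of a workflow usually spread across AmpliSAS-style
genotyping, DnaSP, MEGA and a collection of R packages:

- **Amplicon genotype validation** — artefact-frequency thresholding
  (median within-amplicon frequency of putative artefacts), a
  deterministic three-rule allele/artefact decision procedure, replicate
  merging, reproducibility 2·|A∩B|/(|A|+|B|), negative-control and
  parent-offspring plausibility checks.
- **Allele classification** — translation and pseudogene flagging,
  classical vs nonclassical calls from conserved residues at
  reference-anchored alignment columns, frequency-ordered nomenclature
  (`Mumu class-I-2*01`, `…*02-Ps`).
- **Polymorphism statistics** — segregating sites S, total mutations η,
  mean pairwise differences k, nucleotide diversity π = k/L, pairwise
  identity, amino acid p-distance with bootstrap SE, allele accumulation
  curves, per-individual allele/supertype summaries.
- **Selection inference** — Nei–Gojobori counts with exhaustive
  mutational-pathway resolution and stop-codon exclusion, Jukes–Cantor
  correction, mean dN−dS over pairs with codon-bootstrap SE and the
  one-tailed Z-test of positive selection, over all sites or site masks
  (PSS / PBR).
- **Supertype clustering** — five z-descriptors per residue at selected
  sites, repeated k-means with BIC-based cluster-number selection, DAPC
  assignment, Light's Kappa repeatability.
- **Linkage structure** — Phi coefficients on binary allele presence,
  Ward (`ward.D`-style) haplotype blocks, co-occurrence percentages,
  minimum-locus bounds.
- **Comparative phylogenetics** — majority-rule consensus trees with
  averaged branch lengths, Brownian species covariance, and a conjugate
  Gibbs sampler for the Bayesian phylogenetic linear mixed model
  log₁₀(alleles) ~ status + log₁₀(n) + exons + class + (1|species) +
  (1|phylo), with λ = σ²ₚ/(σ²ₚ+σ²ₛ+σ²ᵣ).
- **Synthetic data** — a generator for every input above with recorded
  ground truth (true alleles, artefact events, haplotypes, per-site ω,
  model parameters), so each stage is testable without external data.

See `docs/methods.md` for model details and numerical conventions.

## Worked example

Simulate a noisy duplicate-typed study, validate genotypes and compute
diversity and selection statistics:

```python
import mungomhc as m

cfg = m.SimConfig(seed=1, n_alleles=24, n_individuals=120,
                  artefact_fraction=0.3, pseudo_fraction=0.15,
                  nonclassical_fraction=0.1)
fasta, truth = m.simulate_allele_pool(cfg)
gm = m.simulate_population_genotypes(truth, cfg)
table = m.simulate_amplicon_run(truth, cfg)

thr = m.estimate_frequency_threshold(table)
labels = m.validate_variants(table, m.ValidationParams(min_frequency=thr))
rep = m.replicate_reproducibility(table, labels)
print(f"threshold = {thr:.4f}")
print(f"alleles retained = {(labels.label == 'allele').sum()} of {len(labels)} variants")
print(f"mean reproducibility = {rep.mean():.3f}")

stats = m.polymorphism_stats(list(truth.allele_seqs.values()))
print(f"S = {stats['S']}, eta = {stats['eta']}, k = {stats['k']:.3f}, "
      f"pi = {stats['pi']:.4f}, identity = {stats['pairwise_identity_pct']:.1f}%")

classical = [s for a, s, st in truth.true_alleles if st == "classical"]
res = m.mean_dn_minus_ds(classical, n_bootstrap=1000, seed=1)
print(f"dN-dS = {res.dn_minus_ds:.3f} +/- {res.se:.3f}, "
      f"Z = {res.z:.2f}, p = {res.p_value:.3f}")
```

prints

```
threshold = 0.0283
alleles retained = 18 of 481 variants
mean reproducibility = 1.000
S = 83, eta = 230, k = 46.290, pi = 0.2030, identity = 79.7%
dN-dS = -0.017 +/- 0.023, Z = -0.74, p = 0.771
```

The 481 observed sequence variants collapse to exactly the 18 alleles
segregating in the simulated population (artefacts filtered, none of the
true alleles lost), replicate genotypes agree perfectly after validation,
and the scaffold-derived allele pool — which evolves without selection —
shows dN−dS indistinguishable from neutrality, as it should.

The same stages are available as a CLI
(`mungomhc simulate|genotype|classify|diversity|selection|supertype|linkage|comparative|run-all`);
`run-all` writes a manifest with seeds, parameters and output checksums,
and reruns with the same seed are byte-identical.

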