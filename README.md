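# idpevo

Tools for studying how an interaction between two intrinsically disordered
protein domains (CID and NCBD) emerged and evolved: maximum-likelihood
ancestral sequence reconstruction, domain substitution/indel accounting,
thermodynamic fitting of ITC and chemical-denaturation data, weighted
structural-ensemble statistics, and a desk-scale metainference /
parallel-bias well-tempered metadynamics sampler, together with seeded
synthetic-data generators so the whole pipeline is testable offline.

## Modules

| module | what it does |
| --- | --- |
| `idpevo.phylo_asr` | JTT+Gamma(+I) pruning likelihoods, marginal ancestral posteriors, alternative-residue reports, binary Fitch indel reconstruction, alignment masking/stripping |
| `idpevo.domain_rates` | substitution + indel tallies between ancestor/descendant domain windows, normalized and accumulated along a lineage |
| `idpevo.itc_binding` | single-site Wiseman isotherm forward model (iTC200-style perfusion corrections), nonlinear fits, Kd summaries and relative affinities |
| `idpevo.denaturation` | two-state urea/TFE CD transitions with linear baselines, single and global shared-m fits, `dG = m x midpoint` |
| `idpevo.ensemble_analysis` | multi-model PDB ensembles: bias reweighting `w ∝ exp(+B/kT)`, 0.5 nm heavy-atom contact maps, interface summaries, RMSF, helix populations, Rg, 2-D free-energy surfaces |
| `idpevo.metainference_toy` | Gaussian metainference energy over replicas with on-the-fly error sampling, PBMetaD bias deposition (bias factor 16 default), Metropolis sampling, final-bias reweighting, convergence drift |
| `idpevo.synthetic_data` | seeded generators: sequences evolved on trees, noisy isotherms and CD curves, two-chain backbone ensembles with known helix/contact statistics, analytic toy systems with quadrature reference free energies |

## CLI

Every analysis is exposed through the `idpevo` entry point:

```sh
idpevo asr --aln aln.fasta --tree tree.nwk --model jtt --gamma 4 \
       --mask-threshold 0.5 --gap-strip 0.95 --alt-threshold 0.7 --node root
idpevo domain-rates --nodes nodes.fasta --windows domains.tsv --lineage lineage.csv
idpevo itc-fit --data run.csv --config itc.yaml [--fix-n 1]
idpevo itc-summary --values kd_list.csv --reference 0.071
idpevo denat-fit --data a.csv b.csv --mode urea --shared-m
idpevo ensemble --pdb complex.pdb --bias bias.csv --kt 2.48 \
       --cutoff 0.5 --contact-threshold 0.05 --domain A=CID --domain B=NCBD
idpevo metainf-toy --config toy.yaml --seed 7
idpevo simulate {msa|itc|denat|ensemble|toy} --recipe recipe.yaml --seed 3 --out dir/
```

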