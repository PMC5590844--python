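# endopop

Statistical machinery for studying **endogamous populations** with genetic
data: haplotype-painting profile distances, coancestry-curve admixture
dating, Y-STR / haplogroup diversity and differentiation statistics, and
XP-EHH selection scans with permutation-calibrated thresholds — all
exercisable end to end on synthetic data with known ground truth.

Communities that marry within the group (religious minorities, caste and
tribal groups, priestly lineages) accumulate drift and long shared
haplotypes that confound naive distance measures: two groups can look
strongly differentiated simply because one has been isolated. The methods
here are the standard toolkit for separating *isolation* from *distinct
ancestry* and for timing the admixture events that did happen.

## What it computes

**Painting (`endopop.painting`).** The Li–Stephens copying model: each
recipient haplotype is an imperfect mosaic of donor haplotypes, with donor
switches at rate ρ per Morgan and per-site copying error θ, both fitted by
E-M. Output per recipient is the *painting profile* f_k — the share of its
genome copied from each donor group — plus expected segment counts
(`average_segment_size` summarizes within-group haplotype diversity) and
posterior path samples.

**Profile statistics (`endopop.profile_stats`).**

* TVD_XY = ½ Σ_k |f_kX − f_kY| — total variation distance between profiles.
* F_XY = TVD_XY / (½ (TVD~_X + TVD~_Y)), where
  TVD~_X = ½ Σ_i (L_i/L) Σ_k |f_ikX − f_kY| scatters X's per-chromosome
  profiles against Y. Because chromosomes drift independently, F_XY
  attenuates differences caused by recent isolation rather than ancestry.
* A simplex-constrained least-squares fit of a target profile onto
  surrogate profiles (with a 0.001 sparsity pass).
* f3(X; A, B) = mean[(x−a)(x−b) − h_x/(2n_x−1)] with block-jackknife Z
  scores; Z < −2 with f3 < 0 indicates admixture in X.

**Admixture dating (`endopop.admixture_dating`).** Coancestry curves — the
probability, relative to independence, that two sampled path labels at cM
distance d copy a given surrogate pair — fitted with
y(d) = A·exp(−λ d/100) + c. The decay rate λ per Morgan *is* the admixture
age in generations; CIs come from a hierarchical bootstrap over whole
chromosomes and recipient haplotypes.

**Uniparental (`endopop.uniparental`).** Nei's unbiased gene diversity with
SE; AMOVA Φ_ST on haplotype/haplogroup identity with permutation p; the
Markov-chain exact test of differentiation; principal coordinates of
1 − F_ST similarity matrices; a grid posterior for two-source admixture
proportions from haplogroup counts; and modal-haplotype ASD dating of
Y-STR clusters (t̂ = ASD/μ generations with μ = 15/7,856 by default,
years at 28 years/generation).

**Selection (`endopop.selection`).** EHH, iHH and normalized XP-EHH scans,
with genome-wide significance thresholds taken from the pooled empirical
distribution of scans over random re-partitions of the individuals
(quantiles 0.0001/0.9999 by default).

**Synthetic data (`endopop.synthetic_data`).** Generators with known truth
for every input: Balding–Nichols diverged haplotype panels smoothed by a
copying pass, admixed mosaics with Poisson breakpoints (rate g per Morgan),
stepwise-mutation STR sets (E[ASD] = μt), and two-source haplogroup
mixtures.

## Worked example

Simulate an admixture event 30 generations old (α = 0.25), paint the
admixed haplotypes against the two source panels, and date the event:

```sh
endopop --seed 5 --out-dir run simulate --mode admixed \
    --haplotypes 15 --sites 2400 --chrom-cm 100,100,100,100,100,100 \
    --divergence 0.3 --n 25 --generations 30
endopop --seed 5 --out-dir run paint \
    --haps run/panel.haps --map run/panel.map.tsv \
    --groups run/panel.groups.tsv \
    --recipients adm_h0,adm_h1,...,adm_h24 --samples 10
endopop --seed 5 --out-dir run date-admixture \
    --paths run/painting.paths.tsv --sites run/painting.sites.tsv \
    --pair A,B --bootstrap 100
```

`run/profiles.tsv` holds each recipient's painting profile (rows sum to 1;
these haplotypes are ~25% source A):

```
recipient	A	B
adm_h0	0.2886580818636855	0.7113419181363144
adm_h1	0.27150163667602345	0.7284983633239767
```

and `run/admixture_date.json` the fitted date:

```json
{
  "date_generations": 31.6993330424499,
  "ci": [22.318077525678977, 41.08058855922083],
  "amplitude": -0.9840865850207915,
  "asymptote": 1.0074962971352917,
  "no_signal": false
}
```

The fitted decay rate of 31.7 per Morgan is the age estimate in
generations; the 95% CI (22.3–41.1, wide at this deliberately small demo
size of 25 haplotypes and 6 chromosomes) covers the simulated truth of
30. The
negative amplitude is expected for a cross-source pair: nearby segments
tend to share a source, so joint (A, B) copying is depressed below its
asymptote at short distances.

The same works for Y-STR coalescence dating:

```sh
endopop --seed 7 --out-dir run2 simulate --mode str --n 40 --str-t 35
endopop --seed 7 --out-dir run2 uniparental --mode tmrca \
    --str run2/str.tsv --haplogroup HG1 --iterations 50000
```

→ ASD = 0.0375 from the modal haplotype (frequency 0.825), t̂ = 19.6
generations (95% CI 8.7–34.9), i.e. ~550 years at 28 years/generation —
the 40 simulated chromosomes are a small sample, hence the wide interval
around the generating value of 35.

The library API mirrors the CLI; see the module docstrings and
`docs/methods.md` for the models, estimators and defaults.

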