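# phylocap

Paralog screening and unrooted-triplet coalescent inference for
targeted-enrichment (hybrid capture) phylogenomics of recent radiations.

Capture datasets for recently radiated groups — hundreds of nuclear loci
sequenced across closely related species and conspecific populations — face
two recurring problems.  First, reads from different members of a gene
family co-map onto a single target, so an accession's consensus may
represent one paralog in some samples and another paralog in the rest,
corrupting phylogenetic signal.  Second, once clean orthologous loci are in
hand, the interesting questions sit at the population level, where gene-tree
discordance from incomplete lineage sorting demands coalescent-aware model
comparison rather than concatenated tree building.  `phylocap` implements
both stages for the common study design of one (consensus) sequence per
sample:

* **Locus screening** (`phylocap.locus_screening`) — mapping-stringency scan
  metrics, base-call quality filtering (drop quality < 36 and indels),
  IUPAC-ambiguity masking, a coverage screen (exclude a locus when, for more
  than a third of its accessions, depth exceeds 3× that accession's own
  across-locus mean), an outgroup delta-variation screen (exclude when
  removing a deeply divergent outgroup changes the proportion of variable
  sites by ≤ 8%), missing-data column trimming, variable /
  parsimony-informative site statistics, and supermatrix concatenation with
  partition tables (FASTA/NEXUS/relaxed-PHYLIP output).
* **Target selection** (`phylocap.target_selection`) — RPKM and the pure
  filter predicates for choosing capture targets from annotated
  transcriptome contigs (identity < 98.5%, single-copy, 1–3 introns < 1 kb,
  balanced read shares; or differential expression: EC numbers with > 75% of
  reads from one species, orthology support at e-value < 1e-40).
* **Triplet coalescent model** (`phylocap.triplet_model`) — the exact
  probability of unrooted triplet mutation configurations under a
  three-population divergence model, maximum-likelihood fitting, nested
  model comparison and profile confidence intervals.
* **Power analysis** (`phylocap.power_analysis`) — expected per-locus
  log-likelihood differences between the full model and each nested model,
  and the number of unlinked loci required for rejection.
* **Synthetic data** (`phylocap.synthetic_data`) — generators with known
  truth for every input above: coalescent triplet loci, alignments that
  invert exactly to their configurations, capture datasets with planted
  paralogous loci, stringency-scan call tables and candidate-locus tables.

## The model

One haploid (or N-masked consensus) sequence is sampled from each of three
populations *a*, *b*, *c*, where *b* and *c* split at time *T₁* and their
ancestor splits from *a* after a further internode *T₂* (times in units of
2*Nₑ* generations).  Under infinite-sites mutation at per-locus rate θ/2 per
branch (θ = 4*Nₑ*μ), every segregating site isolates exactly one sequence,
so each locus reduces to counts (s_a, s_b, s_c) of minority-state sites —
the sufficient statistic of the unrooted genealogy, requiring no outgroup.

Backwards in time, lineages *b*, *c* may coalesce at rate 1 on
[*T₁*, *T₁*+*T₂*]; all surviving lineages then enter the ancestral
population (first of three pairs at rate 3, final pair at rate 1).  A
genealogy whose first coalescence joins pair (x, y) at time *u* with the
final coalescence at *w* has unrooted branch lengths ℓₓ = ℓᵧ = *u* and
ℓ_z = 2*w* − *u*; mutation counts are independent Poisson((θ/2)ℓ).  The
package integrates the genealogy density analytically (the ancestral phase
reduces to incomplete-gamma sums; the intermediate epoch is one smooth 1-D
integral under a fixed Gauss–Legendre rule), giving configuration
probabilities accurate to ~1e-12.  For example, with no divergence
(panmixia), P(0,0,0) = [2/(2+θ)]·[1/(1+θ)].

Four nested models are compared by likelihood-ratio tests: **full** (θ, T₁,
T₂ free), **two-population** (T₁ = 0), **polytomy** (T₂ = 0) and
**panmixia** (T₁ = T₂ = 0), with plain chi-square reference distributions
(df 1 or 2) and profile-likelihood confidence intervals (lnL drop of half
the chi-square(1) quantile, 1.9207 at 95%).

Because loci are unlinked, log likelihoods add across loci, so the expected
support for the full model grows linearly: n·E[ΔlnL], where the per-locus
expectation is the KL divergence from the generating model to the nested
model at its pseudo-true (KL-projected) parameters.  The loci required to
reject a nested model at level α is ceil(threshold / E[ΔlnL]) with
threshold = χ²_df(1−α)/2.

## Worked example

```python
from phylocap import DivergenceParams, fit_mle, profile_ci, loci_required
from phylocap.synthetic_data import simulate_triplet_configs

true = DivergenceParams(theta=1.0, t1=0.1, t2=0.4)
configs, truth = simulate_triplet_configs(true, n_loci=5000, seed=20150917)
fit = fit_mle(configs, "full", assignment="fixed")
print(f"theta={fit.mle.theta:.3f} t1={fit.mle.t1:.3f} t2={fit.mle.t2:.3f}")
lo, hi = profile_ci(configs, fit, "t2")
print(f"t2 95% CI: {lo:.3f}-{hi:.3f}")
res = loci_required(true, "polytomy", alpha=0.05)
print(f"loci to reject a polytomy: {res.loci_required} "
      f"(E[dlnL]={res.e_delta_lnl:.4f}/locus)")
```

prints

```
theta=0.984 t1=0.090 t2=0.416
t2 95% CI: 0.376-0.458
loci to reject a polytomy: 38 (E[dlnL]=0.0515/locus)
```

Fitting 5000 simulated loci recovers the generating parameters within a few
percent; the profile interval brackets the true T₂ = 0.4; and at this
divergence depth ~38 unlinked loci already suffice in expectation to reject
a star-shaped (polytomy) history at α = 0.05.

A CLI mirrors the library: `phylocap simulate|fit|power|screen|concat|select`
(see `phylocap --help`).

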