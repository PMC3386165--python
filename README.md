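# perturbnet

Posterior association networks and functional modules from rich
single-gene perturbation phenotypes.

## The problem

Combinatorial knock-downs measure genetic interactions directly but scale
terribly in human cells: every pair of genes needs its own double
perturbation. An affordable alternative is to perturb each gene once,
measure a *rich* phenotype — the same readout across several biochemical
conditions or cell lines, in replicates — and infer which genes act
together from the similarity of their phenotypic profiles. `perturbnet`
implements this strategy end to end for screens such as RNAi libraries
read out by plate-based reporter assays. Its users are computational
biologists holding a gene × replicate matrix of phenotype Z-scores who
want (a) a network of statistically supported functional interactions and
(b) compact, significance-filtered gene modules to prioritise for
follow-up experiments.

## The model

The association between genes *i* and *j* is the cosine similarity
(uncentred correlation) of their phenotype vectors,
cc<sub>ij</sub> = x<sub>i</sub>·x<sub>j</sub> / (‖x<sub>i</sub>‖‖x<sub>j</sub>‖),
mapped onto the unit interval by a<sub>ij</sub> = (cc<sub>ij</sub>+1)/2.
Transformed scores are modelled as a three-component beta mixture

&nbsp;&nbsp;&nbsp;&nbsp;f(a) = π₋ f(a; α₋, β₋) + π₀ f(a; α₀, β₀) + π₊ f(a; α₊, β₊),

whose components represent negative association (x−), no association
(x0) and positive association (x+). The x0 shapes are *fixed* before
fitting: the screen is permuted, a single beta is fitted to each
permutation's scores by maximum likelihood, and the component is pinned
at the coordinate-wise medians of the fitted shapes. The remaining
parameters are estimated by an EM algorithm; with a prior interaction
network (e.g. protein–protein interactions) the pairs are stratified and
each stratum *k* gets its own mixture coefficients π<sub>k</sub>,
regularised by a Dirichlet prior with hyperparameters γ<sub>km</sub>
(maximum a posteriori; γ ≡ 1 recovers plain maximum likelihood).

Each pair's evidence for interaction is the posterior odds
("signal-to-noise ratio")

&nbsp;&nbsp;&nbsp;&nbsp;K<sub>ij</sub> = (P(x−) + P(x+)) / P(x0),

and edges with K<sub>ij</sub> ≥ 10 — "strong" evidence on the Jeffreys
scale — form the posterior association network (PAN), signed by
comparing P(x+) and P(x−). In parallel, genes are clustered
hierarchically on their association profiles, cluster uncertainty is
assessed by multiscale bootstrap resampling of replicate columns
(sample-size scales 0.5–1.4), and each cluster receives an approximately
unbiased (AU) p-value from the regression
Φ⁻¹(1−BP<sub>r</sub>) = v√r + c/√r, p = Φ(v−c). Significant clusters are
superimposed on the PAN and filtered by p-value, size, edge density and
phenotype sign to yield functional modules.

A fully seeded synthetic-screen generator with planted modules, a prior
corruption model and an AUC harness reproduce the method's operating
characteristics without any external data.

## Worked example

Simulate a screen with two planted 30-gene modules among 100 genes
(noise proportion 0.4, 8 replicates), fit the global model and infer the
network:

```python
import numpy as np
import perturbnet as pn

spec = pn.SimulationSpec(noise=0.4, n_rep=8)
screen, gold = pn.sample_screen(spec, seed=11)

assoc = pn.cosine_matrix(screen)
rng = np.random.default_rng(12)
null = pn.fit_null(pn.permute_screen(screen, 20, rng, mode="per_column"))
res = pn.BetaMixtureModel(assoc, null).fit()
print(res.summary())
```

```
Beta-mixture model of association scores
============================================
pairs: 4950   strata: 1   gamma scale: 0
EM iterations: 36   converged: True   log-posterior: 1835.6221

component   alpha      beta       mean     fixed
neg         1.6467     14.1085    0.1045   no
null        2.4795     2.4768     0.5003   yes
pos         14.8119    1.5813     0.9035   no

stratum     n pairs    pi_neg    pi_null   pi_pos
0           4950       0.4269    0.1607    0.4125
```

The permutation null is symmetric about 0.5 (Beta(2.48, 2.48)); the free
components settle at the low and high ends of the score range, and the
fitted coefficients say roughly 84% of pairs carry some association —
plausible for a screen in which 60 of 100 genes belong to planted
modules and all pairs share mean-driven similarity. Thresholding the
posterior odds and scoring against the planted truth:

```python
pan = res.infer_network(screen, cutoff=10.0)
print(pan)                                        # PAN(100 nodes, 3403 edges, cutoff=10)
print(pn.auc(res.snr(), gold.edge_labels()))      # 0.883
```

`1688` edges are positive and `1715` negative; the posterior-odds
ranking separates planted from background pairs with AUC 0.883 at this
noise level. Module search runs the same way through
`pn.multiscale_bootstrap`, `pn.filter_modules`, or from the shell:

```bash
perturbnet infer --screen screen.tsv --out-dir results/ --seed 7
```

which writes the association table, fitted model JSON, posterior/SNR
table, SIF + TSV networks and the filtered module report.

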