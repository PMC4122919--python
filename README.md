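# mitopopcons

**Functional-element discovery from ultradense within-species polymorphism
in a mitochondrial-like genome.**

Purifying selection removes deleterious variants, so at functional sites it
depresses both between-species divergence and within-species diversity.
Comparative methods (phyloP, phastCons) exploit the first signal; this
package models the second, for the regime where polymorphism is so dense —
on the order of one segregating mutation on every other base pair, as in
deep samples of human mtDNA — that the per-site number of segregating
alleles becomes a quantitative, near base-pair-resolution readout of
constraint.

It is a library for population geneticists and method developers who want
to study that readout end to end on data with known ground truth: a
synthetic-data generator with explicit per-site constraint, the
mutational-bias correction, the correlation analyses, the element-calling
HMM, and the evaluation machinery, all importable and all exercisable
without any external download.

## The model

For each site *i* of a circular genome of length *L*, the observation is
the number of distinct alleles `a_i ∈ {1, 2, 3, 4}` in a sample of *n*
chromosomes (1 = monomorphic).

**Mutational-bias correction.** Asymmetric mtDNA replication leaves the
parental heavy strand single-stranded for a duration `D_ssH(i)`: with unit
fork speeds, leading-strand distance *d* from the heavy-strand origin O_H
and origin separation *D*,

```
D_ssH = 2 (D − d)          if d ≤ D          (major arc)
D_ssH = max(L − 2y, 0)     if d = D + y      (minor arc)
```

Single-stranded DNA mutates faster, so before reading polymorphism as
selection the gradient is absorbed by a Poisson GLM,
`a_i ~ Poisson(exp(β0 + β1 · D_ssH(i)))`, fitted by IRLS with the control
region omitted; deviance residuals are the bias-corrected polymorphism.

**Correlation analyses.** Spearman's ρ (midranks — allele counts are almost
all ties — with the *t*-approximation for *p*) between allele counts (or GLM
residuals) and the negated phyloP-like score, at single sites, in 10-bp
adjacent windows, per gene, per codon class (second positions vs 4-fold
degenerate third positions under the vertebrate mitochondrial code), and
between minor allele frequencies and divergence.

**mitoPopCons HMM.** A two-state (constrained/unconstrained) HMM over
`a_1..a_L` with a *fixed* transition matrix (default: symmetric, stay
probability 0.99, i.e. 100-bp expected runs; a phastCons-style
(length, coverage) parametrization is provided). Baum–Welch learns the
2×4 emission matrix only — the transition M-step is swamped with
pseudocounts proportional to the fixed matrix — from 10 random restarts,
keeping the highest-likelihood fit. The state more likely to emit
monomorphic sites is "functional"; Viterbi runs of it are the called
elements.

**Evaluation.** Base-pair overlap between polymorphism-called and
divergence-called elements, tested by 10,000 random re-placements of the
calls on the circular genome; genic/intergenic composition summaries; and a
power analysis that hypergeometrically downsamples the per-site allele
counts to sample sizes 100..1,800 (+1,864), retrains the HMM at each size,
and scores the fraction of truly constrained bp recovered.

## Worked example

```python
from mitopopcons import (
    SyntheticConfig, generate_layout, simulate_site_alleles,
    simulate_divergence, spearman, baum_welch_train, viterbi_decode,
    call_elements, element_recovery,
)

config = SyntheticConfig(seed=7)            # 16,569 bp, n = 16,411 samples
_, truth = generate_layout(config)
sites = simulate_site_alleles(config, truth, seed=8)
neg_phylop, _ = simulate_divergence(config, truth, seed=9)

print(spearman(sites.allele_count.astype(float), neg_phylop.values))
# CorrelationResult(rho=0.399, P < 2.2e-16, n=16569)

train = baum_welch_train(sites.allele_count, n_restarts=10, seed=10)
path = viterbi_decode(train.params, sites.allele_count)
elements = call_elements(path, train.functional_state, sites.length)
print(len(elements), elements.total_bp)
# 1 15411
print(element_recovery(elements, truth.elements))
# {'recall': 0.932, 'precision': 1.0, 'f1': 0.965, 'overlap_bp': 15411}
```

The site-level ρ ≈ 0.4 (*P* below the 2.2 × 10⁻¹⁶ reporting floor) is the
polymorphism–divergence coupling created purely by shared constraint; the
HMM then recovers 93% of the truly constrained base pairs with essentially
no false-positive calls — the missing 7% is the weakly constrained control
region, which polymorphism alone cannot separate from neutral sequence.

The `examples/` directory holds one short narrative script per capability
(simulation, correlations, bias correction, element calling, overlap
testing, power analysis); each prints the numbers it computes and says what
they mean. A thin CLI (`mitopopcons simulate|run|hmm-train|hmm-call|
overlap|dssh-correct|power|liftover`) wraps the same functions for shell
use.

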