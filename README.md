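# bissekit

Power and accuracy analysis for **BiSSE** — the binary-state speciation and
extinction model — aimed at researchers who test whether a binary trait
drives diversification and want to know, before trusting a significant
result, how much power their tree actually affords and whether the inferred
rate asymmetry could be an artifact of tip-ratio bias.

The package provides, in one place:

- an exact event-driven simulator of trees with a co-evolving binary
  character under state-dependent rates λ0, λ1 (speciation), μ0, μ1
  (extinction) and q01, q10 (character transitions), stopped at a fixed
  number of contemporaneous extant tips;
- the BiSSE log-likelihood of an ultrametric tree with tip states, computed
  by pruning with an adaptive Runge–Kutta–Fehlberg 4(5) integrator
  (E′ = μ − (λ+μ+q)E + qE' + λE², D′ = −(λ+μ+q)D + qD' + 2λED per state);
- maximum-likelihood fitting under equality constraints (the 3/4/5/6
  parameter model family) via multi-start cyclic Brent coordinate descent
  with warm-start chains;
- likelihood-ratio power analysis with simulated null distributions and
  empirical critical values (the χ² cutoff is available but not default);
- stationary-frequency machinery: the equilibrium state-0 frequency x̂
  solving g·x̂(1−x̂) − x̂·q01 + (1−x̂)·q10 = 0 (g = λ0−μ0−λ1+μ1), and its
  inverse — the rate ratio producing a target tip bias;
- parameter-recovery experiments and summaries.

See `docs/methods.md` for the model, numerics and design choices.

## Worked example

```python
from bissekit import (BisseModel, ConstraintPattern, OptimizerConfig,
                      RateSet, prune_extinct, simulate_tree)
from bissekit.simulate import batch_rng

# simulate a 200-tip tree where state 1 speciates 1.5x faster
truth = RateSet(lambda0=0.1, lambda1=0.15, mu0=0.03, mu1=0.03,
                q01=0.01, q10=0.01)
tree = prune_extinct(simulate_tree(truth, 200, batch_rng(11, 0)))

full = BisseModel(tree).fit(OptimizerConfig(seed=0))
print(full.summary())
constrained = BisseModel(
    tree, pattern=ConstraintPattern.constrained("speciation")
).fit(OptimizerConfig(seed=0))
stat, pval = full.lrt(constrained)
print(f"LRT = {stat:.3f}  (chi2 p = {pval:.3f})")
```

prints

```
BiSSE maximum-likelihood fit
==============================================
tips: 200  (state 0: 58, state 1: 142, frac0 = 0.2900)
pattern: l0,l1,m0,m1,q0,q1  (free parameters: 6)
root prior: stationary
ln L = -678.407337   converged: True   cycles: 7
----------------------------------------------
     rate     estimate
  lambda0    0.0923804
  lambda1     0.134276
      mu0        1e-08  (at bound)
      mu1    0.0178974
      q01    0.0135282
      q10   0.00480877
==============================================
LRT = 2.249  (chi2 p = 0.134)
```

The speciation estimates land near the truth (0.1 / 0.15) with the
asymmetry in the right direction, and μ̂0 pins at the lower bound — a
typical reconstructed-tree extinction estimate, and exactly the kind of
diagnostic the summary flags. Yet the LRT does not clear a 5% cutoff: on a
single 200-tip tree the test has little power even when the asymmetry is
real, the central cautionary point of the analysis (below ~300 tips,
significant results deserve a power check).
The same interfaces accept user data: `BisseModel.from_files("tree.nwk",
"states.tsv")` with a Newick tree and a two-column tip/state TSV.

A CLI mirrors the library (`bissekit simulate|loglik|fit|power|recover|
solve-bias`); `bissekit solve-bias --process extinction --target-ratio 3:1`
prints the extinction ratio (1.3046) that yields a 3:1 stationary tip bias
around base rates.

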