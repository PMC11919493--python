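# polyspace

**Finite polymorphic spaces and the saturation of the molecular clock in
prokaryotes.**

The molecular-clock reading of sequence data assumes that dissimilarity
between homologous genes keeps growing with time, so that divergence `d`
can stand in for phylogenetic time `t`.  But the variants a gene can
realise are finite: at most `k^L` for length `L` over `k` monomers, and
far fewer once purifying selection limits each site to a small allowed
set and transition/transversion bias (κ) concentrates the mutation
kernel.  In a bounded space, mean divergence from any ancestor saturates
at a plateau `D∞`, and past the critical times

* `tcrit50` — generations until `d` reaches `0.5·D∞`, and
* `tcrit90` — generations until `d` reaches `0.9·D∞`,

divergence decouples from time: trees mixing sequences from beyond these
horizons inherit artefacts, and distant lineages can re-visit each
other's sequences.  `polyspace` is a toolkit for microbial
phylogenetics researchers to quantify all of this for a given gene:

* log-space-exact sizes of naive spaces (`k^L`) and blind-permutation
  probabilities (`(1/k)^L`);
* exhaustion times under two demographies — unlimited doubling
  (`k^L = μ·N0·2^n`) and constant effective population
  (`k^L = μ·Ne·n`);
* effective spaces `ke^Le` read off reference alignments (effective
  length `Le` = variable sites; effective base `ke` = accessibility
  perplexity under κ-bias);
* a forward-time birth–death simulator of gene-copy populations with
  per-site allowed-set constraints, validated against Jukes–Cantor and
  Kimura two-parameter closed forms;
* estimators for `D∞`, `tcrit50/90`, post-saturation steady-state
  divergence distributions, the collapse of the time–divergence
  correlation, and lineage revisitation probabilities (with an exact
  Poisson-binomial reference);
* a generator of 5S-rRNA-like synthetic reference alignments with known
  ground truth.

## Worked example

```bash
polyspace exhaust -L 120                      # unlimited doubling
polyspace exhaust -L 120 --regime constant_Ne # constant Ne = 2e8
```

prints (abridged):

```
"n_rounded_up": 272, "duration_days_sci": "3.78e+00"
"n_sci": "3.48e+73", "duration_years_sci": "1.32e+69"
```

A 120 bp gene exhausts its naive space in 272 generations (under four
days of *E. coli*-style doubling) if growth is unlimited, but in
`1.32e69` years at a constant `Ne = 2e8` — the clock's safety depends
entirely on which accounting applies.

The full simulated analysis lives in `analysis/` (each script states what
it does and writes its tables under `results/`):

```bash
python analysis/01_exhaust_space.py       # the two analytic regimes
python analysis/02_build_references.py    # synthetic 5S-like references
python analysis/03_simulate_divergence.py # 24-replicate forward simulation
python analysis/04_critical_times.py      # plateau, tcrit50/90, steady state
python analysis/05_clock_collapse.py      # correlation decay, revisitation
```

With the default 120 nt gene (50 variable sites, κ = 4, per-generation
substitution probability 1.5e-3, 100 copies/replicate) this prints:

```
effective space: Le = 50, ke = 3.299 -> 10^25.92 variants (naive: 10^72.25)
plateau D_inf = 0.3099 (SD 0.0206); tcrit50 = 381 generations, tcrit90 = 1569
steady-state distribution over 4790 copies, max TV between snapshots 0.031
time-divergence correlation: r = +0.967 (first window) ... r = -0.067 (past tcrit90)
revisitation (L=6, free sites): exact 2.441e-04, Monte-Carlo 1.950e-04 +/- 3.1e-05
```

Read: constraint and bias shrink the space by ~46 orders of magnitude;
divergence saturates at ~0.31 (the free-site fraction times 3/4); past
~1600 generations the divergence distribution is stationary and the
time–divergence correlation is gone; and two fully independent lineages
of a short unconstrained gene coincide at the exactly predicted
stationary rate.  See `docs/methods.md` for models, estimators and
limitations.

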