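# redpart

**Coordination as redundancy, and redundancy partitioning of collective
systems.**

From fish schools to neural populations, "how coordinated is this
system?" is usually answered with system-specific order parameters that
cannot be compared across systems.  `redpart` implements a
system-independent alternative: the **relative redundancy**
(normalized total correlation) of the system's microscopic variables
$\{X_i\}_{i \in S}$,

$$r \;=\; \frac{\sum_i H(X_i) - H(\{X_i\})}{\sum_i H(X_i)} \;\in\; [0,\, 1 - 1/n),$$

the fraction of the system's description that a joint encoding makes
unnecessary.  It is 0 for independent elements, $1 - 1/n$ for $n$
perfect copies, and invariant to the overall scale of individual
variability — a dimensionless coordination scale shared by any system.

On top of the measure, the package implements **redundancy
partitioning**: decomposing a system into its most coordinated
components by maximizing the average expected component redundancy
$\tfrac1m\sum_j \mathbb{E}[r(A)\,|\,j]$ over probabilistic assignments
$p(j|i)$, via a Blahut–Arimoto-style alternating minimization
($p(j|i) \propto p(j)\,e^{\beta\,\Delta d(i,j)}$), with exact,
Monte-Carlo, and fast hard-partition ($\beta\to\infty$) variants.
Scanning the number of components $m$ and looking for the first local
minimum of the drop $\Delta(m) = \bar r(m-1) - \bar r(m)$ gives a
data-driven component count.

Intended users: researchers in collective behavior, systems biology,
and network inference who have multivariate time series (tracked
trajectories, simulations, population recordings) and want a
comparable coordination number and a principled mesoscale
decomposition.

## What's inside

- `redpart.discrete` — exact total correlation / relative redundancy
  for discrete joint distributions (bits).
- `redpart.observations`, `redpart.gaussian` — observation matrices,
  rank-Gaussianization, and the practical Gaussian lower bound on
  redundancy for continuous data (with the per-variate quantization
  offset α that makes the bound's denominator positive).
- `redpart.partition` — expected component redundancy, Δd, the
  soft-assignment solver, the greedy hard-partition solver, the
  achieved rate I(S; Ŝ), and the Δ-average-redundancy scan.
- `redpart.simulate` — seeded Vicsek and zone-based schooling
  simulators, multi-group fixtures, the redundancy-vs-noise sweep, and
  KDE mode estimation.
- `redpart.tracks`, `redpart.cli` — tracked-trajectory ingestion
  (frame, id, x, y), Savitzky–Golay velocities, ±15 s windowing, and a
  `redpart` command-line tool (`simulate-vicsek`, `simulate-school`,
  `redundancy`, `sweep`, `partition`, `scan`).

See `docs/methods.md` for the model, estimators, numerical choices,
and known limitations.

## Worked example

Two non-interacting schooling groups of 5 agents each are simulated at
the high-noise condition, velocities are rank-Gaussianized, and the
hard-partition scan is run for m = 1..10:

```python
import numpy as np
from redpart import (DiscretePMF, discrete_relative_redundancy,
                     group_structure_scan, solve_hard)

pmf = DiscretePMF.identical_copies([0.5, 0.5], 4)
print(f"four synchronized coins: r = {discrete_relative_redundancy(pmf):.3f}")

curve, model, truth = group_structure_scan([5, 5], eta=0.2, seed=42)
print("delta curve (m=2..10):", [round(v, 4) for v in curve.delta])
print("first local minimum at m =", curve.first_local_minimum)

result = solve_hard(model, m=2, restarts=50, seed=43)
print("recovered components:", result.hard_labels.tolist())
print("true group labels:   ", truth.tolist())
```

prints

```
four synchronized coins: r = 0.750
delta curve (m=2..10): [0.0026, 0.0537, 0.0269, 0.0337, 0.0224, 0.016, 0.012, 0.0094, 0.0075]
first local minimum at m = 2
recovered components: [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
true group labels:    [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
```

Four perfectly synchronized coins score $r = 1 - 1/4 = 0.75$.  For the
two simulated groups, splitting the system into two components costs
almost nothing (Δ(2) = 0.0026: the groups are independent), while a
third component would have to cut a coordinated group (Δ(3) = 0.054,
twenty times larger) — so the Δ curve has its first local minimum at
m = 2, and the m = 2 partition recovers the two groups exactly from
velocity coordination alone, with no position information.

The same pipeline runs from the shell:

```bash
redpart simulate-school --group-sizes 5,5 --eta 0.2 --steps 5500 --seed 42 --out groups.csv
redpart scan --input groups.csv --window 5000 --restarts 50 --seed 1 --out curve.json
```

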