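# rrbm — a refined resource budget model of mast seeding

Many perennial plants reproduce in intermittent, highly variable pulses
("masting"). The classic resource budget model explains this for purely
sexual reproducers: a plant banks an annual photosynthetic surplus and
flowers only when its stored reserve crosses a threshold, with seed set
costing a multiple *R* of the flowering effort. Species such as *Stipa
tenacissima*, however, reproduce both sexually and asexually, and the
classic model has nothing to say about them. This package implements a
refined resource budget model for such species: a second, lower threshold
for asexual (clonal) reproduction and an explicit split of reproductive
allocation between the sexual and asexual modes.

It is aimed at theoretical ecologists who want to simulate the model,
analyze its equilibria in closed form, and map reproductive-period regimes
across parameter space.

## The model

The stored reserve `y(t)` of a single plant evolves annually. With surplus
`Ps`, asexual threshold `L1`, sexual threshold `L2 > L1`, flowering
coefficient `p`, asexual coefficient `q`, asexual depletion `d` and
depletion coefficient `R` (seed-set cost / flowering cost):

```
y(t+1) = y(t) + Ps                                    if y(t)+Ps <  L1   (RA)
y(t+1) = y(t) + Ps − d·(y(t)+Ps−L1)                   if L1 ≤ y(t)+Ps ≤ L2 (AR)
y(t+1) = y(t) + Ps − (p+q+R·p)·(y(t)+Ps−L1)           if y(t)+Ps >  L2   (SAR)
```

In an SAR year the flowering cost is `C_f = p·(y+Ps−L1)`, the asexual cost
`C_v = q·(y+Ps−L1)` and the seed-set cost `C_a = R·C_f`. The map is
piecewise linear, so both candidate equilibria are closed-form:

* asexual branch: `y2* = L1 + Ps/d − Ps`, exists iff `Ps < (L2−L1)·d`,
  Lyapunov exponent `λ = ln|1−d| < 0` (always stable when it exists);
* sexual branch: `y1* = L1 − Ps + Ps/(p+q+R·p)`, exists iff
  `Ps > (p+q+R·p)·(L2−L1)`, `λ = ln|1−p−q−R·p|`, stable iff
  `R·p < 2−p−q`.

These split parameter space into four regimes ("scenes"): (1) stable
asexual equilibrium, (2) no equilibrium (multi-year mixed cycles),
(3) stable annual sexual reproduction, (4) unstable sexual equilibrium
(variable seed set). Long-run behaviour is summarized by an integer period
code: −1 (asexual every year), 0 (sexual every year at a fixed point),
1–18 (sexual reproduction every so many years), 19 (longer or irregular).

## Worked example

Analyze the bundled constant-annual-reproduction scenario (`fig1c`:
`L1=2, Ps=3, L2=3, d=0.6, p=0.1, q=0.9, R=6`):

```sh
rrbm analyze --scenario fig1c
```

prints (abridged):

```json
{
  "scene": 3,
  "fixed_points": {
    "asexual": {"value": 4.0, "exists": false},
    "sexual":  {"value": 0.875, "exists": true, "stable": "stable",
                "lyapunov": -0.5108256237659905}
  },
  "lyapunov_numeric": -0.5108256237659905
}
```

The plant sits in scene 3: the sexual-branch equilibrium
`y1* = 2 − 3 + 3/1.6 = 0.875` exists and is stable (`λ = ln 0.6 ≈ −0.511`),
so reserves settle at 0.875 and the plant reproduces sexually and asexually
every year. Consistently,

```sh
rrbm period --scenario fig1c     # -> {"code": 0, "cycle_length": 1, ...}
rrbm period --scenario fig1b     # -> {"code": 3, ...}  (sexual every 3 years)
```

Raising the sexual threshold to `L2=6` (`fig1b`) removes both equilibria and
produces a 3-year cycle: two asexual years bank surplus until the pool
clears `L2`, then one costly sexual year resets the reserve.

Phase diagrams over the (p, q) unit square at several depletion
coefficients (the bundled `fig2_base` template fixes `L1=2, Ps=3, L2=3,
d=0.6`):

```sh
rrbm sweep --scenario fig2_base --R-values 1,2,3,6,9 --grid 51 --out sweep.csv
```

Counting cells whose code is not 0 in `sweep.csv` gives 650, 1309, 1638,
2062 and 2231 of 2601 cells for R = 1, 2, 3, 6 and 9: costlier seed set
pushes an ever larger share of allocation space away from constant annual
reproduction toward long or irregular masting cycles. With
`--simplex --R-values 1` (total allocation `p+q ≤ 1`) every evaluated cell
is code 0 — at cheap seed set the plant reproduces sexually every year
regardless of how allocation is split.

The same operations are available as library functions
(`rrbm.simulate`, `rrbm.step`, `rrbm.classify_regime`,
`rrbm.asexual_fixed_point`, `rrbm.sexual_fixed_point`,
`rrbm.lyapunov_numeric`, `rrbm.period_code`, `rrbm.sweep`).

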