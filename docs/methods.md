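# Methods

## Model

A single adult plant carries a stored resource `y(t)` (resource units) at
the start of year `t` and gains a fixed annual surplus `Ps` after growth
and maintenance. The pre-reproduction pool `y(t)+Ps` is compared with two
thresholds, `L1` (asexual reproduction) and `L2` (sexual reproduction),
with `L1 < L2`: below `L1` the plant only accumulates (RA); between the
thresholds it spends a fraction `d` of the excess `y+Ps−L1` on clonal
reproduction (AR); above `L2` it spends fractions `p` (flowering) and `q`
(clonal) of the excess, plus a seed-set cost equal to `R` times the
flowering cost (SAR), for a total outlay `(p+q+R·p)·(y+Ps−L1)`. The model
is a deterministic one-dimensional piecewise-linear map with branch slopes
1, `1−d` and `1−(p+q+R·p)`.

Assumptions inherited from the resource-budget tradition: constant annual
surplus (no environmental stochasticity), a single individual (no pollen
coupling or population synchrony), reproduction thresholds constant over
time, and reserves allowed to go negative (a costly sexual year may
overdraw storage; the linear branches are never clamped).

### Boundary convention

A pool exactly equal to `L1` or `L2` is assigned to the middle (AR)
branch. At `pool == L1` the AR cost is zero, so the choice is
inconsequential there; at `pool == L2` it is a genuine tie-break, applied
consistently in the scalar and vectorized code paths.

## Parameters

| symbol | meaning | units | valid range | bundled values |
|---|---|---|---|---|
| `L1` | asexual threshold | resource | `L1 < L2` | 2 or 4 |
| `L2` | sexual threshold | resource | `> L1` | 3, 6 or 8 |
| `Ps` | annual surplus | resource/yr | `> 0` | 3 |
| `p` | flowering coefficient | — | (0, 1) | 0.1 |
| `q` | asexual (SAR) coefficient | — | (0, 1) | 0.9 |
| `d` | asexual (AR) depletion | — | (0, 1) | 0.6 |
| `R` | seed-set / flowering cost ratio | — | `> 0` | 1–12 |

`p + q` is deliberately not constrained to 1 (the sweep axes are
independent); when the total SAR allocation `p+q+R·p` exceeds 1 a warning
is logged because reproduction years then overdraw the reserve. `d` and
`q` are kept independent: nothing in the model ties the asexual spending
fraction of an AR year to that of an SAR year. A `reduction` flag relaxes
the invariants to `L1 == L2`, `p == 1`, `q == 0`, collapsing the map to
the classic single-threshold resource budget rule
`y + Ps − (1+R)(y+Ps−L)`; this is used as an exactness cross-check.

## Equilibrium analysis

Setting `y(t+1) = y(t)` on each reproductive branch gives two candidate
equilibria:

* `y2* = L1 + Ps/d − Ps` on the AR branch, which lies inside the branch
  iff `Ps < (L2−L1)·d`; Lyapunov exponent `ln|1−d|`, negative for any
  valid `d`, so it is stable whenever it exists.
* `y1* = L1 − Ps + Ps/(p+q+R·p)` on the SAR branch, which lies above `L2`
  iff `Ps > (p+q+R·p)·(L2−L1)`; exponent `ln|1−p−q−R·p|`, so stability is
  `R·p < 2−p−q`.

(The SAR denominator is `p+q+R·p`; only that form passes the substitution
check `step(y1*) == y1*`, which the test suite enforces on 1000 random
parameter draws.)

All comparisons are strict; an equality within `1e-12` is reported as a
boundary (scene 0, `exists = false`) rather than silently assigned to a
side, and `|λ| ≤ 1e-12` is reported as `marginal` rather than folded into
stable/unstable. The four scenes follow: (1) `y2*` exists (stable);
(2) neither exists; (3)/(4) `y1*` exists and is stable/unstable. The
numeric Lyapunov estimator averages `ln|slope|` over the branches visited
after burn-in; because the map is piecewise linear this equals the
analytic exponent exactly whenever the orbit settles on one branch.

## Period classification

A parameter set is classified from a simulated orbit: discard `burn_in`
years, inspect a `window` of years, and encode the pattern of SAR
(sexual) years. No sexual years → −1. Sexual reproduction every year →
0 if the reserve sequence is constant within `tol` (fixed point), else 1.
A constant inter-event interval of 2–18 years → that interval. Anything
else (single event, unequal intervals, interval beyond 18) → 19. Interval
analysis is exact on this orbit; no spectral estimation is needed.
Defaults: `window = 2000` years, `tol = 1e-9` (absolute, on reserves),
maximum recognized period 18.

The sweep evaluates a (p, q) grid per value of `R` with the same
elementwise operation ordering as the scalar map, so every cell is
bit-identical to a pointwise call (a tested invariant). Grids use interior
midpoints `i/(N+1)` so the invalid endpoints 0 and 1 are never sampled. A
divergent cell is coded −9 and logged instead of aborting the sweep; cells
excluded by the optional simplex restriction `p+q ≤ 1` are coded −2.

## Numerical choices

* **Initial reserve.** Default `y0 = L1/2` (mid-accumulation). A zero
  default is avoided deliberately: it makes the year-0 pool exactly `Ps`,
  which for the bundled phase-diagram family coincides with `L2`, and the
  AR tie-break then steers the orbit into a non-representative coexisting
  attractor (see limitations). Transients, and in multistable regions the
  selected attractor, depend on this choice; the closed-form analysis does
  not.
* **Burn-in.** Default 2000 years. The slowest stable contraction sampled
  by a default 51-point grid has branch-slope magnitude ≈ 0.981, which
  needs ≈ 1100 years to shrink an O(1) displacement below the `1e-9`
  constancy tolerance; 2000 years covers this with a factor-two margin.
* **SAR update form.** `y_next = pool − (p+q+R·p)·(pool−L1)`, with the
  three costs recorded separately for accounting. This makes the classic
  single-threshold reduction bit-exact; the ledgered trade-off is that
  conservation (`Δy = Ps − ΣC`) holds to ~1 ulp relative rather than
  bitwise, and is asserted at `1e-12` relative.
* **Divergence guard.** `|y| > 1e12` raises an error naming the year. From
  ordinary starts the accumulation branch re-injects overdrafted orbits,
  so the map is bounded; the guard matters only for extreme reserves or
  extreme `R`.
* **Serialization.** Trajectory CSV floats use 17 significant digits and
  are parsed back with round-trip precision, so write/read is bit-exact.

## What the tests show — and do not show

The map is **multistable**: stable AR/SAR two-year cycles coexist with the
stable SAR fixed point in parts of scene 3 (in roughly one in ten random
scene-3 parameter draws the orbit from a fixed faraway start is captured
by such a cycle). The scene taxonomy is a *local* stability statement, and
the suite verifies it as such: scene⇒dynamics checks start orbits at the
equilibrium plus a small perturbation (`0.01·Ps`). Phase diagrams, by
contrast, are global statements *conditional on the default initial
reserve*; a different `y0` can recolor cells that sit in a contested
basin. Period codes near regime boundaries are also sensitive to the
burn-in/tolerance pair, because contraction rates approach 1 there.

The model is deterministic and single-individual. Passing tests therefore
say nothing about environmental noise, threshold variability, pollinator
coupling, or population-level synchrony — all outside this package's
scope — nor about the alternative threshold ordering `L1 ≥ L2`.

## Problem sizes

Reference-scenario checks simulate 1500–4000 years; the property suites
use 100–1000 random parameter draws; phase-diagram reproduction uses
51×51 grids at five values of `R` with 4000 simulated years per cell
(vectorized across cells). The acceptance script classifies the two
reference scenarios from 2000-year analysis windows after a 2000-year
burn-in.
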