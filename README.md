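# orbitpanel

Lossless two-dimensional orbit encoding and cohort analytics for **binary
multivariate longitudinal data** (BMLD): panels in which *n* subjects answer
*p* yes/no questions at times *t* = 0, …, *T*, with answers coded
0 = unfavourable and 1 = favourable. The motivating use case is household
panel data from demographic surveillance systems (e.g. indicators such as
household-head age, household size, mortality, adult/minor ratio and
migration influx tracked yearly), but the machinery applies to any complete
binary panel.

## The method

Conventional summaries of BMLD fix the variable order once. Here, each
subject's whole p-variable series is instead encoded as a walk — an
**orbit** — on the *change space*

```
S_p = X_p × Y_p,   |S_p| = 2^p · p!
```

* the **fitness axis** `X_p = {0,1}^p` holds the answer string `x`,
  leftmost digit most significant;
* the **significance axis** `Y_p` holds a permutation `y` of the variable
  indices, ranking variables from least frequently changing (left) to most
  frequently changing (right).

Each state `s = (x, y)` has a canonical 1-based index

```
index(x, y) = (p! − 1 − lex_rank(y)) · 2^p + value(x) + 1 ,
```

scanning the space left-to-right, top-to-bottom (top row = lexicographically
largest permutation). A subject's initial order sorts variables by their
change counts `f_i = #{t : a[i,t] ≠ a[i,t+1]}` (population counts, then the
variable index, break ties); the initial fitness is the t = 0 answers in
that order. Afterwards the **swap-and-flip rule** applies: the variables
that change answer between t and t+1 move to the rightmost significance
positions (in reverse of their previous position order) and their fitness
digits are negated. Edges are colored red (fitness decreased), green
(increased) or blue (unchanged). The encoding is bijective: the raw data is
recovered exactly by un-permuting each `x` by its `y`.

Population-level analytics over a set of orbits:

* **capacity** `c[s, t]` — number of orbits at state `s` at time `t`;
* **density** `d(s, s′)` — accumulated transition counts (self-transitions
  are "idle");
* **region visit percentages** — share of all `n·(T+1)` orbit points in the
  regions fixed by the leading significant variable(s) and their answers;
* **clusters / holes** — depth-1 regions with a large / zero visit share,
  flagging stable / volatile variables;
* stratification by constant subject attributes, per-variable unfavourable
  percentages and change frequencies, and heat maps of group proportions by
  fitness label.

## Worked example

```python
import numpy as np
from orbitpanel import change_frequencies, encode_orbit, orbits_to_frame
from orbitpanel.simulate import example_subjects

demo = example_subjects()["demo"]     # 3 variables, 8 observations
print(change_frequencies(demo))       # -> [3 0 2]
print(encode_orbit(demo).indices)     # -> (24, 24, 23, 29, 30, 30, 24, 23)
print(orbits_to_frame([encode_orbit(demo)]).to_string(index=False))
```

```
subject_id  t   x   y  state_index edge_color
      demo  0 111 120           24       blue
      demo  1 111 120           24        red
      demo  2 110 120           23        red
      demo  3 100 102           29      green
      demo  4 101 102           30       blue
      demo  5 101 102           30      green
      demo  6 111 120           24        red
      demo  7 110 120           23
```

Variable 1 never changes (`f = (3, 0, 2)`), so it leads the initial order
`y₀ = 120`; the t = 0 answers in that order give `x₀ = 111`, state index 24.
At t = 2 variable 0 turns unfavourable: it is already rightmost, its digit
flips, and the orbit drops to state 23 along a red edge. Because variable 1
stays favourably constant, the whole orbit lives in the region
`x=1**, y=1**` (indices {21–24, 29–32}).

The `examples/` scripts walk through the state space (`01`), single-subject
encoding (`02`), cohort analytics on a synthetic panel with planted stable
and volatile variables (`03`, where the stable variable produces a single
100 %-share cluster and the volatile ones lead only holes), and the plot
families plus the CLI pipeline (`04`).

## Command line

```
orbitpanel simulate --n 400 --p 5 --phi 0.0,0.05,0.1,0.2,0.6 \
    --out panel.csv --strata-out strata.csv
orbitpanel orbits panel.csv --strata strata.csv --out orbits.csv
orbitpanel summarize panel.csv --out-dir summary/
orbitpanel plot panel.csv --kind capacity-histogram --out capacity.png
orbitpanel space --p 3
```

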