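# Methods

## Model and encoding

A complete binary panel `D[p, n, T]` holds answers `a[i, t] ∈ {0, 1}` of
each subject to p questions at times t = 0..T, coded 1 = favourable.
Each subject is mapped to an orbit on the change space
`S_p = {0,1}^p × Sym(p)`: a fitness string (answers, most significant
leftmost) paired with a significance permutation (variables ranked from
least to most frequently changing). The encoding is deterministic and
bijective; no information is lost or approximated, and question order is
itself part of the state, so clusters tied to stable variables that a
fixed-order analysis (e.g. a 2^p-state Markov chain) would overlay into
one row are spatially separated.

Per subject:

1. change counts `f_i = #{t < T : a[i,t] ≠ a[i,t+1]}`;
2. initial significance: variables sorted ascending by the key
   `(f_i_subject, f_i_population, i)` — a single deterministic stable
   sort implementing the tie-breaking cascade (population counts break
   subject ties; the ascending variable index breaks the rest). When no
   population counts are given they default to zero so ties fall
   through to the index. Population counts are computed within the
   stratum being analysed, since orbits are built per stratum;
3. initial fitness: the t = 0 answers permuted into that order;
4. for t → t+1 with change set C: unchanged variables keep their
   relative order on the left; changed variables are appended on the
   right in reverse of their previous position order, each with its
   digit negated; C = ∅ is the idle transition. Edges are classified by
   the move of the fitness value: red = down, green = up, blue = equal.

**Generalization note.** The two-variable change case determines the
appended-block order (previously-rightmost variable first); the rule
above is the natural extension to |C| > 2 and reduces exactly to the
two-variable formula. It is an interpretation in the sense that only
the |C| ≤ 2 case is pinned down by worked examples.

**Decoding.** At each t the answers are recovered by un-permuting the
fitness string by its significance order; the decoder additionally
verifies that each consecutive state pair equals the transition applied
to the implied change set and raises a corruption error otherwise.

## Canonical indexing

States are labeled 1..2^p·p! scanning left to right, top to bottom:
columns are fitness strings in ascending binary order; rows are
significance permutations in *descending* lexicographic order from the
top. The closed form is

    index(x, y) = (p! − 1 − lex_rank(y)) · 2^p + value(x) + 1.

The row orientation is not stated in prose anywhere; it is the unique
orientation consistent with the worked-example indices this package
reproduces in its tests (states 24, 23, 29, 30 of S_3, the subset
{21, 22, 23, 24, 29, 30, 31, 32}, and the corner states 1 = (000, 210)
and 48 = (111, 012)). Permutation rank/unrank uses the factorial number
system; both are exercised exhaustively for p ≤ 5.

## Admissible transitions

`admissible_successors(s)` enumerates the full one-step image
`{step(s, C) : C ⊆ {0..p−1}}`. Distinct change sets flip distinct digit
sets, so the image always has exactly 2^p states (out of 2^p·p!), which
is what makes most state pairs non-admissible. The optional `within=`
region argument restricts the image to a region of S_p: an orbit whose
leading variable never changes stays in that variable's depth-1 region,
and its reachable set from any state is the restricted one. For state
23 of S_3 within the region `x=1**, y=1**` this gives {23, 24, 29, 31};
the unrestricted image has 8 states. Note the restriction is a property
of the *subject* (a constant variable), not of the space: a variable
that changed earlier can drift back to the leading position, so the
leading variable is not frozen in general.

## Cohort analytics

* Capacity `c[s, t]` and density `d(s, s′)` are exact counts; their
  conservation laws (`Σ_s c[s,t] = n` per time, `Σ d = n·T`) are tested
  properties. Display thresholds (e.g. capacity ≥ 50 per time step,
  density ≥ 100) are reporting filters only and never modify stored
  tables.
* Region visit percentages use the denominator n·(T+1) — every orbit
  point including t = T. This is a documented choice: the published
  survey analysis this design follows does not state its denominator,
  and the check that would discriminate (a printed 62 % share) needs
  the original dataset. Depth-k regions partition S_p, so
  percentages sum to 100 at each depth and depth-2 shares nest exactly
  inside depth-1 shares.
* Clusters are depth-1 regions with visit share ≥ `min_share`
  (default 0.10). Clustering is a visual notion in the source analysis;
  the default is an explicit screening threshold, exposed as a
  parameter. Holes are depth-1 regions with zero visits.
* `code_mean_constant` codes a stratification attribute by its mean
  over observed times, with the closed lower interval [0, 0.5] coding
  0 — hence the documented asymmetry at the boundary: (1,0) and its
  complement (0,1) both code 0.
* `group_proportion_by_fitness` uses the fixed order 0..p−1 (fitness
  labels 1..2^p in ascending binary order) and reports absent
  (label, time) cells as NaN, rendered in a distinct no-data color by
  the heat map.

## Synthetic data generator

`generate_panel(PanelSpec)` draws `a[i,0] ~ Bernoulli(π_i)` and evolves
`a[i,t+1] = a[i,t] XOR Bernoulli(φ_i)` independently across subjects,
variables and times, reproducibly from a seed. This is the simplest
process expressed in the frequency-of-change vocabulary the method
ranks variables by: `E[f_i] = T·φ_i` per subject, so φ directly plants
stable (small φ → clusters) and volatile (large φ → holes) variables.
Strata carry per-stratum n/π/φ overrides and constant labels; an
optional shared latent flip event (`coupling=(variables, ρ)`) induces
positive change-correlation between chosen variables for exercising the
region-based correlation screening.

Defaults used in the stochastic tests: φ = (0.01, 0.01, 0.2, 0.3, 0.6)
with n = 2000, T = 6 for moment recovery (checked within 3 binomial
standard errors), and a planted φ = 0, π = 1 variable among volatile
ones for cluster/hole structure. What the generator does *not* emulate:
serial correlation within a variable beyond first-order flips,
cross-sectional heterogeneity in φ across subjects, attrition/missing
data, and real survey marginals — so passing tests demonstrate
correctness of the encoding and analytics under known dynamics, not
goodness-of-fit to any real population.

## Numerical and degenerate-input choices

* T = 0 panels are legal: orbits are single states, all frequencies 0.
* p is unbounded for indexing and stepping; full enumeration of S_p is
  capped at p = 8 (≈ 10.3 M states) and raises a size error above.
* Incomplete subjects are never imputed: strict readers raise a
  completeness error naming the first missing
  (subject, variable, time); `completeness_filter` instead drops
  incomplete subjects and reports them.
* Time labels may be arbitrary but must sort consistently; files are
  comma-delimited UTF-8 with a header row.

## Validation against the published survey

The full pipeline (stratification by constant attributes,
unfavourable percentages, change-frequency tables, depth-2 region
shares) is exercised end-to-end on synthetic four-stratum panels. The
test `test_survey_reproduction` additionally asserts the published
four-subpopulation household values (stratum sizes 2610/421/468/659,
SA Rich Q0 unfavourable 17.4 %, SA Rich Q4 change frequency 3373, 62 %
depth-2 region share). That dataset is an external download not
distributed here; to run the test, export it as
`data/subpopulations.csv` (wide layout: `subject_id,time,Q0..Q4`) and
`data/subpopulations_strata.csv` (`subject_id,nationality,mean_aps`).
Without the files the test fails on the missing path. The 62 % check is
also what would empirically validate the n·(T+1) visit-share
denominator.

## Known limitations

* Complete data only; no missing-data machinery.
* Binary variables only. The type layer does not hard-code the arity
  into the indexing contract beyond `value(x)` and `2^p` factors, so an
  m-ary fitness axis (m^p states, same p! significance axis) is a
  documented extension point, but no m-ary operations are provided.
* The region-based correlation screening is descriptive; no formal
  correlation test or regression modelling is included.
* Orbit plots with all p! significance rows become unreadable quickly;
  by default only visited rows are drawn.
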