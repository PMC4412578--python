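"""Explore the change space S_3: indexing, regions, admissible transitions.

The change space for p binary variables has 2^p * p! states: every
combination of an answer string (fitness) and a variable ordering
(significance).  States carry a canonical 1-based index.
"""

from orbitpanel import Region, admissible_successors, build_space, index_to_state, region_states

space = build_space(3)
print(f"S_3 has {space.size} states "
      f"({space.n_fitness} fitness x {space.n_significance} significance)")

s = index_to_state(23, 3)
print(f"state 23 is {s}: answers in order {s.order} are {s.bits}")

succ = sorted(x.index for x in admissible_successors(s))
print(f"one-step image of state 23 under the transition rule: {succ}")

# A region fixes the leading significant variable(s) and their answers.
fav1 = Region(sig_prefix=(1,), fit_prefix=(1,))
members = sorted(x.index for x in region_states(fav1, 3))
print(f"region {fav1.label(3)} = {members}")

within = sorted(x.index for x in admissible_successors(s, within=fav1))
print(f"successors of 23 that stay in the region: {within}")
# An orbit whose variable 1 never changes can only use these four.
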