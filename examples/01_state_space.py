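"""Enumerate the hidden-state space and the coded occasion structure.

The biological state of a bird is (wintering area, geolocator status,
awareness-of-trap), plus one absorbing dead state: with 4 areas, 3
device statuses and 2 awareness levels that is (4*3*2) + 1 = 25 states.
Each of the 23 study years splits into an arrival (inter) and a
departure (intra) occasion, giving 45 coded occasions.
"""

import multievent as me

space = me.build_state_space(4, 3, 2)
print(f"{space.n_states} hidden states; dead state index "
      f"{space.dead_index}")
for label, idx, tup in space.data_dictionary()[:6]:
    print(f"  {idx:2d}  {label}")
print("  ...")

occ = me.encode_occasions(23)
print(f"\n{occ.n_years} study years -> {occ.n_coded} coded occasions")
print("first five kinds:", list(occ.coded_kinds[:5]))

alph = me.EventAlphabet(4)
print(f"\n{alph.n_inter_events} arrival events:", alph.inter_labels())
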