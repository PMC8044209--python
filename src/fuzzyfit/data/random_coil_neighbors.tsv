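# Nearest-neighbour corrections (ppm) added to the base random-coil Cα/Cβ shift of
# residue i for the identity of its sequence neighbours.  prev_* applies when the named
# residue type precedes i (occupies i-1); next_* when it follows (occupies i+1).
# Approximate set (version 1) capturing the dominant effects: a following proline
# lowers Cα of the preceding residue by ~2 ppm; glycine and aromatic neighbours give
# small shifts.  Types absent from this table contribute zero correction.
residue_type	prev_ca	prev_cb	next_ca	next_cb
P	-0.20	-0.10	-2.00	0.10
G	-0.10	0.05	0.10	0.05
F	-0.10	0.10	-0.15	0.10
W	-0.10	0.10	-0.15	0.10
Y	-0.10	0.10	-0.15	0.10
H	-0.05	0.05	-0.10	0.05
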