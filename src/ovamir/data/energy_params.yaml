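# Nearest-neighbor-style RNA energy parameters used by ovamir.folding and
# ovamir.targets.duplex_energy.  All values in kcal/mol.
#
# The stacking matrix is this package's own Turner-inspired parameterization.
# It is constructed so that every stack containing a G:U wobble is strictly
# less stable than the same stack with the wobble replaced by the
# corresponding Watson-Crick pair (compare the GU row/column against the AU
# and GC rows/columns, and UG against UA/CG).  That ordering makes duplex
# stability strictly decrease under any single substitution of a perfectly
# complementary site, which downstream scoring relies on.
#
# Pair codes (5'base:3'base): AU, UA, GC, CG, GU, UG.  Rows are the outer
# (5'-most) pair of a stack, columns the inner pair.
stack:
  order: [AU, UA, GC, CG, GU, UG]
  matrix:
    - [-0.9, -1.1, -2.2, -2.1, -0.6, -0.8]   # AU
    - [-1.3, -0.9, -2.4, -2.1, -1.0, -0.7]   # UA
    - [-2.1, -2.2, -3.3, -3.4, -1.5, -1.9]   # GC
    - [-2.1, -2.4, -3.3, -3.3, -1.4, -1.6]   # CG
    - [-0.7, -0.8, -1.6, -1.5, -0.4, -0.5]   # GU
    - [-0.8, -0.6, -1.5, -1.4, -0.3, -0.4]   # UG

# Loop penalties, linear in unpaired length (n): a + per_nt * n.
hairpin:   {a: 4.0, per_nt: 0.25}   # n >= 3
bulge:     {a: 3.0, per_nt: 0.40}
internal:  {a: 2.0, per_nt: 0.35}   # n = n1 + n2
multiloop: {a: 3.4, per_branch: 0.40, per_nt: 0.10}

# Interior loops larger than this (n1 + n2) are not considered by the fold.
max_interior_span: 30

# Bimolecular duplex terms (miRNA:target hybridization).
duplex:
  initiation: 4.09   # cost of bringing two strands together
  au_end: 0.45       # per terminal AU or GU pair
  bulge: 3.8         # fixed penalty per bulge interruption of the helix
  internal: 3.0      # fixed penalty per internal-loop/mismatch interruption
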