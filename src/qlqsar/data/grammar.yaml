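# Default Q-label grammar.
#
# Atom-centered labels key on element, hydrogen count, heavy-atom degree,
# aromaticity and bond pattern; ring labels match whole aromatic rings.
# The five labels used by the calibrated pharmacophore are -N<, -CH=, >C(<),
# -C(Ar)< and CycAr06; the remainder enrich the descriptor matrix so that
# pair enumeration over a compound series yields a non-trivial feature space.
#
# Predicate fields (all optional except element/kind):
#   element                  atomic symbol
#   h                        exact total hydrogen count
#   degree / min_degree      heavy-atom neighbour count (exact / lower bound)
#   aromatic                 true = aromatic atoms only, false = exclude them
#   single_only              all incident bonds single and non-aromatic
#   has_double_bond          at least one double bond
#   double_or_aromatic_to    double OR aromatic bond to the given element
#   forbid_double_to         no double bond to the given element
version: 1
counting_mode: pair_product
labels:
  "-N<":     {kind: atom, element: N, h: 0, degree: 3}
  "=N-":     {kind: atom, element: N, h: 0, degree: 2}
  "-NH-":    {kind: atom, element: N, h: 1, degree: 2}
  "-NH2":    {kind: atom, element: N, h: 2, degree: 1}
  "-CH=":    {kind: atom, element: C, h: 1, double_or_aromatic_to: N}
  "CH(Ar)":  {kind: atom, element: C, h: 1, aromatic: true}
  "=CH-":    {kind: atom, element: C, h: 1, aromatic: false, has_double_bond: true}
  "=CH2":    {kind: atom, element: C, h: 2, has_double_bond: true}
  "-CH3":    {kind: atom, element: C, h: 3, degree: 1}
  "-CH2-":   {kind: atom, element: C, h: 2, degree: 2, single_only: true}
  ">CH-":    {kind: atom, element: C, h: 1, min_degree: 3, single_only: true}
  ">C(<)":   {kind: atom, element: C, h: 0, min_degree: 3}
  "-C(Ar)<": {kind: atom, element: C, h: 0, aromatic: true, forbid_double_to: O}
  "C=O":     {kind: atom, element: C, h: 0, double_or_aromatic_to: O}
  "-O-":     {kind: atom, element: O, h: 0, degree: 2}
  "=O":      {kind: atom, element: O, h: 0, degree: 1, has_double_bond: true}
  "-Cl":     {kind: atom, element: Cl}
  "-Br":     {kind: atom, element: Br}
  ">SO2":    {kind: atom, element: S, min_degree: 3}
  "CycAr06": {kind: ring, size: 6, aromatic: true}
  "CycAr05": {kind: ring, size: 5, aromatic: true}
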