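# Ligand pharmacophore feature patterns.
#
# Format: one entry per line,  <label> <kind> <definition> [key=value ...]
# Labels: A acceptor, D donor, a aromatic, H hydrophobic, P positive, N negative.
# Kinds:
#   smarts        feature anchored on the first atom of each SMARTS match
#   smarts_group  feature at the centroid of all atoms of each SMARTS match
#   apolar_group  SMARTS selects candidate apolar atoms; bonded groups of at
#                 least `minsize` such atoms give one feature at the group
#                 centroid (isolated apolar atoms are ignored)
#   ring          rings of the listed sizes give one feature at the ring
#                 centroid; non-aromatic all-carbon rings qualify only when
#                 planar to within `planarity` (A max deviation from the
#                 best-fit plane), so saturated carbocycles are excluded
#
# The SMARTS below avoid bond orders and formal charges on purpose: ligands
# coming from complex frames have distance-perceived single-bond skeletons,
# and the same dictionary must type both those and library SDF molecules.

A  smarts        [#8]
A  smarts        [#7;X2;H0]
A  smarts        [#7;X1]
D  smarts        [#7;!H0]
D  smarts        [#8;!H0]
P  smarts        [#7;X4]
P  smarts        [#7;X3;H2]
N  smarts_group  [#6](~[#8;D1])~[#8;D1]
N  smarts_group  [#16](~[#8;D1])(~[#8;D1])~[#8;D1]
H  apolar_group  [#6;!R;!$([#6]~[#7,#8,#16,#9,#17,#35,#15])] minsize=2
a  ring          - sizes=5,6 planarity=0.15
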