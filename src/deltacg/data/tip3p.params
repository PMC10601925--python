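# TIP3P water, flexible internal terms (CHARMM-style constants)
# atom  <label>  <charge e>  <epsilon kcal/mol>  <rmin/2 A>  <mass amu>
atom  OT  -0.834  0.1521  1.7682  15.9994
atom  HT   0.417  0.0460  0.2245   1.008
# bond  <label_i> <label_j>  <k_b kcal/mol/A^2>  <b0 A>
bond  OT  HT  450.0  0.9572
# angle <label_i> <label_j(vertex)> <label_k>  <k_theta kcal/mol/rad^2>  <theta0 deg>
angle  HT  OT  HT  55.0  104.52
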