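"""The five tissue-area features, step by step on a handcrafted map.

A tumor mask is closed with a 5x5 rectangle (merging fragments the
classifier split), the largest 8-connected component gives max_tumor_area,
and lymphocytes are split into inside (within the hole-filled tumor region)
vs. around (a Chebyshev band of 2 patches outside it).
"""

import numpy as np

from histoarea import SuperClass, extract_area_features

O, T, L, S = (int(c) for c in SuperClass)

m = np.full((15, 15), O, dtype=np.int8)
m[3:8, 3:8] = T        # 5x5 tumor square (area 25)
m[5, 5] = L            # one lymphocyte enclosed by tumor -> "inside"
m[2, 3] = L            # one at Chebyshev distance 1 -> "around"
m[9, 9] = L            # distance 2 from the square -> "around"
m[10:13, 1:4] = S      # 3x3 stroma block (area 9)

f = extract_area_features(m, superclass_input=True)
print("max_tumor_area        ", f.max_tumor_area)        # 25: closing re-fills the LYM hole
print("lymphocyte_inside     ", f.lymphocyte_inside_tumor)  # 1
print("lymphocyte_around     ", f.lymphocyte_around_tumor)  # 2
print("around_inside_ratio   ", f.around_inside_ratio)      # (2+1)/(1+1) = 1.5
print("total_stroma_area     ", f.total_stroma_area)        # 9
# Units are patch counts except the ratio, which is add-one smoothed so an
# all-zero map yields exactly 1.0.
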