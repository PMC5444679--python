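"""Transcript-level echo of the FBP/PFK substrate cycle.

The RNA-seq abundances: on xylose the two phosphofructokinase subunits
fall about five-fold while fructose-1,6-bisphosphatase rises 27-fold,
bringing the opposed enzymes from wildly different to near-equal
expression -- the pattern seen where substrate cycling is confirmed.
"""

import kmflux as kf

table = kf.fold_change_table()
print(table.to_string(float_format=lambda x: f"{x:.2f}"))
print("\nPFK1/FBP1 expression ratio, glucose: "
      f"{table.loc['PFK1', 'fpkm_glucose'] / table.loc['FBP1', 'fpkm_glucose']:.0f}x")
print("PFK1/FBP1 expression ratio, xylose:  "
      f"{table.loc['PFK1', 'fpkm_xylose'] / table.loc['FBP1', 'fpkm_xylose']:.1f}x")
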