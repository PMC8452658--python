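"""Compute LAI for one destructive 1 m x 1 m plot.

A subsample of typical leaves is scanned and dried to get the specific leaf
weight (dry mass per leaf area); the plot's total leaf dry weight then
converts to leaf area index.
"""

from lairef import plot_lai, specific_leaf_weight

dw_sub = 30.0      # dry weight of the scanned typical leaves (g)
area_sub = 3000.0  # their scanned one-sided area (cm2)
dw_total = 300.0   # total leaf dry weight of the plot (g)
area_plot = 10000.0  # sampling area: 1 m x 1 m in cm2

slw = specific_leaf_weight(dw_sub, area_sub)
lai = plot_lai(dw_total, slw, area_plot)

print(f"specific leaf weight: {slw:.4f} g/cm2")
print(f"plot LAI:             {lai:.2f} m2/m2")
print("The plot carries", f"{lai:.2f}", "square metres of one-sided leaf "
      "area per square metre of ground.")
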