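"""Anatomical maximum stomatal conductance from stomatal dimensions.

Computes g_smax = d·SD·a_max / (v·(l + (π/2)·√(a_max/π))) for each leaf
surface from stomatal density (SD), pore length (elliptical pore,
a_max = π·p²/8) and guard-cell length (pore depth l = GCL/4), then sums the
surfaces (parallel conductances) for the leaf-level ceiling on g_s.
"""

from gasxkit import anatomical_gsmax, leaf_gsmax
from gasxkit.data_model import Constants

consts = Constants()  # d = 24.6e-6 m2 s-1, v = 24.4e-3 m3 mol-1 at 25 °C

# abaxial (lower) surface: denser; adaxial (upper): sparser — typical for
# an amphistomatous C4 grass leaf
ab = anatomical_gsmax(SD=120e6, pore_length_um=20.0, guard_cell_length_um=40.0,
                      consts=consts, surface="abaxial")
ad = anatomical_gsmax(SD=70e6, pore_length_um=19.0, guard_cell_length_um=38.0,
                      consts=consts, surface="adaxial")

for res in (ab, ad):
    print(f"{res.surface:8s} SD={res.SD/1e6:6.1f} mm-2  a_max={res.a_max*1e12:6.1f} um2  "
          f"pore depth={res.pore_depth_l*1e6:4.1f} um  gsmax={res.gsmax:.4f} mol m-2 s-1")
print(f"leaf gsmax (parallel sum): {leaf_gsmax(ab, ad):.4f} mol m-2 s-1")

# reference point: 100 mm-2, 20 um pore, 40 um guard cell -> 0.7503 mol m-2 s-1
print(f"reference geometry check : {anatomical_gsmax(1e8, 20.0, 40.0).gsmax:.4f}")
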