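"""O2 delivery from a coronary capillary versus perfusion rate.

Simulates the delivery rate for wild-type, HbH and hereditary-
spherocytosis T95 populations over a range of perfusion and prints the
delivery of each condition relative to wild type.
"""

import numpy as np

from rbcgas import capillary as cap

grid = np.array([0.25, 0.5, 1.0, 2.0, 5.0, 10.0])
curves = {
    name: cap.simulate_delivery(
        cap.preset_config(name, n_cells=5000, seed=5,
                          perfusion_multiples=grid))
    for name in ("WT", "HbH", "HS_anemic", "HS_compensated")
}

wt = curves["WT"]
print("perfusion (x rest):  " + "  ".join(f"{m:6.2f}" for m in grid))
print("WT flux (fmol/s):    "
      + "  ".join(f"{f:6.1f}" for f in wt.flux))
for name in ("HbH", "HS_anemic", "HS_compensated"):
    ratio = cap.relative_delivery(curves[name], wt)["ratio"]
    print(f"{name:>12} / WT:    " + "  ".join(f"{r:6.2f}" for r in ratio))
print()
cfg = cap.preset_config("WT", n_cells=5000, seed=5)
print(f"WT plateau (analytic): {cap.plateau_flux(cfg):.0f} fmol/s")
print()
print("HbH's deficit (low [Hb]) shrinks at high perfusion because its")
print("small cells unload faster; compensated HS starts near-normal but")
print("worsens as transits shorten - its slow subpopulation cannot finish")
print("unloading, so restored hematocrit does not restore O2 delivery.")
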