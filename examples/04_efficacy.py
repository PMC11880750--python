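"""Relate tumor subgroups to antitumor activity via the ΔT/C statistic.

An antiangiogenic "drugA" effect is planted in the MVD-high models only;
ΔT/C at day 15 (change in mean treated volume over change in mean control
volume, x100; lower = stronger activity) should therefore separate the
MVD-high from the MVD-low models.
"""

import pandas as pd

from mvdsig._seeds import derive_seed
from mvdsig.efficacy import compare_high_low, delta_t_c_table
from mvdsig.io import load_scenario
from mvdsig.synthetic import assign_quadrant_truth, simulate_growth
from mvdsig.pipeline import simulate_scenario

cfg = load_scenario("panel12")
profiles, adata, panel, truth, _ = simulate_scenario(cfg, seed=1)

effect_map = {
    "drugA": {
        "MVD-high/Tcell_inf_GEP-high": 0.9,
        "MVD-high/Tcell_inf_GEP-low": 0.9,
        "MVD-low/Tcell_inf_GEP-high": 0.1,
        "MVD-low/Tcell_inf_GEP-low": 0.1,
    }
}
g = cfg["growth"]
growth = simulate_growth(
    panel, truth, effect_map, growth_rate=g["growth_rate"], days=g["days"],
    n_animals=g["n_animals"], noise_sd=g["noise_sd"], seed=derive_seed(1, "growth"),
)

dtc = delta_t_c_table(growth, day=15)
drug_a = dtc[dtc["arm"] == "drugA"].set_index("model")["delta_t_c"]
high = pd.Series({m: q.startswith("MVD-high") for m, q in truth.items()})

table = pd.DataFrame({"delta_t_c_day15": drug_a.round(1), "mvd_high": high})
print(table.sort_values("delta_t_c_day15").to_string())

cmp = compare_high_low(drug_a, high)
print(f"\nWelch t, MVD-high vs MVD-low ΔT/C: t = {cmp.t:.2f}, "
      f"df = {cmp.df:.1f}, P = {cmp.p:.2g}")
print(f"group means: high = {cmp.mean_x:.1f}, low = {cmp.mean_y:.1f}")
# ΔT/C near zero in the high group (growth nearly arrested) versus ~70-80
# in the low group reproduces the planted association between vessel
# density and antiangiogenic drug sensitivity.
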