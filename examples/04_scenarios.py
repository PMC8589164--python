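"""Scenario analyses: strategies, switch points, horizons, VKA pricing.

Re-solves the model under alternative assumptions: the three step-down
treatment strategies with their switch timepoints, shorter horizons,
warfarin instead of acenocoumarol pricing, and the societal perspective.
"""

import apixvka as av

config = av.load_parameter_pack()
grid = av.run_scenario_grid(config)

print(f"{'scenario':24s}{'d_cost':>10s}{'d_QALY':>9s}{'INMB':>9s}  verdict")
for name, res in grid.items():
    i = res.increment
    print(f"{name:24s}{i.d_cost:10.0f}{i.d_qaly:9.3f}{i.inmb:9.0f}  "
          f"{i.dominance}")

warf = grid["warfarin_cost"].increment
base = grid["base"].increment
print(f"\nswitching the VKA price to warfarin moves d_cost from "
      f"{base.d_cost:+.0f} to {warf.d_cost:+.0f} EUR: the cheaper "
      f"comparator erodes part of the saving but apixaban stays dominant.")

soc = grid["societal"].increment_societal
print(f"societal perspective (adding indirect stroke/ICH costs): d_cost "
      f"{soc.d_cost:+.0f} EUR, INMB {soc.inmb:+,.0f} EUR.")
print("every scenario leaves apixaban with positive QALY gains at lower "
      "cost than VKA.")
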