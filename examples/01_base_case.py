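"""Base case: lifetime costs, LYs and QALYs of apixaban vs VKA.

Loads the shipped parameter pack (trial event rates, Spanish tariffs and
utilities) with the synthetic national life table, runs both arms of the
base-case strategy (blended triple-or-dual therapy for 6 months, then OAC
monotherapy) and prints a results table shaped like a standard
cost-effectiveness base-case report.
"""

import apixvka as av

config = av.load_parameter_pack()
base = av.run_base_case(config)
a, v = base.apixaban, base.vka

print(f"{'':38s}{'apixaban':>10s}{'VKA':>10s}{'difference':>12s}")
rows = [
    ("Bleeding events per 100 patients", a.bleeding_per_100(),
     v.bleeding_per_100()),
    ("Ischemic events per 100 patients", a.ischemic_per_100(),
     v.ischemic_per_100()),
    ("Treatment costs (EUR)", a.treatment_cost, v.treatment_cost),
    ("Monitoring costs (EUR)", a.monitoring_cost, v.monitoring_cost),
    ("Acute event costs (EUR)", a.acute_event_cost, v.acute_event_cost),
    ("Post-acute costs (EUR)", a.maintenance_cost, v.maintenance_cost),
    ("Total costs, payer (EUR)", a.total_cost_payer, v.total_cost_payer),
    ("Total costs, societal (EUR)", a.total_cost_societal,
     v.total_cost_societal),
    ("Total LYs (discounted)", a.ly, v.ly),
    ("Total QALYs (discounted)", a.qaly, v.qaly),
    ("Time on treatment (years)", a.time_on_treatment, v.time_on_treatment),
]
for label, x, y in rows:
    print(f"{label:38s}{x:10.2f}{y:10.2f}{x - y:+12.2f}")

inc = base.increment
print(f"\nICER: apixaban is {inc.dominance} "
      f"(d_cost {inc.d_cost:+.0f} EUR, d_QALY {inc.d_qaly:+.3f})")
print(f"INMB at EUR{inc.wtp:,.0f}/QALY: {inc.inmb:+,.0f} EUR "
      f"(INHB {inc.inhb:+.3f} QALYs)")
print("\nA negative cost difference with positive QALY gain means the "
      "apixaban strategy saves money while adding healthy life: it "
      "dominates the VKA strategy.")
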