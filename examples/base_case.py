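"""Base-case cohort run: 20-year outcomes for a PV cohort starting at 57.

Builds the shipped configuration (base-case risks, synthetic life table,
reference JAK2 trajectory), runs the 80-cycle simulation and prints the
cumulative progression incidences and restricted mean overall survival,
next to the general-population comparator.
"""

import pvmarkov as pv

config = pv.base_case_config()
trace = pv.run(config)
summary = pv.summarize(trace)

print(summary)
print(
    f"General population RMST from age 57 over 20 y: "
    f"{pv.general_population_rmst(config.life_table, 57, 20):.1f} LY"
)
print(
    "The difference between the two survival figures is the life-expectancy "
    "loss attributable to disease progression over the horizon."
)
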