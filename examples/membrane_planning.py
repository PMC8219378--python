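"""Plan a mixed inner leaflet and its counter-ion complement.

Builds the 70:25:5 POPC/POPS/PIP2 leaflet used throughout the package's
synthetic systems, audits the built structure, and sizes the salt content
for physiological (150 mM) conditions.
"""

from memtether.synthetic_data import (
    SynthConfig,
    audit_membrane,
    build_system,
    plan_ions,
    plan_membrane,
)

counts = plan_membrane(540, {"POPC": 0.70, "POPS": 0.25, "PIP2": 0.05})
print("planned counts for 540 lipids at 70:25:5 ->", counts)

system = build_system(SynthConfig(n_lipids_lower=540))
audit = audit_membrane(system.structure)
print("audit of the built leaflet:")
for name, row in audit.items():
    print(f"  {name}: {row['count']:4d} molecules  fraction {row['fraction']:.3f}")

plan = plan_ions(55_345, 0.150)
print(f"150 mM salt in 55,345 waters -> {plan.n_na} Na+ / {plan.n_cl} Cl- pairs")
print("(largest-remainder counts sum exactly; PIP2 is 5% of the leaflet)")
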