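"""Predict the equilibrium drug-to-lipid ratio for a bench protocol.

Builds the standard formulation — 10 mM lipid stock injected 1-in-10 into
warm water, concentrated 20-fold to 20 mM in 500 uL, then 450 uL of the
slurry mixed with 50 uL of 172 mM doxorubicin stock — and predicts the
loading endpoint for 100 nm vesicles.
"""

from lipoload import (
    Compound,
    LoadingConditions,
    SizeDistribution,
    Suspension,
    concentrate,
    equilibrate,
    mix,
)

synthesized = Suspension(
    lipid_concentration_mM=1.0,  # 10 mM stock diluted 1-in-10 on injection
    volume_uL=10_000.0,
    distribution=SizeDistribution(mean_diameter_nm=100.0),
)
slurry = concentrate(synthesized, fold=20.0, lipid_retention=1.0)
print(f"concentrated suspension: {slurry.lipid_concentration_mM:.1f} mM lipid "
      f"in {slurry.volume_uL:.0f} uL")

aliquot = slurry.aliquot(450.0)
mixed, c_t = mix(aliquot, aliquot_volume_uL=50.0, aliquot_concentration_mM=172.0)
print(f"after drug aliquot: C_T = {c_t:.1f} mM, "
      f"lipid = {mixed.lipid_concentration_mM:.1f} mM")

result = equilibrate(
    mixed,
    Compound("doxorubicin", "hydrophilic"),
    LoadingConditions(c_t, temperature_C=55.0, duration_h=1.0),
)
print(f"alpha (core excluded-volume fraction) = {result.alpha:.4f}")
print(f"C_max = alpha * C_E = {result.c_max_mM:.3f} mM")
print(f"predicted D:L = {result.dl_ratio:.4f} mol/mol "
      f"(drug-limited: {result.drug_limited})")
# alpha is the fraction of the suspension volume inside vesicle cores; at
# equilibrium that fraction of the bulk drug ends up encapsulated, and
# dividing by the lipid molarity gives the potency metric D:L.
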