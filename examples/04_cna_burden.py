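"""Copy-number burden: ploidy, percent genome altered, arm calls.

Percent genome altered (PGA) is the fraction of covered autosomal
genome in gain, loss or copy-neutral LOH relative to the
diploid-heterozygous baseline; arm-level calls require at least half
the arm in one altered state.
"""

from crcevo.cna import arm_calls, pga, ploidy_summary
from crcevo.simulate import SimulationParams, simulate_patient

patient = simulate_patient(SimulationParams(), seed=42)

for profile in patient.cn_profiles():
    ploidy = ploidy_summary(profile, patient.layout)
    burden = pga(profile, patient.layout)
    print(f"{profile.sample_id}: psi = {ploidy.psi:.2f} ({ploidy.ploidy_class}), "
          f"PGA = {100 * burden.pga_full:.1f}% "
          f"(gains {100 * burden.frac_gain:.1f}%, losses {100 * burden.frac_loss:.1f}%, "
          f"cnLOH {100 * burden.frac_cnloh:.1f}%)")

from crcevo.model import TissueClass

roles = patient.tissue_roles()
carcinoma = next(p for p in patient.cn_profiles()
                 if roles[p.sample_id] == TissueClass.CARCINOMA)
table = arm_calls(carcinoma, patient.layout)
altered = table[table.call != "neutral"]
print(f"\n{carcinoma.sample_id}: {len(altered)} altered arms")
print(altered.to_string(index=False))
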