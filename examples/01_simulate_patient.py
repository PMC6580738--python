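"""Simulate one multiregion patient and inspect its ground truth.

A simulated patient carries biopsies of non-dysplastic mucosa, LGD,
HGD and carcinoma, with mutations and copy-number events placed on a
known clone tree.  Everything downstream of sequencing — VAFs,
detection, segment tables — is produced by the generator's observation
model.
"""

from crcevo.simulate import SimulationParams, simulate_patient

params = SimulationParams()  # the default study conditions
patient = simulate_patient(params, seed=42)

print(f"patient {patient.patient_id} (seed {patient.seed})")
print("regions:", ", ".join(f"{s.sample_id} [{s.tissue_class.value}]"
                            for s in patient.samples))
print(f"{len(patient.calls)} mutation calls across regions; "
      f"{len(set(c.mutation_id for c in patient.calls))} distinct mutations")
print(f"{len(patient.segments)} copy-number segments")
print("truth clone tree:", patient.truth_tree.to_newick())
counts = {}
for label in patient.truth_clonality.values():
    counts[label] = counts.get(label, 0) + 1
print("truth clonality labels:", counts)
# The newick branch lengths above are the number of mutations the
# generator placed on each lineage segment; 'germline' is the outgroup.
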