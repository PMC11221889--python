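"""Parse mutation strings, build a wild/mutant complex pair, featurize it.

Every model input starts as one record: chain sequences for an
antigen-antibody complex, a mutation list like "A:Y32W", and a measured
ΔΔG.  Featurization turns each chain into an (n, 40) matrix — 20 one-hot
columns and 20 substitution-profile columns.
"""

from seqddg import MutationRecord, featurize, parse_mutation_string

antibody = "EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGK"
antigen = "KVFGRCELAAAMKRHGLDNYRGYSLGNWVCAAKFESNFNT"

mutations = parse_mutation_string("H:S30W,H:Y32F")
print("parsed mutations:", ", ".join(str(m) for m in mutations))

record = MutationRecord(
    complex_id="DEMO",
    antibody_chains=[("H", antibody)],
    antigen_chains=[("A", antigen)],
    mutations=mutations,
    ddg=0.85,  # kcal/mol, ΔG_mutant − ΔG_wild: positive = binding weakened
)

print("wild antibody:  ", record.antibody_seq[:40], "...")
print("mutant antibody:", record.mutant_antibody_seq[:40], "...")

fm_wt = featurize(record.antibody_seq)
fm_mt = featurize(record.mutant_antibody_seq)
print(f"feature matrix shape: {fm_wt.values.shape} (n residues x 40 features)")
changed = (fm_wt.values != fm_mt.values).any(axis=1).sum()
print(f"rows changed by the mutations: {changed} (one per mutated site)")
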