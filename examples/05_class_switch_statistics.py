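"""Subclass distributions and cross-subclass sequence overlap by age.

Simulates a small age gradient, then reports IGG1-4 / IGA1-2 usage per age
group and the percentage of transcripts with the exact same CDR1-CDR3
nucleotide sequence observed under two different constant genes — the
signature of class switching without additional hypermutation.
"""

from bcrep import DonorMetadata, SimulationConfig, emit_repertoire
from bcrep.csr import cross_class_overlap, cross_subclass_overlap, overlap_frame, subclass_distribution
from bcrep.filtering import apply_quality_filters

donors = [
    DonorMetadata(f"D{i}", age, False, "F")
    for i, age in enumerate((2.0, 8.0, 15.0, 30.0, 60.0))
]
config = SimulationConfig(seed=19, donors=donors, n_clones=50)
repertoire = emit_repertoire(config)
unique, _ = apply_quality_filters(repertoire.rearrangements)

strata = {d.donor_id: d.age_group for d in donors}
print("subclass usage (% within family) per age group:")
print(subclass_distribution(unique, strata=strata).round(1).to_string(index=False))

results = []
for family in ("IGG", "IGA"):
    results.extend(cross_subclass_overlap(unique, family, stratum="all"))
results.append(cross_class_overlap(unique, stratum="all"))
print("\ncross-subclass overlap of exact CDR1-CDR3 sequences:")
print(overlap_frame(results).round(2).to_string(index=False))
# Rising IGG2/IGA2 usage with age reflects the downstream-only switching
# model; non-zero overlap rows are transcripts caught both before and after
# a class switch that added no new mutations.
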