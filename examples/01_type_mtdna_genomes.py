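"""Call variants and assign mtDNA haplogroups by diagnostic motifs.

Simulates genomes that carry a full founder-haplogroup motif (A2/B2/C1/D1)
plus up to ten private mutations, types them against the packaged
reference, and prints the calls. A match score of 1.0 means every
diagnostic site of the winning motif was observed.
"""

from unipargen import load_default_motifs, load_reference, type_genomes
from unipargen.mtdna import calls_table
from unipargen.simulate import sim_haplogroup_genomes

reference = load_reference()
panel = load_default_motifs(reference)

records, truth = sim_haplogroup_genomes(panel, n=8, seed=42, max_private=10)
genomes = type_genomes(records, reference, panel)

table = calls_table(genomes)
table["true"] = [truth[s] for s in table["sample_id"]]
print(table[["sample_id", "true", "haplogroup", "score"]].to_string(index=False))
recovered = (table["true"] == table["haplogroup"]).mean()
print(f"\nrecovered the generating haplogroup for {recovered:.0%} of genomes")
print("(the classifier tolerates private mutations because they hit none of")
print(" the diagnostic motif sites; score < 1 would indicate back-mutations)")
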