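"""Call lac genotypes from amplicon sequences and map them to phenotype.

Generates amplicons for every recognized genotype and round-trips them
through the caller: repeat-unit indels in the lacI hotspot, operator SNPs,
and the known-null missense change.
"""

import lacprofiler as lp
from lacprofiler.synthetic import GENOTYPE_LABELS

print(f"{'genotype':16s} {'variant type':18s} expected regulation")
for label in GENOTYPE_LABELS:
    lacI_rec, lacO1_rec = lp.generate_lac_sequences(label)
    call = lp.genotype_clone(str(lacI_rec.seq), str(lacO1_rec.seq))
    print(f"{call.label:16s} {call.variant_type:18s} {call.expected_class}")
print()
print("A 4-bp repeat-unit gain or loss frameshifts the repressor (constitutive")
print("expression); a single operator substitution weakens repressor binding")
print("(lower induction threshold); wild type keeps the bistable bimodal")
print("response.")
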