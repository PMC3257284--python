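"""Operator target-size model and mutation-environment association.

Why do operator mutants dominate only where glucose and lactose are presented
together, despite arising ~1000x less often than repressor nulls?
"""

import lacprofiler as lp
from lacprofiler.selection import MutationTargetModel

m = MutationTargetModel()   # 21 bp, 5e-10 /bp/gen, 1/3 deleterious
sub = lp.substitution_probability(m)
lof = lp.lof_frequency(m)
print(f"operator substitutions/generation: {sub['exact']:.3g} (~{sub['rounded']:.0e})")
print(f"binding-loss frequency/generation: {lof['exact']:.3g} (~{lof['rounded']:.0e})")
print(f"repressor-null vs operator frequency: "
      f"{lp.frequency_ratio(3e-6, lof['rounded']):.0f}-fold")
print(f"possible operator substitutions: {lp.possible_substitutions(m)}")

records, df = lp.load_table1()
table, audit = lp.build_environment_table(records)
p = lp.fisher_exact_two_sided(table)
print(f"\nenvironment x genotype table {table.row_labels} x {table.col_labels}:")
print(table.as_array())
print(f"exact two-sided P = {p:.4f}")
print(f"excluded: {', '.join(audit[audit.status != 'included'].population)}")
print()
print("Operator-mutant populations are confined to the glucose+lactose row;")
print("the exact test enumerates all tables with these margins, so a P this")
print("small despite the operator's tiny mutational target is what makes the")
print("environment association worth explaining.")
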