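"""Mendelian validation of allele calls in a parent-child quartet.

Builds a family by explicit transmission (the father recombines between
HLA-B and HLA-DRB1), checks every gene's transmission, and localizes the
recombination event with minimum-switch parsimony.
"""

import numpy as np

from hlaphase.trio import (GENE_ORDER, check_gene_transmission,
                           detect_recombination, simulate_family)

pool = {g: [f"{g.split('-')[1]}*{i:02d}:01" for i in range(1, 11)]
        for g in GENE_ORDER}
fam = simulate_family(pool, np.random.default_rng(6), n_children=2,
                      father_pattern=[0, 0, 0, 1, 1, 1], family_id="famB")

for child in fam.children:
    ok = all(check_gene_transmission(fam.members[child][g],
                                     fam.members["father"][g],
                                     fam.members["mother"][g])
             for g in GENE_ORDER)
    print(f"{child}: Mendelian consistent at all 6 genes: {ok}")

report = detect_recombination(fam)
for child, rep in report.items():
    print(f"{child}: father haplotype per gene {rep['father_haplotype']}, "
          f"{rep['n_recombination']} recombination event(s): {rep['events']}")
# One event between HLA-B and HLA-DRB1 in each child: exactly the
# transmission pattern that was planted; 0 events would mean both
# children inherited intact parental haplotypes.
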