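"""Extract introns and trace their origin by sequence identity.

Introns of transferred genes are globally aligned against candidate introns
at analogous positions (same protein-alignment column, same phase) from the
donor and relative clades; the best-identity group is the inferred origin.
A transferred gene should carry donor-derived intron sequence.
"""

from hgtkit import (
    SimulationConfig,
    assign_intron_origin,
    extract_introns,
    flag_long_intron_genes,
    project_intron_positions,
    simulate,
)
from hgtkit.introns import score_intron_matches
from hgtkit.model import Role
from hgtkit.pipeline import run_hgt_screen

dataset = simulate(SimulationConfig(seed=4, n_families=15, n_transfer_families=5))
introns = {
    gid: extract_introns(rec, dataset.genome[rec.contig])
    for gid, rec in dataset.records.items()
}
n_introns = sum(len(v) for v in introns.values())
n_canonical = sum(i.canonical for v in introns.values() for i in v)
long_genes = sum(flag_long_intron_genes(introns).values())
print(f"{n_introns} introns extracted; {n_canonical} with canonical GT..AG termini; "
      f"{long_genes} genes carry an intron > 1 kb")

analyses = run_hgt_screen(dataset.records, dataset.orthogroups, dataset.roles,
                          dataset.species_of, n_bootstrap=100, seed=4)
assigned = {"donor": 0, "relative": 0, "uncertain": 0}
for a in analyses:
    if a.alignment is None:
        continue
    fam = {g: introns.get(g, []) for g in a.alignment.ids}
    project_intron_positions(a.alignment, fam)
    role = lambda g: dataset.roles.role_of(dataset.species_of[g])
    subjects = {
        "donor": [i for g in a.alignment.ids if role(g) is Role.DONOR for i in fam[g]],
        "relative": [i for g in a.alignment.ids if role(g) is Role.RELATIVE for i in fam[g]],
    }
    for call in a.calls:
        if call.status.value != "hgt":
            continue
        for intron in fam.get(call.gene_id, []):
            matches = score_intron_matches(intron, subjects, min_len_bp=100)
            if matches:
                assigned[assign_intron_origin(matches).origin] += 1

print(f"origin of transferred genes' introns (best identity): {assigned}")
print("donor-dominated counts show the introns moved with the gene from the host.")
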