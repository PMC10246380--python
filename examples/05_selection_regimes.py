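"""Estimate dN/dS (omega) by the Nei-Gojobori counting method and classify
selection regimes on transferred vs background genes.

omega < 1 indicates purifying selection, omega near 1 neutral evolution,
and omega > 1 positive selection (with a +/- 0.1 neutral band on
estimates).  Foreground = transferred genes paired with their closest donor
homolog; background = the vertically inherited genes.
"""

import numpy as np

from hgtkit import SimulationConfig, simulate, classify_regime, ng86_pair, run_hgt_screen
from hgtkit.align import back_translate
from hgtkit.model import HgtStatus, Role
from hgtkit.selection import lineage_omega
from hgtkit.simulate import CodonModel, evolve_codon_sequence, random_sense_codons

# 1. the estimator recovers a planted omega on a single branch
rng = np.random.default_rng(0)
ancestor = random_sense_codons(500, rng)
for omega in (0.1, 0.5, 1.0, 2.0):
    rng = np.random.default_rng(0)
    descendant = evolve_codon_sequence(ancestor, 0.6, 2.0, omega, rng)
    _, est = ng86_pair(ancestor, descendant)
    print(f"planted omega {omega:>4}: NG86 estimate {est.omega:.3f} "
          f"-> {classify_regime(est.omega).value}")

# 2. foreground/background contrast on a simulated transfer family
cfg = SimulationConfig(
    seed=7, n_families=1, n_transfer_families=1, n_codons=500,
    codon_model=CodonModel(omega_by_class={"vertical": 0.2, "hgt": 1.8}),
)
ds = simulate(cfg)
analysis = run_hgt_screen(ds.records, ds.orthogroups, ds.roles, ds.species_of,
                          n_bootstrap=50, seed=7)[0]
fg = [c.gene_id for c in analysis.calls if c.status is HgtStatus.HGT]
codon_aln = back_translate(analysis.alignment,
                           {g: ds.records[g].cds_seq for g in analysis.alignment.ids})
rows = dict(zip(codon_aln.ids, codon_aln.rows))
role = lambda g: ds.roles.role_of(ds.species_of[g])
donors = [g for g in codon_aln.ids if role(g) is Role.DONOR]
background = [g for g in codon_aln.ids if g not in fg and role(g) in (Role.RELATIVE, Role.FOCAL)]
call = lineage_omega(rows, analysis.orthogroup_id, fg, donors, background)
print(f"\ntransfer family: omega_fg = {call.omega_fg:.2f} ({call.regime_fg.value}), "
      f"omega_bg = {call.omega_bg:.2f} ({call.regime_bg.value})")
print("the accelerated foreground shows the planted positive-selection signal;")
print("the background stays strongly purifying.")
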