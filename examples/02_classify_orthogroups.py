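"""Classify orthogroups by focal-vs-other copy numbers.

Each orthogroup's copy-number vector is placed in exactly one category:
single-copy 1:1, lost (exactly 0:1, or 0:n with n > 1), duplicated
(exactly 2:1, or at least 2n:n), focal-specific, or unclassified.  The
fraction of conserved orthogroups lost in the focal species is the
headline gene-loss statistic for a reduced parasite genome.
"""

from hgtkit import SimulationConfig, simulate, summarize_categories

# loss-heavy conditions: the parasite genome sheds genes
dataset = simulate(SimulationConfig(seed=2, n_families=60, rate_loss=0.25, rate_dup=0.05))
vectors = dataset.orthogroups.copy_numbers(dataset.roles.species)

# emulate extra focal-lineage loss: drop the focal entry of some families
for k, og in enumerate(sorted(vectors)):
    if k % 4 == 0:
        vectors[og]["Shim"] = 0

labels, summary = summarize_categories(vectors, focal="Shim")
for category, count in sorted(summary.counts.items()):
    print(f"{category:18s} {count}")
print(f"\nfraction of conserved orthogroups lost in the focal species: "
      f"{summary.fraction_lost_conserved_denominator:.2%}")
print("(denominator: orthogroups with >= 1 copy in every non-focal species;")
print(f" with the any-species denominator: {summary.fraction_lost_any_denominator:.2%})")
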