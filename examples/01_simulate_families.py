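"""Generate a synthetic gene-family dataset with a ground-truth event log.

Six species evolve 25 gene families along a fixed tree: one focal
endoparasite (Shim), a two-species donor clade standing for the host's
family (Vvin, Tpla), two relatives (Mesc, Ptri) and an outgroup (Osat).
Five families receive one planted host-to-parasite transfer each.
"""

from collections import Counter

from hgtkit import SimulationConfig, simulate

config = SimulationConfig(seed=1, n_families=25, n_transfer_families=5)
dataset = simulate(config)

labels = Counter(dataset.true_labels.values())
events = Counter(e.event for e in dataset.events)
print(f"families:            {len(dataset.orthogroups)}")
print(f"genes:               {len(dataset.records)}")
print(f"focal gene labels:   {dict(labels)}")
print(f"recorded events:     {dict(events)}")
print(f"expression matrix:   {dataset.expression.frame.shape} (genes x tissues)")

# The event log is the ground truth every later stage is scored against:
# each planted 'transfer' should come back as an hgt call, everything else
# as vertical.  'duplication'/'loss' events reshape family sizes, which the
# copy-number classifier summarizes.
for event in dataset.events[:5]:
    print("  ", event)
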