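"""Generate a seeded synthetic concentration-response dataset.

Builds the 8-concentration x 4-replicate design (0.4x dilution series from
50 µM), draws negative-binomial counts for four gene classes and a binomial
teratogenicity screen, and prints the design anchors.
"""

import numpy as np

import phenanchor as pa

series = pa.dilution_series(50, 0.4, 7, 3)
print("dilution series (µM):", series)
# -> the 0.4x series the expression experiment uses; 0.205 is 50*0.4^6
# rounded to 3 significant figures.

ds = pa.simulate_dataset(pa.SimulationConfig(seed=1))
print("count matrix:", ds.counts.shape, "genes x samples")
classes = {}
for t in ds.truths:
    classes[t.klass] = classes.get(t.klass, 0) + 1
print("gene classes:", classes)

p = ds.phenotype.incidence()
print(p[["concentration", "n_affected", "incidence"]].to_string(index=False))
# -> incidence rises sigmoidally with concentration: the ground-truth curve
# has EC50 16.5 µM and slope 2, so ~10% added risk appears near 5.5 µM.
print("true phenotype EC50 (µM):", ds.phenotype_truth.ec50)
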