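"""Comparing samples of unequal depth by rarefying repeatedly.

Five libraries of very different sizes are drawn from one source, then
each is independently subsampled (without replacement) 1,000 times down
to the smallest depth, 25 reads. The resulting Shannon distributions
overlap — as they should, since all samples share one source.
"""

import numpy as np

from ampdiv import (
    rarefy_repeatedly,
    sample_library,
    scrabble_population,
    shannon_of_counts,
)

pop = scrabble_population()
rng = np.random.default_rng(11)
print("library  plug-in S   rarefied-to-25: mean [q1, q3]")
for n in (50, 100, 200, 500, 1000):
    vec = sample_library(pop, n, rng)
    res = rarefy_repeatedly(vec, 25, 1000, rng)
    s = res.summary
    print(
        f"{n:7d}  {shannon_of_counts(vec.counts):9.3f}   "
        f"{s['mean']:.3f} [{s['q1']:.3f}, {s['q3']:.3f}]"
    )
print(
    "\nPlug-in Shannon grows with library size (left column), yet at the\n"
    "common depth of 25 every sample shows a Shannon index of about 2.5:\n"
    "repeated rarefaction both normalizes the comparison and quantifies\n"
    "the subsampling noise a single rarefaction would hide."
)
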