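"""Generate a synthetic decoy ensemble with planted basins.

Builds a self-avoiding CA trace as the "native", plants 4 structural
basins around it, assigns funnel-plus-noise energies, and writes the
dataset (PDBs, scores.csv, native.pdb, truth.csv) to disk.
"""

from pathlib import Path

import numpy as np

from decoyreduce import SynthSpec, kabsch_lrmsd, make_ensemble, write_dataset

spec = SynthSpec(length=60, n_clusters=4, sizes=[50] * 4, seed=0)
ensemble, truth = make_ensemble(spec)

lrmsd = np.array([kabsch_lrmsd(s, ensemble.native) for s in ensemble])
print(f"structures: {len(ensemble)}  (4 planted basins of 50)")
print(f"lRMSD to native: {lrmsd.min():.2f} .. {lrmsd.max():.2f} A")
print(f"energies: {ensemble.energies.min():.2f} .. {ensemble.energies.max():.2f} REU")

out = Path("scratch/example_dataset")
paths = write_dataset(ensemble, truth, out)
print(f"wrote dataset under {out}/")
# The lRMSD range shows every decoy is far from the native (a hard target);
# the energy range reflects the 2 REU/A funnel plus 3 REU of noise.
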