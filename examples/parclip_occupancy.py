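"""Expression-normalised PAR-CLIP occupancy recovers motif density.

Simulates crosslinking reads whose local rate follows strand expression
times local predicted-site content, then shows that dividing binned read
midpoints by each gene's strand expression recovers the site-density
profile around the stop codon.
"""

import numpy as np
from scipy.stats import pearsonr

from codonmask import density_profile, make_dataset, occupancy_profile
from codonmask.simulate import occupancy_validation_config

cfg = occupancy_validation_config(seed=0)
cfg.n_cut = 300          # lighter than the full validation run
cfg.read_rate = 0.055    # keep depth near 50k reads
ds = make_dataset(cfg)
orfs = [t for t in ds.transcripts if t.ttype == "ORF"]
print(f"{len(orfs)} CUT-like ORFs, {len(ds.midpoints)} simulated reads")

dens = density_profile(orfs, ds.genome, "stop_codon", "antisense")
occ = occupancy_profile(orfs, ds.midpoints, ds.track, ds.genome,
                        "stop_codon", "antisense")

r, _ = pearsonr(dens.values, occ.values)
cds_bins = dens.bin_starts < 0
print(f"antisense site density: {dens.values[cds_bins].mean():.3f}/bin in "
      f"the CDS vs {dens.values[~cds_bins].mean():.3f}/bin downstream")
print(f"occupancy (reads per expression unit): "
      f"{occ.values[cds_bins].mean():.3f} vs {occ.values[~cds_bins].mean():.3f}")
print(f"Pearson r between profiles: {r:.3f}")
print("After normalising away expression differences, protein occupancy")
print("mirrors where the predicted binding sites are - the signature that")
print("motif counts, not transcript abundance, drive the binding pattern.")
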