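"""Call TF target genes on a simulated ChIP-exo track.

Generates a 200-gene chromosome with Poisson background signal and 20
planted promoter peaks, extracts the +/-1 kb TSS window for every gene,
and calls targets with the 2.5x-over-background rule.
"""

import numpy as np

from exoscreen import CallParameters, call_targets, metagene_profile
from exoscreen.simulate import SimulationConfig, simulate_chipexo
from exoscreen.windows import extract_all_windows

config = SimulationConfig(seed=1)
sim = simulate_chipexo(config, tf="TF")

profiles = extract_all_windows(sim.stress, sim.annotation, config.window)
result = call_targets(profiles, CallParameters(), tf="TF", condition="stress")

print(f"genes:               {config.n_genes}")
print(f"background (mean over all genes): {result.background:.2f} reads")
print(f"threshold (2.5x):    {result.threshold:.2f} reads")
print(f"targets called:      {len(result.targets)}")
print(f"planted targets hit: {len(result.targets & sim.planted)} of {len(sim.planted)}")
print(f"mean reads per target: {result.mean_reads_per_target:.1f}")

meta = metagene_profile(profiles, config.window)
peak = config.window.offsets()[int(np.nanargmax(meta))]
print(f"metagene peak at {peak} bp relative to the TSS")

# The calling rule compares each gene's mean window signal against the
# all-gene mean; with peaks planted at 8x the window's background mass,
# every planted gene clears the 2.5x threshold and nothing else does.
# The metagene maximum sits at the planted peak centre, ~250 bp upstream.
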