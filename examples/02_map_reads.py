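"""Map simulated paired-end reads to a usable-read count matrix.

Writes a small error-containing simulated screen to a temporary directory,
runs adapter trimming, seeded local alignment against the 3'-end references
and the orientation/offset filters, and prints the per-filter read tallies.
An error-free run would give a usable fraction of 1; substitution errors
knock reads out mostly at the adapter filter (2-mismatch budget).
"""

import tempfile

from recynh.mapping import count_pairs
from recynh.simulate import SimConfig, simulate_fastq

cfg = SimConfig(
    n_baits=6,
    n_preys=6,
    interactions=(("BAIT001", "PREY004", 40.0),),
    reads_per_condition=500,
    per_base_error=0.01,
    seed=7,
)

with tempfile.TemporaryDirectory() as tmp:
    sim = simulate_fastq(cfg, tmp)
    matrix, stats = count_pairs(
        sim.rs_r1,
        sim.rs_r2,
        cfg.adapter_spec(),
        bait_refs=sim.truth.bait_references(),
        prey_refs=sim.truth.prey_references(),
        condition="RS",
    )

print(f"total read pairs        {stats.total_pairs}")
print(f"both adapters matched   {stats.adapter_pass_pairs}")
print(f"read 1 mapped           {stats.read1_mapped}")
print(f"read 2 mapped           {stats.read2_mapped}")
print(f"usable pairs            {stats.usable_pairs}")
print(f"usable fraction         {stats.usable_fraction:.3f}")
print(
    "\nEach usable pair increments N(bait, prey); at a 1% per-base error "
    "rate most losses are reads whose 54-56 nt adapter collected >2 errors."
)
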