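"""Three-hybrid variant: RNA motifs as baits with exact read-1 matching.

Simulates a protein-RNA screen (RNA motifs fused to MS2 stem-loops read as
read 1; protein preys as read 2), maps the reads -- RNA side by exact
prefix matching, protein side by seeded alignment -- and scores the matrix
with the identical chain used for protein-protein screens.
"""

import tempfile

import numpy as np

from recynh import score_replicate, subtract_q3
from recynh.mapping import count_pairs
from recynh.simulate import SimConfig, simulate_fastq

cfg = SimConfig(
    mode="Y3H",
    n_baits=8,   # RNA motifs
    n_preys=8,   # RNA-binding proteins
    interactions=(
        ("RNA001", "PREY001", 40.0),
        ("RNA004", "PREY006", 40.0),
    ),
    reads_per_condition=2000,
    per_base_error=0.0,
    seed=5,
)

with tempfile.TemporaryDirectory() as tmp:
    sim = simulate_fastq(cfg, tmp)
    matrices = {}
    for condition, r1, r2 in (
        ("RS", sim.rs_r1, sim.rs_r2),
        ("RIS", sim.ris_r1, sim.ris_r2),
    ):
        matrix, stats = count_pairs(
            r1,
            r2,
            cfg.adapter_spec(),
            rna_entries=sim.truth.bait_entries,
            prey_refs=sim.truth.prey_references(),
            condition=condition,
        )
        matrices[condition] = matrix
        print(f"{condition}: usable fraction {stats.usable_fraction:.3f}")

scores, _ = score_replicate(matrices["RS"], matrices["RIS"], seed=5)
is_final = subtract_q3(scores)
top = np.unravel_index(np.argsort(is_final.values, axis=None)[::-1][:4], is_final.shape)
print("\ntop RNA-protein pairs (planted marked *):")
for i, j in zip(*top):
    rna, prot = is_final.baits[i], is_final.preys[j]
    mark = "*" if (rna, prot) in sim.truth.planted_pairs else " "
    print(f"  {mark} {rna} x {prot}  IS_FINAL = {is_final.values[i, j]:6.2f}")
print("\nplanted pairs and their final scores:")
for rna, prot in sorted(sim.truth.planted_pairs):
    print(f"    {rna} x {prot}  IS_FINAL = {is_final[rna, prot]:6.2f}")
print(
    "\nThe RNA side uses exact matching because some target motifs are "
    "short; the scoring chain is shared with the protein-protein screen. "
    "A planted pair whose clones are strongly underrepresented can vanish "
    "in a single replicate -- averaging replicate screens is what rescues "
    "such pairs in practice."
)
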