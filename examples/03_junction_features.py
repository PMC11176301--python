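"""Junction sequence features: hydrophobicity, V/N/J decomposition.

Decomposes simulated junction nucleotide sequences into V-germline,
N-region and J-germline parts (checking against the generator's truth)
and contrasts Eisenberg hydrophobicity between two junction sets.
"""

import numpy as np

from pitmatch import (
    SimConfig,
    decompose_junction,
    hydrophobicity,
    simulate_germline_reference,
    simulate_repertoire,
)

germline = simulate_germline_reference(seed=5)
cfg = SimConfig(seed=5, n_donors=3, clones_per_donor=40, n_insert_mean=4.0)
_, truth = simulate_repertoire(cfg, germline, with_paired_trb=False)

print("junction decomposition (first 5 clones): v3 + N + j5 = length")
for row in truth.head(5).itertuples(index=False):
    v = germline.v_segments[row.locus][row.v_gene]
    j = germline.j_segments[row.locus][row.j_gene]
    v3, n, j5 = decompose_junction(row.junction_nt, v, j)
    print(f"  {row.junction_aa:<18} {v3:>2} + {n:>2} + {j5:>2} = {len(row.junction_nt)}"
          f"   (planted N = {row.n_region_nt})")

n_rec = [
    decompose_junction(
        r.junction_nt,
        germline.v_segments[r.locus][r.v_gene],
        germline.j_segments[r.locus][r.j_gene],
    )[1]
    for r in truth.itertuples(index=False)
]
print(f"\nmedian recovered N-region length: {np.median(n_rec):.0f} nt "
      f"(generator mean {cfg.n_insert_mean} nt; recovered medians track the "
      f"planted insertion rate)")

print("\nEisenberg hydrophobicity (per-residue mean; P=0.12, Y=0.26 anchors):")
for j in ("CAASNTGNQFYF", "CAERGLTGGGNKLTF", "CVVSGGSNYKLTF"):
    print(f"  {j:<16} {hydrophobicity(j):+.3f}")
print("More positive = more hydrophobic; junction values live between the")
print("scale extremes R=-2.53 and I=+1.38.")
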