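#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/:
  * plates.csv      — competition plates for rosiglitazone and GW1929 against
                      three coregulator RIDs (24-point series, 2 technical x 8
                      dilution replicates), with a +0.3 log10 PGC1a bias
                      planted for GW1929;
  * de_table.tsv    — a ~15,000-gene DE table for both ligands at 24 h with a
                      0.3-sigma offset planted on one pathway;
  * pathways.gmt    — the 98-pathway layout plus the AMPK-like reference;
  * promoters.fa    — 200 upstream windows, 30% carrying a planted DR1 motif;
  * dr1_matrix.txt  — the DR1 probability matrix used for planting/scanning.
"""

import sys
from pathlib import Path

import pandas as pd

from pparbias import io as pio
from pparbias.motifs import DR1_CONSENSUS, MotifMatrix
from pparbias.simulate import (
    DESimSpec,
    PlateSimSpec,
    build_pathway_db,
    simulate_de_tables,
    simulate_plate,
    simulate_promoters,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/inputs")
OUT.mkdir(parents=True, exist_ok=True)

# --- anisotropy plates: planted coregulator bias for GW1929 on PGC1a
PLANTED_BIAS = 0.3
base_ki = {"CBP_1-127": 4_000.0, "PGC1a_100-220": 8_000.0, "MED1_557-870": 15_000.0}
frames = []
seed = SEED
for ligand in ("rosiglitazone", "GW1929"):
    for coreg, ki in base_ki.items():
        if ligand == "GW1929" and coreg == "PGC1a_100-220":
            ki = ki * 10 ** (-PLANTED_BIAS)  # tighter binding -> positive bias
        curve = simulate_plate(PlateSimSpec(true_ki=ki, seed=seed, ligand=ligand,
                                            coregulator=coreg, assembly="PPARgamma-FL"))
        frames.append(pio.curve_to_plate_frame(curve))
        seed += 1
pio.write_plate_csv(pd.concat(frames, ignore_index=True), OUT / "plates.csv")
print(f"plates.csv: {sum(len(f) for f in frames)} wells, "
      f"planted GW1929/PGC1a bias = {PLANTED_BIAS}")

# --- DE tables: one pathway with reference-ligand effects inflated by 10^0.3
# shared-effect condition (no ligand-specific genes) so the planted offset is
# the only systematic ligand difference
db = build_pathway_db(seed=SEED)
target = next(pid for pid in db if pid != "AMPK" and 60 <= len(db[pid]) <= 90)
de, truth = simulate_de_tables(DESimSpec(pathway_db=db, seed=SEED,
                                         ligand_specific_fraction=0.0,
                                         planted_pathway_bias=((target, 0.3),)))
pio.write_de_table(de, OUT / "de_table.tsv")
pio.write_gmt(db, OUT / "pathways.gmt")
print(f"de_table.tsv: {de['gene_id'].nunique()} genes x 2 ligands; "
      f"planted 0.3-sigma offset on {target} ({len(db[target])} genes)")

# --- promoters with planted DR1 sites
matrix = MotifMatrix.from_consensus(DR1_CONSENSUS)
seqs, motif_truth = simulate_promoters(200, 2_000, matrix, plant_rate=0.3, seed=SEED)
pio.write_fasta(seqs, OUT / "promoters.fa")
probs = matrix.probabilities
with open(OUT / "dr1_matrix.txt", "w") as fh:
    for i, base in enumerate("ACGT"):
        fh.write(base + " " + " ".join(f"{v:.6f}" for v in probs[:, i]) + "\n")
motif_truth.to_csv(OUT / "promoter_truth.tsv", sep="\t", index=False)
print(f"promoters.fa: 200 windows of 2 kb, {int(motif_truth['planted'].sum())} "
      "with a planted DR1 site")
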