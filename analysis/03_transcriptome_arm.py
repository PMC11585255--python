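#!/usr/bin/env python
"""Transcriptome arm: DE tables -> enrichment, pathway bias, partitions.

Reads results/inputs/de_table.tsv and pathways.gmt, runs over-representation,
computes pathway-level bias for GW1929 against rosiglitazone with the AMPK
reference pathway, and partitions the DE gene sets.  Tables land in
results/transcriptome/.
"""

from pparbias.config import RunConfig
from pparbias.pathway_bias import expected_false_positive_pathways
from pparbias.pipelines import run_transcriptome_arm

cfg = RunConfig(de_table="results/inputs/de_table.tsv", gmt="results/inputs/pathways.gmt",
                output_dir="results/transcriptome")
result = run_transcriptome_arm(cfg)

(ligand, tp), table = next(iter(result.pathway_bias_tables.items()))
n_pathways = (table["call"] != "indeterminate").sum()
biased = table[table["call"].isin(["biased-toward-reference", "biased-toward-test"])]
print(f"pathway bias, {ligand} vs rosiglitazone at {tp}: "
      f"{len(biased)} of {n_pathways} pathways called biased "
      f"(expected by chance per direction: "
      f"{expected_false_positive_pathways(n_pathways):.2f})")
for row in biased.sort_values("mean_bias", ascending=False).itertuples():
    print(f"  {row.pathway_id:8s} n={row.n_genes:3d} "
          f"mean bias {row.mean_bias:+.3f} [{row.ci_lo:+.3f}, {row.ci_hi:+.3f}] "
          f"-> {row.call}")

enr = result.enrichment[(ligand, tp)]
print(f"\nenrichment ({ligand}, {tp}): {int(enr['significant'].sum())} of "
      f"{len(enr)} pathways over-represented at adjusted p < 0.05")

for tp_key, part in result.partitions.items():
    print(f"\nDE-set partition at {tp_key}:")
    print(part["counts"].to_string(index=False))
print("\ntables written to results/transcriptome/")
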