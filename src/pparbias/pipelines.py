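"""End-to-end drivers for the two analysis arms.

The binding arm goes plate CSV -> per-replicate 4PL fits -> Ki -> sigma/bias
with CIs -> predicted cellular occupancy.  The transcriptome arm goes DE
tables + gene sets -> over-representation -> pathway bias calls ->
selectivity indices -> DE-set partitions.  Both write TSV/JSON outputs plus
the fully resolved configuration, and are deterministic given config + data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import RunConfig
from .equilibria import BindingSystem
from .fitting import fit_4pl, ki_from_ec50
from .ligand_bias import aggregate_bias, bias_results_frame, predict_cellular_occupancy
from .pathway_bias import (
    enrich_pathways,
    partition_de_sets,
    pathway_bias,
    pathway_bias_frame,
    selectivity_index,
)

log = logging.getLogger("pparbias")

__all__ = ["BindingArmResult", "TranscriptomeArmResult", "run_binding_arm",
           "run_transcriptome_arm"]


@dataclass
class BindingArmResult:
    ki_table: pd.DataFrame
    bias_table: pd.DataFrame
    occupancy_table: pd.DataFrame
    n_fit_failures: int = 0
    failures: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.n_fit_failures == 0


def run_binding_arm(config: RunConfig, curves=None) -> BindingArmResult:
    """Fit every curve per dilution replicate, convert to Ki, aggregate bias.

    ``curves`` may be passed directly (e.g. from the simulator); otherwise
    the plate CSVs in the config are read.  Per-curve fit failures are
    collected and the run continues.
    """
    if curves is None:
        curves = []
        for path in config.plate_csvs:
            curves.extend(pio.plate_frame_to_curves(pio.read_plate_csv(path)))
    assay = BindingSystem(config.receptor_total, config.tracer_total, config.tracer_kd)

    rows, failures = [], []
    for curve in curves:
        md = curve.metadata
        for rep, sub in sorted(curve.split_by_dilution_replicate().items()):
            try:
                fit = fit_4pl(sub, rout_q=config.rout_q)
                if not fit.converged:
                    raise RuntimeError("fit did not converge")
                ki = ki_from_ec50(fit, assay, convention=config.ki_convention)
                rows.append((md.get("ligand"), md.get("coregulator"), md.get("assembly"),
                             int(rep), ki, fit.ec50, int(fit.outlier_mask.sum())))
            except (RuntimeError, ValueError) as exc:
                failures.append({"curve": dict(md), "replicate": int(rep), "error": str(exc)})
                log.warning("fit failure for %s replicate %s: %s", md, rep, exc)
    ki_table = pd.DataFrame(
        rows, columns=["ligand", "coregulator", "assembly", "replicate", "ki",
                       "ec50_nM", "n_outliers"],
    )
    if ki_table.empty:
        raise ValueError("no curve could be fit; nothing to aggregate")

    results = aggregate_bias(ki_table, config.reference_ligand, config.reference_coregulator)
    per_rep = bias_results_frame(results)
    summary = pd.DataFrame(
        [(r.ligand, r.coregulator, r.assembly, r.mean_bias, r.ci95[0], r.ci95[1], r.significant)
         for r in results],
        columns=["ligand", "coregulator", "assembly", "mean_bias", "ci_lo", "ci_hi",
                 "significant"],
    )
    bias_table = summary.merge(
        per_rep.groupby(["ligand", "coregulator", "assembly"])["bias"].count().rename("n"),
        on=["ligand", "coregulator", "assembly"],
    )

    grid = {name: tuple(config.coregulator_concentrations_nM)
            for name in ki_table["coregulator"].unique()}
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # cellular grid intentionally exceeds trace threshold
        occupancy = predict_cellular_occupancy(
            ki_table, grid, receptor_total=config.cellular_receptor_nM)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_ki_table(ki_table, out / "ki_table.tsv")
    bias_table.to_csv(out / "bias_table.tsv", sep="\t", index=False)
    per_rep.to_csv(out / "bias_per_replicate.tsv", sep="\t", index=False)
    occupancy.to_csv(out / "occupancy_table.tsv", sep="\t", index=False)
    if failures:
        (out / "fit_failures.json").write_text(json.dumps(failures, indent=2))
    config.echo(out)
    log.info("binding arm: %d Ki values, %d fit failures", len(ki_table), len(failures))
    return BindingArmResult(ki_table, bias_table, occupancy, len(failures), failures)


@dataclass
class TranscriptomeArmResult:
    enrichment: dict
    pathway_bias_tables: dict
    selectivity: pd.DataFrame
    partitions: dict


def run_transcriptome_arm(config: RunConfig, de=None, db=None,
                          antidiabetic=None, adverse=None) -> TranscriptomeArmResult:
    """Enrichment, pathway-bias calls, selectivity indices and DE partitions.

    Inputs may be passed in memory or read from the config's paths.  The
    reference pathway must exist in the gene-set database; an empty database
    yields empty results and a clean return.
    """
    if de is None:
        if config.de_table is None:
            raise ValueError("no DE table provided")
        de = pio.read_de_table(config.de_table)
    if db is None:
        if config.gmt is None:
            raise ValueError("no pathway GMT provided")
        db = pio.read_gmt(config.gmt)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ligands = sorted(de["ligand"].unique())
    timepoints = sorted(de["timepoint"].unique())
    if len(db) == 0:
        config.echo(out)
        return TranscriptomeArmResult({}, {}, pd.DataFrame(), {})
    if config.reference_pathway not in db:
        raise ValueError(
            f"reference pathway {config.reference_pathway!r} absent from the pathway database"
        )

    universe = set(de["gene_id"].unique())
    enrichment = {}
    for lig in ligands:
        for tp in timepoints:
            sub = de[(de["ligand"] == lig) & (de["timepoint"] == tp)]
            if sub.empty:
                continue
            de_genes = set(sub.loc[sub["padj"] < config.alpha, "gene_id"])
            table = enrich_pathways(de_genes, universe, db, alpha=config.alpha)
            enrichment[(lig, tp)] = table
            table.to_csv(out / f"enrichment_{lig}_{tp}.tsv", sep="\t", index=False)

    bias_tables = {}
    for lig in ligands:
        if lig == config.reference_ligand:
            continue
        for tp in timepoints:
            if de[(de["ligand"] == lig) & (de["timepoint"] == tp)].empty:
                continue
            results = pathway_bias(
                de, db, config.reference_pathway, lig, config.reference_ligand, tp,
                alpha=config.alpha, epsilon=config.lfc_epsilon,
            )
            table = pathway_bias_frame(results)
            bias_tables[(lig, tp)] = table
            table.to_csv(out / f"pathway_bias_{lig}_{tp}.tsv", sep="\t", index=False)

    sel_rows = []
    if antidiabetic is None and config.antidiabetic_genes:
        antidiabetic = set(Path(config.antidiabetic_genes).read_text().split())
    if adverse is None and config.adverse_genes:
        adverse = set(Path(config.adverse_genes).read_text().split())
    if antidiabetic and adverse:
        for lig in ligands:
            for tp in timepoints:
                if de[(de["ligand"] == lig) & (de["timepoint"] == tp)].empty:
                    continue
                idx = selectivity_index(de, antidiabetic, adverse, lig, tp)
                sel_rows.append((lig, tp, idx))
    selectivity = pd.DataFrame(sel_rows, columns=["ligand", "timepoint", "selectivity_index"])
    if not selectivity.empty:
        selectivity.to_csv(out / "selectivity_index.tsv", sep="\t", index=False)

    partitions = {}
    for tp in timepoints:
        partitions[tp] = partition_de_sets(de, ligands, [tp], alpha=config.alpha)
        partitions[tp]["counts"].to_csv(out / f"de_partition_{tp}.tsv", sep="\t", index=False)

    config.echo(out)
    log.info("transcriptome arm: %d enrichment tables, %d bias tables",
             len(enrichment), len(bias_tables))
    return TranscriptomeArmResult(enrichment, bias_tables, selectivity, partitions)
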