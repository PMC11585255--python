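"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study's data structures so every analysis stage is
testable without external downloads:

* anisotropy plates mirror the assay design — 800 nM receptor, 50 nM tracer,
  a 24-point competitor dilution series read with 2 technical replicates per
  dilution replicate and 8 dilution replicates;
* differential-expression tables mirror the processed RNA-seq outputs —
  ~15,000 tested genes, per-ligand log2 fold changes and adjusted p-values
  with shared and ligand-specific effects, ~100 pathways;
* promoter windows carry motif instances planted at known strand/offset.

Every generator is a pure function of its spec (seed included): the same spec
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .equilibria import BindingSystem, competitive_equilibrium
from .fitting import TitrationCurve
from .motifs import MotifMatrix
from .pathway_bias import PathwayDB

__all__ = [
    "PlateSimSpec",
    "DESimSpec",
    "default_concentration_series",
    "simulate_plate",
    "build_pathway_db",
    "simulate_de_tables",
    "simulate_promoters",
]


def default_concentration_series(n_points: int = 24, low: float = 500.0,
                                 high: float = 185_000.0) -> np.ndarray:
    """Geometric competitor series in nM, low to high (final in-well span)."""
    return high * (low / high) ** (np.arange(n_points)[::-1] / (n_points - 1))


@dataclass(frozen=True)
class PlateSimSpec:
    """Forward-model parameters for one simulated competition plate."""

    true_ki: float = 5_000.0  # nM
    receptor_total: float = 800.0
    tracer_total: float = 50.0
    tracer_kd: float = 200.0
    concentration_series: tuple[float, ...] = tuple(default_concentration_series())
    noise_sd: float = 0.004  # anisotropy units
    anisotropy_free: float = 0.08
    anisotropy_bound: float = 0.20
    technical_replicates: int = 2
    dilution_replicates: int = 8
    seed: int = 0
    ligand: str = "ligand"
    coregulator: str = "coregulator"
    assembly: str = "PPARgamma-FL"

    def __post_init__(self) -> None:
        if self.true_ki <= 0 or self.receptor_total <= 0 or self.tracer_total <= 0:
            raise ValueError("concentrations and constants must be positive")
        if self.tracer_kd <= 0 or self.noise_sd < 0:
            raise ValueError("tracer_kd must be positive and noise_sd non-negative")
        if min(self.concentration_series) <= 0:
            raise ValueError("concentration series must be strictly positive")


def noise_free_responses(spec: PlateSimSpec) -> np.ndarray:
    """Anisotropy on the forward model at each concentration point."""
    conc = np.asarray(spec.concentration_series)
    base = BindingSystem(spec.receptor_total, spec.tracer_total, spec.tracer_kd)
    frac = np.array(
        [competitive_equilibrium(base.with_competitor(c, spec.true_ki))[0] for c in conc]
    )
    return spec.anisotropy_free + (spec.anisotropy_bound - spec.anisotropy_free) * frac


def simulate_plate(spec: PlateSimSpec) -> TitrationCurve:
    """Simulate one plate: exact equilibrium + linear anisotropy mixing + noise."""
    rng = np.random.default_rng(spec.seed)
    conc = np.asarray(spec.concentration_series)
    clean = noise_free_responses(spec)

    n_pts = conc.size
    n_tech, n_dil = spec.technical_replicates, spec.dilution_replicates
    conc_all = np.tile(conc, n_tech * n_dil)
    resp_all = np.tile(clean, n_tech * n_dil) + rng.normal(0.0, spec.noise_sd,
                                                           n_pts * n_tech * n_dil)
    tech = np.repeat(np.tile(np.arange(1, n_tech + 1), n_dil), n_pts)
    dil = np.repeat(np.arange(1, n_dil + 1), n_pts * n_tech)
    return TitrationCurve(
        conc_all, resp_all, tech, dil,
        metadata={"ligand": spec.ligand, "coregulator": spec.coregulator,
                  "assembly": spec.assembly},
        ground_truth={"true_ki": spec.true_ki, "spec": spec},
    )


def build_pathway_db(
    n_pathways: int = 98,
    reference_id: str = "AMPK",
    reference_size: int = 300,
    size_range: tuple[int, int] = (20, 120),
    n_genes: int = 15_000,
    seed: int = 0,
) -> PathwayDB:
    """Disjoint synthetic pathway layout over a gene universe of ``n_genes``.

    The reference pathway is deliberately the largest (the study's reference
    was chosen as the pathway most consistently affected by both ligands):
    every gene's bias is centred by the reference pathway's mean sigma, so a
    large reference keeps that shared centering noise small relative to
    per-pathway noise.  Gene ids are ``G000000 ...``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:06d}" for i in range(n_genes)]
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_pathways)
    need = reference_size + int(sizes.sum())
    if need > n_genes:
        raise ValueError(f"pathway layout needs {need} genes but universe has {n_genes}")
    order = rng.permutation(n_genes)
    sets = {reference_id: set(genes[i] for i in order[:reference_size])}
    pos = reference_size
    for j, size in enumerate(sizes):
        sets[f"PW{j:03d}"] = set(genes[i] for i in order[pos:pos + size])
        pos += size
    return PathwayDB(sets)


@dataclass(frozen=True)
class DESimSpec:
    """Generative model for per-ligand differential-expression tables.

    Responsive genes share a base log2 fold change between the reference and
    test ligand; a ``ligand_specific_fraction`` of responsive genes respond to
    only one ligand.  ``planted_pathway_bias`` maps pathway id -> sigma offset:
    the reference ligand's effects on that pathway's genes are scaled by
    ``10**sigma`` so the pathway's true mean bias equals the offset.  Adjusted
    p-values are assigned by responsiveness label rather than refit from
    counts (DE model fitting is upstream of this pipeline).
    """

    n_genes: int = 15_000
    pathway_db: PathwayDB | None = None
    test_ligand: str = "GW1929"
    reference_ligand: str = "rosiglitazone"
    timepoint: str = "24h"
    background_responsive_rate: float = 0.08
    pathway_responsive_rate: float = 0.35
    reference_responsive_rate: float = 0.60
    ligand_specific_fraction: float = 0.10
    base_lfc_location: float = 1.2
    base_lfc_scale: float = 0.6
    lfc_noise_sd: float = 0.25
    planted_pathway_bias: tuple[tuple[str, float], ...] = ()
    seed: int = 0


def simulate_de_tables(spec: DESimSpec) -> tuple[pd.DataFrame, dict]:
    """Tidy DE table for the test and reference ligand plus ground truth.

    Returns ``(de_table, truth)``; the table has one row per gene per ligand
    with columns ``gene_id, ligand, timepoint, log2fc, padj``; ``truth``
    records responsiveness labels and planted offsets.
    """
    rng = np.random.default_rng(spec.seed)
    db = spec.pathway_db if spec.pathway_db is not None else build_pathway_db(
        n_genes=spec.n_genes, seed=spec.seed)
    genes = np.array([f"G{i:06d}" for i in range(spec.n_genes)])
    gene_index = {g: i for i, g in enumerate(genes)}

    in_pathway = np.zeros(spec.n_genes, dtype=bool)
    in_reference = np.zeros(spec.n_genes, dtype=bool)
    reference_pid = "AMPK" if "AMPK" in db else None
    for pid in db:
        for g in db[pid]:
            if g in gene_index:
                in_pathway[gene_index[g]] = True
                if pid == reference_pid:
                    in_reference[gene_index[g]] = True

    rate = np.where(in_pathway, spec.pathway_responsive_rate, spec.background_responsive_rate)
    rate = np.where(in_reference, spec.reference_responsive_rate, rate)
    responsive = rng.random(spec.n_genes) < rate

    sign = rng.choice([-1.0, 1.0], size=spec.n_genes)
    magnitude = np.abs(rng.normal(spec.base_lfc_location, spec.base_lfc_scale, spec.n_genes))
    magnitude = np.maximum(magnitude, 0.3)
    base = np.where(responsive, sign * magnitude, 0.0)

    specific = responsive & (rng.random(spec.n_genes) < spec.ligand_specific_fraction)
    specific_to_test = specific & (rng.random(spec.n_genes) < 0.5)
    specific_to_ref = specific & ~specific_to_test

    effect_ref = np.where(specific_to_test, 0.0, base)
    effect_test = np.where(specific_to_ref, 0.0, base)
    planted = dict(spec.planted_pathway_bias)
    for pid, offset in planted.items():
        idx = [gene_index[g] for g in db[pid] if g in gene_index]
        effect_ref[idx] = effect_ref[idx] * 10.0 ** offset

    lfc_ref = effect_ref + rng.normal(0.0, spec.lfc_noise_sd, spec.n_genes)
    lfc_test = effect_test + rng.normal(0.0, spec.lfc_noise_sd, spec.n_genes)

    def padj_for(effect):
        sig = effect != 0.0
        p = np.where(sig, 10.0 ** rng.uniform(-8.0, -1.4, spec.n_genes),
                     rng.uniform(0.06, 1.0, spec.n_genes))
        return p

    rows = []
    for ligand, lfc, effect in ((spec.reference_ligand, lfc_ref, effect_ref),
                                (spec.test_ligand, lfc_test, effect_test)):
        rows.append(pd.DataFrame({
            "gene_id": genes,
            "ligand": ligand,
            "timepoint": spec.timepoint,
            "log2fc": lfc,
            "padj": padj_for(effect),
        }))
    de = pd.concat(rows, ignore_index=True)
    truth = {
        "responsive": pd.Series(responsive, index=genes),
        "specific_to_test": pd.Series(specific_to_test, index=genes),
        "specific_to_ref": pd.Series(specific_to_ref, index=genes),
        "planted_pathway_bias": planted,
        "pathway_db": db,
    }
    return de, truth


def simulate_promoters(
    n: int,
    length: int,
    matrix: MotifMatrix,
    plant_rate: float,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-background sequences with consensus motifs planted at known sites.

    A ``plant_rate`` fraction of sequences receives one copy of the matrix
    consensus at a uniform random offset and strand (minus-strand plants
    insert the reverse complement).  Returns ``(sequences, truth)`` where
    ``truth`` has columns ``sequence_id, planted, offset, strand``.
    """
    if length < matrix.width:
        raise ValueError("sequence length must be at least the matrix width")
    if not 0.0 <= plant_rate <= 1.0:
        raise ValueError("plant_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    comp = str.maketrans("ACGT", "TGCA")
    consensus = matrix.consensus
    seqs: dict[str, str] = {}
    rows = []
    for i in range(n):
        seq_id = f"seq{i:04d}"
        seq = "".join(rng.choice(bases, size=length))
        planted = bool(rng.random() < plant_rate)
        offset, strand = -1, "."
        if planted:
            offset = int(rng.integers(0, length - matrix.width + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = consensus if strand == "+" else consensus.translate(comp)[::-1]
            seq = seq[:offset] + insert + seq[offset + matrix.width:]
        seqs[seq_id] = seq
        rows.append((seq_id, planted, offset, strand))
    truth = pd.DataFrame(rows, columns=["sequence_id", "planted", "offset", "strand"])
    return seqs, truth
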