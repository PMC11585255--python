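"""Transcriptome-level signaling bias from differential-expression tables.

Per-gene sigma compares effect magnitudes between two ligands,

    sigma_g = log10(|LFC_reference| / |LFC_test|)

so genes affected more strongly by the reference ligand score positive.
Each gene's bias subtracts the mean sigma over the reference pathway's
scorable genes (the AMPK KEGG pathway with rosiglitazone as reference
ligand in the study); pathway bias is then the mean of its genes' bias
values with a Student-t 95% confidence interval, and a pathway is called
biased when that interval excludes zero (toward the reference ligand when
entirely positive, toward the test ligand when entirely negative).

DE tables are tidy pandas DataFrames with columns
``gene_id, ligand, timepoint, log2fc, padj`` (one row per gene per
contrast); a gene is differentially expressed when ``padj < 0.05``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayDB",
    "PathwayBiasResult",
    "gene_sigma",
    "pathway_bias",
    "expected_false_positive_pathways",
    "enrich_pathways",
    "selectivity_index",
    "partition_de_sets",
    "SIGNIFICANCE_ALPHA",
    "LFC_EPSILON",
]

SIGNIFICANCE_ALPHA = 0.05
#: absolute log2 fold changes below this are floored before ratioing
LFC_EPSILON = 0.01

DE_COLUMNS = ["gene_id", "ligand", "timepoint", "log2fc", "padj"]


class PathwayDB:
    """Mapping of pathway id -> gene-id set, with optional display names."""

    def __init__(self, sets: dict[str, set[str]], names: dict[str, str] | None = None):
        if any(len(genes) == 0 for genes in sets.values()):
            raise ValueError("pathway gene sets must be nonempty")
        self._sets = {pid: frozenset(genes) for pid, genes in sets.items()}
        self._names = dict(names or {})

    def __getitem__(self, pathway_id: str) -> frozenset:
        return self._sets[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def items(self):
        return self._sets.items()

    def display_name(self, pathway_id: str) -> str:
        return self._names.get(pathway_id, pathway_id)

    def genes(self) -> frozenset:
        out = frozenset()
        for s in self._sets.values():
            out |= s
        return out


@dataclass
class PathwayBiasResult:
    pathway_id: str
    gene_bias_values: np.ndarray
    mean_bias: float
    ci95: tuple[float, float]
    call: str  # biased-toward-reference | biased-toward-test | unbiased | indeterminate
    n_genes: int
    n_clamped: int = 0


def _validate_de(de: pd.DataFrame) -> pd.DataFrame:
    missing = set(DE_COLUMNS) - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    bad = de["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("padj values must lie in [0, 1]")
    return de


def gene_sigma(lfc_test, lfc_reference, epsilon: float = LFC_EPSILON):
    """Per-gene sigma = log10(|LFC_ref| / |LFC_test|), with epsilon flooring.

    Vectorised; effects with |LFC| < ``epsilon`` are floored at ``epsilon``
    before ratioing so a near-zero effect for one ligand yields a large but
    finite sigma.  Returns a float for scalar inputs.
    """
    t = np.abs(np.asarray(lfc_test, dtype=float))
    r = np.abs(np.asarray(lfc_reference, dtype=float))
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("fold changes must be finite")
    t = np.maximum(t, epsilon)
    r = np.maximum(r, epsilon)
    out = np.log10(r / t)
    return float(out) if out.ndim == 0 else out


def _contrast_frame(de: pd.DataFrame, test_ligand: str, reference_ligand: str,
                    timepoint) -> pd.DataFrame:
    """Wide per-gene frame for one test/reference contrast at one timepoint."""
    de = _validate_de(de)
    sub = de[(de["timepoint"] == timepoint) & (de["ligand"].isin([test_ligand, reference_ligand]))]
    wide = sub.pivot_table(index="gene_id", columns="ligand", values=["log2fc", "padj"],
                           aggfunc="first")
    for lig in (test_ligand, reference_ligand):
        if ("log2fc", lig) not in wide.columns:
            raise ValueError(f"no DE rows for ligand {lig!r} at timepoint {timepoint!r}")
    out = pd.DataFrame({
        "lfc_test": wide[("log2fc", test_ligand)],
        "lfc_ref": wide[("log2fc", reference_ligand)],
        "padj_test": wide[("padj", test_ligand)],
        "padj_ref": wide[("padj", reference_ligand)],
    }).dropna(subset=["lfc_test", "lfc_ref"])
    out["de_any"] = (out["padj_test"] < SIGNIFICANCE_ALPHA) | (out["padj_ref"] < SIGNIFICANCE_ALPHA)
    return out


def pathway_bias(
    de: pd.DataFrame,
    db: PathwayDB,
    reference_pathway: str,
    test_ligand: str,
    reference_ligand: str,
    timepoint,
    alpha: float = SIGNIFICANCE_ALPHA,
    epsilon: float = LFC_EPSILON,
) -> list[PathwayBiasResult]:
    """Pathway-level bias calls for one test ligand against the reference ligand.

    A gene is scorable for a pathway when it belongs to the pathway and is
    differentially expressed (padj < ``alpha``) by at least one of the two
    ligands at the timepoint.  Gene bias = sigma_g - mean(sigma_g over the
    reference pathway's scorable genes); pathways with fewer than 2 scorable
    genes are emitted with ``call="indeterminate"``.
    """
    if reference_pathway not in db:
        raise ValueError(f"reference pathway {reference_pathway!r} not in pathway database")
    frame = _contrast_frame(de, test_ligand, reference_ligand, timepoint)
    scorable = frame[frame["de_any"]]
    sigma = pd.Series(
        gene_sigma(scorable["lfc_test"].to_numpy(), scorable["lfc_ref"].to_numpy(), epsilon),
        index=scorable.index,
    )
    clamped = (scorable["lfc_test"].abs() < epsilon) | (scorable["lfc_ref"].abs() < epsilon)

    ref_genes = sigma.index.intersection(db[reference_pathway])
    if len(ref_genes) < 2:
        raise ValueError(
            f"reference pathway {reference_pathway!r} has {len(ref_genes)} scorable genes; need >= 2"
        )
    ref_sigma = float(sigma.loc[ref_genes].mean())

    results = []
    for pid in db:
        genes = sigma.index.intersection(db[pid])
        values = (sigma.loc[genes] - ref_sigma).to_numpy()
        n = values.size
        if n < 2:
            results.append(PathwayBiasResult(pid, values, float("nan"), (float("nan"),) * 2,
                                             "indeterminate", n))
            continue
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        if sd == 0.0:
            lo = hi = mean
        else:
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
        if lo > 0:
            call = "biased-toward-reference"
        elif hi < 0:
            call = "biased-toward-test"
        else:
            call = "unbiased"
        results.append(PathwayBiasResult(pid, values, mean, (lo, hi), call, n,
                                         int(clamped.loc[genes].sum())))
    return results


def pathway_bias_frame(results: list[PathwayBiasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pathway_id, r.n_genes, r.mean_bias, r.ci95[0], r.ci95[1], r.call, r.n_clamped)
         for r in results],
        columns=["pathway_id", "n_genes", "mean_bias", "ci_lo", "ci_hi", "call", "n_clamped"],
    )


def expected_false_positive_pathways(n_pathways: int, alpha: float = SIGNIFICANCE_ALPHA) -> float:
    """Pathways expected biased per direction by chance: n * alpha / 2."""
    if n_pathways <= 0:
        raise ValueError("n_pathways must be positive")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    return n_pathways * alpha / 2.0


def enrich_pathways(de_genes, universe, db: PathwayDB,
                    alpha: float = SIGNIFICANCE_ALPHA) -> pd.DataFrame:
    """Over-representation of each pathway among DE genes (hypergeometric + BH).

    Upper-tail hypergeometric p-value per pathway (pathway membership is
    intersected with the tested universe first), Benjamini-Hochberg adjusted;
    ``significant`` marks adjusted p < ``alpha``.
    """
    de_genes = set(de_genes)
    universe = set(universe)
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    if not de_genes:
        return pd.DataFrame(columns=["pathway_id", "n_pathway", "n_overlap", "p", "padj",
                                     "significant"])
    m = len(universe)
    n_draw = len(de_genes)
    rows = []
    for pid in db:
        members = db[pid] & universe
        k = len(members & de_genes)
        # P(X >= k) for X ~ Hypergeom(M=m, n=|members|, N=n_draw)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_draw))
        rows.append((pid, len(members), k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["pathway_id", "n_pathway", "n_overlap", "p"])
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["padj"] < alpha
    return out.sort_values("p", ignore_index=True)


def selectivity_index(
    de: pd.DataFrame,
    antidiabetic_genes,
    adverse_genes,
    ligand: str,
    timepoint,
) -> float:
    """Selectivity index: mean |LFC| over antidiabetic genes minus adverse genes.

    Higher values indicate relatively stronger regulation of the
    antidiabetic-associated gene set and weaker regulation of the
    adverse-effect set; equal regulation of both sets gives zero.
    """
    de = _validate_de(de)
    sub = de[(de["ligand"] == ligand) & (de["timepoint"] == timepoint)].set_index("gene_id")
    sets = {"antidiabetic": set(antidiabetic_genes), "adverse": set(adverse_genes)}
    means = {}
    for label, genes in sets.items():
        present = sub.index.intersection(genes)
        if len(present) == 0:
            missing = sorted(genes)[:10]
            raise ValueError(
                f"{label} gene set has no genes in the DE table for ({ligand}, {timepoint}); "
                f"missing e.g. {missing}"
            )
        means[label] = float(sub.loc[present, "log2fc"].abs().mean())
    return means["antidiabetic"] - means["adverse"]


def _significant_sets(de: pd.DataFrame, ligands, timepoint, alpha) -> dict[str, set[str]]:
    sets = {}
    for lig in ligands:
        sub = de[(de["ligand"] == lig) & (de["timepoint"] == timepoint)]
        if sub.empty:
            raise ValueError(f"no DE rows for ligand {lig!r} at timepoint {timepoint!r}")
        sets[lig] = set(sub.loc[sub["padj"] < alpha, "gene_id"])
    return sets


def partition_de_sets(
    de: pd.DataFrame,
    ligands,
    timepoints,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> dict:
    """Exclusive/shared DE-gene membership per timepoint, plus transitions.

    Returns ``{"cells": {timepoint: {frozenset(ligands): gene set}},
    "counts": DataFrame, "transitions": DataFrame}``.  Venn cells are keyed by
    the exact subset of ligands that call the gene significant; transitions
    track genes significant for exactly one ligand at the first timepoint into
    their membership class at the second (requires two timepoints).
    """
    de = _validate_de(de)
    ligands = list(ligands)
    timepoints = list(timepoints)
    cells: dict = {}
    count_rows = []
    for tp in timepoints:
        sig = _significant_sets(de, ligands, tp, alpha)
        all_genes = set().union(*sig.values())
        tp_cells: dict[frozenset, set] = {}
        for gene in all_genes:
            key = frozenset(l for l in ligands if gene in sig[l])
            tp_cells.setdefault(key, set()).add(gene)
        cells[tp] = tp_cells
        for key, genes in sorted(tp_cells.items(), key=lambda kv: sorted(kv[0])):
            count_rows.append((tp, "+".join(sorted(key)), len(genes)))
    counts = pd.DataFrame(count_rows, columns=["timepoint", "ligand_set", "n_genes"])

    transitions = pd.DataFrame(columns=["from_timepoint", "to_timepoint", "ligand",
                                        "to_class", "n_genes"])
    if len(timepoints) == 2:
        t1, t2 = timepoints
        sig2 = _significant_sets(de, ligands, t2, alpha)
        rows = []
        for lig in ligands:
            only = cells[t1].get(frozenset([lig]), set())
            for gene in only:
                members = frozenset(l for l in ligands if gene in sig2[l])
                if members == frozenset(ligands):
                    cls = "both" if len(ligands) == 2 else "all"
                elif not members:
                    cls = "neither"
                else:
                    cls = "only " + "+".join(sorted(members))
                rows.append((lig, cls))
        if rows:
            trans = pd.DataFrame(rows, columns=["ligand", "to_class"])
            transitions = (trans.value_counts().rename("n_genes").reset_index())
            transitions.insert(0, "from_timepoint", t1)
            transitions.insert(1, "to_timepoint", t2)
    return {"cells": cells, "counts": counts, "transitions": transitions}
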