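"""Ligand-bias (sigma / bias) statistics from competitive Ki measurements.

A test ligand's sigma value for one coregulator compares its Ki with the
reference ligand's Ki for the same coregulator and assembly:

    sigma = log10(Ki_reference_ligand / Ki_test_ligand)

so sigma > 0 means the test ligand confers tighter coregulator binding than
the reference (rosiglitazone by default).  Ligand bias for a coregulator is
the difference of sigma values against the reference coregulator (CBP 1-127
by default):

    bias = sigma_coregulator - sigma_reference_coregulator

Bias is therefore identically zero for the reference ligand and for the
reference coregulator, antisymmetric under swapping test and reference
ligand, and invariant to any global rescaling of Ki values.

Replicates are paired within dilution-replicate index before averaging
(the assay's n = 8 design); means carry Student-t 95% confidence intervals
and a group is flagged as significantly biased when its interval excludes
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .equilibria import CoregulatorPool, multi_competitor_occupancy

__all__ = [
    "KiMeasurement",
    "BiasResult",
    "sigma_value",
    "bias_value",
    "aggregate_bias",
    "compare_bias_groups",
    "predict_cellular_occupancy",
    "REFERENCE_LIGAND",
    "REFERENCE_COREGULATOR",
]

REFERENCE_LIGAND = "rosiglitazone"
REFERENCE_COREGULATOR = "CBP_1-127"


@dataclass(frozen=True)
class KiMeasurement:
    """One (ligand, coregulator, assembly, replicate) -> Ki record."""

    ligand: str
    coregulator: str
    assembly: str
    replicate: int
    ki: float  # nM

    def __post_init__(self) -> None:
        if self.ki <= 0:
            raise ValueError("ki must be positive")


@dataclass
class BiasResult:
    """Per-replicate and aggregated bias for one (ligand, coregulator, assembly)."""

    ligand: str
    coregulator: str
    assembly: str
    sigma_per_replicate: np.ndarray
    bias_per_replicate: np.ndarray
    mean_bias: float
    ci95: tuple[float, float]
    significant: bool = False


def _measurements_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
        required = {"ligand", "coregulator", "assembly", "replicate", "ki"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    else:
        df = pd.DataFrame(
            [(m.ligand, m.coregulator, m.assembly, m.replicate, m.ki) for m in measurements],
            columns=["ligand", "coregulator", "assembly", "replicate", "ki"],
        )
    if (df["ki"] <= 0).any():
        raise ValueError("all Ki values must be positive")
    dup = df.duplicated(["ligand", "coregulator", "assembly", "replicate"])
    if dup.any():
        raise ValueError("duplicate replicate indices within a (ligand, coregulator, assembly) group")
    return df


def sigma_value(ki_test: float, ki_reference: float, coregulator: str | None = None,
                reference_coregulator: str | None = None, assembly: str | None = None,
                reference_assembly: str | None = None) -> float:
    """sigma = log10(Ki_reference / Ki_test) for one coregulator and assembly.

    Optional label pairs are checked for agreement: sigma only compares Ki
    values measured against the same coregulator in the same assembly.
    """
    if coregulator is not None and reference_coregulator is not None:
        if coregulator != reference_coregulator:
            raise ValueError(
                f"sigma compares the same coregulator: {coregulator!r} != {reference_coregulator!r}"
            )
    if assembly is not None and reference_assembly is not None and assembly != reference_assembly:
        raise ValueError(f"sigma compares the same assembly: {assembly!r} != {reference_assembly!r}")
    if ki_test <= 0 or ki_reference <= 0:
        raise ValueError("Ki values must be positive")
    return float(np.log10(ki_reference / ki_test))


def bias_value(sigma_coregulator: float, sigma_reference_coregulator: float) -> float:
    """bias = sigma(coregulator) - sigma(reference coregulator)."""
    return float(sigma_coregulator - sigma_reference_coregulator)


def _t_ci(values: np.ndarray, conf: float = 0.95) -> tuple[float, float]:
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    if n < 2 or sd == 0.0:
        return (mean, mean)
    half = stats.t.ppf(0.5 + conf / 2, n - 1) * sd / np.sqrt(n)
    return (mean - half, mean + half)


def aggregate_bias(
    measurements,
    reference_ligand: str = REFERENCE_LIGAND,
    reference_coregulator: str = REFERENCE_COREGULATOR,
) -> list[BiasResult]:
    """Per-replicate sigma and bias for every (ligand, coregulator, assembly).

    Sigma is computed within matching replicate index against the reference
    ligand; bias subtracts the reference coregulator's sigma within the same
    replicate (unpaired fallback: if replicate indices differ between groups
    the sorted Ki values are matched in order and a warning is emitted).
    Groups whose 95% CI excludes zero are flagged ``significant``.
    """
    df = _measurements_frame(measurements)
    assemblies = df["assembly"].unique()

    missing = []
    for asm in assemblies:
        sub = df[df["assembly"] == asm]
        if reference_ligand not in set(sub["ligand"]):
            missing.append((reference_ligand, "<any>", asm))
        for lig in sub["ligand"].unique():
            if reference_coregulator not in set(sub.loc[sub["ligand"] == lig, "coregulator"]):
                missing.append((lig, reference_coregulator, asm))
    if missing:
        raise ValueError(f"missing reference groups: {missing}")

    def replicate_series(lig, coreg, asm) -> pd.Series:
        sub = df[(df["ligand"] == lig) & (df["coregulator"] == coreg) & (df["assembly"] == asm)]
        return sub.set_index("replicate")["ki"].sort_index()

    results: list[BiasResult] = []
    for asm in assemblies:
        sub = df[df["assembly"] == asm]
        for lig in sub["ligand"].unique():
            for coreg in sub.loc[sub["ligand"] == lig, "coregulator"].unique():
                ki_test = replicate_series(lig, coreg, asm)
                ki_ref = replicate_series(reference_ligand, coreg, asm)
                ki_test_rc = replicate_series(lig, reference_coregulator, asm)
                ki_ref_rc = replicate_series(reference_ligand, reference_coregulator, asm)
                if len(ki_test) < 2:
                    raise ValueError(
                        f"need >= 2 replicates for ({lig}, {coreg}, {asm}); got {len(ki_test)}"
                    )
                frames = [ki_test, ki_ref, ki_test_rc, ki_ref_rc]
                idx = ki_test.index
                if not all(f.index.equals(idx) for f in frames):
                    warnings.warn(
                        f"unpaired replicate indices for ({lig}, {coreg}, {asm}); "
                        "matching sorted Ki values in order",
                        stacklevel=2,
                    )
                    n = min(len(f) for f in frames)
                    frames = [pd.Series(np.sort(f.values)[:n]) for f in frames]
                ki_test, ki_ref, ki_test_rc, ki_ref_rc = (f.to_numpy() for f in frames)
                sigma = np.log10(ki_ref / ki_test)
                sigma_rc = np.log10(ki_ref_rc / ki_test_rc)
                bias = sigma - sigma_rc
                lo, hi = _t_ci(bias)
                results.append(
                    BiasResult(
                        lig, coreg, asm, sigma, bias,
                        float(np.mean(bias)), (lo, hi),
                        significant=(lo > 0 or hi < 0),
                    )
                )
    return results


def bias_results_frame(results: list[BiasResult]) -> pd.DataFrame:
    """Long per-replicate table (ligand, coregulator, assembly, replicate, bias)."""
    rows = []
    for r in results:
        for i, b in enumerate(r.bias_per_replicate):
            rows.append((r.ligand, r.coregulator, r.assembly, i, float(b)))
    return pd.DataFrame(rows, columns=["ligand", "coregulator", "assembly", "replicate", "bias"])


def compare_bias_groups(results: list[BiasResult]) -> dict:
    """Two-way (ligand x coregulator) ANOVA with Tukey HSD pairwise comparisons.

    Returns ``{"anova": DataFrame, "tukey": DataFrame}``.  Unbalanced designs
    are analysed with Type-II sums of squares and a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = bias_results_frame(results)
    if df.groupby(["ligand", "coregulator"]).ngroups < 2:
        raise ValueError("need at least 2 (ligand, coregulator) groups to compare")

    counts = df.groupby(["ligand", "coregulator"]).size()
    if counts.nunique() > 1:
        warnings.warn("unbalanced design; using Type-II sums of squares", stacklevel=2)

    n_lig = df["ligand"].nunique()
    n_coreg = df["coregulator"].nunique()
    formula = "bias ~ C(ligand) * C(coregulator)" if n_lig > 1 and n_coreg > 1 else (
        "bias ~ C(ligand)" if n_lig > 1 else "bias ~ C(coregulator)"
    )
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    group = df["ligand"] + ":" + df["coregulator"]
    tukey = pairwise_tukeyhsd(df["bias"].to_numpy(), group.to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    return {"anova": anova, "tukey": tukey_df}


def predict_cellular_occupancy(
    measurements,
    concentration_grid: dict[str, tuple[float, ...]],
    receptor_total: float = 50.0,
    exact: bool = False,
) -> pd.DataFrame:
    """Predicted receptor occupancy per ligand over a coregulator concentration grid.

    For each ligand, coregulator Ki values are summarised by their geometric
    mean across replicates; every combination on the grid (cartesian product
    of the per-coregulator concentration lists, in nM) is solved with
    :func:`pparbias.equilibria.multi_competitor_occupancy` at the cellular
    receptor concentration (default 50 nM).
    """
    from itertools import product

    df = _measurements_frame(measurements)
    names = sorted(concentration_grid)
    rows = []
    for (lig, asm), sub in df.groupby(["ligand", "assembly"]):
        kis = {}
        for name in names:
            vals = sub.loc[sub["coregulator"] == name, "ki"]
            if vals.empty:
                raise ValueError(f"no Ki for coregulator {name!r} under ligand {lig!r} ({asm})")
            kis[name] = float(np.exp(np.mean(np.log(vals))))
        for combo in product(*(concentration_grid[n] for n in names)):
            pool = CoregulatorPool(tuple(names), tuple(float(c) for c in combo),
                                   tuple(kis[n] for n in names))
            prof = multi_competitor_occupancy(pool, receptor_total, exact=exact)
            row = {"ligand": lig, "assembly": asm}
            row.update({f"conc_{n}": c for n, c in zip(names, combo)})
            row.update({f"occ_{n}": o for n, o in zip(prof.names, prof.fraction_bound_per_species)})
            row["unoccupied"] = prof.fraction_unoccupied
            rows.append(row)
    return pd.DataFrame(rows)
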