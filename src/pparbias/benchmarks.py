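"""Reproducible validation experiments for the pipeline's statistical claims.

Each function runs the relevant stage of the package end to end on freshly
simulated inputs and returns measured quantities (errors, rates, powers)
together with the problem size used.  The experiments mirror the assay and
study designs (800 nM receptor / 50 nM tracer plates with the 24-point
series; ~15,000-gene DE tables over 98 pathways plus the reference), scaled
to run on a single CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibria import (
    BindingSystem,
    CoregulatorPool,
    competitive_equilibrium,
    free_receptor_cubic,
    free_receptor_fixed_point,
    fraction_tracer_bound,
    multi_competitor_occupancy,
    single_site_occupancy,
)
from .fitting import TitrationCurve, fit_4pl, ki_from_ec50
from .ligand_bias import aggregate_bias
from .motifs import MotifMatrix, DR1_CONSENSUS, scan_upstream, score_window
from .pathway_bias import expected_false_positive_pathways, pathway_bias
from .simulate import DESimSpec, PlateSimSpec, build_pathway_db, simulate_de_tables, \
    simulate_plate, simulate_promoters

ASSAY = BindingSystem(800.0, 50.0, 200.0)
MOTIF_CUTOFF = 7.350619126


def equilibrium_solver_agreement(n_systems: int = 1000, seed: int = 0) -> dict:
    """Max relative disagreement between the closed-form and fixed-point solvers.

    Random systems with totals and constants log-uniform on [1, 1e5] nM; both
    the tracer and competitor bound fractions are compared.
    """
    rng = np.random.default_rng(seed)
    vals = 10 ** rng.uniform(0, 5, size=(n_systems, 5))
    worst = 0.0
    for p, l, kd, i, ki in vals:
        r_closed = free_receptor_cubic(p, l, kd, i, ki)
        r_fp = free_receptor_fixed_point(p, l, kd, i, ki)
        for k in (kd, ki):
            a, b = r_closed / (k + r_closed), r_fp / (k + r_fp)
            worst = max(worst, abs(a - b) / b)
    return {"max_rel_error": worst, "n": n_systems}


def ki_roundtrip(n_plates: int = 200, true_ki: float = 5000.0, seed: int = 0) -> dict:
    """Simulate -> 4PL fit -> Ki conversion, at zero and assay-realistic noise.

    Returns the zero-noise recovery error and the systematic bias of the mean
    recovered Ki over ``n_plates`` noisy plates (both as percentages).
    """
    clean = simulate_plate(PlateSimSpec(true_ki=true_ki, noise_sd=0.0, seed=seed))
    ki0 = ki_from_ec50(fit_4pl(clean, rout_q=0.0), ASSAY)
    zero_noise_err = abs(ki0 - true_ki) / true_ki * 100.0

    kis = []
    for s in range(n_plates):
        curve = simulate_plate(PlateSimSpec(true_ki=true_ki, seed=seed + 1 + s))
        kis.append(ki_from_ec50(fit_4pl(curve), ASSAY))
    bias_pct = (float(np.mean(kis)) - true_ki) / true_ki * 100.0
    return {"zero_noise_error_pct": zero_noise_err, "noisy_mean_bias_pct": bias_pct,
            "n": n_plates}


def rout_performance(n_sims: int = 500, noise_sd: float = 0.004, seed: int = 0) -> dict:
    """Detection and false-flag rates of ROUT at Q = 1% with 10-sigma displacements."""
    rng = np.random.default_rng(seed)
    n_hit = n_disp = n_false = n_clean = 0
    for s in range(n_sims):
        curve = simulate_plate(PlateSimSpec(noise_sd=noise_sd, technical_replicates=2,
                                            dilution_replicates=1, seed=seed + 10_000 + s))
        displaced = rng.random(curve.n_obs) < 0.05
        y = curve.responses.copy()
        y[displaced] += rng.choice([-1.0, 1.0], displaced.sum()) * 10 * noise_sd
        fit = fit_4pl(TitrationCurve(curve.concentrations, y), rout_q=0.01)
        n_hit += int((fit.outlier_mask & displaced).sum())
        n_disp += int(displaced.sum())
        n_false += int((fit.outlier_mask & ~displaced).sum())
        n_clean += int((~displaced).sum())
    return {"detection_pct": 100.0 * n_hit / n_disp,
            "false_flag_pct": 100.0 * n_false / n_clean, "n": n_sims}


def ec50_ci_coverage(n_sims: int = 500, true_ki: float = 5000.0, seed: int = 0) -> dict:
    """Fraction of fits whose 95% EC50 interval covers the true midpoint."""
    f0 = fraction_tracer_bound(ASSAY)
    true_ic50 = brentq(
        lambda i: competitive_equilibrium(ASSAY.with_competitor(i, true_ki))[0] - f0 / 2,
        1.0, 1e9, rtol=8.9e-16,
    )
    covered = 0
    for s in range(n_sims):
        curve = simulate_plate(PlateSimSpec(true_ki=true_ki, seed=seed + 50_000 + s,
                                            technical_replicates=2, dilution_replicates=1))
        lo, hi = fit_4pl(curve, rout_q=0.01).ec50_ci
        covered += int(lo <= true_ic50 <= hi)
    return {"coverage_pct": 100.0 * covered / n_sims, "n": n_sims}


def bias_flag_power(n_sims: int = 1000, planted_bias: float = 0.3,
                    log_ki_noise_sd: float = 0.05, n_replicates: int = 8,
                    seed: int = 0) -> dict:
    """Power to flag a planted coregulator bias at the assay's n = 8 design."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        rows = []
        for lig in ("rosiglitazone", "GW1929"):
            for coreg in ("CBP_1-127", "PGC1a_100-220"):
                for rep in range(1, n_replicates + 1):
                    log_ki = 3.7
                    if lig == "GW1929" and coreg == "PGC1a_100-220":
                        log_ki -= planted_bias
                    rows.append((lig, coreg, "LBD", rep,
                                 10 ** (log_ki + rng.normal(0, log_ki_noise_sd))))
        df = pd.DataFrame(rows, columns=["ligand", "coregulator", "assembly",
                                         "replicate", "ki"])
        res = aggregate_bias(df)
        hit = next(r for r in res
                   if r.ligand == "GW1929" and r.coregulator == "PGC1a_100-220")
        hits += int(hit.significant)
    return {"power_pct": 100.0 * hits / n_sims, "n": n_sims}


def occupancy_contract(receptor_total: float = 50.0) -> dict:
    """Trace closed form vs exact solver at cellular concentrations.

    Coregulators at 150-1500 nM with low-micromolar Ki values; also reports
    the closure error of the occupancy profile and the single-site occupancy
    at a ligand concentration 30x its dissociation constant.
    """
    import warnings

    pool = CoregulatorPool(("CBP_1-127", "PGC1a_100-220", "MED1_557-870"),
                           (150.0, 600.0, 1500.0), (2000.0, 8000.0, 20000.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        approx = multi_competitor_occupancy(pool, receptor_total)
    exact = multi_competitor_occupancy(pool, receptor_total, exact=True)
    a = np.array(approx.fraction_bound_per_species + (approx.fraction_unoccupied,))
    b = np.array(exact.fraction_bound_per_species + (exact.fraction_unoccupied,))
    return {
        "sum_closure_error": abs(float(a.sum()) - 1.0),
        "trace_vs_exact_max_abs_err": float(np.max(np.abs(a - b))),
        "single_site_occupancy_pct_at_30x_kd": 100.0 * single_site_occupancy(30.0, 1.0),
        "n": len(pool.names),
    }


def pathway_null_calibration(n_runs: int = 500, seed: int = 0) -> dict:
    """Biased-pathway calls per direction with no planted bias, 98 pathways."""
    db = build_pathway_db(seed=seed)
    n_ref = n_test = 0
    ref_self_biased = 0
    for s in range(n_runs):
        de, _ = simulate_de_tables(DESimSpec(pathway_db=db, seed=seed + s))
        res = pathway_bias(de, db, "AMPK", "GW1929", "rosiglitazone", "24h")
        n_ref += sum(r.call == "biased-toward-reference" for r in res
                     if r.pathway_id != "AMPK")
        n_test += sum(r.call == "biased-toward-test" for r in res
                      if r.pathway_id != "AMPK")
        ref_self_biased += int(next(r for r in res if r.pathway_id == "AMPK").call
                               != "unbiased")
    return {
        "mean_flagged_toward_reference": n_ref / n_runs,
        "mean_flagged_toward_test": n_test / n_runs,
        "expected_per_direction": expected_false_positive_pathways(98, 0.05),
        "reference_self_biased_runs": ref_self_biased,
        "n": n_runs,
    }


def planted_pathway_power(n_runs: int = 500, planted_sigma: float = 0.3,
                          seed: int = 0) -> dict:
    """Power to call a ~30-gene pathway biased at a planted sigma offset.

    Shared-effect condition: both ligands act on the same genes with log2FC
    noise 0.25; the reference ligand's effects on the target pathway are
    scaled by 10**sigma.  The reference pathway must never be called biased
    against itself.
    """
    db = build_pathway_db(seed=seed)
    target = next(pid for pid in db if pid != "AMPK" and 28 <= len(db[pid]) <= 35)
    hits = 0
    ref_self_biased = 0
    for s in range(n_runs):
        de, _ = simulate_de_tables(DESimSpec(
            pathway_db=db, seed=seed + 20_000 + s, ligand_specific_fraction=0.0,
            planted_pathway_bias=((target, planted_sigma),)))
        res = pathway_bias(de, db, "AMPK", "GW1929", "rosiglitazone", "24h")
        hits += int(next(r for r in res if r.pathway_id == target).call
                    == "biased-toward-reference")
        ref_self_biased += int(next(r for r in res if r.pathway_id == "AMPK").call
                               != "unbiased")
    return {"power_pct": 100.0 * hits / n_runs,
            "reference_self_biased_runs": ref_self_biased,
            "n": n_runs}


def motif_scan_agreement(n_sequences: int = 60, length: int = 400,
                         seed: int = 0) -> dict:
    """Scan vs exhaustive both-strand enumeration at the printed cutoff,
    plus planted-consensus recovery at plant rate 1."""
    matrix = MotifMatrix.from_consensus(DR1_CONSENSUS)
    comp = str.maketrans("ACGT", "TGCA")
    seqs, _ = simulate_promoters(n_sequences, length, matrix, plant_rate=0.5, seed=seed)
    hits, _ = scan_upstream(seqs, matrix, MOTIF_CUTOFF)
    got = sorted((r.sequence_id, r.start, r.strand, round(r.score, 9))
                 for r in hits.itertuples())
    expected = []
    for sid, seq in seqs.items():
        for i in range(len(seq) - matrix.width + 1):
            w = seq[i:i + matrix.width]
            for strand, ww in (("+", w), ("-", w.translate(comp)[::-1])):
                s = score_window(ww, matrix)
                if s >= MOTIF_CUTOFF:
                    expected.append((sid, i, strand, round(s, 9)))
    agreement = got == sorted(expected)

    planted_seqs, truth = simulate_promoters(n_sequences, length, matrix,
                                             plant_rate=1.0, seed=seed + 1)
    planted_hits, _ = scan_upstream(planted_seqs, matrix, MOTIF_CUTOFF)
    keys = set(map(tuple, planted_hits[["sequence_id", "start", "strand"]].to_numpy()))
    recovered = sum((row.sequence_id, row.offset, row.strand) in keys
                    for row in truth.itertuples())
    return {
        "brute_force_agreement": bool(agreement),
        "n_hits_compared": len(expected),
        "planted_recovery_pct": 100.0 * recovered / n_sequences,
        "n": n_sequences,
    }
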