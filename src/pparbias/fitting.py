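"""Competition-curve fitting and EC50 -> Ki conversion.

Responses are equilibrium anisotropy values (the assay incubates to
equilibrium before reading, so no kinetic correction is applied).  Curves are
fit with the variable-slope four-parameter logistic

    y = bottom + (top - bottom) / (1 + 10^((logEC50 - logC) * hill))

after robust outlier removal (ROUT): a robust fit with Lorentzian (Cauchy)
loss yields studentised residuals whose two-sided t p-values are screened by
Benjamini-Hochberg at false-discovery rate Q; flagged observations are
excluded and the final fit is ordinary least squares on the remainder.

The fitted EC50 is converted to a competitive dissociation constant with the
exact competition-assay correction of Huang / Nikolovska-Coleska, expressed in
terms of F0 (fraction of tracer bound at zero competitor) and L0 (total tracer
concentration); see :func:`ki_from_ec50`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit, least_squares

from .equilibria import BindingSystem, fraction_tracer_bound

__all__ = ["TitrationCurve", "FitResult", "four_param_logistic", "fit_4pl", "ki_from_ec50"]

_N_PARAMS = 4


@dataclass
class TitrationCurve:
    """One competitor dilution series in tidy (per-observation) form.

    ``concentrations`` are competitor totals in nM, one per observation, with
    parallel ``responses`` (anisotropy) and replicate labels.  ``metadata``
    carries ligand / coregulator / assembly identifiers; ``ground_truth`` is
    populated by the simulator.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    technical_rep: np.ndarray | None = None
    dilution_rep: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have the same shape")
        if np.any(self.concentrations <= 0):
            raise ValueError("competitor concentrations must be strictly positive")
        for name in ("technical_rep", "dilution_rep"):
            rep = getattr(self, name)
            if rep is not None:
                rep = np.asarray(rep)
                if rep.shape != self.concentrations.shape:
                    raise ValueError(f"{name} must match the observation shape")
                setattr(self, name, rep)

    @property
    def n_obs(self) -> int:
        return self.concentrations.size

    def split_by_dilution_replicate(self) -> dict[Any, "TitrationCurve"]:
        """One curve per dilution replicate (the paper's unit of replication)."""
        if self.dilution_rep is None:
            raise ValueError("curve has no dilution replicate labels")
        out = {}
        for rep in np.unique(self.dilution_rep):
            m = self.dilution_rep == rep
            out[rep] = TitrationCurve(
                self.concentrations[m],
                self.responses[m],
                None if self.technical_rep is None else self.technical_rep[m],
                self.dilution_rep[m],
                dict(self.metadata),
                dict(self.ground_truth),
            )
        return out


@dataclass
class FitResult:
    """Four-parameter logistic fit of one competition curve."""

    bottom: float
    top: float
    log_ec50: float
    hill_slope: float
    standard_errors: dict[str, float]
    ec50_ci: tuple[float, float]
    outlier_mask: np.ndarray
    converged: bool
    n_used: int = 0
    rms: float = float("nan")

    @property
    def ec50(self) -> float:
        """EC50 in nM."""
        return 10.0 ** self.log_ec50


def four_param_logistic(log_c, bottom, top, log_ec50, hill):
    """Variable-slope 4PL in log10 concentration."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - log_c) * hill))


def _initial_guess(log_c: np.ndarray, y: np.ndarray) -> np.ndarray:
    bottom, top = float(np.min(y)), float(np.max(y))
    half = 0.5 * (bottom + top)
    # half-response crossing on the concentration axis
    order = np.argsort(log_c)
    yo = y[order]
    below = np.nonzero(yo <= half)[0]
    log_ec50 = float(log_c[order][below[0]]) if below.size else float(np.median(log_c))
    return np.array([bottom, top, log_ec50, -1.0])


def _ls_fit(log_c, y, p0, maxfev=20000):
    popt, pcov = curve_fit(four_param_logistic, log_c, y, p0=p0, maxfev=maxfev)
    return popt, pcov


def _robust_residual_scale(residuals: np.ndarray, n_params: int) -> float:
    """Robust SD of residuals: 68.27th percentile of |r| with a dof correction."""
    n = residuals.size
    p68 = np.percentile(np.abs(residuals), 68.27)
    return float(p68 * np.sqrt(n / max(n - n_params, 1)))


def rout_outliers(log_c: np.ndarray, y: np.ndarray, q: float, p0: np.ndarray) -> np.ndarray:
    """Boolean outlier mask by robust regression + FDR residual screen.

    Robust 4PL fit with Cauchy loss (scale re-estimated twice), then each
    observation's studentised residual gets a two-sided t p-value which is
    screened by Benjamini-Hochberg at rate ``q``.  ``q = 0`` disables removal.
    """
    n = y.size
    if q <= 0:
        return np.zeros(n, dtype=bool)

    def resid(params):
        return four_param_logistic(log_c, *params) - y

    params = p0
    scale = max(_robust_residual_scale(resid(params), _N_PARAMS), 1e-12)
    for _ in range(3):
        sol = least_squares(resid, params, loss="cauchy", f_scale=scale, max_nfev=5000)
        params = sol.x
        scale = max(_robust_residual_scale(resid(params), _N_PARAMS), 1e-12)

    t_stat = resid(params) / scale
    pvals = 2.0 * stats.t.sf(np.abs(t_stat), df=max(n - _N_PARAMS, 1))
    order = np.argsort(pvals)
    thresholds = q * (np.arange(1, n + 1)) / n
    passed = pvals[order] <= thresholds
    mask = np.zeros(n, dtype=bool)
    if passed.any():
        k = int(np.max(np.nonzero(passed)[0])) + 1
        mask[order[:k]] = True
    if mask.all():
        raise ValueError("ROUT flagged every observation as an outlier")
    return mask


def fit_4pl(curve: TitrationCurve, rout_q: float = 0.01, n_restarts: int = 5) -> FitResult:
    """Fit a competition curve, excluding ROUT-flagged observations.

    Returns a :class:`FitResult` with asymptotic standard errors and a
    t-based 95% confidence interval on EC50 (computed on the log scale).  A
    fit that fails to converge after jittered restarts is returned with
    ``converged=False`` rather than raising.
    """
    if np.unique(curve.concentrations).size < 6:
        raise ValueError("need at least 6 distinct concentrations to fit a 4PL")
    if not np.all(np.isfinite(curve.responses)):
        raise ValueError("responses must be finite")

    log_c = np.log10(curve.concentrations)
    y = curve.responses
    p0 = _initial_guess(log_c, y)

    rng = np.random.default_rng(0)
    mask = np.zeros(y.size, dtype=bool)
    popt = pcov = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else p0 * (1 + 0.1 * rng.standard_normal(4))
        try:
            mask = rout_outliers(log_c, y, rout_q, start)
            popt, pcov = _ls_fit(log_c[~mask], y[~mask], start)
            break
        except (RuntimeError, ValueError):
            if attempt == n_restarts:
                nan = float("nan")
                return FitResult(
                    nan, nan, nan, nan,
                    {k: nan for k in ("bottom", "top", "log_ec50", "hill_slope")},
                    (nan, nan), np.zeros(y.size, dtype=bool), converged=False,
                )

    bottom, top, log_ec50, hill = (float(v) for v in popt)
    if top < bottom:  # orientation normalisation: equivalent curve with top > bottom
        bottom, top, hill = top, bottom, -hill
        popt = np.array([bottom, top, log_ec50, hill])

    se = np.sqrt(np.diag(pcov))
    names = ("bottom", "top", "log_ec50", "hill_slope")
    dof = max(int((~mask).sum()) - _N_PARAMS, 1)
    tcrit = stats.t.ppf(0.975, dof)
    ci = (10.0 ** (log_ec50 - tcrit * se[2]), 10.0 ** (log_ec50 + tcrit * se[2]))
    resid = four_param_logistic(log_c[~mask], *popt) - y[~mask]
    return FitResult(
        bottom, top, log_ec50, hill,
        dict(zip(names, (float(s) for s in se))),
        ci, mask, converged=True,
        n_used=int((~mask).sum()), rms=float(np.sqrt(np.mean(resid**2))),
    )


def ki_from_ec50(
    fit: FitResult | float,
    assay: BindingSystem,
    convention: str = "nikolovska",
) -> float:
    """Competitive Ki (nM) from a fitted EC50 and the assay constants.

    Default ``convention="nikolovska"`` is the exact competition correction
    (Nikolovska-Coleska et al., in the Huang family), written in terms of F0
    and L0.  With F0 the fraction of tracer bound at zero competitor and L0
    the total tracer concentration:

        PL50 = F0 L0 / 2                (tracer-receptor complex at midpoint)
        L50  = L0 - PL50                (free tracer at midpoint)
        P0   = Kd F0 / (1 - F0)         (free receptor at zero competitor)
        P50  = Kd F0 / (2 - F0)         (free receptor at midpoint)
        I50  = EC50 - (PT - P50 - PL50) (free competitor at midpoint)
        Ki   = I50 / (L50/Kd + P0/Kd + 1)

    ``convention="cheng_prusoff"`` applies the classical dilute-limit formula
    ``Ki = EC50 / (1 + L_free/Kd)`` instead.
    """
    if isinstance(fit, FitResult):
        if not fit.converged:
            raise ValueError("cannot convert EC50 from a non-converged fit")
        ec50 = fit.ec50
    else:
        ec50 = float(fit)
    if ec50 <= 0:
        raise ValueError("EC50 must be positive")

    base = BindingSystem(assay.receptor_total, assay.tracer_total, assay.tracer_kd)
    f0 = fraction_tracer_bound(base)
    l0, kd, pt = assay.tracer_total, assay.tracer_kd, assay.receptor_total

    if convention == "cheng_prusoff":
        l_free = l0 * (1.0 - f0)
        return ec50 / (1.0 + l_free / kd)
    if convention != "nikolovska":
        raise ValueError(f"unknown Ki conversion convention {convention!r}")

    pl50 = f0 * l0 / 2.0
    l50 = l0 - pl50
    p0_free = kd * f0 / (1.0 - f0)
    p50_free = kd * f0 / (2.0 - f0)
    i50 = ec50 - (pt - p50_free - pl50)
    if i50 <= 0:
        raise ValueError(
            f"EC50 = {ec50:.4g} nM is below the competitor bound to receptor at "
            "the midpoint; no positive Ki is consistent with these assay constants"
        )
    ki = i50 / (l50 / kd + p0_free / kd + 1.0)
    if ki <= 0:
        raise ValueError("derived Ki is non-positive")
    return float(ki)
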