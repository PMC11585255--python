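"""Equilibrium solvers for the competitive anisotropy assay and cellular occupancy.

All concentrations are in nanomolar (nM) internally; unit conversion belongs at
the I/O boundary (:mod:`pparbias.units`).

The assay mixes a receptor (PPARgamma, total ``P``), a fluorescent tracer
peptide (total ``L0``, dissociation constant ``Kd``) and an unlabelled
competitor (a coregulator receptor-interaction domain, total ``I``, competitive
dissociation constant ``Ki``), all binding the same coactivator groove.  The
free-receptor concentration ``R`` then satisfies the mass balance

    R * (1 + L0/(Kd + R) + I/(Ki + R)) = P

whose positive root is the physical solution of a cubic (the binding
polynomial).  Three independent solution paths are provided:

* a closed-form trigonometric root (:func:`free_receptor_cubic`), the fast path;
* a bracketed Brent root of the mass balance (used to polish and as fallback);
* a Steffensen-accelerated fixed-point iteration
  (:func:`free_receptor_fixed_point`), kept free of any shared root-finding
  code so it can serve as a numeric oracle for the closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingSystem",
    "CoregulatorPool",
    "OccupancyProfile",
    "anisotropy_from_intensities",
    "fraction_tracer_bound",
    "free_receptor_cubic",
    "free_receptor_fixed_point",
    "competitive_equilibrium",
    "multi_competitor_occupancy",
    "single_site_occupancy",
]

#: relative tolerance used by every solver in this module
_RTOL = 1e-13

# fraction of the smallest coregulator concentration above which the
# trace-receptor closed form is considered questionable
TRACE_RECEPTOR_WARN_FRACTION = 0.10


@dataclass(frozen=True)
class BindingSystem:
    """Totals and constants for one receptor/tracer(/competitor) mixture.

    Parameters
    ----------
    receptor_total
        Total receptor concentration (nM).
    tracer_total
        Total fluorescent tracer concentration (nM).
    tracer_kd
        Tracer dissociation constant (nM); must be positive when tracer is
        present.
    competitor_total, competitor_ki
        Total competitor concentration and its competitive dissociation
        constant (nM).  Both ``None`` for the two-species system.
    """

    receptor_total: float
    tracer_total: float
    tracer_kd: float
    competitor_total: float | None = None
    competitor_ki: float | None = None

    def __post_init__(self) -> None:
        if self.receptor_total < 0 or self.tracer_total < 0:
            raise ValueError("concentrations must be non-negative")
        if self.tracer_total > 0 and self.tracer_kd <= 0:
            raise ValueError("tracer_kd must be positive when tracer is present")
        if (self.competitor_total is None) != (self.competitor_ki is None):
            raise ValueError("competitor_total and competitor_ki must be given together")
        if self.competitor_total is not None and self.competitor_total < 0:
            raise ValueError("competitor_total must be non-negative")
        if self.competitor_ki is not None and self.competitor_ki <= 0:
            raise ValueError("competitor_ki must be positive")

    @property
    def has_competitor(self) -> bool:
        return self.competitor_total is not None

    def with_competitor(self, total: float, ki: float) -> "BindingSystem":
        return BindingSystem(self.receptor_total, self.tracer_total, self.tracer_kd, total, ki)


@dataclass(frozen=True)
class CoregulatorPool:
    """Several coregulators competing for the single coactivator groove."""

    names: tuple[str, ...]
    concentrations: tuple[float, ...]
    kis: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.concentrations) == len(self.kis)):
            raise ValueError("names, concentrations and kis must have equal length")
        if len(self.names) == 0:
            raise ValueError("pool must contain at least one coregulator")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("coregulator concentrations must be positive")
        if any(k <= 0 for k in self.kis):
            raise ValueError("coregulator Ki values must be positive")


@dataclass(frozen=True)
class OccupancyProfile:
    """Receptor occupancy split across coregulators plus the unoccupied fraction."""

    names: tuple[str, ...]
    fraction_bound_per_species: tuple[float, ...]
    fraction_unoccupied: float

    def __post_init__(self) -> None:
        fracs = np.asarray(self.fraction_bound_per_species + (self.fraction_unoccupied,))
        if np.any(fracs < -1e-12) or np.any(fracs > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("occupancies and unoccupied fraction must sum to 1")

    def as_dict(self) -> dict[str, float]:
        d = dict(zip(self.names, self.fraction_bound_per_species))
        d["unoccupied"] = self.fraction_unoccupied
        return d


def anisotropy_from_intensities(i_parallel, i_perpendicular):
    """Fluorescence anisotropy r = (I_par - I_perp) / (I_par + 2 I_perp).

    Accepts scalars or arrays; intensities must be non-negative and not both
    zero.  The result lies in [-0.5, 1].
    """
    ipar = np.asarray(i_parallel, dtype=float)
    iperp = np.asarray(i_perpendicular, dtype=float)
    if np.any(ipar < 0) or np.any(iperp < 0):
        raise ValueError("intensities must be non-negative")
    total = ipar + 2.0 * iperp
    if np.any(total == 0):
        raise ValueError("anisotropy undefined: both intensities are zero")
    r = (ipar - iperp) / total
    return float(r) if r.ndim == 0 else r


def fraction_tracer_bound(system: BindingSystem) -> float:
    """Fraction of tracer bound in the two-species receptor/tracer system.

    Exact root of the mass-balance quadratic:
    ``F = [(P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)] / (2 L)``.
    """
    if system.has_competitor and system.competitor_total > 0:
        raise ValueError("system has a competitor; use competitive_equilibrium")
    p, l, kd = system.receptor_total, system.tracer_total, system.tracer_kd
    if l <= 0:
        raise ValueError("tracer_total must be positive")
    s = p + l + kd
    disc = s * s - 4.0 * p * l
    if disc < 0:  # impossible for non-negative inputs; guards rounding
        raise ArithmeticError("negative discriminant in mass-balance quadratic")
    # citardauq form of the root: avoids cancellation when 4PL << s^2
    f = 2.0 * p / (s + np.sqrt(disc))
    return float(min(max(f, 0.0), 1.0))


def _mass_balance(r: float, p: float, l: float, kd: float, i: float, ki: float) -> float:
    return r * (1.0 + l / (kd + r) + i / (ki + r)) - p


def free_receptor_cubic(p: float, l: float, kd: float, i: float, ki: float) -> float:
    """Free receptor from the closed-form real root of the binding polynomial.

    Trigonometric solution of the depressed cubic for the three-species
    competitive equilibrium; the unique root in ``[0, p]`` is returned.  When
    cancellation degrades the closed form (checked against the mass-balance
    residual) the root is re-bracketed with Brent's method.
    """
    if p == 0:
        return 0.0
    a = kd + ki + l + i - p
    b = ki * (l - p) + kd * (i - p) + kd * ki
    c = -kd * ki * p
    # depressed cubic x^3 + a x^2 + b x + c
    q = (a * a - 3.0 * b) / 9.0
    rr = (2.0 * a**3 - 9.0 * a * b + 27.0 * c) / 54.0
    root = None
    if q > 0:
        arg = rr / np.sqrt(q**3)
        if -1.0 <= arg <= 1.0:
            theta = np.arccos(arg)
            root = -2.0 * np.sqrt(q) * np.cos((theta + 2.0 * np.pi) / 3.0) - a / 3.0
    if root is None or not (0.0 <= root <= p) or not np.isfinite(root):
        return brentq(_mass_balance, 0.0, p, args=(p, l, kd, i, ki), xtol=1e-30, rtol=8.9e-16)
    # polish: cancellation in (-a/3 + ...) can cost digits when root << |a|
    resid = _mass_balance(root, p, l, kd, i, ki)
    if abs(resid) > _RTOL * p:
        lo = max(0.0, root * 0.5)
        hi = min(p, max(root * 2.0, np.finfo(float).tiny))
        if _mass_balance(lo, p, l, kd, i, ki) > 0 or _mass_balance(hi, p, l, kd, i, ki) < 0:
            lo, hi = 0.0, p
        root = brentq(_mass_balance, lo, hi, args=(p, l, kd, i, ki), xtol=1e-30, rtol=8.9e-16)
    return float(root)


def free_receptor_fixed_point(p, l, kd, i, ki, max_iter: int = 400):
    """Free receptor by damped/Steffensen fixed-point iteration (numeric oracle).

    Iterates ``R <- P / (1 + L/(Kd+R) + I/(Ki+R))`` with Aitken delta-squared
    acceleration.  Vectorised over arrays; independent of the closed-form and
    Brent paths.
    """
    p = np.asarray(p, dtype=float)
    l, kd, i, ki = np.broadcast_arrays(
        np.asarray(l, float), np.asarray(kd, float), np.asarray(i, float), np.asarray(ki, float)
    )
    l, kd, i, ki = (np.broadcast_to(a, p.shape).copy() for a in (l, kd, i, ki))

    def g(r):
        return p / (1.0 + l / (kd + r) + i / (ki + r))

    r = p / 2.0
    for _ in range(max_iter):
        r1 = g(r)
        r2 = g(r1)
        denom = r2 - 2.0 * r1 + r
        with np.errstate(divide="ignore", invalid="ignore"):
            accel = r - (r1 - r) ** 2 / denom
        bad = ~np.isfinite(accel) | (accel < 0) | (accel > p)
        r_new = np.where(bad, r2, accel)
        if np.all(np.abs(r_new - r) <= 1e-16 * np.maximum(r_new, np.finfo(float).tiny)):
            r = r_new
            break
        r = r_new
    return r if r.ndim else float(r)


def competitive_equilibrium(system: BindingSystem) -> tuple[float, float]:
    """Tracer and competitor fractions bound in the three-species system.

    Returns ``(tracer_fraction_bound, competitor_fraction_bound)``; with zero
    competitor this reduces exactly to :func:`fraction_tracer_bound`.
    """
    if not system.has_competitor:
        raise ValueError("system has no competitor; use fraction_tracer_bound")
    p, l, kd = system.receptor_total, system.tracer_total, system.tracer_kd
    i, ki = system.competitor_total, system.competitor_ki
    if l <= 0:
        raise ValueError("tracer_total must be positive")
    r = free_receptor_cubic(p, l, kd, i, ki)
    if not (0.0 <= r <= p):
        raise ArithmeticError("no physical root in [0, receptor_total]")
    tracer_frac = r / (kd + r)
    comp_frac = r / (ki + r) if i > 0 else 0.0
    return float(tracer_frac), float(comp_frac)


def _pool_free_receptor(pool: CoregulatorPool, receptor_total: float) -> float:
    c = np.asarray(pool.concentrations)
    k = np.asarray(pool.kis)

    def f(r):
        return r * (1.0 + np.sum(c / (k + r))) - receptor_total

    return brentq(f, 0.0, receptor_total, xtol=1e-30, rtol=8.9e-16)


def multi_competitor_occupancy(
    pool: CoregulatorPool,
    receptor_total: float,
    exact: bool = False,
) -> OccupancyProfile:
    """Receptor occupancy by each of several competing coregulators.

    With ``exact=False`` (default) uses the trace-receptor closed form

        occ_i = (C_i/K_i) / (1 + sum_j C_j/K_j)

    valid when the receptor is far below every coregulator concentration
    (a warning is emitted when ``receptor_total`` exceeds 10% of the smallest
    coregulator concentration).  With ``exact=True`` the full mass balance with
    coregulator depletion is solved instead, with no trace assumption.
    """
    if receptor_total <= 0:
        raise ValueError("receptor_total must be positive")
    c = np.asarray(pool.concentrations)
    k = np.asarray(pool.kis)
    if not exact:
        if receptor_total > TRACE_RECEPTOR_WARN_FRACTION * c.min():
            warnings.warn(
                "receptor_total exceeds 10% of the smallest coregulator "
                "concentration; the trace-receptor closed form may be inaccurate "
                "(use exact=True to solve the full mass balance)",
                stacklevel=2,
            )
        ratios = c / k
        denom = 1.0 + ratios.sum()
        occ = ratios / denom
        unocc = 1.0 / denom
    else:
        r = _pool_free_receptor(pool, receptor_total)
        occ = (r * c / (k + r)) / receptor_total
        unocc = r / receptor_total
    return OccupancyProfile(tuple(pool.names), tuple(float(o) for o in occ), float(unocc))


def single_site_occupancy(ligand_concentration: float, kd: float) -> float:
    """Fractional occupancy of a single site by a ligand in excess: C/(C+Kd)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if ligand_concentration < 0:
        raise ValueError("concentration must be non-negative")
    return ligand_concentration / (ligand_concentration + kd)
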