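"""Hill-curve fitting, dose-response harmonization and the toxicity filter.

Viability follows the four-parameter Hill model

    E(C) = E0 + (Einf - E0) / (1 + (EC50 / C)^H),

with E0 the low-dose asymptote (fraction of untreated control), Einf the
high-dose asymptote, EC50 the half-effect concentration (uM) and H the
Hill slope. Heterogeneous screens are harmonized by fitting each
(drug, cell) series and re-evaluating the fitted curve on a common dose
grid; flat curves contribute only their extreme-dose points, and series the
model cannot fit are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .data_core import DoseResponsePoint

logger = logging.getLogger(__name__)

FLATNESS_TOLERANCE = 0.01


@dataclass
class HillParams:
    """Four-parameter Hill curve: asymptotes, half-effect dose, slope."""

    E0: float
    Einf: float
    EC50: float  # uM
    H: float

    def __post_init__(self):
        if not (math.isfinite(self.EC50) and self.EC50 > 0):
            raise ValueError(f"EC50 must be finite and positive, got {self.EC50}")
        for name in ("E0", "Einf", "H"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class DoseGrid:
    """Strictly increasing positive dose ladder (uM)."""

    doses: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        if np.any(self.doses <= 0) or np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be positive and strictly increasing")

    @classmethod
    def log_spaced(cls, lo: float, hi: float, n: int) -> "DoseGrid":
        return cls(np.logspace(np.log10(lo), np.log10(hi), n))


@dataclass
class HillFit:
    """Fit outcome: parameters, residual sum of squares, convergence flag."""

    params: HillParams | None
    rss: float
    converged: bool
    message: str = ""

    @property
    def unfittable(self) -> bool:
        return not self.converged or self.params is None


def hill_viability(p: HillParams, dose) -> np.ndarray | float:
    """Evaluate the Hill curve at dose(s) C > 0."""
    c = np.asarray(dose, dtype=float)
    if np.any(c <= 0):
        raise ValueError("dose must be positive")
    val = p.E0 + (p.Einf - p.E0) / (1.0 + (p.EC50 / c) ** p.H)
    return float(val) if np.isscalar(dose) or val.ndim == 0 else val


def _residuals(theta, log_c, viab):
    e0, einf, log_ec50, h = theta
    return e0 + (einf - e0) / (1.0 + 10.0 ** ((log_ec50 - log_c) * h)) - viab


class HillCurveModel:
    """Nonlinear least squares for one (drug, cell) viability series.

    Doses are handled on log10 scale internally; EC50 is bounded to
    [min_dose/100, max_dose*100] and H to [0.1, 10]. Initialization is
    multi-start over H in {0.5, 1, 2} with E0/Einf seeded from the observed
    extremes and EC50 from the dose nearest the half-response.
    """

    def __init__(self, doses, viabilities):
        self.doses = np.asarray(doses, dtype=float)
        self.viab = np.asarray(viabilities, dtype=float)
        if self.doses.shape != self.viab.shape:
            raise ValueError("doses and viabilities must have equal length")
        if len(self.doses) < 4 or len(np.unique(self.doses)) < 3:
            raise ValueError("need >= 4 points with >= 3 distinct doses")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")

    def fit(self) -> HillFit:
        log_c = np.log10(self.doses)
        vmax, vmin = float(self.viab.max()), float(self.viab.min())
        if vmax - vmin < 1e-12:
            return HillFit(None, rss=0.0, converged=False,
                           message="flat series: EC50 unidentifiable")
        lo_ec, hi_ec = np.log10(self.doses.min() / 100), np.log10(self.doses.max() * 100)
        # dose nearest the half-response seeds EC50
        half = (vmax + vmin) / 2.0
        ec0 = log_c[int(np.argmin(np.abs(self.viab - half)))]
        bounds = ([-1.0, -1.0, lo_ec, 0.1], [3.0, 3.0, hi_ec, 10.0])
        best = None
        for h0 in (0.5, 1.0, 2.0):
            theta0 = np.clip([vmax, vmin, ec0, h0],
                             np.array(bounds[0]) + 1e-9, np.array(bounds[1]) - 1e-9)
            try:
                sol = least_squares(_residuals, theta0, args=(log_c, self.viab),
                                    bounds=bounds, xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception as exc:  # pragma: no cover - scipy failure path
                logger.warning("Hill fit failed: %s", exc)
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol)
        if best is None:
            return HillFit(None, rss=float("inf"), converged=False,
                           message="optimizer failure")
        rss, sol = best
        e0, einf, log_ec50, h = sol.x
        at_bound = log_ec50 <= lo_ec + 1e-6 or log_ec50 >= hi_ec - 1e-6
        if not sol.success or at_bound:
            return HillFit(None, rss=rss, converged=False,
                           message="EC50 at bound" if at_bound else sol.message)
        return HillFit(HillParams(E0=float(e0), Einf=float(einf),
                                  EC50=float(10.0**log_ec50), H=float(h)),
                       rss=rss, converged=True)


def fit_hill(points) -> HillFit:
    """Fit the Hill model to (dose, viability) pairs."""
    doses, viab = zip(*points)
    return HillCurveModel(doses, viab).fit()


def harmonize(records: list[DoseResponsePoint], grid: DoseGrid,
              flat_tol: float = FLATNESS_TOLERANCE) -> list[DoseResponsePoint]:
    """Refit each (drug, cell) series and re-evaluate it on a common grid.

    Unfittable series are dropped (logged); flat fitted curves (viability
    range over the grid < ``flat_tol``) contribute only the minimum- and
    maximum-dose points.
    """
    groups: dict[tuple, list[DoseResponsePoint]] = {}
    for p in records:
        groups.setdefault((p.drug_id, p.cell_id), []).append(p)
    out: list[DoseResponsePoint] = []
    for (drug, cell), pts in groups.items():
        try:
            fit = fit_hill([(p.dose, p.viability) for p in pts])
        except ValueError as exc:
            logger.info("dropping %s/%s: %s", drug, cell, exc)
            continue
        if fit.unfittable:
            logger.info("dropping %s/%s: %s", drug, cell, fit.message)
            continue
        vals = hill_viability(fit.params, grid.doses)
        if float(vals.max() - vals.min()) < flat_tol:
            out.append(DoseResponsePoint(drug, cell, float(grid.doses[0]),
                                         float(vals[0])))
            out.append(DoseResponsePoint(drug, cell, float(grid.doses[-1]),
                                         float(vals[-1])))
        else:
            out.extend(DoseResponsePoint(drug, cell, float(d), float(v))
                       for d, v in zip(grid.doses, vals))
    return out


def is_safe(curve, dose: float = 1.0, threshold: float = 0.9) -> bool:
    """Toxicity filter: viability strictly above ``threshold`` at ``dose``.

    ``curve`` is a HillParams or a callable dose -> viability.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    v = hill_viability(curve, dose) if isinstance(curve, HillParams) else curve(dose)
    return bool(v > threshold)
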