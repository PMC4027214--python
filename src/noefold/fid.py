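"""Fluorescent-intercalator-displacement binding analysis.

The 2:1 drug:duplex binding is treated with the equal-site approximation
(K_D1 = K_D2), under which the bound fraction follows

    f = [X2T]/[T0] = B [X] / (K_D + [X])

with [X] the *free* drug concentration.  Free drug is recovered from the
dispensed totals by the 2-per-duplex mass balance

    [X] = X_total - 2 [T0] B [X] / (K_D + [X]),

solved by damped fixed-point iteration (the closed-form quadratic root is
used as an independent oracle in the tests).  K_D and B are fitted by
least squares with the free concentration recomputed each iteration, and
uncertainty comes from seeded case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares


class FidError(ValueError):
    pass


@dataclass
class TitrationTable:
    """Rows of (drug_total M, replicate id, bound fraction)."""

    rows: list[tuple[float, int, float]]
    duplex_total: float = 16.7e-6

    def __post_init__(self) -> None:
        if any(x < 0 for x, _r, _f in self.rows):
            raise FidError("negative drug totals")

    @property
    def drug_totals(self) -> np.ndarray:
        return np.array([x for x, _r, _f in self.rows])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _x, _r, f in self.rows])

    def n_concentrations(self) -> int:
        return len(set(self.drug_totals.tolist()))


def correct_fluorescence(raw: np.ndarray, f0: float, blank: float,
                         clip_max: float = 1.05) -> np.ndarray:
    """Convert raw fluorescence readings to bound fractions.

    ``f0`` is the no-drug (fully loaded EtBr-DNA) intensity and ``blank``
    the summed baselines (free EtBr plus drug-DNA background).  The bound
    fraction is 1 - (F - blank)/(F0 - blank), clipped to [0, clip_max].
    """
    if f0 <= blank:
        raise FidError("reference intensity must exceed the blank")
    frac = 1.0 - (np.asarray(raw, float) - blank) / (f0 - blank)
    return np.clip(frac, 0.0, clip_max)


def free_ligand(drug_total: float, duplex_total: float, kd: float,
                b: float = 1.0, rtol: float = 1e-12) -> float:
    """Free drug concentration from totals under the 2:1 mass balance.

    Unique non-negative fixed point of x = X_t - 2 T0 B x/(K_D + x).
    The residual h(x) = x - X_t + 2 T0 B x/(K_D + x) is strictly
    increasing on [0, X_t] with h(0) <= 0 <= h(X_t), so the bracketed
    Brent solve below is guaranteed; the closed-form quadratic root
    serves as an independent oracle in the tests.
    """
    if min(drug_total, duplex_total, kd) < 0 or b < 0:
        raise FidError("inputs must be >= 0")
    if drug_total == 0.0 or duplex_total == 0.0 or b == 0.0:
        return float(drug_total)

    def h(x: float) -> float:
        return x - drug_total + 2.0 * duplex_total * b * x / (kd + x)

    x = float(brentq(h, 0.0, drug_total, xtol=1e-300, rtol=max(rtol, 4e-16)))
    return x


def binding_fraction(drug_total: np.ndarray, duplex_total: float,
                     kd: float, b: float) -> np.ndarray:
    """Model-predicted bound fraction at dispensed totals."""
    x = np.array([free_ligand(xt, duplex_total, kd, b)
                  for xt in np.atleast_1d(np.asarray(drug_total, float))])
    return b * x / (kd + x)


@dataclass
class BindingFit:
    """Fitted equal-site binding parameters."""

    kd: float
    b: float
    residual: float
    converged: bool
    kd_ci: tuple[float, float] | None = None
    b_ci: tuple[float, float] | None = None
    n_bootstrap: int = 0

    def as_dict(self) -> dict:
        return {
            "kd_M": self.kd, "amplitude_B": self.b,
            "residual_rms": self.residual, "converged": self.converged,
            "kd_ci95_M": list(self.kd_ci) if self.kd_ci else None,
            "amplitude_ci95": list(self.b_ci) if self.b_ci else None,
            "n_bootstrap": self.n_bootstrap,
        }


def _fit_once(x_tot: np.ndarray, frac: np.ndarray, duplex_total: float,
              kd0: float, b0: float):
    def resid(p):
        log_kd, b = p
        return binding_fraction(x_tot, duplex_total, np.exp(log_kd), b) - frac

    return least_squares(resid, [np.log(kd0), b0], method="lm", xtol=1e-14,
                         ftol=1e-14, gtol=1e-14)


def fit_kd(table: TitrationTable, kd_start: float = 1e-6, b_start: float = 1.0,
           n_bootstrap: int = 0, seed: int = 0) -> BindingFit:
    """Least-squares fit of (K_D, B) to a titration table.

    K_D is optimized on a log scale; to avoid local minima the fit is
    multi-started from {0.1, 1, 10} x ``kd_start``.  With ``n_bootstrap``
    > 0, 95% CIs come from seeded case resampling of the rows.
    """
    if table.n_concentrations() < 4:
        raise FidError("need >= 4 distinct concentrations to fit")
    x_tot, frac = table.drug_totals, table.fractions
    best = None
    for mult in (0.1, 1.0, 10.0):
        res = _fit_once(x_tot, frac, table.duplex_total, mult * kd_start, b_start)
        if best is None or res.cost < best.cost:
            best = res
    kd, b = float(np.exp(best.x[0])), float(best.x[1])
    rms = float(np.sqrt(np.mean(best.fun ** 2)))

    kd_ci = b_ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        kds, bs = [], []
        nrows = len(table.rows)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, nrows, nrows)
            r = _fit_once(x_tot[idx], frac[idx], table.duplex_total, kd, b)
            kds.append(np.exp(r.x[0]))
            bs.append(r.x[1])
        kd_ci = tuple(np.percentile(kds, [2.5, 97.5]))
        b_ci = tuple(np.percentile(bs, [2.5, 97.5]))
    return BindingFit(kd, b, rms, bool(best.success), kd_ci, b_ci, n_bootstrap)
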