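"""ATPase kinetics and ligand-saturation arithmetic.

Initial-rate titrations (phosphate released per minute versus ATP
concentration) are fit to the Michaelis–Menten equation extended with a
Hill coefficient n,

    v0 = Vmax * [S]**n / (Km**n + [S]**n)

which reduces to plain Michaelis–Menten at n = 1 and satisfies
v0(Km) = Vmax/2 for every n.  Free ligand is approximated by total
ligand (no depletion correction): in these assays [ATP] exceeds the
enzyme concentration by orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConvergenceError, UnderdeterminedError

__all__ = [
    "TitrationSeries",
    "HillFit",
    "hill_rate",
    "fit_hill_kinetics",
    "fraction_bound",
]


@dataclass
class TitrationSeries:
    """Substrate concentrations (µM) and initial rates (pmol PO4/min)."""

    concentrations: np.ndarray
    rates: np.ndarray
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations.shape != self.rates.shape or self.concentrations.ndim != 1:
            raise ValueError("concentrations and rates must be 1-D, equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)
            if self.sds.shape != self.rates.shape:
                raise ValueError("sds must match rates in length")

    @classmethod
    def from_text(cls, path) -> "TitrationSeries":
        """Read delimited text: concentration, rate[, sd]."""
        data = np.atleast_2d(np.loadtxt(path, comments="#"))
        sds = data[:, 2] if data.shape[1] >= 3 else None
        return cls(concentrations=data[:, 0], rates=data[:, 1], sds=sds)


@dataclass
class HillFit:
    """Fitted Hill kinetics: Vmax (pmol/min), Km (µM), Hill n."""

    vmax: float
    km: float
    n: float
    covariance: np.ndarray
    residual_norm: float
    n_fixed: bool = False

    def rate(self, concentration):
        return hill_rate(concentration, self.vmax, self.km, self.n)

    def report(self) -> str:
        se = np.sqrt(np.diag(self.covariance)) if self.covariance.size else []
        lines = [f"Vmax = {self.vmax:.4g} pmol/min",
                 f"Km   = {self.km:.4g} uM",
                 f"n    = {self.n:.4g}" + ("  (fixed)" if self.n_fixed else ""),
                 f"residual norm = {self.residual_norm:.4g}"]
        if len(se) == 3 and not self.n_fixed:
            lines[0] += f" +/- {se[0]:.2g}"
            lines[1] += f" +/- {se[1]:.2g}"
            lines[2] += f" +/- {se[2]:.2g}"
        return "\n".join(lines)


def hill_rate(concentration, vmax: float, km: float, n: float):
    """v0 = Vmax * S^n / (Km^n + S^n), elementwise."""
    s = np.asarray(concentration, dtype=float)
    sn = np.power(s, n, where=s > 0, out=np.zeros_like(s))
    return vmax * sn / (km**n + sn)


def fit_hill_kinetics(
    series: TitrationSeries, *, fix_n: float | None = None
) -> HillFit:
    """Least-squares Hill fit of an ATPase titration.

    Initial guesses: Vmax from the maximal rate, Km from the
    concentration nearest half-max, n = 1.  ``fix_n`` pins the Hill
    coefficient (``fix_n=1`` gives the plain Michaelis–Menten fit).
    """
    conc, rates = series.concentrations, series.rates
    n_distinct = len(np.unique(conc))
    if n_distinct < 5:
        raise UnderdeterminedError(
            f"need at least 5 distinct concentrations, got {n_distinct}"
        )
    vmax0 = float(rates.max())
    if vmax0 <= 0:
        raise ValueError("all rates are non-positive; nothing to fit")
    half_idx = int(np.argmin(np.abs(rates - vmax0 / 2)))
    km0 = float(max(conc[half_idx], conc[conc > 0].min()))
    sigma = series.sds if series.sds is not None and np.all(series.sds > 0) else None

    if fix_n is not None:
        model = lambda s, vmax, km: hill_rate(s, vmax, km, fix_n)
        p0, bounds = [vmax0, km0], ([1e-12, 1e-12], [np.inf, np.inf])
    else:
        model = hill_rate
        p0, bounds = [vmax0, km0, 1.0], ([1e-12, 1e-12, 0.05], [np.inf, np.inf, 10.0])

    try:
        popt, pcov = curve_fit(
            model, conc, rates, p0=p0, sigma=sigma, bounds=bounds,
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise ConvergenceError(f"Hill fit did not converge: {exc}") from exc
    resid = rates - model(conc, *popt)
    if fix_n is not None:
        vmax, km, n = float(popt[0]), float(popt[1]), float(fix_n)
    else:
        vmax, km, n = (float(v) for v in popt)
    return HillFit(
        vmax=vmax, km=km, n=n, covariance=pcov,
        residual_norm=float(np.linalg.norm(resid)), n_fixed=fix_n is not None,
    )


def fraction_bound(ligand: float, kd: float) -> float:
    """Single-site saturation L / (L + Kd), in [0, 1).

    Assumes free ligand ≈ total ligand (no depletion).  Monotone
    increasing in L; exactly 0.5 at L = Kd; fraction free is the exact
    complement.
    """
    if not kd > 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    if ligand < 0:
        raise ValueError(f"ligand concentration must be nonnegative, got {ligand}")
    return ligand / (ligand + kd)
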