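"""Small-angle scattering profiles from bead models, and population fits.

Theoretical profiles come from the orientationally averaged Debye sum

    I(q) = sum_i sum_j f_i f_j sin(q r_ij) / (q r_ij)

over bead pairs, with uniform unit form factors by default (one bead per
residue).  No hydration layer or excluded-volume term is modelled, so
absolute goodness-of-fit values against real beamline data are not
comparable with atomistic calculators; the machinery targets relative
model ranking and population deconvolution.

An experimental profile is compared to a theoretical one through the
scale-optimized, sigma-weighted chi-square; multi-state fitting finds
the nonnegative, unit-sum state populations w_k minimizing the
chi-square of c * sum_k w_k I_k, solved deterministically by nonnegative
least squares on sigma-whitened profiles (the global scale c absorbs the
simplex constraint exactly).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import EmptyResultError

__all__ = [
    "SaxsProfile",
    "BeadModel",
    "PopulationFit",
    "debye_profile",
    "chi2_with_scale",
    "fit_populations",
    "rank_single_states",
    "read_profile",
    "write_profile",
    "DEFAULT_Q_GRID",
]

#: Default momentum-transfer grid, Å^-1.
DEFAULT_Q_GRID = np.linspace(0.01, 0.35, 200)


@dataclass
class SaxsProfile:
    """A scattering curve: q (Å^-1), intensity, and optional sigma."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1-D and equal length")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(self.q > 0):
            raise ValueError("q must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("all sigma values must be positive")

    def interpolated_to(self, q: np.ndarray) -> "SaxsProfile":
        """Linear interpolation onto another q grid (theoretical curves)."""
        q = np.asarray(q, dtype=float)
        if q.min() < self.q.min() - 1e-12 or q.max() > self.q.max() + 1e-12:
            raise ValueError("target q grid extends beyond the profile's range")
        return SaxsProfile(q=q, intensity=np.interp(q, self.q, self.intensity),
                           label=self.label)


@dataclass
class BeadModel:
    """A coarse bead representation of one conformer."""

    positions: np.ndarray
    form_factors: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            raise EmptyResultError("bead model must contain at least one bead")
        if self.positions.shape[1] != 3 or not np.all(np.isfinite(self.positions)):
            raise ValueError("bead positions must be finite N x 3 coordinates")
        if self.form_factors is None:
            self.form_factors = np.ones(len(self.positions))
        else:
            self.form_factors = np.asarray(self.form_factors, dtype=float)
            if self.form_factors.shape != (len(self.positions),):
                raise ValueError("one form factor per bead required")
            if np.any(self.form_factors < 0):
                raise ValueError("form factors must be nonnegative")

    @classmethod
    def from_model_coordinates(cls, model, label: str = "") -> "BeadModel":
        """One unit bead per restrainable residue position."""
        positions = np.array(list(model.coords.values()))
        return cls(positions=positions, label=label or model.model_id)


def debye_profile(model: BeadModel, q_grid: np.ndarray | None = None) -> SaxsProfile:
    """Orientationally averaged scattering intensity of a bead model.

    Vectorized over the upper triangle of the pair-distance matrix; the
    i = j (r = 0) terms contribute f_i^2 exactly (sinc -> 1).  At the
    forward-scattering limit I(q -> 0) -> (sum f)^2.
    """
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or len(q) == 0 or np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be positive and strictly increasing")
    pos, f = model.positions, model.form_factors
    iu, ju = np.triu_indices(len(pos), k=1)
    intensity = np.full(len(q), float(np.sum(f**2)))
    if len(iu):
        r = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        ff = f[iu] * f[ju]
        # np.sinc(x) = sin(pi x)/(pi x); handles r == 0 pairs exactly
        intensity = intensity + 2.0 * (ff[None, :] * np.sinc(q[:, None] * r[None, :] / np.pi)).sum(axis=1)
    return SaxsProfile(q=q, intensity=intensity, label=model.label)


def _aligned_theoretical(
    experimental: SaxsProfile, theoretical: SaxsProfile, interpolate: bool
) -> np.ndarray:
    if theoretical.q.shape == experimental.q.shape and np.allclose(
        theoretical.q, experimental.q, rtol=0, atol=1e-12
    ):
        return theoretical.intensity
    if not interpolate:
        raise ValueError(
            "q grids differ; pass interpolate=True to interpolate the "
            "theoretical profile onto the experimental grid"
        )
    return theoretical.interpolated_to(experimental.q).intensity


def chi2_with_scale(
    experimental: SaxsProfile,
    theoretical: SaxsProfile,
    *,
    interpolate: bool = False,
    ddof: int = 0,
) -> tuple[float, float]:
    """Best global scale c and the resulting chi-square.

    c minimizes sum(((I_exp - c*I_th)/sigma)^2) in closed form; the
    chi-square is normalized by M (``ddof=0``, default) or M-1
    (``ddof=1``) data points.
    """
    if experimental.sigma is None:
        raise ValueError("experimental profile must carry sigma values")
    i_th = _aligned_theoretical(experimental, theoretical, interpolate)
    w = 1.0 / experimental.sigma**2
    denom = float(np.sum(w * i_th**2))
    if denom == 0:
        raise ValueError("theoretical profile is identically zero")
    c = float(np.sum(w * experimental.intensity * i_th) / denom)
    resid = (experimental.intensity - c * i_th) / experimental.sigma
    m = len(resid) - ddof
    if m <= 0:
        raise ValueError("not enough points for the requested normalization")
    return c, float(np.sum(resid**2) / m)


@dataclass
class PopulationFit:
    """Fitted state populations for a multi-state ensemble."""

    labels: list[str]
    weights: np.ndarray
    scale: float
    chi2: float
    n_states: int
    non_identifiable: bool = False

    def as_dict(self) -> dict[str, float]:
        return {lab: float(w) for lab, w in zip(self.labels, self.weights)}


def _nnls_population_fit(
    experimental: SaxsProfile,
    profiles: Sequence[SaxsProfile],
    interpolate: bool,
    ddof: int,
) -> tuple[np.ndarray, float, float]:
    design = np.column_stack([
        _aligned_theoretical(experimental, p, interpolate) / experimental.sigma
        for p in profiles
    ])
    target = experimental.intensity / experimental.sigma
    coef, _ = nnls(design, target)
    total = float(coef.sum())
    if total <= 0:
        raise EmptyResultError("population fit collapsed to zero amplitude")
    resid = target - design @ coef
    m = len(target) - ddof
    chi2 = float(np.sum(resid**2) / m)
    return coef / total, total, chi2


def fit_populations(
    experimental: SaxsProfile,
    theoretical: Sequence[SaxsProfile],
    n_states: int,
    *,
    interpolate: bool = False,
    ddof: int = 0,
) -> PopulationFit:
    """Fit nonnegative unit-sum state populations to an experimental curve.

    Minimizes the chi-square of c * sum_k w_k I_k over the scale c >= 0
    and simplex-constrained weights w.  Because c is free, the simplex
    constraint costs nothing: unconstrained nonnegative coefficients
    beta_k are fit by NNLS and split as c = sum(beta), w = beta / c.
    When ``n_states`` is smaller than the number of candidate profiles,
    every subset of that size is fit and the best kept (state selection
    as in ensemble-fitting practice).
    """
    theoretical = list(theoretical)
    if not theoretical:
        raise EmptyResultError("no theoretical profiles supplied")
    if not 1 <= n_states <= len(theoretical):
        raise ValueError(
            f"n_states must be in [1, {len(theoretical)}], got {n_states}"
        )
    if experimental.sigma is None:
        raise ValueError("experimental profile must carry sigma values")

    non_identifiable = False
    for a, b in itertools.combinations(theoretical, 2):
        ia = _aligned_theoretical(experimental, a, interpolate)
        ib = _aligned_theoretical(experimental, b, interpolate)
        # identical up to scale: cannot be told apart by any fit
        cos = np.dot(ia, ib) / (np.linalg.norm(ia) * np.linalg.norm(ib))
        if cos > 1.0 - 1e-12:
            non_identifiable = True
            warnings.warn(
                f"theoretical profiles {a.label!r} and {b.label!r} are "
                "numerically proportional; populations between them are "
                "not identifiable",
                stacklevel=2,
            )

    best: tuple[float, tuple[int, ...], np.ndarray, float] | None = None
    for subset in itertools.combinations(range(len(theoretical)), n_states):
        weights, scale, chi2 = _nnls_population_fit(
            experimental, [theoretical[i] for i in subset], interpolate, ddof
        )
        if best is None or chi2 < best[0]:
            best = (chi2, subset, weights, scale)
    chi2, subset, sub_weights, scale = best
    weights = np.zeros(len(theoretical))
    for idx, w in zip(subset, sub_weights):
        weights[idx] = w
    labels = [p.label or f"state_{i}" for i, p in enumerate(theoretical)]
    return PopulationFit(
        labels=labels, weights=weights, scale=scale, chi2=chi2,
        n_states=n_states, non_identifiable=non_identifiable,
    )


def rank_single_states(
    experimental: SaxsProfile,
    theoretical: Sequence[SaxsProfile],
    *,
    interpolate: bool = False,
    ddof: int = 0,
) -> list[tuple[str, float]]:
    """Single-state chi-square per candidate model, best first."""
    theoretical = list(theoretical)
    if not theoretical:
        raise EmptyResultError("no theoretical profiles supplied")
    ranked = []
    for i, prof in enumerate(theoretical):
        _, chi2 = chi2_with_scale(experimental, prof,
                                  interpolate=interpolate, ddof=ddof)
        ranked.append((prof.label or f"state_{i}", chi2))
    return sorted(ranked, key=lambda item: item[1])


# ------------------------------------------------------------------- I/O


def write_profile(profile: SaxsProfile, path: str | Path) -> None:
    """Write a 3-column (q, I, sigma) text profile; 2 columns if no sigma."""
    path = Path(path)
    lines = [f"# {profile.label}".rstrip(), "# q_invA\tintensity\tsigma"]
    for i in range(len(profile.q)):
        row = f"{profile.q[i]:.6f}\t{profile.intensity[i]:.8g}"
        if profile.sigma is not None:
            row += f"\t{profile.sigma[i]:.8g}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path, label: str = "") -> SaxsProfile:
    """Read a beamline-style (q, I[, sigma]) text profile ('#' comments)."""
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SaxsProfile(q=data[:, 0], intensity=data[:, 1], sigma=sigma,
                       label=label or Path(path).stem)
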