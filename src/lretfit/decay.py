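"""Multi-exponential fitting of time-resolved emission decays.

Acquisition model: after the excitation pulse the fluorimeter waits out a
short delay (default 0.2 ms) so that autofluorescence, directly excited
acceptor emission and scattering have decayed, then samples the emission
intensity.  Each trace is fit to

    I(t) = sum_i a_i * exp(-t / tau_i) + b,     a_i >= 0, b >= 0

with 1-3 components.  Apparent lifetimes shorter than ~100 us are an
artifact of the instrument response and are stripped before any distance
analysis; the remaining lifetimes are the physical, conformer-resolved
sensitized-acceptor lifetimes.

Fitting uses variable projection: the outer optimizer moves the log
lifetimes while the amplitudes and baseline are solved by linear least
squares at each step, which makes the fit exactly invariant to uniform
intensity rescaling.  Component-count selection (2 vs 3) uses the
small-sample corrected Akaike criterion with a two-unit preference
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .errors import (
    ConvergenceError,
    EmptyResultError,
    InvalidTraceError,
    UnderdeterminedError,
)
from .photophysics import DyePair, distance_from_lifetimes

__all__ = [
    "DecayTrace",
    "ExponentialComponent",
    "LifetimeFit",
    "fit_decay",
    "fit_donor_lifetime",
    "channel_distances",
    "read_trace",
    "write_trace",
    "read_manifest",
    "INSTRUMENT_CUTOFF_MS",
]

#: Lifetimes below this are treated as instrument response and discarded.
INSTRUMENT_CUTOFF_MS = 0.1

Channel = Literal["donor", "bodipy", "cy3"]


@dataclass
class DecayTrace:
    """A sampled emission decay for one sample/channel."""

    times: np.ndarray
    intensities: np.ndarray
    channel: str
    delay: float = 0.2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise InvalidTraceError("times and intensities must be 1-D and equal length")
        if len(self.times) < 50:
            raise InvalidTraceError(f"trace too short ({len(self.times)} < 50 points)")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidTraceError("times must be strictly increasing")
        if self.times[0] < self.delay - 1e-12:
            raise InvalidTraceError(
                f"first sample ({self.times[0]} ms) precedes the acquisition "
                f"delay ({self.delay} ms)"
            )
        if self.channel not in ("donor", "bodipy", "cy3"):
            raise InvalidTraceError(f"unknown channel {self.channel!r}")

    def _validate_signal(self) -> None:
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidTraceError("trace contains non-finite intensities")
        if np.allclose(self.intensities, 0.0):
            raise InvalidTraceError("trace is identically zero")
        if self.intensities.min() < 0 and abs(self.intensities.min()) > 0.5 * self.intensities.max():
            raise InvalidTraceError("trace is dominated by negative intensities")


@dataclass(frozen=True)
class ExponentialComponent:
    """One decay component: nonnegative amplitude and lifetime in ms."""

    amplitude: float
    lifetime: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not self.lifetime > 0:
            raise ValueError("lifetime must be positive")


@dataclass
class LifetimeFit:
    """Result of a multi-exponential decay fit.

    ``components`` are sorted by lifetime ascending and, when
    ``instrument_stripped`` is set, contain only physical lifetimes
    (>= 0.1 ms).  ``n_selected`` is the component count of the selected
    model before stripping.
    """

    components: list[ExponentialComponent]
    baseline: float
    residual_norm: float
    n_selected: int
    instrument_stripped: bool = False
    stripped_components: list[ExponentialComponent] = field(default_factory=list)
    aicc: dict[int, float] = field(default_factory=dict)

    @property
    def lifetimes(self) -> list[float]:
        return [c.lifetime for c in self.components]

    @property
    def amplitudes(self) -> list[float]:
        return [c.amplitude for c in self.components]


# ---------------------------------------------------------------- fitting


def _poisson_weights(y: np.ndarray) -> np.ndarray:
    """1/sigma weights assuming counting statistics (sigma ~ sqrt(I)).

    Emission decays are photon-counting-like: the variance tracks the
    intensity.  Weighting the fit accordingly keeps the residuals
    homoscedastic, which the component-count selection relies on.  The
    floor guards the deep tail where the intensity approaches zero.
    """
    mag = np.abs(y)
    return 1.0 / np.sqrt(np.maximum(mag, 1e-3 * mag.max()))


def _solve_amplitudes(t: np.ndarray, y: np.ndarray, taus: np.ndarray,
                      w: np.ndarray | None = None,
                      nonneg: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Amplitudes + baseline for fixed lifetimes (the linear subproblem)."""
    design = np.column_stack([np.exp(-t[:, None] / taus[None, :]),
                              np.ones_like(t)])
    if w is None:
        w = np.ones_like(y)
    if nonneg:
        coef, _ = nnls(design * w[:, None], y * w)
    else:
        coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
    return coef, design @ coef


def _varpro_cost(log_taus: np.ndarray, t: np.ndarray, y: np.ndarray,
                 w: np.ndarray) -> np.ndarray:
    taus = np.exp(log_taus)
    _, model = _solve_amplitudes(t, y, taus, w)
    return (model - y) * w


def _starting_grids(k: int, t_max: float) -> list[np.ndarray]:
    """Deterministic multistart lifetime seeds, log-spread over the window."""
    lo, hi = 0.04, 2.0 * t_max
    anchors = [
        np.geomspace(lo, hi, k + 2)[1:-1],
        np.geomspace(lo * 1.7, hi / 3.0, k),
        np.geomspace(lo, t_max / 2.0, k),
    ]
    if k >= 2:
        # one start with an explicit instrument-like short component
        anchors.append(np.concatenate([[0.05], np.geomspace(0.3, t_max, k - 1)]))
    return [np.sort(a) for a in anchors]


def _fit_k_components(
    t: np.ndarray, y: np.ndarray, k: int, *, weighting: str = "poisson",
    extra_starts: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-multistart variable-projection fit with k components.

    Returns (lifetimes, [amplitudes..., baseline], weighted RSS at the
    variable-projection optimum).  The reported amplitudes are refit
    under a nonnegativity constraint at the optimal lifetimes.
    ``extra_starts`` adds data-adaptive lifetime seeds to the built-in
    grid (e.g. splits of a lower-order fit).
    """
    n_params = 2 * k + 1
    if len(t) < 3 * n_params:
        raise UnderdeterminedError(
            f"{len(t)} points cannot support a {k}-component fit "
            f"({n_params} parameters; need >= {3 * n_params})"
        )
    if weighting == "poisson":
        w = _poisson_weights(y)
    elif weighting == "none":
        w = np.ones_like(y)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    t_max = float(t[-1])
    bounds = (np.log(1e-3), np.log(4.0 * t_max))
    starts = _starting_grids(k, t_max) + [
        np.sort(np.clip(s, 1.1e-3, 3.9 * t_max)) for s in (extra_starts or [])
    ]
    best = None
    for start in starts:
        try:
            sol = least_squares(
                _varpro_cost, np.log(start), args=(t, y, w),
                bounds=bounds, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise ConvergenceError(
            f"{k}-component fit failed to converge",
            best_residual=None if best is None else float(np.sqrt(2 * best.cost)),
        )
    taus = np.exp(best.x)
    coef, _ = _solve_amplitudes(t, y, taus, w, nonneg=True)
    return taus, coef, float(2.0 * best.cost)


def _consolidate(
    comps: list[ExponentialComponent], t_start: float, *,
    merge_ratio: float = 1.6, amplitude_floor: float = 0.05,
) -> list[ExponentialComponent]:
    """Merge split components and drop trace amplitudes.

    Two lifetimes within ``merge_ratio`` of each other are one physical
    component that the optimizer split (adjacent conformer lifetimes in
    this system differ by at least a factor of 2); they are combined at
    their amplitude-weighted mean lifetime.  Components whose observable
    contribution at the start of the acquisition window,
    ``a * exp(-t_start/tau)``, is below ``amplitude_floor`` of the
    largest contribution are noise artifacts and are dropped (the t=0
    amplitude itself is meaningless for ultra-short components
    extrapolated past the delay).  The floor assumes roughly comparable
    state populations; both knobs are exposed through
    :func:`fit_decay`.
    """
    if not comps:
        return comps
    merged: list[ExponentialComponent] = []
    for c in comps:  # already sorted by lifetime
        if merged and c.lifetime / merged[-1].lifetime < merge_ratio:
            prev = merged[-1]
            total = prev.amplitude + c.amplitude
            merged[-1] = ExponentialComponent(
                amplitude=total,
                lifetime=(prev.amplitude * prev.lifetime
                          + c.amplitude * c.lifetime) / total,
            )
        else:
            merged.append(c)
    eff = [c.amplitude * np.exp(-t_start / c.lifetime) for c in merged]
    floor = amplitude_floor * max(eff)
    return [c for c, e in zip(merged, eff) if e >= floor]


def _aicc(rss: float, n: int, n_params: int) -> float:
    # guard the log for numerically perfect (noiseless) fits
    rss = max(rss, 1e-300)
    p = n_params + 1  # + variance
    val = n * np.log(rss / n) + 2 * p
    if n - p - 1 > 0:
        val += 2 * p * (p + 1) / (n - p - 1)
    return float(val)


def fit_decay(
    trace: DecayTrace,
    n_components: int | Literal["auto"] = "auto",
    *,
    strip_cutoff: float = INSTRUMENT_CUTOFF_MS,
    aicc_threshold: float = 2.0,
    weighting: str = "poisson",
    merge_ratio: float = 1.6,
    amplitude_floor: float = 0.05,
) -> LifetimeFit:
    """Fit a 2- or 3-exponential model and strip the instrument component.

    With ``n_components="auto"`` both a 2- and a 3-component model are
    fit and the 3-component model is kept only when its corrected Akaike
    score improves on the 2-component one by at least ``aicc_threshold``
    (scores computed on counting-weighted residuals unless
    ``weighting="none"``).  Components with lifetime < ``strip_cutoff``
    (default 0.1 ms) are then removed as instrument response;
    zero-amplitude components are dropped.
    """
    trace._validate_signal()
    t, y = trace.times, trace.intensities
    if n_components == "auto":
        candidates = (2, 3)
    elif n_components in (1, 2, 3):
        candidates = (int(n_components),)
    else:
        raise ValueError(f"n_components must be 1-3 or 'auto', got {n_components!r}")

    fits: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    scores: dict[int, float] = {}
    for k in candidates:
        extra = None
        if k == 3 and 2 in fits:
            # seed the 3-component search from splits of the 2-component
            # optimum: an added short (instrument-like) lifetime, a split
            # of either component, and a geometric-mean middle component
            t1, t2 = np.sort(fits[2][0])
            extra = [
                np.array([0.05, t1, t2]),
                np.array([t1 / 4.0, t1, t2]),
                np.array([t1, np.sqrt(t1 * t2), t2]),
                np.array([t1, t2, 3.0 * t2]),
            ]
        taus, coef, rss = _fit_k_components(t, y, k, weighting=weighting,
                                            extra_starts=extra)
        fits[k] = (taus, coef, rss)
        scores[k] = _aicc(rss, len(t), 2 * k + 1)

    if len(candidates) == 1:
        k_sel = candidates[0]
    elif fits[2][2] < 1e-16 * float(np.sum((y * _poisson_weights(y)) ** 2)):
        # the 2-component fit already sits at numerical noise (noiseless
        # trace); an extra component can only split degenerately
        k_sel = 2
    else:
        k_sel = 3 if scores[3] < scores[2] - aicc_threshold else 2

    taus, coef, rss = fits[k_sel]
    baseline = float(coef[-1])
    comps = sorted(
        (ExponentialComponent(float(a), float(tau))
         for a, tau in zip(coef[:-1], taus) if a > 0),
        key=lambda c: c.lifetime,
    )
    comps = _consolidate(comps, float(t[0]), merge_ratio=merge_ratio,
                         amplitude_floor=amplitude_floor)
    kept = [c for c in comps if c.lifetime >= strip_cutoff]
    stripped = [c for c in comps if c.lifetime < strip_cutoff]
    scale = float(np.max(np.abs(y)))
    return LifetimeFit(
        components=kept,
        baseline=baseline,
        residual_norm=float(np.sqrt(rss)) / scale,
        n_selected=k_sel,
        instrument_stripped=True,
        stripped_components=stripped,
        aicc=scores,
    )


def fit_donor_lifetime(
    trace: DecayTrace, *, amplitude_rule: float = 0.85
) -> tuple[float, float]:
    """Donor-only lifetime: two-exponential fit, longer component kept.

    Returns ``(tau_d, amplitude_fraction)`` where the fraction is the
    long component's share of the total decay amplitude.  Donor decays
    are expected to be dominated by the long lifetime; a fraction below
    ``amplitude_rule`` triggers a quality warning.
    """
    if trace.channel != "donor":
        raise InvalidTraceError(
            f"donor lifetime requires a donor-channel trace, got {trace.channel!r}"
        )
    trace._validate_signal()
    taus, coef, _ = _fit_k_components(trace.times, trace.intensities, 2)
    amps = coef[:-1]
    if np.sum(amps) <= 0:
        raise ConvergenceError("two-exponential donor fit found no signal amplitude")
    i_long = int(np.argmax(taus))
    fraction = float(amps[i_long] / np.sum(amps))
    tau_d = float(taus[i_long])
    if fraction < amplitude_rule:
        warnings.warn(
            f"long donor lifetime carries only {fraction:.0%} of the signal "
            f"(quality rule requires >= {amplitude_rule:.0%})",
            stacklevel=2,
        )
    return tau_d, fraction


def channel_distances(
    fit: LifetimeFit, tau_d: float, pair: DyePair
) -> list[float]:
    """Per-component donor-acceptor distances, sorted ascending.

    Each retained physical lifetime is a sensitized-acceptor lifetime
    for one conformer; components at or beyond the donor-only lifetime
    carry no transfer and are rejected.
    """
    if not fit.instrument_stripped:
        raise ValueError("fit must have the instrument component stripped first")
    if not 1 <= len(fit.components) <= 3:
        raise EmptyResultError(
            f"expected 1-3 physical components, got {len(fit.components)}"
        )
    dists = []
    for comp in fit.components:
        if comp.lifetime >= tau_d:
            continue  # non-transferring
        dists.append(distance_from_lifetimes(comp.lifetime, tau_d, pair).mean)
    if not dists:
        raise EmptyResultError(
            "no transferring components (all lifetimes >= donor lifetime)"
        )
    return sorted(dists)


# ------------------------------------------------------------------- I/O


def write_trace(trace: DecayTrace, path: str | Path) -> None:
    """Write a trace as 2-column text with a '#'-prefixed header block."""
    path = Path(path)
    lines = [f"# channel: {trace.channel}", f"# delay_ms: {trace.delay:g}"]
    for key, val in sorted(trace.metadata.items()):
        lines.append(f"# {key}: {val}")
    lines.append("# time_ms\tintensity")
    body = "\n".join(
        f"{t:.6f}\t{i:.10g}" for t, i in zip(trace.times, trace.intensities)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_trace(path: str | Path) -> DecayTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    meta: dict[str, str] = {}
    times, intens = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        t_str, i_str = line.split()
        times.append(float(t_str))
        intens.append(float(i_str))
    channel = meta.pop("channel", "donor")
    delay = float(meta.pop("delay_ms", 0.2))
    meta.pop("time_ms", None)
    return DecayTrace(
        times=np.array(times), intensities=np.array(intens),
        channel=channel, delay=delay, metadata=meta,
    )


MANIFEST_COLUMNS = ["file", "pair", "channel", "condition", "replicate"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the trace manifest (tab-separated) mapping files to samples."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df
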