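"""Synthetic-data generation for every stage of the pipeline.

The generator inverts the analysis assumptions so that each stage can be
tested round-trip without any instrument data:

* emission decays are built from a ground-truth table of conformer
  distances by mapping each distance to a sensitized-acceptor lifetime
  through the inverse Förster relation, then adding a short
  instrument-response component and (optionally) noise;
* toy bead conformers are two C2-symmetric protomer bead clouds placed
  so that every probe Cβ–Cβ separation matches its target distance;
* scattering mixtures are population-weighted sums of Debye profiles;
* ATPase titrations are forward-evaluated Hill kinetics.

A channel sees a conformer only inside an efficiency window
[``e_min``, ``e_max``]: below ``e_min`` the distance sits on the flat
tail of the transfer curve (no measurable sensitized decay), above
``e_max`` the sensitized lifetime is too short to separate from the
instrument response.  With the default window the short-R0 acceptor
(Bodipy FL) reports the closed and partially open separations while the
long-R0 acceptor (Cy3) reports the partially open and open ones — the
channel pattern the analysis stage expects.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .decay import DecayTrace, write_trace
from .errors import FeasibilityError
from .enzymology import TitrationSeries, hill_rate
from .photophysics import (
    DYE_PAIRS,
    efficiency_from_distance,
    lifetime_from_distance,
)
from .restraints import ModelCoordinates
from .saxs import BeadModel, SaxsProfile, debye_profile
from .states import ProbePair

__all__ = [
    "TruthRecord",
    "GroundTruth",
    "load_reference_distances",
    "reference_ground_truth",
    "simulate_decay",
    "simulate_study",
    "build_toy_conformers",
    "write_conformer_pdb",
    "simulate_saxs_mixture",
    "simulate_titration",
]


def load_reference_distances() -> pd.DataFrame:
    """The bundled reference distance table (probe pair x condition)."""
    with importlib.resources.files("lretfit.data").joinpath(
        "reference_distances.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@dataclass(frozen=True)
class TruthRecord:
    """True conformer distances for one probe pair under one condition.

    The partially open state keeps one value per acceptor channel: the
    two channels are independent measurements of that separation and the
    reference table reports both.
    """

    pair: ProbePair
    condition: str
    closed: float | None = None
    partially_open_bodipy: float | None = None
    partially_open_cy3: float | None = None
    open_: float | None = None

    def channel_distances(self, channel: str) -> dict[str, float]:
        if channel == "bodipy":
            po = self.partially_open_bodipy
        elif channel == "cy3":
            po = self.partially_open_cy3
        else:
            raise ValueError(f"not an acceptor channel: {channel!r}")
        states = {"closed": self.closed, "partially_open": po, "open": self.open_}
        return {k: v for k, v in states.items() if v is not None}


@dataclass
class GroundTruth:
    """Complete specification of a synthetic LRET study."""

    records: list[TruthRecord]
    donor_lifetimes: dict[int, float] = field(default_factory=dict)
    default_donor_lifetime: float = 2.0     # ms, typical Tb3+ chelate
    donor_short_lifetime: float = 0.3       # ms, minor donor component
    donor_long_fraction: float = 0.9        # amplitude share of the long lifetime
    delay: float = 0.2                      # ms acquisition delay
    duration: float = 10.0                  # ms
    step: float = 0.01                      # ms sampling interval
    instrument_lifetime: float = 0.05       # ms, detection-electronics component
    instrument_fraction: float = 0.2        # its share of the t=0 amplitude
    e_min: float = 0.08                     # channel visibility window
    e_max: float = 0.93
    noise_model: str = "none"               # none | gaussian | poisson
    noise_scale: float = 0.01               # k in sigma = max(floor, k*sqrt(I))
    noise_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for rec in self.records:
            vals = [v for v in (rec.closed, rec.partially_open_bodipy,
                                rec.partially_open_cy3, rec.open_) if v is not None]
            if any(v <= 0 for v in vals):
                raise ValueError(f"non-positive distance in {rec}")
            if rec.closed is not None and rec.open_ is not None and not rec.closed < rec.open_:
                raise ValueError(f"closed >= open for {rec.pair.label}/{rec.condition}")

    def donor_lifetime(self, residue: int) -> float:
        return self.donor_lifetimes.get(residue, self.default_donor_lifetime)

    def record(self, pair_label: str, condition: str) -> TruthRecord:
        for rec in self.records:
            if rec.pair.label == pair_label and rec.condition == condition:
                return rec
        raise KeyError(f"no ground truth for pair {pair_label!r} under {condition!r}")

    @property
    def probe_residues(self) -> list[int]:
        res = {r.pair.residue_a for r in self.records} | {
            r.pair.residue_b for r in self.records
        }
        return sorted(res)

    def times(self) -> np.ndarray:
        if self.duration <= self.delay:
            raise ValueError(
                f"acquisition duration ({self.duration} ms) must exceed the "
                f"delay ({self.delay} ms)"
            )
        return np.arange(self.delay, self.duration + self.step / 2, self.step)


def reference_ground_truth(
    construct: str = "NBD",
    conditions: tuple[str, ...] | None = None,
    **overrides,
) -> GroundTruth:
    """Ground truth seeded from the bundled reference distance table."""
    table = load_reference_distances()
    table = table[table["construct"] == construct]
    if conditions is not None:
        table = table[table["condition"].isin(conditions)]
    if table.empty:
        raise ValueError(f"no reference rows for construct {construct!r}")
    records = [
        TruthRecord(
            pair=ProbePair(int(row.pair_a), int(row.pair_b)),
            condition=row.condition,
            closed=row.closed_mean,
            partially_open_bodipy=row.po_bodipy_mean,
            partially_open_cy3=row.po_cy3_mean,
            open_=row.open_mean,
        )
        for row in table.itertuples()
    ]
    return GroundTruth(records=records, **overrides)


# ------------------------------------------------------------ decay traces


def _apply_noise(truth: GroundTruth, intensity: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    if truth.noise_model == "none":
        return intensity
    if truth.noise_model == "gaussian":
        sigma = np.maximum(truth.noise_floor,
                           truth.noise_scale * np.sqrt(np.abs(intensity)))
        return intensity + rng.normal(0.0, sigma)
    if truth.noise_model == "poisson":
        counts = np.maximum(intensity, 0.0) / max(truth.noise_scale, 1e-12)
        return rng.poisson(counts).astype(float) * truth.noise_scale
    raise ValueError(f"unknown noise model {truth.noise_model!r}")


def simulate_decay(
    truth: GroundTruth,
    pair_label: str,
    condition: str,
    channel: str,
    *,
    replicate: int = 1,
    rng: np.random.Generator | None = None,
) -> DecayTrace:
    """Forward-simulate one emission decay trace.

    Acceptor channels convert each visible conformer distance to a
    sensitized lifetime via the inverse Förster map (donor lifetime of
    the Tb3+-labelled residue), weight visible conformers equally, and
    add the instrument-response component.  The donor channel is a
    two-exponential decay dominated by the long donor lifetime.
    """
    rec = truth.record(pair_label, condition)
    t = truth.times()
    tau_d = truth.donor_lifetime(rec.pair.residue_a)
    components: list[tuple[float, float]] = []  # (amplitude, lifetime)

    if channel == "donor":
        components = [
            (truth.donor_long_fraction, tau_d),
            (1.0 - truth.donor_long_fraction, truth.donor_short_lifetime),
        ]
    else:
        pair = DYE_PAIRS[channel]
        visible = {
            state: dist
            for state, dist in rec.channel_distances(channel).items()
            if truth.e_min <= efficiency_from_distance(dist, pair) <= truth.e_max
        }
        if not visible:
            raise ValueError(
                f"no conformer visible in the {channel} channel for "
                f"{pair_label}/{condition}"
            )
        amp = (1.0 - truth.instrument_fraction) / len(visible)
        components = [
            (amp, lifetime_from_distance(dist, pair, tau_d))
            for dist in visible.values()
        ]
        components.append((truth.instrument_fraction, truth.instrument_lifetime))

    intensity = np.zeros_like(t)
    for amp, tau in components:
        intensity += amp * np.exp(-t / tau)
    if truth.noise_model != "none":
        rng = rng if rng is not None else np.random.default_rng(truth.seed)
        intensity = _apply_noise(truth, intensity, rng)
    return DecayTrace(
        times=t, intensities=intensity, channel=channel, delay=truth.delay,
        metadata={
            "pair": pair_label, "condition": condition,
            "replicate": str(replicate), "tau_d_ms": f"{tau_d:g}",
        },
    )


def simulate_study(
    truth: GroundTruth,
    out_dir: str | Path,
    *,
    replicates: int = 3,
) -> pd.DataFrame:
    """Write trace files plus a manifest for a full synthetic study.

    One trace per (pair, condition, acceptor channel, replicate), plus
    one donor-only trace per probe residue and replicate.  Everything is
    a pure function of the ground truth (including its seed): reruns are
    byte-identical.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    rows = []
    for rec in sorted(truth.records, key=lambda r: (r.pair.label, r.condition)):
        for channel in ("bodipy", "cy3"):
            for rep in range(1, replicates + 1):
                trace = simulate_decay(
                    truth, rec.pair.label, rec.condition, channel,
                    replicate=rep, rng=rng,
                )
                fname = (f"{rec.pair.label}_{rec.condition}_{channel}_r{rep}.dat"
                         .replace("+", "_"))
                write_trace(trace, out_dir / fname)
                rows.append({
                    "file": fname, "pair": rec.pair.label, "channel": channel,
                    "condition": rec.condition, "replicate": rep,
                })
    # donor-only traces, one per labelled residue
    for residue in truth.probe_residues:
        for rep in range(1, replicates + 1):
            tau_d = truth.donor_lifetime(residue)
            t = truth.times()
            intensity = (
                truth.donor_long_fraction * np.exp(-t / tau_d)
                + (1 - truth.donor_long_fraction) * np.exp(-t / truth.donor_short_lifetime)
            )
            if truth.noise_model != "none":
                intensity = _apply_noise(truth, intensity, rng)
            trace = DecayTrace(
                times=t, intensities=intensity, channel="donor",
                delay=truth.delay,
                metadata={"pair": str(residue), "condition": "donor-only",
                          "replicate": str(rep)},
            )
            fname = f"donor_{residue}_r{rep}.dat"
            write_trace(trace, out_dir / fname)
            rows.append({
                "file": fname, "pair": str(residue), "channel": "donor",
                "condition": "donor-only", "replicate": rep,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


# ------------------------------------------------------- toy bead conformers


def _solve_probe_geometry(
    residues: list[int], targets: dict[tuple[int, int], float]
) -> np.ndarray:
    """Place protomer-A probe beads so C2-mirrored distances hit targets.

    Protomer B is the C2 image of A about the z axis:
    B = (-x, -y, z).  Then |A_i - B_j| depends only on the A-side
    coordinates, and mirrored pairs (i,j)/(j,i) are automatically equal.
    """
    index = {res: i for i, res in enumerate(residues)}
    pairs = sorted(targets)

    def unpack(v: np.ndarray) -> np.ndarray:
        return v.reshape(len(residues), 3)

    def residual(v: np.ndarray) -> np.ndarray:
        X = unpack(v)
        out = np.empty(len(pairs))
        for k, (ra, rb) in enumerate(pairs):
            a, b = X[index[ra]], X[index[rb]]
            bx = np.array([-b[0], -b[1], b[2]])
            out[k] = np.linalg.norm(a - bx) - targets[(ra, rb)]
        return out

    # start: spread residues on a half-arc at half their identity distance
    x0 = np.zeros((len(residues), 3))
    for i, res in enumerate(residues):
        d_self = targets.get((res, res))
        radius = (d_self / 2.0) if d_self else np.mean(list(targets.values())) / 2.0
        angle = 0.5 + 0.9 * i
        x0[i] = [radius * np.cos(angle * 0.3) + 1.0,
                 radius * np.sin(angle * 0.3),
                 4.0 * i]
    sol = least_squares(residual, x0.ravel(), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    resid = residual(sol.x)
    if np.max(np.abs(resid)) > 1e-6:
        worst = pairs[int(np.argmax(np.abs(resid)))]
        raise FeasibilityError(
            f"distance set admits no C2 bead geometry; worst violation "
            f"{np.max(np.abs(resid)):.3f} Å on pair {worst[0]}-{worst[1]} "
            "(inconsistent with the triangle inequality over the probe network)"
        )
    return unpack(sol.x)


def build_toy_conformers(
    state_targets: dict[str, dict[tuple[int, int], float]],
    *,
    n_filler: int = 24,
    filler_seed: int = 7,
    chains: tuple[str, str] = ("A", "B"),
) -> dict[str, tuple[BeadModel, ModelCoordinates]]:
    """Construct one toy bead conformer per state.

    ``state_targets`` maps a state label to {(residue_a, residue_b):
    distance} inter-protomer targets.  Each conformer is two
    C2-symmetric protomer copies: probe beads solved to satisfy every
    target to < 1e-6 Å, plus a deterministic filler-bead cloud (rigid
    per protomer) that gives the model a molecular-envelope-like shape
    for scattering calculations.  Returns both the bead model (all
    beads) and the probe-only coordinates keyed by (chain, residue).
    """
    chain_a, chain_b = chains
    out: dict[str, tuple[BeadModel, ModelCoordinates]] = {}
    for state, targets in state_targets.items():
        if not targets:
            raise ValueError(f"no distance targets for state {state!r}")
        residues = sorted({r for pair in targets for r in pair})
        # symmetrize: (a,b) and (b,a) are the same physical target
        canon: dict[tuple[int, int], float] = {}
        for (ra, rb), d in targets.items():
            key = (min(ra, rb), max(ra, rb))
            if key in canon and abs(canon[key] - d) > 1e-9:
                raise ValueError(f"conflicting targets for pair {key} in {state!r}")
            canon[key] = float(d)
        probes_a = _solve_probe_geometry(residues, canon)

        rng = np.random.default_rng(filler_seed)
        centroid = probes_a.mean(axis=0)
        spread = max(probes_a.std(), 5.0)
        filler_a = centroid + rng.normal(scale=spread, size=(n_filler, 3))

        def mirror(x: np.ndarray) -> np.ndarray:
            return np.column_stack([-x[:, 0], -x[:, 1], x[:, 2]])

        beads = np.vstack([probes_a, filler_a, mirror(probes_a), mirror(filler_a)])
        coords = {}
        for i, res in enumerate(residues):
            coords[(chain_a, res)] = probes_a[i]
            coords[(chain_b, res)] = mirror(probes_a)[i]
        out[state] = (
            BeadModel(positions=beads, label=state),
            ModelCoordinates(coords=coords, model_id=state),
        )
    return out


def write_conformer_pdb(model: ModelCoordinates, path: str | Path) -> None:
    """Write probe coordinates as a minimal PDB (ALA residues, Cβ atoms)."""
    import gemmi

    structure = gemmi.Structure()
    structure.name = model.model_id or "conformer"
    gm = gemmi.Model("1")
    by_chain: dict[str, list[tuple[int, np.ndarray]]] = {}
    for (chain, res), pos in sorted(model.coords.items()):
        by_chain.setdefault(chain, []).append((res, pos))
    for chain_name, entries in sorted(by_chain.items()):
        chain = gemmi.Chain(chain_name)
        for res_num, pos in entries:
            residue = gemmi.Residue()
            residue.name = "ALA"
            residue.seqid = gemmi.SeqId(res_num, " ")
            atom = gemmi.Atom()
            atom.name = "CB"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            residue.add_atom(atom)
            chain.add_residue(residue)
        gm.add_chain(chain)
    structure.add_model(gm)
    structure.setup_entities()
    structure.write_pdb(str(path))


# ------------------------------------------------------------ SAXS + kinetics


def simulate_saxs_mixture(
    models: list[BeadModel],
    weights,
    q_grid: np.ndarray | None = None,
    *,
    noise_level: float = 0.0,
    seed: int = 0,
    scale: float = 1.0,
) -> SaxsProfile:
    """Population-weighted scattering mixture with a sigma column.

    ``sigma = max(noise_level, 0.01) * I``; Gaussian noise of that sigma
    is added only when ``noise_level > 0`` (a noiseless profile still
    carries sigmas so that chi-square fits are defined).
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(models):
        raise ValueError("one weight per model required")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"weights must be nonnegative and sum to 1, got {weights.tolist()}"
        )
    q = DEFAULT_Q_GRID_COPY() if q_grid is None else np.asarray(q_grid, dtype=float)
    intensity = np.zeros_like(q)
    for w, model in zip(weights, models):
        if w > 0:
            intensity += w * debye_profile(model, q).intensity
    intensity *= scale
    sigma = max(noise_level, 0.01) * intensity
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, sigma)
    return SaxsProfile(q=q, intensity=intensity, sigma=sigma, label="mixture")


def DEFAULT_Q_GRID_COPY() -> np.ndarray:
    from .saxs import DEFAULT_Q_GRID

    return DEFAULT_Q_GRID.copy()


def simulate_titration(
    vmax: float,
    km: float,
    n: float,
    concentrations,
    *,
    noise_level: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Forward Hill kinetics with optional proportional Gaussian noise."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration list")
    rates = hill_rate(conc, vmax, km, n)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        rates = rates + rng.normal(0.0, noise_level * max(vmax, 1e-12), size=rates.shape)
    return TitrationSeries(concentrations=conc, rates=rates)
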