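"""Distance restraints for macromolecular docking, and model validation.

State-resolved LRET distances become unambiguous Cβ–Cβ restraints
between the two Rad50 protomers (chains A and B by default).  Bounds
follow the measurement error structure: ±5 Å for targets up to 75 Å,
widened to ±7 Å beyond that because long Cy3 distances fall on the flat,
error-prone tail of the transfer-efficiency curve.  Because donor and
acceptor labels are interchangeable between protomers, every mixed pair
(i on A, j on B) is duplicated as its mirror (j on A, i on B); identity
pairs are their own mirror.

Restraints export to the CNS/HADDOCK ``assign`` dialect and round-trip
through the companion parser.  Structural models (PDB, or synthetic bead
geometries) are checked restraint-by-restraint via Cβ–Cβ Euclidean
distances, with Cα fallback for glycine.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError
from .states import ConformerDistances, ProbePair

__all__ = [
    "DistanceRestraint",
    "RestraintSet",
    "ModelCoordinates",
    "DeviationReport",
    "bounds_for_target",
    "build_restraints",
    "export_restraint_table",
    "parse_restraint_table",
    "dropout_subset",
    "validate_model",
    "cluster_consistency",
]

#: Targets above this many Å get the wider ±7 Å bounds ("greater than 75";
#: the boundary itself keeps ±5).
WIDE_BOUNDS_THRESHOLD = 75.0


def bounds_for_target(target: float) -> tuple[float, float]:
    """(minus, plus) bounds: ±5 Å up to 75 Å inclusive, ±7 Å beyond."""
    return (7.0, 7.0) if target > WIDE_BOUNDS_THRESHOLD else (5.0, 5.0)


@dataclass(frozen=True)
class DistanceRestraint:
    segment_a: str
    residue_a: int
    segment_b: str
    residue_b: int
    target: float
    minus: float
    plus: float
    atom: str = "CB"
    state: str = ""
    source_pair: ProbePair | None = None

    def __post_init__(self) -> None:
        if self.minus <= 0 or self.plus <= 0:
            raise ValueError("restraint bounds must be positive")
        if self.target <= 0:
            raise ValueError("restraint target must be positive")

    @property
    def selection_key(self) -> tuple:
        return (self.segment_a, self.residue_a, self.segment_b, self.residue_b,
                self.atom)

    def mirrored(self) -> "DistanceRestraint":
        """Swap the residues between segments (same chains, same bounds)."""
        return DistanceRestraint(
            segment_a=self.segment_a, residue_a=self.residue_b,
            segment_b=self.segment_b, residue_b=self.residue_a,
            target=self.target, minus=self.minus, plus=self.plus,
            atom=self.atom, state=self.state, source_pair=self.source_pair,
        )


@dataclass
class RestraintSet:
    restraints: list[DistanceRestraint]
    state: str = ""
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def sorted(self) -> list[DistanceRestraint]:
        return sorted(
            self.restraints,
            key=lambda r: (r.segment_a, r.residue_a, r.segment_b, r.residue_b,
                           r.state, r.target),
        )

    def is_mirror_symmetric(self, atol: float = 1e-9) -> bool:
        """Every hetero-residue restraint has its mirror with equal bounds."""
        index: dict[tuple[int, int], list[DistanceRestraint]] = {}
        for r in self.restraints:
            index.setdefault((r.residue_a, r.residue_b), []).append(r)
        for r in self.restraints:
            if r.residue_a == r.residue_b:
                continue
            mirrors = index.get((r.residue_b, r.residue_a), [])
            if not any(
                abs(m.target - r.target) <= atol and m.minus == r.minus
                and m.plus == r.plus for m in mirrors
            ):
                return False
        return True


def build_restraints(
    conformers: Iterable[ConformerDistances],
    state: str,
    chain_map: Mapping[str, str] | None = None,
    *,
    partially_open_mode: str = "mean",
    strict: bool = False,
) -> RestraintSet:
    """Build the symmetric restraint set for one conformer state.

    ``state`` is one of ``closed``, ``partially_open``, ``open``,
    ``short`` or ``long``.  For the partially open state, which carries
    one estimate per acceptor channel, ``partially_open_mode="mean"``
    emits a single restraint at the channel mean while ``"both"`` emits
    one restraint per channel value.

    Mixed pairs yield two mirrored restraints; identity pairs are
    already symmetric and yield one.  Records lacking the requested
    state are skipped with a warning (or raise when ``strict``).
    """
    chain_map = dict(chain_map or {"A": "A", "B": "B"})
    seg_a, seg_b = chain_map["A"], chain_map["B"]
    if not seg_a or not seg_b:
        raise ValueError("chain_map must assign non-empty chain ids to A and B")
    out: list[DistanceRestraint] = []
    condition = None
    for rec in conformers:
        condition = condition or rec.condition
        if state == "partially_open":
            ests = [e for e in (rec.partially_open_bodipy, rec.partially_open_cy3) if e]
            if not ests:
                targets = []
            elif partially_open_mode == "mean":
                targets = [sum(e.mean for e in ests) / len(ests)]
            elif partially_open_mode == "both":
                targets = [e.mean for e in ests]
            else:
                raise ValueError(f"unknown partially_open_mode {partially_open_mode!r}")
        else:
            est = rec.state(state)
            targets = [est.mean] if est is not None else []
        if not targets:
            msg = f"state {state!r} absent for pair {rec.pair.label} ({rec.condition})"
            if strict:
                raise EmptyResultError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        for target in targets:
            minus, plus = bounds_for_target(target)
            r = DistanceRestraint(
                segment_a=seg_a, residue_a=rec.pair.residue_a,
                segment_b=seg_b, residue_b=rec.pair.residue_b,
                target=round(float(target), 3), minus=minus, plus=plus,
                state=state, source_pair=rec.pair,
            )
            out.append(r)
            if not rec.pair.is_identity:
                out.append(r.mirrored())
    return RestraintSet(
        restraints=out, state=state,
        provenance={"condition": condition, "partially_open_mode": partially_open_mode},
    )


# ------------------------------------------------------------- export/parse

_ASSIGN_RE = re.compile(
    r"assign\s*\(segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+(\S+)\)\s*"
    r"\(segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+(\S+)\)\s*"
    r"([\d.]+)\s+([\d.]+)\s+([\d.]+)"
)


def export_restraint_table(
    restraint_set: RestraintSet,
    dialect: str = "cns",
    *,
    air_passthrough: str | Path | None = None,
) -> str:
    """Serialize a restraint set in the CNS/HADDOCK ``assign`` dialect.

    One ``assign`` statement per restraint, in stable (chain, residue,
    state, target) order.  ``air_passthrough`` names a user-supplied
    ambiguous-interaction-restraint file whose content is appended
    verbatim (this package never derives AIRs).
    """
    if dialect != "cns":
        raise ValueError(f"unknown restraint dialect {dialect!r}")
    if len(restraint_set) == 0:
        raise EmptyResultError("cannot export an empty restraint set")
    lines = []
    for r in restraint_set.sorted():
        if not r.segment_a or not r.segment_b:
            raise ValueError(f"restraint missing a chain id: {r}")
        lines.append(
            f"assign (segid {r.segment_a} and resid {r.residue_a} and name {r.atom}) "
            f"(segid {r.segment_b} and resid {r.residue_b} and name {r.atom}) "
            f"{r.target:.3f} {r.minus:.1f} {r.plus:.1f}"
        )
    text = "\n".join(lines) + "\n"
    if air_passthrough is not None:
        text += Path(air_passthrough).read_text()
    return text


def parse_restraint_table(text: str, state: str = "") -> RestraintSet:
    """Parse ``assign`` statements back into a restraint set."""
    restraints = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("!", "#")):
            continue
        m = _ASSIGN_RE.match(line)
        if m is None:
            continue  # AIR passthrough or other CNS statements
        sa, ra, atom_a, sb, rb, _atom_b, target, minus, plus = m.groups()
        restraints.append(DistanceRestraint(
            segment_a=sa, residue_a=int(ra), segment_b=sb, residue_b=int(rb),
            target=float(target), minus=float(minus), plus=float(plus),
            atom=atom_a, state=state,
        ))
    return RestraintSet(restraints=restraints, state=state)


def dropout_subset(restraint_set: RestraintSet, probe_residue: int) -> RestraintSet:
    """Remove every restraint whose source pair involves ``probe_residue``.

    Used for leave-one-probe-out robustness runs: dropping a cysteine
    position removes all restraints measured from it, on either
    protomer.  An absent residue leaves the set unchanged (with a
    warning).
    """
    kept = [
        r for r in restraint_set
        if probe_residue not in (r.residue_a, r.residue_b)
    ]
    if len(kept) == len(restraint_set):
        warnings.warn(
            f"residue {probe_residue} appears in no restraint; set unchanged",
            stacklevel=2,
        )
    return RestraintSet(
        restraints=kept, state=restraint_set.state,
        provenance={**restraint_set.provenance, "dropout": probe_residue},
    )


# --------------------------------------------------------------- validation


@dataclass
class ModelCoordinates:
    """Cβ positions per (chain, residue) for one structural model."""

    coords: dict[tuple[str, int], np.ndarray]
    model_id: str = ""
    cluster_id: str | None = None

    def position(self, chain: str, residue: int) -> np.ndarray:
        key = (chain, residue)
        if key not in self.coords:
            raise KeyError(
                f"model {self.model_id!r} has no coordinates for chain "
                f"{chain} residue {residue}"
            )
        return self.coords[key]

    def distance(self, chain_a: str, res_a: int, chain_b: str, res_b: int) -> float:
        return float(np.linalg.norm(self.position(chain_a, res_a)
                                    - self.position(chain_b, res_b)))

    @classmethod
    def from_pdb(
        cls, path: str | Path, *, atom: str = "CB", model_index: int = 0
    ) -> "ModelCoordinates":
        """Read Cβ coordinates from a PDB file (Cα fallback for glycine).

        Multi-model files use the first model unless ``model_index`` says
        otherwise.
        """
        import gemmi

        structure = gemmi.read_structure(str(path))
        if len(structure) == 0:
            raise ValueError(f"no models in {path}")
        model = structure[model_index]
        coords: dict[tuple[str, int], np.ndarray] = {}
        for chain in model:
            for residue in chain:
                at = residue.find_atom(atom, "*")
                if at is None:
                    at = residue.find_atom("CA", "*")
                    if at is not None and residue.name != "GLY":
                        warnings.warn(
                            f"{residue.name} {chain.name}{residue.seqid.num}: "
                            f"no {atom} atom, using CA",
                            stacklevel=2,
                        )
                if at is None:
                    continue
                coords[(chain.name, residue.seqid.num)] = np.array(
                    [at.pos.x, at.pos.y, at.pos.z]
                )
        return cls(coords=coords, model_id=Path(path).stem)


@dataclass
class DeviationReport:
    """Restraint-by-restraint comparison of a model against a set."""

    table: pd.DataFrame
    threshold: float

    @property
    def n_satisfied(self) -> int:
        return int(self.table["satisfied"].sum())

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def max_abs_deviation(self) -> float:
        return float(self.table["deviation"].abs().max())

    @property
    def fraction_satisfied(self) -> float:
        return self.n_satisfied / self.n_total if self.n_total else float("nan")

    def to_text(self) -> str:
        head = (f"satisfied {self.n_satisfied}/{self.n_total} at ±{self.threshold} Å"
                f"; max |deviation| {self.max_abs_deviation:.2f} Å\n")
        return head + self.table.to_string(index=False, float_format="%.2f")


def validate_model(
    model: ModelCoordinates,
    restraint_set: RestraintSet,
    threshold: float = 5.0,
) -> DeviationReport:
    """Check a model's Cβ–Cβ distances against a restraint set.

    A restraint is satisfied when |model distance − target| ≤ threshold.
    Missing residues raise a KeyError naming the residue.
    """
    if len(restraint_set) == 0:
        raise EmptyResultError("no restraints to validate against")
    rows = []
    for r in restraint_set.sorted():
        d = model.distance(r.segment_a, r.residue_a, r.segment_b, r.residue_b)
        dev = d - r.target
        rows.append({
            "segid_a": r.segment_a, "resid_a": r.residue_a,
            "segid_b": r.segment_b, "resid_b": r.residue_b,
            "state": r.state, "target": r.target,
            "model_distance": d, "deviation": dev,
            "satisfied": abs(dev) <= threshold,
        })
    return DeviationReport(table=pd.DataFrame(rows), threshold=threshold)


def cluster_consistency(
    models: Sequence[ModelCoordinates],
    pairs: Iterable[tuple[str, int, str, int]],
) -> tuple[pd.DataFrame, float]:
    """Spread of pair distances across cluster-representative models.

    For each (chain, residue, chain, residue) pair, the sample SD of the
    model distance across clusters; returns the per-pair table and the
    mean SD.  Requires at least two models.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("cluster consistency needs at least two cluster models")
    rows = []
    for chain_a, res_a, chain_b, res_b in pairs:
        dists = [m.distance(chain_a, res_a, chain_b, res_b) for m in models]
        rows.append({
            "segid_a": chain_a, "resid_a": res_a,
            "segid_b": chain_b, "resid_b": res_b,
            "mean_distance": float(np.mean(dists)),
            "sd": float(np.std(dists, ddof=1)),
        })
    if not rows:
        raise EmptyResultError("no pairs supplied")
    table = pd.DataFrame(rows)
    return table, float(table["sd"].mean())
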