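#!/usr/bin/env python
"""Turn state-resolved distances into docking restraints and validate.

From the fitted conformer table (ATP condition): builds the symmetric
Cβ-Cβ restraint set per state with the ±5/±7 Å bounds rule, writes the
docking-ready .tbl files plus one leave-one-probe-out dropout variant
per labelled residue, then constructs toy bead conformers satisfying the
restraint targets and cross-validates each geometry against each state's
restraint set (own state satisfied, contrasting states violated).
"""

import argparse
from pathlib import Path

import pandas as pd

from lretfit.restraints import (
    build_restraints,
    dropout_subset,
    export_restraint_table,
    validate_model,
)
from lretfit.states import records_from_table
from lretfit.synthetic import build_toy_conformers, write_conformer_pdb

ROOT = Path(__file__).resolve().parent.parent
STATES = ("closed", "partially_open", "open")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table", type=Path,
                        default=ROOT / "results" / "conformer_table.tsv")
    parser.add_argument("--condition", default="ATP")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "restraints")
    args = parser.parse_args()

    table = pd.read_csv(args.table, sep="\t")
    records = records_from_table(table[table["condition"] == args.condition])
    args.out.mkdir(parents=True, exist_ok=True)

    sets, targets = {}, {}
    for state in STATES:
        rset = build_restraints(records, state)
        sets[state] = rset
        (args.out / f"{state}.tbl").write_text(export_restraint_table(rset))
        targets[state] = {
            (r.source_pair.residue_a, r.source_pair.residue_b): r.target
            for r in rset
        }
        print(f"{state}: {len(rset)} restraints "
              f"(mirror-symmetric: {rset.is_mirror_symmetric()})")
        residues = sorted({r for pair in targets[state] for r in pair})
        for res in residues:
            sub = dropout_subset(rset, res)
            (args.out / f"{state}_drop{res}.tbl").write_text(
                export_restraint_table(sub)
            )
        print(f"  dropout variants: {residues}")

    conformers = build_toy_conformers(targets)
    print("\ncross-validation (fraction of restraints satisfied at ±5 Å):")
    header = "model".ljust(16) + "".join(s.ljust(16) for s in STATES)
    print(header)
    for model_state, (_, coords) in conformers.items():
        write_conformer_pdb(coords, args.out / f"toy_{model_state}.pdb")
        row = model_state.ljust(16)
        for restraint_state in STATES:
            rep = validate_model(coords, sets[restraint_state], threshold=5.0)
            row += f"{rep.fraction_satisfied:.0%}".ljust(16)
        print(row)
    print(f"\nrestraint files and toy-conformer PDBs written to {args.out}")


if __name__ == "__main__":
    main()
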