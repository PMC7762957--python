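#!/usr/bin/env python
"""Specificity-subsite mapping on a synthetic ligand site.

Builds a six-ring ligand with sulfate-like substituents, a catalytic
histidine facing ring position 6, and a shell of residues planted at
known distances; maps subsites A-F with the 6 A rule and reports the
recovered contacts against the planted ground truth.  Writes
results/subsite_contacts.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from phytomotion.active_site import map_subsites
from phytomotion.structure_io import extract_ligands
from phytomotion.synthetic_data import SyntheticSiteSpec, make_ligand_site

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    spec = SyntheticSiteSpec(
        shell_residues=[
            ("ALA", 1, 4.0), ("SER", 2, 5.5), ("LYS", 3, 3.0),
            ("GLU", 4, 5.9), ("THR", 5, 4.5), ("ASP", 6, 6.05),
        ],
        his_subsite=6,
    )
    model, gt = make_ligand_site(spec)
    ligand = extract_ligands(model, "IHS")[0]
    smap = map_subsites(model, ligand, gt.catalytic_his, cutoff=6.0)
    planted = {(str(r), lab): d for r, lab, d in gt.planted}
    rows = []
    for lab in "ABCDEF":
        entry = smap.entries[lab]
        for ref, dmin, dside in entry.contact_residues:
            rows.append(
                {
                    "subsite": lab,
                    "ring_position": entry.ring_position,
                    "residue": str(ref),
                    "res_name": model.find(ref).name,
                    "min_distance_A": round(dmin, 2),
                    "planted_distance_A": planted.get((str(ref), lab), ""),
                }
            )
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "subsite_contacts.csv", index=False)
    n_recovered = sum(
        ref in smap.contacts(lab) for ref, lab, d in gt.planted if d <= 6.0
    )
    n_in = sum(1 for *_, d in gt.planted if d <= 6.0)
    print(frame.to_string(index=False))
    print(
        f"recovered {n_recovered}/{n_in} planted in-cutoff contacts; "
        f"the 6.05 A planting is excluded at the 6.0 A cutoff; "
        f"label anchor holds (A=6 -> E=2: E is ring position "
        f"{smap.entries['E'].ring_position})"
    )
    print(f"table written to {OUT / 'subsite_contacts.csv'}")


if __name__ == "__main__":
    sys.exit(main())
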