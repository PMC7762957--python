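"""Active-site analytics: specificity-subsite mapping around a bound
six-ring ligand, contact and disulfide detection, and per-residue
displacement classification between conformational states.

Subsite convention: the six substituent groups of the bound ligand define
six specificity pockets.  Pocket A holds the analog of the scissile
phosphate — the substituent whose central S/P atom is nearest the
catalytic histidine's imidazole nitrogens.  The remaining pockets are
labelled B-F following cyclically decreasing ring-position order from A,
an orientation-free restatement of the counterclockwise convention used
when viewing the ring from behind toward the catalytic centre (A at ring
position 6 therefore puts the axial 2-substituent in pocket E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .rigid_geometry import apply, superpose
from .structure_io import (
    AtomRecord,
    LigandGroup,
    MAINCHAIN_ATOMS,
    MalformedLigandError,
    Residue,
    ResidueRef,
    Selection,
    StructureModel,
    select_atoms,
)

__all__ = [
    "SubsiteMap",
    "SubsiteEntry",
    "ContactRecord",
    "DisplacementTable",
    "map_subsites",
    "min_distance",
    "find_disulfides",
    "polar_contacts",
    "displacement_table",
    "compare_subsites",
]


class MalformedResidueError(ValueError):
    pass


class SelectionError(ValueError):
    pass


@dataclass
class ContactRecord:
    partner_1: tuple[ResidueRef, str]  # (residue, atom name)
    partner_2: tuple[ResidueRef, str]
    distance: float
    kind: str = "any"  # any | polar | disulfide


@dataclass
class SubsiteEntry:
    ring_position: int
    substituent_atoms: list[AtomRecord]
    #: (residue, min heavy-atom distance, side-chain-only distance or None)
    contact_residues: list[tuple[ResidueRef, float, float | None]]
    conformer: str


@dataclass
class SubsiteMap:
    entries: dict[str, SubsiteEntry]  # label A-F
    catalytic_his: ResidueRef
    cutoff: float
    conformer: str

    def contacts(self, label: str) -> list[ResidueRef]:
        return [r for r, _, _ in self.entries[label].contact_residues]


@dataclass
class DisplacementRow:
    ref: ResidueRef
    ca_displacement: float
    max_mainchain_displacement: float
    displacement_class: str  # lt2 | 2to4 | gt4


@dataclass
class DisplacementTable:
    rows: list[DisplacementRow]
    fixed_domain_rmsd: float

    def row(self, ref: ResidueRef) -> DisplacementRow:
        for r in self.rows:
            if r.ref == ref:
                return r
        raise LookupError(f"residue {ref} not in displacement table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [r.ref.chain_id for r in self.rows],
                "resi": [r.ref.seq_number for r in self.rows],
                "icode": [r.ref.insertion_code for r in self.rows],
                "res_name": [r.ref.res_name for r in self.rows],
                "ca_displacement": [r.ca_displacement for r in self.rows],
                "max_mainchain_displacement": [
                    r.max_mainchain_displacement for r in self.rows
                ],
                "class": [r.displacement_class for r in self.rows],
            }
        )


# ---------------------------------------------------------------------------
# subsite mapping


def _heavy(atoms: list[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if not a.is_hydrogen]


def _conformer_atoms(res: Residue, conformer: str) -> list[AtomRecord]:
    """Residue atoms paired with a ligand conformer: matching altloc label
    when present, else the highest-occupancy copy per atom name."""
    atoms = _heavy(res.atoms)
    if conformer and any(a.altloc == conformer for a in atoms):
        return [a for a in atoms if a.altloc in ("", conformer)]
    best: dict[str, AtomRecord] = {}
    for a in atoms:
        cur = best.get(a.name)
        if cur is None or a.occupancy > cur.occupancy:
            best[a.name] = a
    return list(best.values())


def map_subsites(
    model: StructureModel,
    ligand: LigandGroup,
    catalytic_his: ResidueRef,
    cutoff: float = 6.0,
) -> SubsiteMap:
    """Label the six substituent positions A-F and collect the residues
    within ``cutoff`` (A) of each substituent group.

    The contact rule is inclusive: any heavy atom of a polymer residue
    within the cutoff of any atom of the group (central S/P, its terminal
    O atoms, and the ring-linking O).
    """
    his = model.find(catalytic_his)
    imid = [a for a in his.atoms if a.name in ("NE2", "ND1")]
    if not imid:
        raise MalformedResidueError(
            f"catalytic histidine {catalytic_his} lacks imidazole nitrogens"
        )
    imid_coords = np.stack([a.coords for a in imid])

    # subsite A: substituent central atom nearest the imidazole nitrogens
    dists = {}
    for pos in range(1, 7):
        if not ligand.substituents.get(pos):
            raise MalformedLigandError(
                f"ring position {pos} has no substituent group"
            )
        central = ligand.central_atom(pos)
        dists[pos] = float(
            cdist(central.coords[None, :], imid_coords).min()
        )
    pos_a = min(dists, key=dists.get)
    labels = {"ABCDEF"[i]: (pos_a - 1 - i) % 6 + 1 for i in range(6)}

    lig_atom_ids = {
        id(a)
        for grp in ligand.substituents.values()
        for a in grp
    } | {id(a) for a in ligand.ring_atoms}

    entries: dict[str, SubsiteEntry] = {}
    for label, pos in labels.items():
        group = ligand.substituents[pos]
        gcoords = np.stack([a.coords for a in group])
        contacts: list[tuple[ResidueRef, float, float | None]] = []
        for res in model.residues(het=False):
            atoms = [
                a
                for a in _conformer_atoms(res, ligand.conformer)
                if id(a) not in lig_atom_ids
            ]
            if not atoms:
                continue
            acoords = np.stack([a.coords for a in atoms])
            dmat = cdist(acoords, gcoords)
            dmin = float(dmat.min())
            if dmin <= cutoff:
                side = [
                    i
                    for i, a in enumerate(atoms)
                    if a.name not in MAINCHAIN_ATOMS
                ]
                dside = float(dmat[side].min()) if side else None
                contacts.append((res.ref, dmin, dside))
        contacts.sort(key=lambda c: c[0])
        entries[label] = SubsiteEntry(
            ring_position=pos,
            substituent_atoms=list(group),
            contact_residues=contacts,
            conformer=ligand.conformer,
        )
    return SubsiteMap(
        entries=entries,
        catalytic_his=catalytic_his,
        cutoff=cutoff,
        conformer=ligand.conformer,
    )


# ---------------------------------------------------------------------------
# distances and contacts


def min_distance(
    model: StructureModel,
    selection_a: Selection,
    selection_b: Selection,
    side_chain_only: bool = False,
) -> tuple[float, tuple[ResidueRef, str], tuple[ResidueRef, str]]:
    """Minimum heavy-atom distance between two selections and the achieving
    atom pair.  ``side_chain_only`` drops N, CA, C, O from both sides."""
    atoms_a = select_atoms(model, selection_a)
    atoms_b = select_atoms(model, selection_b)
    if side_chain_only:
        atoms_a = [(r, a) for r, a in atoms_a if a.name not in MAINCHAIN_ATOMS]
        atoms_b = [(r, a) for r, a in atoms_b if a.name not in MAINCHAIN_ATOMS]
    if not atoms_a or not atoms_b:
        raise SelectionError("empty selection in min_distance")
    ca = np.stack([a.coords for _, a in atoms_a])
    cb = np.stack([a.coords for _, a in atoms_b])
    d = cdist(ca, cb)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    ra, aa = atoms_a[i]
    rb, ab = atoms_b[j]
    return float(d[i, j]), (ra, aa.name), (rb, ab.name)


def find_disulfides(
    model: StructureModel, sg_cutoff: float = 2.3
) -> list[ContactRecord]:
    """All cysteine SG-SG pairs within ``sg_cutoff`` (A), each pair once."""
    sgs: list[tuple[ResidueRef, AtomRecord]] = []
    for res in model.residues(het=False):
        if res.name != "CYS":
            continue
        sg = res.atom("SG")
        if sg is not None:
            sgs.append((res.ref, sg))
    out = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1].coords - sgs[j][1].coords))
            if d <= sg_cutoff:
                out.append(
                    ContactRecord(
                        partner_1=(sgs[i][0], "SG"),
                        partner_2=(sgs[j][0], "SG"),
                        distance=d,
                        kind="disulfide",
                    )
                )
    return out


def polar_contacts(
    model: StructureModel,
    sel_a: Selection,
    sel_b: Selection,
    cutoff: float = 3.5,
) -> list[ContactRecord]:
    """N/O...N/O heavy-atom pairs within ``cutoff`` between two selections,
    deduplicated (a pair is reported once even when the selections
    overlap)."""
    atoms_a = [
        (r, a)
        for r, a in select_atoms(model, sel_a)
        if a.element in ("N", "O")
    ]
    atoms_b = [
        (r, a)
        for r, a in select_atoms(model, sel_b)
        if a.element in ("N", "O")
    ]
    seen = set()
    out = []
    for ra, aa in atoms_a:
        for rb, ab in atoms_b:
            if (ra, aa.name, aa.altloc) == (rb, ab.name, ab.altloc):
                continue
            key = frozenset([(ra, aa.name, aa.altloc), (rb, ab.name, ab.altloc)])
            if key in seen:
                continue
            d = float(np.linalg.norm(aa.coords - ab.coords))
            if d <= cutoff:
                seen.add(key)
                out.append(
                    ContactRecord(
                        partner_1=(ra, aa.name),
                        partner_2=(rb, ab.name),
                        distance=d,
                        kind="polar",
                    )
                )
    out.sort(key=lambda c: (c.partner_1[0], c.partner_1[1], c.distance))
    return out


# ---------------------------------------------------------------------------
# displacement classification


def displacement_table(
    model_a: StructureModel,
    model_b: StructureModel,
    fixed_domain: set[ResidueRef],
) -> DisplacementTable:
    """Per-residue displacement between two states after superposing on the
    fixed-domain C-alpha set; classes cut at 2.0 and 4.0 A on the
    C-alpha metric."""
    if not fixed_domain:
        raise ValueError("fixed_domain must be non-empty")
    pairs: dict[ResidueRef, tuple[Residue, Residue]] = {}
    for chain in model_a.chain_ids:
        if chain not in model_b.chains:
            continue
        by_key_b = {
            (r.ref.seq_number, r.ref.insertion_code): r
            for r in model_b.polymer(chain)
        }
        for res_a in model_a.polymer(chain):
            key = (res_a.ref.seq_number, res_a.ref.insertion_code)
            if key in by_key_b:
                pairs[res_a.ref] = (res_a, by_key_b[key])
    fit_refs = sorted(r for r in fixed_domain if r in pairs)
    fit_pairs = [
        (pairs[r][0].atom("CA"), pairs[r][1].atom("CA")) for r in fit_refs
    ]
    fit_pairs = [(a, b) for a, b in fit_pairs if a is not None and b is not None]
    if len(fit_pairs) < 3:
        raise ValueError("insufficient fixed-domain Ca pairing")
    fa = np.stack([a.coords for a, _ in fit_pairs])
    fb = np.stack([b.coords for _, b in fit_pairs])
    t, rmsd = superpose(fa, fb)

    rows = []
    for ref in sorted(pairs):
        res_a, res_b = pairs[ref]
        disp = {}
        for name in MAINCHAIN_ATOMS:
            aa = res_a.atom(name)
            ab = res_b.atom(name)
            if aa is None or ab is None:
                continue
            moved = apply(t, aa.coords[None, :])[0]
            disp[name] = float(np.linalg.norm(moved - ab.coords))
        if "CA" not in disp:
            continue
        ca_d = disp["CA"]
        cls = "lt2" if ca_d < 2.0 else ("2to4" if ca_d <= 4.0 else "gt4")
        rows.append(
            DisplacementRow(
                ref=ref,
                ca_displacement=ca_d,
                max_mainchain_displacement=max(disp.values()),
                displacement_class=cls,
            )
        )
    return DisplacementTable(rows=rows, fixed_domain_rmsd=rmsd)


# ---------------------------------------------------------------------------
# cross-structure subsite comparison


def compare_subsites(maps: list[SubsiteMap]) -> pd.DataFrame:
    """Per-subsite residue counts and shared/unique identities across maps.

    Returns one row per (subsite label, map index) with the residues the
    map places in that subsite, those shared with every other map, and
    those unique to it.
    """
    if len(maps) < 2:
        raise ValueError("need >= 2 subsite maps to compare")
    rows = []
    for label in "ABCDEF":
        sets = [
            {str(r) for r in m.contacts(label)} if label in m.entries else set()
            for m in maps
        ]
        shared = set.intersection(*sets)
        for i, s in enumerate(sets):
            others = set.union(*(sets[:i] + sets[i + 1 :]))
            rows.append(
                {
                    "subsite": label,
                    "map": i,
                    "n_residues": len(s),
                    "residues": ",".join(sorted(s)),
                    "shared": ",".join(sorted(shared)),
                    "unique": ",".join(sorted(s - others)),
                }
            )
    return pd.DataFrame(rows)
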