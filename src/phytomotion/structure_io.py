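"""Reading, writing and atom selection for macromolecular structures.

gemmi does the actual PDB/mmCIF parsing and PDB writing; this module
flattens its hierarchy into small plain dataclasses keyed by *author*
residue numbering, which is the coordinate system used throughout the
package (His-45, residues 257-300, ...).  Alternate locations (altlocs) and
occupancies are preserved because disordered ligand conformers carry the
information of interest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "Residue",
    "StructureModel",
    "LigandGroup",
    "Selection",
    "StructureParseError",
    "UnknownFormatError",
    "ComponentNotFoundError",
    "MalformedLigandError",
    "read_structure",
    "write_structure",
    "select_atoms",
    "parse_selection",
    "extract_ligands",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_NAMES = {"HOH", "WAT", "DOD"}
MAINCHAIN_ATOMS = ("N", "CA", "C", "O")

#: ring-carbon atom names per chemical component, in ring-position order
#: 1-6.  Components not listed fall back to six-cycle detection on the
#: covalent-distance graph.
RING_ATOM_TABLE: dict[str, tuple[str, ...]] = {
    # myo-inositol hexakissulfate / hexakisphosphate; orthophosphate has no
    # ring and is deliberately absent
    "IHS": ("C1", "C2", "C3", "C4", "C5", "C6"),
    "IHP": ("C1", "C2", "C3", "C4", "C5", "C6"),
    "I6S": ("C1", "C2", "C3", "C4", "C5", "C6"),
}

COVALENT_CUTOFF = 1.8  # A, bond if closer


class StructureParseError(ValueError):
    pass


class UnknownFormatError(ValueError):
    pass


class ComponentNotFoundError(KeyError):
    pass


class MalformedLigandError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    altloc: str  # "" when not alternate
    occupancy: float
    bfactor: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float).reshape(3)
        object.__setattr__(self, "coords", c)
        if not np.all(np.isfinite(c)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0 + 1e-6:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass(frozen=True, order=True)
class ResidueRef:
    chain_id: str
    seq_number: int
    insertion_code: str = ""
    res_name: str = field(default="", compare=False)

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"


@dataclass
class Residue:
    ref: ResidueRef
    atoms: list[AtomRecord]
    is_het: bool = False

    @property
    def name(self) -> str:
        return self.ref.res_name

    def atom(self, name: str, altloc: str | None = None) -> AtomRecord | None:
        """First atom with this name; highest occupancy among altlocs unless
        a specific altloc is requested."""
        hits = [a for a in self.atoms if a.name == name]
        if altloc is not None:
            hits = [a for a in hits if a.altloc in ("", altloc)]
        if not hits:
            return None
        return max(hits, key=lambda a: (a.occupancy, a.altloc == ""))


@dataclass
class StructureModel:
    id: str
    chains: dict[str, list[Residue]]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def polymer(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise LookupError(f"chain {chain_id!r} not in model {self.id}")
        return [r for r in self.chains[chain_id] if not r.is_het]

    @property
    def het_components(self) -> list[Residue]:
        return [r for rs in self.chains.values() for r in rs if r.is_het]

    def residues(self, het: bool = False) -> list[Residue]:
        return [
            r for rs in self.chains.values() for r in rs if r.is_het == het
        ]

    def find(self, ref: ResidueRef) -> Residue:
        for r in self.chains.get(ref.chain_id, []):
            if (
                r.ref.seq_number == ref.seq_number
                and r.ref.insertion_code == ref.insertion_code
            ):
                return r
        raise LookupError(f"residue {ref} not found in model {self.id}")


@dataclass
class LigandGroup:
    """One conformer of a six-ring ligand with per-position substituents."""

    component_id: str
    conformer: str
    ring_atoms: list[AtomRecord]  # ordered by ring position 1..6
    substituents: dict[int, list[AtomRecord]]  # ring position -> group atoms
    occupancy: float

    def central_atom(self, position: int) -> AtomRecord:
        for a in self.substituents[position]:
            if a.element in ("S", "P"):
                return a
        raise MalformedLigandError(
            f"substituent at ring position {position} has no S/P atom"
        )


# ---------------------------------------------------------------------------
# reading / writing


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Author numbering, altlocs and occupancies are preserved; waters,
    ligands and other non-polymer residues are flagged as het components.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".cif", ".mmcif"):
            fmt = "mmcif"
        elif suffix in (".pdb", ".ent"):
            fmt = "pdb"
        else:
            fmt = "detect"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "detect":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise UnknownFormatError(f"unknown structure format {format!r}")
    except UnknownFormatError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError with line context
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise StructureParseError(f"{path}: no atom records found")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            atoms = [
                AtomRecord(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name,
                    altloc=a.altloc if a.altloc != "\0" else "",
                    occupancy=float(a.occ),
                    bfactor=float(a.b_iso),
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                )
                for a in res
            ]
            name = res.name.strip()
            is_het = (
                name in WATER_NAMES
                or res.het_flag == "H"
                or name not in STANDARD_AA
            )
            icode = res.seqid.icode.strip()
            ref = ResidueRef(chain.name, res.seqid.num, icode, name)
            residues.append(Residue(ref=ref, atoms=atoms, is_het=is_het))
        chains.setdefault(chain.name, []).extend(residues)
    return StructureModel(id=path.stem, chains=chains)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model as PDB (wwPDB v3.3 columns, via gemmi)."""
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gc = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.ref.seq_number, res.ref.insertion_code or " ")
            gr.het_flag = "H" if res.is_het else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.altloc = a.altloc or "\0"
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                ga.serial = a.serial
                ga.pos = gemmi.Position(*a.coords)
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)


# ---------------------------------------------------------------------------
# selection


@dataclass
class Selection:
    """Declarative atom selection.

    ``altloc_policy`` is ``"all"``, ``"highest_occupancy"``, or a specific
    altloc label (which also admits non-alternate atoms).
    """

    chains: list[str] | None = None
    residue_ranges: list[tuple[int, int]] | None = None
    atom_names: list[str] | None = None
    elements: list[str] | None = None
    altloc_policy: str = "all"
    include_het: bool = False
    exclude_hydrogens: bool = True


_SEL_TOKEN = re.compile(
    r"(chain\s+(?P<chain>\S+))|(resi\s+(?P<resi>[\d\-,]+))"
    r"|(name\s+(?P<name>\S+))|(elem\s+(?P<elem>\S+))|(altloc\s+(?P<altloc>\S+))"
    r"|(?P<het>het)"
)


def parse_selection(text: str) -> Selection:
    """Parse a CLI selection string, e.g. ``chain A and resi 257-300 and
    name CA``.  Clauses are joined by ``and``; comma lists are unions."""
    sel = Selection()
    for clause in re.split(r"\s+and\s+", text.strip()):
        m = _SEL_TOKEN.fullmatch(clause.strip())
        if not m:
            raise ValueError(f"cannot parse selection clause {clause!r}")
        if m.group("chain"):
            sel.chains = (sel.chains or []) + m.group("chain").split(",")
        elif m.group("resi"):
            ranges = sel.residue_ranges or []
            for part in m.group("resi").split(","):
                if "-" in part[1:]:
                    lo, hi = part.rsplit("-", 1)
                    ranges.append((int(lo), int(hi)))
                else:
                    ranges.append((int(part), int(part)))
            sel.residue_ranges = ranges
        elif m.group("name"):
            sel.atom_names = (sel.atom_names or []) + m.group("name").split(",")
        elif m.group("elem"):
            sel.elements = (sel.elements or []) + m.group("elem").split(",")
        elif m.group("altloc"):
            sel.altloc_policy = m.group("altloc")
        elif m.group("het"):
            sel.include_het = True
    return sel


def select_atoms(
    model: StructureModel, selection: Selection
) -> list[tuple[ResidueRef, AtomRecord]]:
    """Resolve a selection into a deterministically ordered atom list.

    Order is (chain, seq_number, insertion_code, atom name, altloc).  With
    ``altloc_policy="highest_occupancy"`` exactly one copy per atom name is
    kept.
    """
    if selection.chains is not None:
        for c in selection.chains:
            if c not in model.chains:
                raise LookupError(f"chain {c!r} not in model {model.id}")
    out: list[tuple[ResidueRef, AtomRecord]] = []
    for chain_id in sorted(model.chains):
        if selection.chains is not None and chain_id not in selection.chains:
            continue
        for res in model.chains[chain_id]:
            if res.is_het and not selection.include_het:
                continue
            if selection.residue_ranges is not None and not any(
                lo <= res.ref.seq_number <= hi
                for lo, hi in selection.residue_ranges
            ):
                continue
            atoms = res.atoms
            if selection.atom_names is not None:
                atoms = [a for a in atoms if a.name in selection.atom_names]
            if selection.elements is not None:
                atoms = [a for a in atoms if a.element in selection.elements]
            if selection.exclude_hydrogens:
                atoms = [a for a in atoms if not a.is_hydrogen]
            atoms = _apply_altloc_policy(atoms, selection.altloc_policy)
            atoms = sorted(atoms, key=lambda a: (a.name, a.altloc))
            out.extend((res.ref, a) for a in atoms)
    return out


def _apply_altloc_policy(
    atoms: list[AtomRecord], policy: str
) -> list[AtomRecord]:
    if policy == "all":
        return list(atoms)
    if policy == "highest_occupancy":
        best: dict[str, AtomRecord] = {}
        for a in atoms:
            cur = best.get(a.name)
            if cur is None or (a.occupancy, cur.altloc != "") > (
                cur.occupancy,
                a.altloc != "",
            ):
                best[a.name] = a
        return list(best.values())
    # a specific label: keep non-alternate atoms plus that conformer
    return [a for a in atoms if a.altloc in ("", policy)]


def coords_of(atoms: list[tuple[ResidueRef, AtomRecord]]) -> np.ndarray:
    """(N, 3) coordinate array of a selected atom list."""
    if not atoms:
        return np.zeros((0, 3))
    return np.stack([a.coords for _, a in atoms])


# ---------------------------------------------------------------------------
# ligand extraction


def extract_ligands(
    model: StructureModel, component_id: str
) -> list[LigandGroup]:
    """Extract every altloc conformer of a six-ring ligand component.

    Ring order follows the component's C1..C6 atom naming when the
    component is in :data:`RING_ATOM_TABLE` (or uses those names anyway);
    otherwise the six-membered carbon ring is inferred by cycle detection
    on the covalent-distance graph (bond if < 1.8 A) with an arbitrary but
    deterministic starting position.
    """
    residues = [r for r in model.het_components if r.name == component_id]
    if not residues:
        raise ComponentNotFoundError(
            f"component {component_id!r} not among het residues of {model.id}"
        )
    groups: list[LigandGroup] = []
    for res in residues:
        altlocs = sorted({a.altloc for a in res.atoms if a.altloc})
        conformers = altlocs or [""]
        for label in conformers:
            atoms = [a for a in res.atoms if a.altloc in ("", label)]
            groups.append(_build_group(component_id, label, atoms))
    return groups


def _build_group(
    component_id: str, label: str, atoms: list[AtomRecord]
) -> LigandGroup:
    ring_names = RING_ATOM_TABLE.get(component_id)
    by_name = {a.name: a for a in atoms}
    ring: list[AtomRecord] | None = None
    if ring_names is not None or all(
        f"C{i}" in by_name for i in range(1, 7)
    ):
        names = ring_names or ("C1", "C2", "C3", "C4", "C5", "C6")
        missing = [n for n in names if n not in by_name]
        if missing:
            raise MalformedLigandError(
                f"{component_id} conformer {label or '-'}: missing ring "
                f"atoms {missing}"
            )
        ring = [by_name[n] for n in names]
    else:
        ring = _detect_six_ring(atoms)
        if ring is None:
            raise MalformedLigandError(
                f"{component_id} conformer {label or '-'}: no six-membered "
                "carbon ring found"
            )

    substituents: dict[int, list[AtomRecord]] = {}
    for pos, ring_atom in enumerate(ring, start=1):
        substituents[pos] = _substituent_group(ring_atom, ring, atoms)
    central_occ = [
        a.occupancy
        for grp in substituents.values()
        for a in grp
        if a.element in ("S", "P")
    ]
    occupancy = float(np.median(central_occ)) if central_occ else (
        float(np.median([a.occupancy for a in atoms]))
    )
    return LigandGroup(
        component_id=component_id,
        conformer=label,
        ring_atoms=ring,
        substituents=substituents,
        occupancy=occupancy,
    )


def _bonded(a: AtomRecord, b: AtomRecord) -> bool:
    return float(np.linalg.norm(a.coords - b.coords)) < COVALENT_CUTOFF


def _substituent_group(
    ring_atom: AtomRecord, ring: list[AtomRecord], atoms: list[AtomRecord]
) -> list[AtomRecord]:
    """Walk ring carbon -> linking O -> central S/P -> terminal O atoms."""
    ring_ids = {id(a) for a in ring}
    linking = [
        a
        for a in atoms
        if id(a) not in ring_ids
        and a.element == "O"
        and _bonded(a, ring_atom)
    ]
    group: list[AtomRecord] = []
    for link in linking:
        centrals = [
            a
            for a in atoms
            if a.element in ("S", "P") and _bonded(a, link)
        ]
        if not centrals:
            continue  # e.g. a free hydroxyl
        central = centrals[0]
        terminals = [
            a
            for a in atoms
            if a.element == "O" and id(a) != id(link) and _bonded(a, central)
        ]
        group = [link, central, *terminals]
        break
    return group


def _detect_six_ring(atoms: list[AtomRecord]) -> list[AtomRecord] | None:
    """Find a six-membered carbon cycle in the covalent-distance graph and
    return it in connectivity order, deterministic start."""
    carbons = [a for a in atoms if a.element == "C"]
    adj: dict[int, list[int]] = {i: [] for i in range(len(carbons))}
    for i in range(len(carbons)):
        for j in range(i + 1, len(carbons)):
            if _bonded(carbons[i], carbons[j]):
                adj[i].append(j)
                adj[j].append(i)
    n = len(carbons)
    for start in range(n):
        path = [start]
        found = _dfs_cycle(start, start, adj, path, set([start]))
        if found is not None and len(found) == 6:
            # deterministic: start from the lowest serial, walk toward the
            # lower-serial neighbour
            serials = [carbons[i].serial for i in found]
            k = serials.index(min(serials))
            rot = found[k:] + found[:k]
            if carbons[rot[1]].serial > carbons[rot[-1]].serial:
                rot = [rot[0]] + rot[:0:-1]
            return [carbons[i] for i in rot]
    return None


def _dfs_cycle(start, cur, adj, path, seen):
    if len(path) == 6:
        return path[:] if start in adj[cur] else None
    for nxt in adj[cur]:
        if nxt not in seen:
            path.append(nxt)
            seen.add(nxt)
            res = _dfs_cycle(start, nxt, adj, path, seen)
            if res is not None:
                return res
            path.pop()
            seen.remove(nxt)
    return None
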