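"""Seeded generators for structures, ligand sites and sequences with known
ground truth.

The generators emulate, at desk scale, the three kinds of input the
pipeline analyses:

* a two-rigid-body protein joined at a hinge, before/after a known screw
  motion with optional Gaussian coordinate noise (stands in for the
  apo/ligand-bound snapshot pairs);
* a six-membered ring ligand carrying six sulfate-like substituent groups
  inside a shell of residues at controlled distances (stands in for the
  inositol-hexakissulfate complex);
* protein sequence families with planted signature motifs and insertions
  of controlled length and cysteine content (stands in for the U-loop
  families).

Every generator is a pure, seeded function of its spec: the same spec
yields byte-identical file output, and the returned ground truth uses the
same types as the analysis outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rigid_geometry import RigidTransform, ScrewMotion, apply, from_screw
from .structure_io import AtomRecord, Residue, ResidueRef, StructureModel

__all__ = [
    "SyntheticMotionSpec",
    "SyntheticSiteSpec",
    "SyntheticSeqSpec",
    "MotionGroundTruth",
    "SiteGroundTruth",
    "SeqGroundTruth",
    "make_motion_pair",
    "make_closure_pair",
    "make_ligand_site",
    "make_uloop_family",
]

# Ca-Ca virtual bond length along the chain
_CA_SPACING = 3.8


class SpecValidationError(ValueError):
    pass


class PlacementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# motion pairs


@dataclass
class SyntheticMotionSpec:
    # proportioned like a phytase fixed core vs its moving lid, at reduced
    # scale: the larger body is the fixed domain
    n_fixed: int = 120
    n_moving: int = 90
    hinge_axis: np.ndarray | None = None  # None -> seeded random unit vector
    hinge_point: np.ndarray | None = None  # None -> junction Ca
    angle: float = 20.0  # degrees
    pitch: float = 0.0  # A along axis
    noise_sigma: float = 0.0  # A
    seed: int = 0
    chain_id: str = "A"

    def validate(self, min_body: int = 25) -> None:
        if not 0.0 <= self.angle <= 180.0:
            raise SpecValidationError("angle must be in [0, 180] degrees")
        if self.n_fixed < min_body or self.n_moving < min_body:
            raise SpecValidationError(
                f"bodies need >= {min_body} residues "
                f"(got {self.n_fixed}, {self.n_moving})"
            )
        if self.noise_sigma < 0:
            raise SpecValidationError("noise_sigma must be >= 0")


@dataclass
class MotionGroundTruth:
    screw: ScrewMotion
    transform: RigidTransform  # applied to the moving body (A -> B)
    labels: dict[ResidueRef, str]  # "fixed" | "moving"
    junction: tuple[int, int]  # (last fixed seq number, first moving)


def _spherical_spiral(n: int) -> np.ndarray:
    """Ca trace of a compact globular body: a spiral wound over a sphere
    with protein-like packing density, 3.8 A between consecutive Ca.

    The sphere radius follows the ~1.07 sqrt(n) A scaling that makes the
    spiral spacing match typical domain dimensions; being genuinely
    three-dimensional, the body constrains rotations about every axis
    (a thin straight helix would not).
    """
    radius = 1.07 * np.sqrt(n)
    needed = _CA_SPACING * (n - 1)
    th_lo, th_hi = 0.12 * np.pi, 0.88 * np.pi
    th = np.linspace(th_lo, th_hi, 20000)

    def curve_length(k: float) -> np.ndarray:
        # arc length element of (theta, phi = k*theta) on the sphere
        ds = radius * np.sqrt(1.0 + (k * np.sin(th)) ** 2)
        return np.concatenate([[0.0], np.cumsum(ds[1:] * np.diff(th))])

    k_lo, k_hi = 0.5, 400.0
    for _ in range(60):
        k = 0.5 * (k_lo + k_hi)
        if curve_length(k)[-1] < needed * 1.02:
            k_lo = k
        else:
            k_hi = k
    arc = curve_length(k)
    targets = np.linspace(0.0, min(needed, arc[-1] - 1e-9), n)
    th_i = np.interp(targets, arc, th)
    phi_i = k * th_i
    return radius * np.stack(
        [
            np.sin(th_i) * np.cos(phi_i),
            np.sin(th_i) * np.sin(phi_i),
            np.cos(th_i),
        ],
        axis=1,
    )


def _align_unit(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def _two_body_ca(n_fixed: int, n_moving: int) -> np.ndarray:
    """Two tangent globular bodies; the chain runs body 1 then body 2 with
    the connecting termini facing each other across the hinge gap."""
    body1 = _spherical_spiral(n_fixed)
    body2 = _spherical_spiral(n_moving)
    x = np.array([1.0, 0.0, 0.0])
    # orient body 1 so its C-terminal Ca points toward +x, body 2 so its
    # N-terminal Ca points toward -x, then join them along x
    body1 = body1 @ _align_unit(body1[-1] / np.linalg.norm(body1[-1]), x).T
    body2 = body2 @ _align_unit(body2[0] / np.linalg.norm(body2[0]), -x).T
    d = body1[-1, 0] - body2[0, 0] + _CA_SPACING
    return np.vstack([body1, body2 + d * x])


def _backbone_from_ca(ca: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Place dummy N, C, O around each Ca using local chain frames."""
    n = len(ca)
    out = []
    for i in range(n):
        prev_ = ca[max(i - 1, 0)]
        next_ = ca[min(i + 1, n - 1)]
        t = next_ - prev_
        tn = np.linalg.norm(t)
        t = t / tn if tn > 1e-9 else np.array([0.0, 0.0, 1.0])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(t @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(t, ref)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        out.append(
            {
                "N": ca[i] - 1.46 * t + 0.3 * u,
                "CA": ca[i],
                "C": ca[i] + 1.52 * t + 0.3 * u,
                "O": ca[i] + 1.52 * t + 0.3 * u + 1.23 * v,
            }
        )
    return out


def _residues_from_backbone(
    backbone: list[dict[str, np.ndarray]],
    chain_id: str,
    start_seq: int = 1,
    res_name: str = "GLY",
) -> list[Residue]:
    residues = []
    serial = 1
    for i, atoms in enumerate(backbone):
        ref = ResidueRef(chain_id, start_seq + i, "", res_name)
        recs = []
        for name in ("N", "CA", "C", "O"):
            recs.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=name[0],
                    altloc="",
                    occupancy=1.0,
                    bfactor=20.0,
                    coords=atoms[name],
                )
            )
            serial += 1
        residues.append(Residue(ref=ref, atoms=recs, is_het=False))
    return residues


def _model_from_coords(
    spec: SyntheticMotionSpec, coords_per_res: list[dict[str, np.ndarray]], mid: str
) -> StructureModel:
    residues = _residues_from_backbone(coords_per_res, spec.chain_id)
    return StructureModel(id=mid, chains={spec.chain_id: residues})


def make_motion_pair(
    spec: SyntheticMotionSpec,
) -> tuple[StructureModel, StructureModel, MotionGroundTruth]:
    """Two-body structure pair related by a known screw on the second body.

    Model A is the generated backbone; model B applies the screw to the
    moving body only, then Gaussian noise (``noise_sigma``) is added to both
    models independently.  The generating screw is the exact ground truth of
    the noiseless signal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_fixed + spec.n_moving
    ca = _two_body_ca(spec.n_fixed, spec.n_moving)
    axis = spec.hinge_axis
    if axis is None:
        axis = rng.standard_normal(3)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    point = (
        np.asarray(spec.hinge_point, dtype=float)
        if spec.hinge_point is not None
        else 0.5 * (ca[spec.n_fixed - 1] + ca[spec.n_fixed])
    )
    screw = ScrewMotion(axis, point, spec.angle, spec.pitch)
    transform = from_screw(screw)

    backbone_a = _backbone_from_ca(ca)
    backbone_b = [
        {k: v.copy() for k, v in res.items()} for res in backbone_a
    ]
    for i in range(spec.n_fixed, n):
        for k in backbone_b[i]:
            backbone_b[i][k] = apply(transform, backbone_b[i][k][None, :])[0]
    if spec.noise_sigma > 0:
        for backbone in (backbone_a, backbone_b):
            for res in backbone:
                for k in res:
                    res[k] = res[k] + rng.normal(0, spec.noise_sigma, 3)

    model_a = _model_from_coords(spec, backbone_a, f"synth_a_seed{spec.seed}")
    model_b = _model_from_coords(spec, backbone_b, f"synth_b_seed{spec.seed}")
    labels = {}
    for i in range(n):
        ref = ResidueRef(spec.chain_id, i + 1, "", "GLY")
        labels[ref] = "fixed" if i < spec.n_fixed else "moving"
    gt = MotionGroundTruth(
        screw=screw,
        transform=transform,
        labels=labels,
        junction=(spec.n_fixed, spec.n_fixed + 1),
    )
    return model_a, model_b, gt


def make_closure_pair(
    spec: SyntheticMotionSpec,
    mode: str = "pure_closure",
    axis_angle_deg: float | None = None,
) -> tuple[StructureModel, StructureModel, MotionGroundTruth]:
    """Motion pair with the hinge axis at a controlled angle to the line
    joining the two body centroids.

    ``pure_closure`` places the axis perpendicular to the inter-centroid
    line (expected percent closure 100), ``pure_twist`` along it (expected
    0); ``oblique`` uses ``axis_angle_deg`` (expected ``100 sin^2``).  The
    axis passes through the moving-body centroid so the centroid line is
    unchanged by the motion and the expectation is exact by construction.
    """
    spec.validate()
    ca = _two_body_ca(spec.n_fixed, spec.n_moving)
    c_fixed = ca[: spec.n_fixed].mean(axis=0)
    c_moving = ca[spec.n_fixed :].mean(axis=0)
    line = c_moving - c_fixed
    line /= np.linalg.norm(line)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(line @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(line, ref)
    perp /= np.linalg.norm(perp)
    if mode == "pure_closure":
        axis = perp
    elif mode == "pure_twist":
        axis = line
    elif mode == "oblique":
        if axis_angle_deg is None:
            raise SpecValidationError("oblique mode needs axis_angle_deg")
        th = np.radians(axis_angle_deg)
        axis = np.cos(th) * line + np.sin(th) * perp
    else:
        raise SpecValidationError(f"unknown closure mode {mode!r}")
    derived = SyntheticMotionSpec(
        n_fixed=spec.n_fixed,
        n_moving=spec.n_moving,
        hinge_axis=axis,
        hinge_point=c_moving,
        angle=spec.angle,
        pitch=spec.pitch,
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
        chain_id=spec.chain_id,
    )
    return make_motion_pair(derived)


# ---------------------------------------------------------------------------
# ligand sites


@dataclass
class SyntheticSiteSpec:
    ring_radius: float = 1.45  # A
    substituent_length: float = 1.6  # A, O-S bond beyond the linking O
    #: (residue type, target subsite ring position 1-6, target distance A)
    shell_residues: list[tuple[str, int, float]] = field(default_factory=list)
    his_subsite: int = 6  # ring position facing the catalytic histidine
    his_distance: float = 3.0  # A from NE2 to the central S
    seed: int = 0
    chain_id: str = "A"
    component_id: str = "IHS"

    def validate(self) -> None:
        if not 1 <= self.his_subsite <= 6:
            raise SpecValidationError("his_subsite must be a ring position 1-6")
        for name, pos, dist in self.shell_residues:
            if not 1 <= pos <= 6:
                raise SpecValidationError(f"ring position {pos} out of range")
            if dist <= 1.5:
                raise SpecValidationError(
                    f"target distance {dist} too short (> 1.5 A required)"
                )


@dataclass
class SiteGroundTruth:
    #: expected subsite label per planted shell residue
    planted: list[tuple[ResidueRef, str, float]]
    #: expected label -> ring position mapping
    labels: dict[str, int]
    catalytic_his: ResidueRef


def _expected_labels(his_subsite: int) -> dict[str, int]:
    # A at the scissile position, then B..F in cyclically decreasing
    # ring-position order
    return {
        "ABCDEF"[i]: (his_subsite - 1 - i) % 6 + 1 for i in range(6)
    }


def make_ligand_site(
    spec: SyntheticSiteSpec,
) -> tuple[StructureModel, SiteGroundTruth]:
    """Planar six-ring ligand with sulfate-like substituents, a histidine
    facing ``his_subsite`` and shell residues at their target distances.

    Each shell residue's nearest atom (CB) is placed exactly at the target
    distance from the central S of its subsite, along the outward radial
    direction (tilted a little when several residues share a subsite).
    """
    spec.validate()
    chain = spec.chain_id
    serial = [1]

    def atom(name: str, element: str, pos: np.ndarray, occ: float = 1.0,
             altloc: str = "") -> AtomRecord:
        rec = AtomRecord(
            serial=serial[0], name=name, element=element, altloc=altloc,
            occupancy=occ, bfactor=15.0, coords=pos,
        )
        serial[0] += 1
        return rec

    # --- ligand ring + substituents in the z=0 plane
    lig_atoms: list[AtomRecord] = []
    centrals: dict[int, np.ndarray] = {}
    outward: dict[int, np.ndarray] = {}
    for pos in range(1, 7):
        th = np.radians(60.0 * (pos - 1))
        u = np.array([np.cos(th), np.sin(th), 0.0])
        outward[pos] = u
        c = spec.ring_radius * u
        o_link = c + 1.43 * u
        s = o_link + spec.substituent_length * u
        centrals[pos] = s
        lig_atoms.append(atom(f"C{pos}", "C", c))
        lig_atoms.append(atom(f"O{pos}", "O", o_link))
        lig_atoms.append(atom(f"S{pos}", "S", s))
        # three terminal O in a cone tilted back toward the ring so the
        # central S stays the outermost group atom
        v = np.array([-np.sin(th), np.cos(th), 0.0])
        w = np.array([0.0, 0.0, 1.0])
        for k, suffix in enumerate("ABC"):
            phi = np.radians(120.0 * k)
            d = -0.33 * u + 0.94 * (np.cos(phi) * v + np.sin(phi) * w)
            lig_atoms.append(atom(f"O{pos}{suffix}", "O", s + 1.45 * d))
    ligand_res = Residue(
        ref=ResidueRef(chain, 500, "", spec.component_id),
        atoms=lig_atoms,
        is_het=True,
    )

    residues: list[Residue] = []

    # --- catalytic histidine facing his_subsite
    u = outward[spec.his_subsite]
    v = np.array([-u[1], u[0], 0.0])
    ne2 = centrals[spec.his_subsite] + spec.his_distance * u
    his_atoms = [
        atom("NE2", "N", ne2),
        atom("ND1", "N", ne2 + 1.4 * u + 1.4 * v),
        atom("CE1", "C", ne2 + 0.6 * u + 1.2 * v),
        atom("CD2", "C", ne2 + 1.0 * u - 0.8 * v),
        atom("CG", "C", ne2 + 1.9 * u + 0.3 * v),
        atom("CB", "C", ne2 + 3.3 * u + 0.3 * v),
        atom("CA", "C", ne2 + 4.8 * u + 0.3 * v),
        atom("N", "N", ne2 + 5.2 * u + 1.6 * v),
        atom("C", "C", ne2 + 6.2 * u - 0.6 * v),
        atom("O", "O", ne2 + 7.0 * u - 1.5 * v),
    ]
    his_ref = ResidueRef(chain, 45, "", "HIS")
    residues.append(Residue(ref=his_ref, atoms=his_atoms, is_het=False))

    # --- shell residues at controlled distances
    labels = _expected_labels(spec.his_subsite)
    pos_to_label = {p: lab for lab, p in labels.items()}
    planted: list[tuple[ResidueRef, str, float]] = []
    per_subsite_count: dict[int, int] = {}
    seq = 100
    for res_name, pos, dist in spec.shell_residues:
        idx = per_subsite_count.get(pos, 0)
        per_subsite_count[pos] = idx + 1
        u = outward[pos]
        tilt = np.radians(12.0 * idx * (1 if idx % 2 else -1))
        v = np.array([-u[1], u[0], 0.0])
        d = np.cos(tilt) * u + np.sin(tilt) * v
        cb = centrals[pos] + dist * d
        w = np.array([0.0, 0.0, 1.0])
        shell_atoms = [
            atom("CB", "C", cb),
            atom("CA", "C", cb + 1.5 * d),
            atom("N", "N", cb + 2.1 * d + 1.2 * w),
            atom("C", "C", cb + 2.6 * d - 1.1 * w),
            atom("O", "O", cb + 3.7 * d - 1.4 * w),
        ]
        ref = ResidueRef(chain, seq, "", res_name)
        residues.append(Residue(ref=ref, atoms=shell_atoms, is_het=False))
        planted.append((ref, pos_to_label[pos], dist))
        seq += 1

    residues.append(ligand_res)
    model = StructureModel(
        id=f"synth_site_seed{spec.seed}", chains={chain: residues}
    )
    # sanity: planted distances must be achieved exactly (S is the nearest
    # group atom by construction)
    for (ref, lab, dist) in planted:
        pos = labels[lab]
        res = model.find(ref)
        group = [a for a in lig_atoms if a.name.startswith(("O", "S"))
                 and a.name[1:2] == str(pos)]
        dmin = min(
            float(np.linalg.norm(a.coords - g.coords))
            for a in res.atoms
            for g in group
        )
        if abs(dmin - dist) > 0.05:
            raise PlacementError(
                f"shell residue {ref} landed at {dmin:.3f} A, "
                f"target {dist:.3f} A (overlapping shells?)"
            )
    gt = SiteGroundTruth(planted=planted, labels=labels, catalytic_his=his_ref)
    return model, gt


# ---------------------------------------------------------------------------
# sequence families


@dataclass
class SyntheticSeqSpec:
    backbone_length: int = 480  # residues in the loop-free parent
    numbering_offset: int = 33  # author number of the first residue
    #: author positions of the planted anchors in the loop-free parent
    rhg_position: int = 44
    gxlt_position: int = 98
    daam_position: int = 260
    hae_position: int = 399
    loop_length: int = 44
    loop_cys_count: int = 2
    seed: int = 0

    def validate(self) -> None:
        anchors = [
            self.rhg_position, self.gxlt_position, self.daam_position,
            self.hae_position,
        ]
        if anchors != sorted(anchors):
            raise SpecValidationError(
                "anchors must be ordered RHGXRXh < GXLTX2G < DAAM < HAE"
            )
        if self.loop_length and self.loop_length < 0:
            raise SpecValidationError("loop_length must be >= 0")
        if self.loop_cys_count > self.loop_length:
            raise SpecValidationError("more cysteines than loop residues")


@dataclass
class SeqGroundTruth:
    seq_id: str
    has_loop: bool
    loop_start: int | None  # author numbering in the child sequence
    loop_end: int | None
    loop_type: str  # expected classification, "none" when loop-free
    cys_positions: list[int]


# letters that cannot create spurious motif hits (no R, H, D, C)
_SAFE_ALPHABET = "AEFGIKLMNPQSTVWY"


def _expected_type(length: int, n_cys: int, min_insert: int = 8) -> str:
    if length >= 35:
        return "A" if n_cys >= 2 else "B"
    if length >= 20:
        return "B"
    if length >= min_insert:
        return "C"
    return "none"


def make_uloop_family(
    spec: SyntheticSeqSpec, n: int = 6
) -> tuple[
    list[tuple[str, str]],  # (id, sequence) unaligned
    list[tuple[str, str]],  # (id, row) aligned, gaps at insertion columns
    list[SeqGroundTruth],
]:
    """Family of ``n`` sequences sharing planted anchors; loop inserted in
    every second member (members 0, 2, ... carry the loop when
    ``loop_length > 0``).

    The loop is inserted immediately before the conserved block preceding
    the DAAM motif, mirroring the layout of real U-loop MINPPs, and carries
    ``loop_cys_count`` cysteines at evenly spaced internal positions.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    off = spec.numbering_offset
    L = spec.backbone_length

    backbone = list(
        rng.choice(list(_SAFE_ALPHABET), size=L)
    )

    def plant(author_pos: int, text: str) -> None:
        i = author_pos - off
        if i < 0 or i + len(text) > L:
            raise SpecValidationError(
                f"anchor at author position {author_pos} outside backbone"
            )
        backbone[i : i + len(text)] = list(text)

    plant(spec.rhg_position, "RHGERVLTSAK")  # RHGXRXh + full consensus
    plant(spec.gxlt_position, "GALTAAG")  # GXLTX2G
    plant(spec.daam_position - 8, "WNEPSKGE")  # conserved block before DAAM
    plant(spec.daam_position, "DAAM")
    plant(spec.hae_position, "HAE")
    parent = "".join(backbone)
    insert_at = spec.daam_position - 8 - off  # 0-based index of insertion

    sequences: list[tuple[str, str]] = []
    aligned: list[tuple[str, str]] = []
    truths: list[SeqGroundTruth] = []
    for k in range(n):
        has_loop = spec.loop_length > 0 and k % 2 == 0
        sid = f"synth{k:02d}{'_loop' if has_loop else ''}"
        if has_loop:
            loop = list(rng.choice(list(_SAFE_ALPHABET.replace("C", "")),
                                   size=spec.loop_length))
            cys_idx = [
                int(round((j + 1) * spec.loop_length / (spec.loop_cys_count + 1)))
                - 1
                for j in range(spec.loop_cys_count)
            ]
            for j in cys_idx:
                loop[j] = "C"
            loop_str = "".join(loop)
            seq = parent[:insert_at] + loop_str + parent[insert_at:]
            row = seq
            loop_start = off + insert_at
            loop_end = loop_start + spec.loop_length - 1
            cys_pos = [loop_start + j for j in sorted(set(cys_idx))]
            truths.append(
                SeqGroundTruth(
                    seq_id=sid,
                    has_loop=True,
                    loop_start=loop_start,
                    loop_end=loop_end,
                    loop_type=_expected_type(spec.loop_length, len(cys_pos)),
                    cys_positions=cys_pos,
                )
            )
        else:
            seq = parent
            row = (
                parent[:insert_at]
                + "-" * spec.loop_length
                + parent[insert_at:]
            )
            truths.append(
                SeqGroundTruth(
                    seq_id=sid, has_loop=False, loop_start=None,
                    loop_end=None, loop_type="none", cys_positions=[],
                )
            )
        sequences.append((sid, seq))
        aligned.append((sid, row))
    return sequences, aligned, truths


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA, 60 columns, byte-stable."""
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
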