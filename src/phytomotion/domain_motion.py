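"""Quasi-rigid domain decomposition and hinge analysis between two
conformational snapshots of the same protein.

The approach follows the classic sliding-window rotation-vector scheme used
for protein domain-motion analysis: for every residue with a complete
window of paired C-alpha atoms, the local superposition of the two
structures yields a rotation, summarised as an axis-angle vector.  Residues
belonging to the same quasi-rigid body share (up to noise) the same
rotation vector, so k-means clustering of the vectors partitions the chain
into domains.  A candidate split is only accepted when the domains move
significantly relative to one another compared with their internal
deformation, and when each domain is large enough to be mechanically
meaningful.  The interdomain motion of the moving domain relative to the
fixed (largest) domain is then decomposed into a screw: its angle is the
reported domain rotation, and the fraction of the rotation that closes the
two domains onto each other (rather than twisting one against the other)
is ``100 sin^2`` of the angle between the screw axis and the line joining
the domain centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .rigid_geometry import (
    RigidTransform,
    ScrewMotion,
    apply,
    superpose,
    to_screw,
)
from .structure_io import ResidueRef, StructureModel

__all__ = [
    "MotionParams",
    "RotationVectorField",
    "DomainDecomposition",
    "HingeReport",
    "InsufficientOverlapError",
    "rotation_vectors",
    "cluster_domains",
    "interdomain_motion",
    "motion_series",
    "analyse_pair",
]


class InsufficientOverlapError(ValueError):
    pass


@dataclass
class MotionParams:
    window: int = 5  # odd residue count for the sliding window
    min_domain_size: int = 20  # residues
    ratio_threshold: float = 1.0  # interdomain / intradomain displacement
    max_clusters: int = 6
    cluster_seed: int = 17
    hinge_axis_cutoff: float = 5.5  # A, Ca-to-axis distance at junctions
    # windows whose fit RMSD exceeds max(floor, factor * median) span a
    # hinge and are flagged as boundary windows, excluded from clustering
    boundary_rmsd_floor: float = 0.05  # A
    boundary_rmsd_factor: float = 3.0
    # a finer split may not throw away more than this fraction of the
    # residues the coarser decomposition had assigned (guards against
    # noise-driven oversplitting that fragments a rigid body)
    min_assigned_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.min_domain_size <= self.window:
            raise ValueError("min_domain_size must exceed window")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")


@dataclass
class RVEntry:
    ref: ResidueRef
    rotation_vector: np.ndarray  # axis * angle, degrees
    window_rmsd: float
    valid: bool
    ca_a: np.ndarray
    ca_b: np.ndarray
    boundary: bool = False  # window spans a hinge (poor rigid fit)


@dataclass
class RotationVectorField:
    chain_id: str
    entries: list[RVEntry]

    @property
    def valid_entries(self) -> list[RVEntry]:
        return [e for e in self.entries if e.valid]

    @property
    def rigid_entries(self) -> list[RVEntry]:
        """Valid entries whose window fits rigidly (non-boundary)."""
        return [e for e in self.entries if e.valid and not e.boundary]


@dataclass
class Domain:
    label: str  # "fixed" or "moving_k"
    residues: set[ResidueRef]
    centroid: np.ndarray
    intradomain_rmsd: float


@dataclass
class DomainDecomposition:
    domains: list[Domain]
    unassigned: set[ResidueRef]

    @property
    def fixed(self) -> Domain:
        return next(d for d in self.domains if d.label == "fixed")

    @property
    def moving(self) -> list[Domain]:
        return [d for d in self.domains if d.label != "fixed"]

    def label_of(self, ref: ResidueRef) -> str | None:
        for d in self.domains:
            if ref in d.residues:
                return d.label
        return None


@dataclass
class HingeReport:
    screw: ScrewMotion | None
    rotation_angle: float  # degrees
    percent_closure: float  # [0, 100]
    hinge_residues: list[list[ResidueRef]]  # contiguous segments
    fixed_domain_rmsd: float
    moving_domain_fraction: float
    moving_label: str | None = None
    annotations: dict = field(default_factory=dict)

    @property
    def is_null(self) -> bool:
        return self.screw is None


# ---------------------------------------------------------------------------


def _paired_ca(
    model_a: StructureModel, model_b: StructureModel, chain: str
) -> list[tuple[ResidueRef, np.ndarray, np.ndarray]]:
    by_key_b = {
        (r.ref.seq_number, r.ref.insertion_code): r
        for r in model_b.polymer(chain)
    }
    pairs = []
    for res_a in model_a.polymer(chain):
        key = (res_a.ref.seq_number, res_a.ref.insertion_code)
        res_b = by_key_b.get(key)
        if res_b is None:
            continue
        ca_a = res_a.atom("CA")
        ca_b = res_b.atom("CA")
        if ca_a is None or ca_b is None:
            continue
        pairs.append((res_a.ref, ca_a.coords, ca_b.coords))
    return pairs


def rotation_vectors(
    model_a: StructureModel,
    model_b: StructureModel,
    chain: str,
    params: MotionParams | None = None,
) -> RotationVectorField:
    """Per-residue axis-angle rotation vectors from sliding-window fits.

    Residues are paired by identical author numbering.  A residue gets a
    valid vector only when a full window of consecutively numbered paired
    residues exists around it in both structures (numbering gaps invalidate
    the affected windows).
    """
    params = params or MotionParams()
    pairs = _paired_ca(model_a, model_b, chain)
    if len(pairs) < params.min_domain_size:
        raise InsufficientOverlapError(
            f"only {len(pairs)} paired residues on chain {chain!r}, "
            f"need >= {params.min_domain_size}"
        )
    half = params.window // 2
    entries: list[RVEntry] = []
    for i, (ref, ca_a, ca_b) in enumerate(pairs):
        lo, hi = i - half, i + half
        valid = lo >= 0 and hi < len(pairs)
        if valid:
            # windows must be consecutive in author numbering, no icodes
            nums = [pairs[j][0].seq_number for j in range(lo, hi + 1)]
            codes = [pairs[j][0].insertion_code for j in range(lo, hi + 1)]
            valid = all(c == "" for c in codes) and all(
                nums[j + 1] - nums[j] == 1 for j in range(len(nums) - 1)
            )
        if not valid:
            entries.append(
                RVEntry(ref, np.zeros(3), float("nan"), False, ca_a, ca_b)
            )
            continue
        wa = np.stack([pairs[j][1] for j in range(lo, hi + 1)])
        wb = np.stack([pairs[j][2] for j in range(lo, hi + 1)])
        t, rmsd = superpose(wa, wb)
        screw = to_screw(t)
        vec = screw.axis_direction * screw.angle
        entries.append(RVEntry(ref, vec, rmsd, True, ca_a, ca_b))
    rmsds = [e.window_rmsd for e in entries if e.valid]
    if rmsds:
        threshold = max(
            params.boundary_rmsd_floor,
            params.boundary_rmsd_factor * float(np.median(rmsds)),
        )
        for e in entries:
            if e.valid and e.window_rmsd > threshold:
                e.boundary = True
    return RotationVectorField(chain_id=chain, entries=entries)


def _contiguous_segments(
    refs: list[ResidueRef],
) -> list[list[ResidueRef]]:
    segments: list[list[ResidueRef]] = []
    for ref in refs:
        if (
            segments
            and segments[-1][-1].chain_id == ref.chain_id
            and ref.seq_number - segments[-1][-1].seq_number == 1
        ):
            segments[-1].append(ref)
        else:
            segments.append([ref])
    return segments


def _displacement_ratio(
    entries: list[RVEntry], members_i: list[RVEntry], members_j: list[RVEntry]
) -> float:
    """Interdomain-to-intradomain displacement ratio for a domain pair.

    Fit domain i onto itself across the two structures; the residual RMSD
    of domain i is its internal deformation, the RMSD of domain j under the
    same fit is the motion of j relative to i.  The pair ratio is the
    smaller of the two directed ratios.
    """
    eps = 1e-2  # A, floor for the internal deformation of a noiseless body
    ratios = []
    for di, dj in ((members_i, members_j), (members_j, members_i)):
        ai = np.stack([e.ca_a for e in di])
        bi = np.stack([e.ca_b for e in di])
        t, intra = superpose(ai, bi)
        aj = np.stack([e.ca_a for e in dj])
        bj = np.stack([e.ca_b for e in dj])
        d = apply(t, aj) - bj
        inter = float(np.sqrt((d * d).sum(axis=1).mean()))
        ratios.append(inter / max(intra, eps))
    return min(ratios)


def _refine_labels(
    entries: list[RVEntry],
    labels: np.ndarray,
    k: int,
    n_iter: int = 8,
) -> np.ndarray:
    """Iteratively reassign residues to the domain whose rigid-body fit
    best predicts their displacement.

    The k-means seeding works on rotation vectors, which are noisy for
    short windows; this refinement works directly on C-alpha displacements
    and cleans up domain boundaries.  Labels of -1 mark residues excluded
    from the seeding (boundary windows); they are assigned on the first
    iteration.
    """
    ca_a = np.stack([e.ca_a for e in entries])
    ca_b = np.stack([e.ca_b for e in entries])
    labels = labels.copy()
    for _ in range(n_iter):
        residuals = np.full((len(entries), k), np.inf)
        for c in range(k):
            members = labels == c
            if members.sum() < 3:
                continue
            t, _ = superpose(ca_a[members], ca_b[members])
            d = apply(t, ca_a) - ca_b
            residuals[:, c] = (d * d).sum(axis=1)
        if not np.isfinite(residuals).any():
            break
        new_labels = residuals.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels


def _best_contiguous_split(
    entries: list[RVEntry], params: MotionParams
) -> np.ndarray | None:
    """Two-domain seeding by scanning every chain split point and fitting
    each side rigidly; returns the labels of the minimum-residual split.

    Complements the k-means seeding: for small interdomain rotations the
    per-window rotation vectors are noise-dominated, whereas the summed
    rigid-fit residual of a whole-body split still identifies the hinge.
    """
    n = len(entries)
    m = params.min_domain_size
    if n < 2 * m:
        return None
    ca_a = np.stack([e.ca_a for e in entries])
    ca_b = np.stack([e.ca_b for e in entries])
    best_cost = np.inf
    best_cut = None
    for cut in range(m, n - m + 1):
        cost = 0.0
        for sl in (slice(0, cut), slice(cut, n)):
            _, rmsd = superpose(ca_a[sl], ca_b[sl])
            cost += rmsd * rmsd * (sl.stop - sl.start)
        if cost < best_cost:
            best_cost = cost
            best_cut = cut
    labels = np.zeros(n, dtype=int)
    labels[best_cut:] = 1
    return labels


def _total_intra_rmsd(decomp: DomainDecomposition) -> float:
    return float(
        sum(d.intradomain_rmsd * len(d.residues) for d in decomp.domains)
        / max(sum(len(d.residues) for d in decomp.domains), 1)
    )


def _decomposition_from_labels(
    entries: list[RVEntry],
    labels: np.ndarray,
    params: MotionParams,
) -> DomainDecomposition | None:
    """Build a decomposition from cluster labels; None if invalid."""
    by_cluster: dict[int, list[RVEntry]] = {}
    unassigned: set[ResidueRef] = set()
    # discard chain-contiguous segments shorter than the window
    refs = [e.ref for e in entries]
    order = list(range(len(entries)))
    seg_start = 0
    keep = np.ones(len(entries), dtype=bool)
    for i in range(1, len(entries) + 1):
        boundary = (
            i == len(entries)
            or labels[i] != labels[i - 1]
            or refs[i].seq_number - refs[i - 1].seq_number != 1
        )
        if boundary:
            if i - seg_start < params.window:
                keep[seg_start:i] = False
            seg_start = i
    for i in order:
        if keep[i] and labels[i] >= 0:
            by_cluster.setdefault(int(labels[i]), []).append(entries[i])
        else:
            unassigned.add(entries[i].ref)
    clusters = [m for m in by_cluster.values() if m]
    if not clusters:
        return None
    if any(len(m) < params.min_domain_size for m in clusters):
        return None
    if len(clusters) > 1:
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if (
                    _displacement_ratio(entries, clusters[i], clusters[j])
                    < params.ratio_threshold
                ):
                    return None
    clusters.sort(key=len, reverse=True)
    domains = []
    for k, members in enumerate(clusters):
        ai = np.stack([e.ca_a for e in members])
        bi = np.stack([e.ca_b for e in members])
        _, intra = superpose(ai, bi)
        centroid = 0.5 * (ai.mean(axis=0) + bi.mean(axis=0))
        label = "fixed" if k == 0 else f"moving_{k}"
        domains.append(
            Domain(
                label=label,
                residues={e.ref for e in members},
                centroid=centroid,
                intradomain_rmsd=intra,
            )
        )
    return DomainDecomposition(domains=domains, unassigned=unassigned)


def cluster_domains(
    field: RotationVectorField, params: MotionParams | None = None
) -> DomainDecomposition:
    """Partition residues into quasi-rigid domains by k-means over
    rotation vectors, accepting extra clusters only while every domain
    pair moves more between than within domains."""
    params = params or MotionParams()
    rigid = field.rigid_entries
    entries = field.valid_entries
    X = np.stack([e.rotation_vector for e in rigid])
    all_zero = np.zeros(len(entries), dtype=int)
    best = _decomposition_from_labels(entries, all_zero, params)
    if best is None:
        # degenerate (should not happen: one cluster has no ratio test);
        # treat everything as one domain without segment filtering
        best = _decomposition_from_labels(
            entries, all_zero, MotionParams(window=3, min_domain_size=4)
        )
    rigid_idx = {id(e): i for i, e in enumerate(rigid)}
    for k in range(2, params.max_clusters + 1):
        if len(rigid) < k:
            break
        seeds = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # k-means duplicate-point noise
            km = KMeans(
                n_clusters=k, n_init=10, random_state=params.cluster_seed
            ).fit(X)
        seeds.append(
            np.array(
                [
                    km.labels_[rigid_idx[id(e)]] if id(e) in rigid_idx else -1
                    for e in entries
                ]
            )
        )
        if k == 2:
            split = _best_contiguous_split(entries, params)
            if split is not None:
                seeds.append(split)
        cand = None
        for seed_labels in seeds:
            labels = _refine_labels(entries, seed_labels, k)
            c = _decomposition_from_labels(entries, labels, params)
            if c is not None and (
                cand is None
                or _total_intra_rmsd(c) < _total_intra_rmsd(cand)
            ):
                cand = c
        if cand is None or len(cand.domains) < len(best.domains) + 1:
            break
        n_best = sum(len(d.residues) for d in best.domains)
        n_cand = sum(len(d.residues) for d in cand.domains)
        if n_cand < params.min_assigned_fraction * n_best:
            break
        best = cand
    # residues without a valid vector, and boundary windows, are unassigned
    best.unassigned |= {
        e.ref for e in field.entries if not e.valid or e.boundary
    }
    return best


def interdomain_motion(
    model_a: StructureModel,
    model_b: StructureModel,
    decomp: DomainDecomposition,
    chain: str | None = None,
    params: MotionParams | None = None,
) -> HingeReport:
    """Screw decomposition of the moving domain's residual motion after a
    fixed-domain superposition, plus hinge-residue identification."""
    params = params or MotionParams()
    if len(decomp.domains) < 2:
        return HingeReport(
            screw=None,
            rotation_angle=0.0,
            percent_closure=0.0,
            hinge_residues=[],
            fixed_domain_rmsd=decomp.domains[0].intradomain_rmsd
            if decomp.domains
            else 0.0,
            moving_domain_fraction=0.0,
        )
    chain = chain or decomp.fixed and next(iter(decomp.fixed.residues)).chain_id
    pairs = _paired_ca(model_a, model_b, chain)
    coords = {ref: (ca_a, ca_b) for ref, ca_a, ca_b in pairs}

    fixed_refs = sorted(r for r in decomp.fixed.residues if r in coords)
    fa = np.stack([coords[r][0] for r in fixed_refs])
    fb = np.stack([coords[r][1] for r in fixed_refs])
    t_fixed, fixed_rmsd = superpose(fa, fb)

    n_assigned = sum(len(d.residues) for d in decomp.domains)
    best = None
    for dom in decomp.moving:
        refs = sorted(r for r in dom.residues if r in coords)
        ma = apply(t_fixed, np.stack([coords[r][0] for r in refs]))
        mb = np.stack([coords[r][1] for r in refs])
        t_resid, _ = superpose(ma, mb)
        screw = to_screw(t_resid)
        if best is None or screw.angle > best[1].angle:
            c_moving = 0.5 * (ma.mean(axis=0) + mb.mean(axis=0))
            best = (dom, screw, c_moving)
    dom, screw, c_moving = best

    c_fixed = 0.5 * (apply(t_fixed, fa).mean(axis=0) + fb.mean(axis=0))
    line = c_moving - c_fixed
    norm = np.linalg.norm(line)
    if norm > 1e-9 and screw.angle > 0:
        cosg = abs(float(screw.axis_direction @ (line / norm)))
        cosg = min(cosg, 1.0)
        percent_closure = 100.0 * (1.0 - cosg * cosg)
    else:
        percent_closure = 0.0

    hinge = _hinge_residues(decomp, coords, screw, params)
    return HingeReport(
        screw=screw,
        rotation_angle=screw.angle,
        percent_closure=percent_closure,
        hinge_residues=hinge,
        fixed_domain_rmsd=fixed_rmsd,
        moving_domain_fraction=len(dom.residues) / n_assigned,
        moving_label=dom.label,
    )


def _hinge_residues(
    decomp: DomainDecomposition,
    coords: dict[ResidueRef, tuple[np.ndarray, np.ndarray]],
    screw: ScrewMotion,
    params: MotionParams,
) -> list[list[ResidueRef]]:
    """Residues at covalent junctions between differently-assigned segments,
    plus residues near the screw axis around those junctions."""
    refs = sorted(coords)
    label_of = {r: decomp.label_of(r) for r in refs}
    junction_idx: list[int] = []
    hinge: set[ResidueRef] = set()
    last_assigned: tuple[int, str] | None = None
    for i, r in enumerate(refs):
        lab = label_of[r]
        if lab is None:
            continue
        if last_assigned is not None and lab != last_assigned[1]:
            j0 = last_assigned[0]
            # the unassigned gap plus one flanking residue each side
            for j in range(j0, i + 1):
                hinge.add(refs[j])
            junction_idx.append((j0 + i) // 2)
        last_assigned = (i, lab)
    # residues whose Ca lies near the screw axis, within a window of a
    # junction in sequence
    if junction_idx:
        a = screw.axis_direction
        p = screw.axis_point
        for i, r in enumerate(refs):
            if min(abs(i - j) for j in junction_idx) > 2 * params.window:
                continue
            x = coords[r][1]  # reference-frame (model B) coordinates
            d = x - p
            dist = float(np.linalg.norm(d - (d @ a) * a))
            if dist <= params.hinge_axis_cutoff:
                hinge.add(r)
    return _contiguous_segments(sorted(hinge))


def analyse_pair(
    model_a: StructureModel,
    model_b: StructureModel,
    chain: str,
    params: MotionParams | None = None,
) -> tuple[DomainDecomposition, HingeReport]:
    """Convenience: rotation vectors -> clustering -> hinge report."""
    params = params or MotionParams()
    field = rotation_vectors(model_a, model_b, chain, params)
    decomp = cluster_domains(field, params)
    report = interdomain_motion(model_a, model_b, decomp, chain, params)
    return decomp, report


def motion_series(
    models: list[StructureModel],
    reference_index: int = 0,
    chain: str = "A",
    params: MotionParams | None = None,
) -> list[HingeReport]:
    """Hinge report of every model against a reference snapshot, using the
    common decomposition from the pair with the largest motion."""
    if len(models) < 2:
        raise ValueError("need at least two models")
    params = params or MotionParams()
    ref = models[reference_index]
    others = [m for i, m in enumerate(models) if i != reference_index]
    best_decomp = None
    best_angle = -1.0
    for m in others:
        decomp, report = analyse_pair(ref, m, chain, params)
        if report.rotation_angle > best_angle:
            best_angle = report.rotation_angle
            best_decomp = decomp
    reports = []
    for m in others:
        reports.append(
            interdomain_motion(ref, m, best_decomp, chain, params)
        )
    return reports
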