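"""Conformer-ensemble post-processing: superposition, RMSD clustering,
contact distances, and chromophore orientation.

Frames are first superposed by minimising the heavy-atom RMSD of the two
base pairs that form the intercalation site (Kabsch superposition); the
bound-ligand geometry is then characterised by hybrid k-centers/k-medoids
clustering of the ligand heavy atoms under a fixed RMSD cutoff, by the
minimum ligand-amino-nitrogen-to-phosphate distance, and by the in-plane
rotation of the planar chromophore relative to a reference pose.

Input ensembles are assumed whole and centred (no periodic-boundary
imaging is applied).  Coordinates are in nanometres throughout; the PDB
reader converts from Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fnmatch import fnmatch

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateGeometryError, InvalidInputError

__all__ = [
    "ConformerEnsemble",
    "ClusterResult",
    "kabsch_superpose",
    "superpose_ensemble",
    "rmsd",
    "pairwise_rmsd",
    "cluster_kcenters_kmedoids",
    "min_distance_series",
    "chromophore_rotation_angle",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
]


@dataclass
class ConformerEnsemble:
    """frames x atoms x 3 coordinates (nm) with named atom selections."""

    coords: np.ndarray
    atom_names: list = None
    residue_ids: np.ndarray = None
    selections: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidInputError("coords must be frames x atoms x 3")
        if self.coords.shape[0] < 1:
            raise InvalidInputError("ensemble must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidInputError("coordinates must be finite")
        n_atoms = self.coords.shape[1]
        for name, idx in self.selections.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n_atoms):
                raise InvalidInputError(f"selection {name!r} has out-of-range indices")
            self.selections[name] = idx

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def selection(self, name_or_indices):
        if isinstance(name_or_indices, str):
            if name_or_indices not in self.selections:
                raise InvalidInputError(f"unknown selection {name_or_indices!r}")
            return self.selections[name_or_indices]
        return np.asarray(name_or_indices, dtype=int)


@dataclass
class ClusterResult:
    assignments: np.ndarray
    medoid_frames: list
    populations: np.ndarray
    cutoff: float
    n_clusters: int
    max_center_distance: float = float("nan")   # k-centers covering radius


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two (atoms, 3) arrays (no refitting)."""
    a, b = np.asarray(a), np.asarray(b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def pairwise_rmsd(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """RMSD matrix between frame sets of shape (n, atoms, 3), no refitting."""
    A = np.asarray(A, float)
    VA = A.reshape(A.shape[0], -1)
    VB = VA if B is None else np.asarray(B, float).reshape(len(B), -1)
    n_atoms = A.shape[1]
    sq = (
        np.sum(VA ** 2, axis=1)[:, None]
        + np.sum(VB ** 2, axis=1)[None, :]
        - 2.0 * VA @ VB.T
    )
    return np.sqrt(np.maximum(sq, 0.0) / n_atoms)


def _check_noncollinear(points: np.ndarray):
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(s) < 2 or s[1] < 1e-10 * max(s[0], 1.0):
        raise DegenerateGeometryError("selection is collinear or degenerate")


def kabsch_superpose(
    mobile_frame: np.ndarray,
    reference_frame: np.ndarray,
    selection: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Optimal rigid-body superposition of one frame onto a reference.

    The proper rotation minimising the RMSD over ``selection`` (>= 3
    non-collinear atoms) is found by solving Wahba's problem (Kabsch);
    reflections are excluded by construction.  The transformation is
    applied to *all* atoms; the returned RMSD is over the selection.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise DegenerateGeometryError("selection must contain at least 3 atoms")
    mob_sel = mobile_frame[sel]
    ref_sel = reference_frame[sel]
    _check_noncollinear(ref_sel)
    _check_noncollinear(mob_sel)
    c_mob = mob_sel.mean(axis=0)
    c_ref = ref_sel.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sel - c_ref, mob_sel - c_mob)
    transformed = rot.apply(mobile_frame - c_mob) + c_ref
    return transformed, rmsd(transformed[sel], ref_sel)


def superpose_ensemble(
    ensemble: ConformerEnsemble,
    selection,
    reference_frame: int = 0,
) -> ConformerEnsemble:
    """Superpose every frame onto ``reference_frame`` over ``selection``."""
    sel = ensemble.selection(selection)
    ref = ensemble.coords[reference_frame]
    out = np.empty_like(ensemble.coords)
    for i in range(ensemble.n_frames):
        out[i], _ = kabsch_superpose(ensemble.coords[i], ref, sel)
    return ConformerEnsemble(
        coords=out,
        atom_names=ensemble.atom_names,
        residue_ids=ensemble.residue_ids,
        selections=dict(ensemble.selections),
    )


def cluster_kcenters_kmedoids(
    ensemble: ConformerEnsemble,
    selection,
    cutoff: float = 0.3,
    medoid_sweeps: int = 10,
    seed: int | None = None,
    random_first_center: bool = False,
) -> ClusterResult:
    """Hybrid k-centers / k-medoids clustering under an RMSD cutoff.

    Seeding (k-centers): the first centre is frame 0 (or a seeded random
    frame), then repeatedly the frame farthest from all existing centres,
    until every frame lies within ``cutoff`` of a centre — this bounds the
    covering radius by construction.  Refinement (k-medoids): for
    ``medoid_sweeps`` passes, each cluster's centre is replaced by the
    member minimising the summed within-cluster RMSD, followed by
    reassignment; ties break toward the lower frame index.  Frames are
    expected to be pre-superposed (RMSD is computed without refitting).
    """
    if ensemble.n_frames < 1:
        raise InvalidInputError("empty ensemble")
    if not cutoff > 0:
        raise InvalidInputError("cutoff must be positive")
    sel = ensemble.selection(selection)
    X = ensemble.coords[:, sel, :]
    n = len(X)

    if random_first_center:
        first = int(np.random.default_rng(seed).integers(n))
    else:
        first = 0
    centers = [first]
    dist_to_nearest = pairwise_rmsd(X, X[[first]])[:, 0]
    assignments = np.zeros(n, dtype=int)
    while dist_to_nearest.max() > cutoff:
        new = int(np.argmax(dist_to_nearest))        # argmax ties -> lower index
        d_new = pairwise_rmsd(X, X[[new]])[:, 0]
        closer = d_new < dist_to_nearest
        assignments[closer] = len(centers)
        dist_to_nearest = np.minimum(dist_to_nearest, d_new)
        centers.append(new)
    max_center_distance = float(dist_to_nearest.max())

    medoids = list(centers)
    for _ in range(max(medoid_sweeps, 0)):
        changed = False
        for ci in range(len(medoids)):
            members = np.flatnonzero(assignments == ci)
            if members.size == 0:
                continue
            D = pairwise_rmsd(X[members], X[members])
            best = members[int(np.argmin(D.sum(axis=1)))]  # ties -> lower index
            if best != medoids[ci]:
                medoids[ci] = int(best)
                changed = True
        D_med = pairwise_rmsd(X, X[medoids])
        new_assignments = np.argmin(D_med, axis=1)
        if not changed and np.array_equal(new_assignments, assignments):
            break
        assignments = new_assignments

    # Drop clusters emptied by reassignment, keeping medoid order.
    kept = [ci for ci in range(len(medoids)) if np.any(assignments == ci)]
    remap = {old: new for new, old in enumerate(kept)}
    assignments = np.array([remap[a] for a in assignments])
    medoids = [medoids[ci] for ci in kept]
    populations = np.bincount(assignments, minlength=len(medoids)) / n
    return ClusterResult(
        assignments=assignments,
        medoid_frames=medoids,
        populations=populations,
        cutoff=cutoff,
        n_clusters=len(medoids),
        max_center_distance=max_center_distance,
    )


def min_distance_series(
    ensemble: ConformerEnsemble,
    sel_a,
    sel_b,
) -> tuple[np.ndarray, float]:
    """Per-frame minimum inter-selection distance (nm) and its mean."""
    ia = ensemble.selection(sel_a)
    ib = ensemble.selection(sel_b)
    if ia.size == 0 or ib.size == 0:
        raise InvalidInputError("selections must be non-empty")
    series = np.array(
        [cdist(frame[ia], frame[ib]).min() for frame in ensemble.coords]
    )
    return series, float(series.mean())


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if len(s) < 2 or s[0] < 1e-10 or (s[0] - s[1]) < 1e-8 * s[0]:
        raise DegenerateGeometryError("ring principal axis is ill-defined")
    return vt[0]


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if len(s) < 3 or s[1] < 1e-10:
        raise DegenerateGeometryError("site selection does not define a plane")
    return vt[2]


def chromophore_rotation_angle(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    ring_selection,
    site_selection,
) -> float:
    """In-plane rotation (degrees, [0, 90]) of the chromophore long axis.

    The long axis of the ring atoms is taken as the first principal axis
    of their coordinates in each frame; both axes are projected onto the
    mean least-squares plane of the site base pairs (pooled over the two
    frames, which are assumed pre-superposed on the site) and the acute
    angle between the projections is returned.
    """
    ring = np.asarray(ring_selection, dtype=int)
    site = np.asarray(site_selection, dtype=int)
    if ring.size < 4:
        raise DegenerateGeometryError("ring selection must contain >= 4 atoms")
    normal = _plane_normal(np.vstack([frame_a[site], frame_b[site]]))
    ax_a = _principal_axis(frame_a[ring])
    ax_b = _principal_axis(frame_b[ring])
    proj_a = ax_a - np.dot(ax_a, normal) * normal
    proj_b = ax_b - np.dot(ax_b, normal) * normal
    na, nb = np.linalg.norm(proj_a), np.linalg.norm(proj_b)
    if na < 1e-8 or nb < 1e-8:
        raise DegenerateGeometryError("ring axis is perpendicular to the site plane")
    cosang = abs(np.dot(proj_a / na, proj_b / nb))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# multi-model PDB I/O (via biotite; PDB Angstrom <-> package nm)

def read_pdb_ensemble(path, selection_spec: dict | None = None) -> ConformerEnsemble:
    """Read a multi-model PDB file into an ensemble (coordinates in nm).

    ``selection_spec`` maps selection names to matching rules, e.g.::

        {"ligand_heavy": {"residue_names": ["DOX"], "exclude_elements": ["H"]},
         "phosphate_P": {"atom_names": ["P"]}}

    Supported keys per rule: ``residue_names`` (list), ``atom_names``
    (list of fnmatch patterns), ``elements`` (list),
    ``exclude_elements`` (list).
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float) / 10.0
    atom_names = list(stack.atom_name)
    res_names = list(stack.res_name)
    elements = list(stack.element)
    residue_ids = np.asarray(stack.res_id)

    selections = {}
    for name, rule in (selection_spec or {}).items():
        mask = np.ones(len(atom_names), dtype=bool)
        if "residue_names" in rule:
            mask &= np.isin(res_names, rule["residue_names"])
        if "atom_names" in rule:
            pats = rule["atom_names"]
            mask &= np.array(
                [any(fnmatch(a, p) for p in pats) for a in atom_names]
            )
        if "elements" in rule:
            mask &= np.isin(elements, rule["elements"])
        if "exclude_elements" in rule:
            mask &= ~np.isin(elements, rule["exclude_elements"])
        selections[name] = np.flatnonzero(mask)
    return ConformerEnsemble(
        coords=coords,
        atom_names=atom_names,
        residue_ids=residue_ids,
        selections=selections,
    )


def write_pdb_ensemble(ensemble: ConformerEnsemble, path, frames=None) -> None:
    """Write selected frames as a multi-model PDB (nm -> Angstrom)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    frames = list(range(ensemble.n_frames)) if frames is None else list(frames)
    n_atoms = ensemble.n_atoms
    arrays = []
    for fi in frames:
        arr = struc.AtomArray(n_atoms)
        arr.coord = ensemble.coords[fi] * 10.0
        arr.atom_name = np.array(
            ensemble.atom_names
            if ensemble.atom_names is not None
            else [f"C{i + 1}" for i in range(n_atoms)]
        )
        arr.res_id = (
            ensemble.residue_ids
            if ensemble.residue_ids is not None
            else np.ones(n_atoms, dtype=int)
        )
        arr.res_name = np.array(["LIG"] * n_atoms)
        arr.chain_id = np.array(["A"] * n_atoms)
        arr.element = np.array(
            [str(nm)[0] for nm in arr.atom_name]
        )
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
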