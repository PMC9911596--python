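"""Structure-based geometry: superposition, pore profiling, dye volumes.

Operates on atomic models (PDB/mmCIF, read through gemmi) of membrane
machines such as the VTC polyP translocation complex.  Provides

* chain/entity stoichiometry counting,
* Kabsch least-squares superposition and domain RMSD,
* a HOLE-style pore-radius profile along a user-supplied channel axis
  (largest sphere centred in the plane at each axial station touching no
  atom), with channel-length extraction,
* trans-membrane helix counting from backbone geometry, and
* accessible-volume (AV) sampling of dye positions around a labeling site,
  yielding inter-dye distance distributions for FRET prediction.

Distances are in Å throughout.  Van der Waals radii come from a single
Bondi-style table; unknown elements fall back to 1.7 Å with a warning.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .forster import DistanceSummary

__all__ = [
    "VDW_RADII",
    "DEFAULT_VDW",
    "DyeModel",
    "ALEXA488",
    "CY5",
    "Structure",
    "Selection",
    "SuperpositionResult",
    "PoreAxis",
    "PoreProfile",
    "AVCloud",
    "read_structure",
    "chain_stoichiometry",
    "kabsch_superpose",
    "domain_rmsd",
    "pore_profile",
    "channel_length",
    "count_tm_helices",
    "sample_dye_av",
    "av_distance",
    "write_pore_profile",
    "write_av_cloud_pdb",
]

# Bondi (1964)-style van der Waals radii, Å
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90, "B": 1.92,
    "MG": 1.73, "ZN": 1.39, "FE": 1.52, "MN": 1.55, "CA": 2.31, "NA": 2.27,
    "K": 2.75,
}
DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class DyeModel:
    """Geometric dye description for accessible-volume sampling."""

    name: str
    linker_length: float
    linker_width: float
    dye_radius: float


ALEXA488 = DyeModel("Alexa488", linker_length=20.0, linker_width=4.5, dye_radius=3.5)
CY5 = DyeModel("Cy5", linker_length=22.0, linker_width=4.5, dye_radius=3.5)


@dataclass
class Structure:
    """Flat atom-array view of a macromolecular model.

    Author residue numbering is preserved as-is.  ``het`` flags waters and
    ligands so geometry operations can exclude them.
    """

    coords: np.ndarray          # (n, 3) Å
    elements: np.ndarray        # str per atom, upper-case
    vdw: np.ndarray             # Å per atom
    atom_names: np.ndarray
    chain_ids: np.ndarray
    res_seq: np.ndarray         # author residue numbers
    res_names: np.ndarray
    het: np.ndarray             # bool per atom
    name: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def protein_mask(self) -> np.ndarray:
        return ~self.het

    def select(
        self,
        chain: str | None = None,
        res_first: int | None = None,
        res_last: int | None = None,
        atom_names: tuple[str, ...] | None = None,
        protein_only: bool = True,
    ) -> np.ndarray:
        """Boolean atom mask; residue intervals are inclusive."""
        m = np.ones(self.n_atoms, dtype=bool)
        if protein_only:
            m &= ~self.het
        if chain is not None:
            m &= self.chain_ids == chain
        if res_first is not None:
            m &= self.res_seq >= res_first
        if res_last is not None:
            m &= self.res_seq <= res_last
        if atom_names is not None:
            m &= np.isin(self.atom_names, atom_names)
        return m


@dataclass(frozen=True)
class Selection:
    """Inclusive author-numbered residue interval on one chain."""

    chain: str
    res_first: int
    res_last: int


def read_structure(path, fmt: str | None = None, include_het: bool = True) -> Structure:
    """Read a PDB or mmCIF file into a flat :class:`Structure`.

    ``fmt`` is inferred from the extension when omitted.  Alternate
    locations are resolved to the highest-occupancy conformer; the first
    model is used.  Unknown elements receive the default van der Waals
    radius with a warning.
    """
    import gemmi

    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    if fmt == "pdb":
        st = gemmi.read_pdb(path)
    elif fmt == "mmcif":
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    rows = []
    unknown: set[str] = set()
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H" or res.is_water()
            if is_het and not include_het:
                continue
            # altloc resolution: keep highest occupancy per atom name
            best: dict[str, object] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                el = atom.element.name.upper()
                if el not in VDW_RADII:
                    unknown.add(el)
                rows.append((
                    (atom.pos.x, atom.pos.y, atom.pos.z),
                    el,
                    VDW_RADII.get(el, DEFAULT_VDW),
                    atom.name,
                    chain.name,
                    res.seqid.num,
                    res.name,
                    is_het,
                ))
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}: using default vdW {DEFAULT_VDW} Å"
        )
    if not rows:
        raise ValueError(f"{path}: no atoms")
    coords = np.array([r[0] for r in rows], dtype=float)
    return Structure(
        coords=coords,
        elements=np.array([r[1] for r in rows]),
        vdw=np.array([r[2] for r in rows], dtype=float),
        atom_names=np.array([r[3] for r in rows]),
        chain_ids=np.array([r[4] for r in rows]),
        res_seq=np.array([r[5] for r in rows], dtype=int),
        res_names=np.array([r[6] for r in rows]),
        het=np.array([r[7] for r in rows], dtype=bool),
        name=path,
    )


def chain_stoichiometry(struct: Structure) -> dict[str, list[str]]:
    """Group protein chains into entities by identical residue sequence.

    Returns {representative chain id: [chain ids]}; the copy number of each
    entity is the length of its chain list (e.g. a 3:1:1 heteropentamer
    yields lists of length 3, 1 and 1).
    """
    sequences: dict[tuple, list[str]] = {}
    for ch in dict.fromkeys(struct.chain_ids[~struct.het]):
        m = (struct.chain_ids == ch) & ~struct.het
        resseq = struct.res_seq[m]
        resname = struct.res_names[m]
        _, first = np.unique(resseq, return_index=True)
        seq = tuple(resname[np.sort(first)])
        sequences.setdefault(seq, []).append(ch)
    return {chains[0]: chains for chains in sequences.values()}


# ---------------------------------------------------------------------------
# superposition

@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    selection: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: str = "") -> SuperpositionResult:
    """Optimal rigid superposition of paired coordinate sets (Kabsch/SVD).

    Returns the proper rotation (det +1, reflections excluded) and
    translation minimizing the RMSD of ``R @ mobile + t`` to ``reference``.
    Requires >= 3 non-degenerate point pairs.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("inputs must be matching (n, 3) arrays")
    n = len(mob)
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    # degenerate (collinear/coincident) point sets leave the rotation
    # underdetermined about the degenerate axis
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("degenerate point set: collinear or coincident")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    diff = mob_c @ rot.T - ref_c
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rot, trans, rmsd, n, selection)


def domain_rmsd(
    struct_a: Structure,
    struct_b: Structure,
    sel_a: Selection,
    sel_b: Selection,
    atom_names: tuple[str, ...] = ("CA",),
) -> SuperpositionResult:
    """Superpose two domains pairing atoms by author residue number.

    Only residue numbers present in both selections contribute; one atom of
    each listed name per residue.  The default Cα pairing is the common
    convention for domain RMSD values.
    """
    def atoms_by_res(st: Structure, sel: Selection) -> dict[tuple[int, str], np.ndarray]:
        m = st.select(sel.chain, sel.res_first, sel.res_last, atom_names)
        out = {}
        for i in np.flatnonzero(m):
            out[(int(st.res_seq[i]), str(st.atom_names[i]))] = st.coords[i]
        return out

    a = atoms_by_res(struct_a, sel_a)
    b = atoms_by_res(struct_b, sel_b)
    common = sorted(set(a) & set(b))
    if not common:
        raise ValueError("empty residue-number intersection between selections")
    mob = np.array([a[k] for k in common])
    ref = np.array([b[k] for k in common])
    desc = (f"{sel_a.chain}:{sel_a.res_first}-{sel_a.res_last} vs "
            f"{sel_b.chain}:{sel_b.res_first}-{sel_b.res_last} ({len(common)} atoms)")
    return kabsch_superpose(mob, ref, selection=desc)


# ---------------------------------------------------------------------------
# pore profiling

@dataclass(frozen=True)
class PoreAxis:
    """Channel axis as origin plus unit direction."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    @classmethod
    def from_points(cls, p0, p1) -> "PoreAxis":
        p0 = np.asarray(p0, dtype=float)
        d = np.asarray(p1, dtype=float) - p0
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            raise ValueError("axis points coincide")
        return cls(tuple(p0), tuple(d / norm))

    def frame(self) -> np.ndarray:
        """Orthonormal basis with the axis as the third row."""
        ez = np.asarray(self.direction, dtype=float)
        ez = ez / np.linalg.norm(ez)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(ez @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        ex = np.cross(helper, ez)
        ex /= np.linalg.norm(ex)
        ey = np.cross(ez, ex)
        return np.vstack([ex, ey, ez])

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - np.asarray(self.origin)) @ self.frame().T


@dataclass
class PoreProfile:
    """Pore radius versus axial coordinate, HOLE-style."""

    axis: PoreAxis
    z_values: np.ndarray
    radius: np.ndarray
    centers: np.ndarray                  # in-plane (x, y) of each pore point, axis frame
    lining: list[list[tuple[str, int, str]]]
    converged: np.ndarray

    @property
    def min_radius(self) -> float:
        return float(np.min(self.radius))

    @property
    def min_z(self) -> float:
        return float(self.z_values[int(np.argmin(self.radius))])

    def lining_at_min(self) -> list[tuple[str, int, str]]:
        return self.lining[int(np.argmin(self.radius))]


class _SurfaceDistance:
    """Min distance from a point to the nearest atom *surface* via a KD-tree.

    Radii vary, so the closest center need not be the closest surface; the
    query widens by the radius spread to stay exact.
    """

    def __init__(self, coords: np.ndarray, radii: np.ndarray):
        if len(coords) == 0:
            raise ValueError("empty atom set")
        self.tree = cKDTree(coords)
        self.radii = radii
        self.r_max = float(radii.max())
        self.r_min = float(radii.min())

    def __call__(self, p: np.ndarray) -> float:
        d, i = self.tree.query(p, k=1)
        best = d - self.radii[i]
        spread = self.r_max - self.r_min
        if spread > 0:
            idx = self.tree.query_ball_point(p, d + spread + 1e-9)
            ds = np.linalg.norm(self.tree.data[idx] - p, axis=1) - self.radii[idx]
            best = min(best, float(ds.min()))
        return float(best)

    def near(self, p: np.ndarray, cutoff: float) -> np.ndarray:
        """Indices of atoms whose surface is within ``cutoff`` of ``p``."""
        idx = np.array(self.tree.query_ball_point(p, cutoff + self.r_max), dtype=int)
        if len(idx) == 0:
            return idx
        ds = np.linalg.norm(self.tree.data[idx] - p, axis=1) - self.radii[idx]
        return idx[ds <= cutoff]


def pore_profile(
    struct: Structure,
    axis: PoreAxis,
    z_range: tuple[float, float],
    z_step: float = 0.5,
    xy_search: float = 12.0,
    n_starts: int = 64,
    seed: int = 0,
    lining_margin: float = 1.0,
    include_het: bool = False,
    conv_tol: float = 0.01,
) -> PoreProfile:
    """Largest-inscribed-sphere pore radius along a channel axis.

    At each axial station z the in-plane point maximizing the distance to
    the nearest atom surface is located by ``n_starts`` seeded random starts
    (warm-started from the neighbouring station) refined with Nelder–Mead;
    the maximized clearance is the pore radius (floored at 0 where the plane
    is fully occluded).  The search is confined to within ``xy_search`` Å of
    the axis.  Lining residues are those with an atom surface within
    ``lining_margin`` of the pore sphere.  Deterministic for a given seed.
    """
    mask = struct.protein_mask() if not include_het else np.ones(struct.n_atoms, bool)
    if not mask.any():
        raise ValueError("no atoms available for pore profiling")
    local = axis.to_frame(struct.coords[mask])
    radii = struct.vdw[mask]
    idx_map = np.flatnonzero(mask)
    sd = _SurfaceDistance(local, radii)

    rng = np.random.default_rng(seed)
    z_lo, z_hi = z_range
    z_values = np.arange(z_lo, z_hi + 0.5 * z_step, z_step)
    out_r = np.empty(len(z_values))
    out_c = np.empty((len(z_values), 2))
    out_conv = np.ones(len(z_values), dtype=bool)
    lining: list[list[tuple[str, int, str]]] = []

    prev_xy = np.zeros(2)
    penalty = 1e4
    for zi, z in enumerate(z_values):
        def objective(xy, z=z):
            rho = np.hypot(xy[0], xy[1])
            pen = penalty * max(0.0, rho - xy_search)
            return -sd(np.array([xy[0], xy[1], z])) + pen

        # candidate starts: warm start, axis point, seeded random points in the disk
        theta = rng.uniform(0, 2 * np.pi, n_starts)
        rad = xy_search * np.sqrt(rng.uniform(0, 1, n_starts))
        starts = np.vstack([
            prev_xy,
            [0.0, 0.0],
            np.column_stack([rad * np.cos(theta), rad * np.sin(theta)]),
        ])
        vals = np.array([objective(s) for s in starts])
        best_val = np.inf
        best_xy = starts[int(np.argmin(vals))]
        converged = False
        for s in starts[np.argsort(vals)[:4]]:
            res = minimize(objective, s, method="Nelder-Mead",
                           options={"xatol": conv_tol * 0.1,
                                    "fatol": conv_tol * 0.1,
                                    "maxiter": 400})
            if res.fun < best_val:
                best_val = res.fun
                best_xy = res.x
                converged = bool(res.success)
        out_r[zi] = max(0.0, -best_val)
        out_c[zi] = best_xy
        out_conv[zi] = converged
        prev_xy = best_xy

        center = np.array([best_xy[0], best_xy[1], z])
        near = sd.near(center, out_r[zi] + lining_margin)
        residues = sorted({
            (str(struct.chain_ids[idx_map[i]]),
             int(struct.res_seq[idx_map[i]]),
             str(struct.res_names[idx_map[i]]))
            for i in near
        })
        lining.append(residues)

    if not out_conv.all():
        bad = z_values[~out_conv]
        warnings.warn(f"pore search did not converge at z = {bad.tolist()}")
    return PoreProfile(axis, z_values, out_r, out_c, lining, out_conv)


def channel_length(profile: PoreProfile, enclosure_radius: float = 10.0) -> float:
    """Axial length of the enclosed channel around the constriction.

    The channel is the maximal contiguous run of stations with pore radius
    below ``enclosure_radius`` containing the global minimum; its length is
    the number of stations times the step.  Raises when even the
    constriction is wider than ``enclosure_radius``.
    """
    enclosed = profile.radius < enclosure_radius
    i_min = int(np.argmin(profile.radius))
    if not enclosed[i_min]:
        raise ValueError(
            f"no enclosed interval: min radius {profile.min_radius:.2f} Å >= "
            f"enclosure radius {enclosure_radius:.2f} Å"
        )
    i0 = i_min
    while i0 > 0 and enclosed[i0 - 1]:
        i0 -= 1
    i1 = i_min
    while i1 < len(enclosed) - 1 and enclosed[i1 + 1]:
        i1 += 1
    step = float(profile.z_values[1] - profile.z_values[0]) if len(profile.z_values) > 1 else 0.0
    return (i1 - i0 + 1) * step


# ---------------------------------------------------------------------------
# trans-membrane helix counting

def count_tm_helices(
    struct: Structure,
    slab: tuple[float, float],
    axis: PoreAxis | None = None,
    ca_dist_range: tuple[float, float] = (5.0, 6.8),
    min_run: int = 6,
) -> dict[str, int]:
    """Count helices crossing a membrane slab, per chain plus ``"total"``.

    Helical stretches are detected from the Cα(i)→Cα(i+4) distance
    signature (≈6.2 Å in an α-helix; accepted window ``ca_dist_range``) over
    runs of at least ``min_run`` consecutive residues.  A helix counts as
    trans-membrane when its Cα z-extent (along ``axis``, default the global
    z direction) spans both slab faces.
    """
    z_lo, z_hi = slab
    if axis is None:
        axis = PoreAxis((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
    counts: dict[str, int] = {}
    total = 0
    for ch in dict.fromkeys(struct.chain_ids[~struct.het]):
        m = struct.select(chain=str(ch), atom_names=("CA",))
        if not m.any():
            continue
        resnums = struct.res_seq[m]
        order = np.argsort(resnums)
        resnums = resnums[order]
        ca = axis.to_frame(struct.coords[m][order])
        # helical flag per residue i based on the i -> i+4 distance
        helical = np.zeros(len(resnums), dtype=bool)
        pos = {int(r): j for j, r in enumerate(resnums)}
        for j, r in enumerate(resnums):
            j4 = pos.get(int(r) + 4)
            if j4 is not None:
                d = np.linalg.norm(ca[j4] - ca[j])
                lo, hi = ca_dist_range
                helical[j] = lo <= d <= hi
        # segment into runs over consecutive residue numbers
        n_tm = 0
        run: list[int] = []
        def flush(run: list[int]) -> int:
            if len(run) < min_run:
                return 0
            z = ca[run, 2]
            # include the +4 tail residues of the run in the extent
            tail = [pos[int(resnums[j]) + k] for j in run[-1:]
                    for k in range(1, 5) if int(resnums[j]) + k in pos]
            if tail:
                z = np.concatenate([z, ca[tail, 2]])
            return int(z.min() <= z_lo and z.max() >= z_hi)
        for j in range(len(resnums)):
            if helical[j] and (not run or int(resnums[j]) == int(resnums[run[-1]]) + 1):
                run.append(j)
            else:
                n_tm += flush(run)
                run = [j] if helical[j] else []
        n_tm += flush(run)
        counts[str(ch)] = n_tm
        total += n_tm
    counts["total"] = total
    return counts


# ---------------------------------------------------------------------------
# accessible-volume dye sampling

@dataclass
class AVCloud:
    """Sterically allowed dye-sphere centres around a labeling site."""

    attachment: str
    attachment_pos: np.ndarray
    positions: np.ndarray               # (n, 3)
    linker_length: float
    linker_width: float
    dye_radius: float
    n_attempted: int
    n_accepted: int

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def _grid_geodesic(free: np.ndarray, start: tuple[int, int, int],
                   spacing: float) -> np.ndarray:
    """Dijkstra geodesic distance over a boolean obstacle grid (26-conn)."""
    shape = free.shape
    dist = np.full(shape, np.inf)
    if not free[start]:
        return dist
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    costs = [spacing * np.sqrt(i * i + j * j + k * k) for i, j, k in offsets]
    dist[start] = 0.0
    heap = [(0.0, start)]
    while heap:
        d, (x, y, z) = heapq.heappop(heap)
        if d > dist[x, y, z]:
            continue
        for (dx, dy, dz), c in zip(offsets, costs):
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2] \
                    and free[nx, ny, nz]:
                nd = d + c
                if nd < dist[nx, ny, nz]:
                    dist[nx, ny, nz] = nd
                    heapq.heappush(heap, (nd, (nx, ny, nz)))
    return dist


def sample_dye_av(
    struct: Structure,
    chain: str,
    res_num: int,
    atom_name: str,
    dye: DyeModel,
    n_samples: int = 1000,
    seed: int = 0,
    grid_spacing: float = 1.0,
    max_attempt_factor: int = 200,
) -> AVCloud:
    """Rejection-sample clash-free, linker-reachable dye positions.

    Candidate dye-sphere centres are drawn uniformly in the reach sphere of
    radius ``linker_length`` around the attachment atom and accepted when
    (a) the geodesic path from the attachment — breadth-first over an
    obstacle grid with ``linker_width/2`` clearance — reaches the candidate
    within the linker length, and (b) the dye sphere clashes with no
    structure atom.  The attachment atom itself is not an obstacle.  The
    dye-sphere centre stands in for the geometric centre of the chromophore.
    """
    m = struct.select(chain=chain, res_first=res_num, res_last=res_num,
                      atom_names=(atom_name,), protein_only=False)
    idx = np.flatnonzero(m)
    if len(idx) != 1:
        raise ValueError(
            f"attachment atom {chain}/{res_num}/{atom_name}: found {len(idx)} matches"
        )
    a_pos = struct.coords[idx[0]]
    obst_mask = np.ones(struct.n_atoms, dtype=bool)
    obst_mask[idx[0]] = False
    coords = struct.coords[obst_mask]
    radii = struct.vdw[obst_mask]

    length = dye.linker_length
    half = int(np.ceil(length / grid_spacing)) + 1
    n_side = 2 * half + 1
    axes = (np.arange(n_side) - half) * grid_spacing
    if len(coords):
        tree = cKDTree(coords)
        gx, gy, gz = np.meshgrid(axes, axes, axes, indexing="ij")
        centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + a_pos
        d, i = tree.query(centers, k=1)
        clearance = d - radii[i]
        free = (clearance >= dye.linker_width / 2).reshape(n_side, n_side, n_side)
    else:
        tree = None
        free = np.ones((n_side, n_side, n_side), dtype=bool)

    start = (half, half, half)
    start_offset = 0.0
    if not free[start]:
        # the attachment sits against its own residue: seed from the nearest
        # free cell within a short radius, charging its distance to the linker
        reach_cells = int(np.ceil(5.0 / grid_spacing))
        best = None
        for i in range(-reach_cells, reach_cells + 1):
            for j in range(-reach_cells, reach_cells + 1):
                for k in range(-reach_cells, reach_cells + 1):
                    c = (half + i, half + j, half + k)
                    if free[c]:
                        d = grid_spacing * np.sqrt(i * i + j * j + k * k)
                        if best is None or d < best[0]:
                            best = (d, c)
        if best is None:
            raise ValueError("labeling site fully buried: no free cell at attachment")
        start_offset, start = best
    geo = start_offset + _grid_geodesic(free, start, grid_spacing)

    def line_of_sight(pts: np.ndarray) -> np.ndarray:
        """Straight linker path from the attachment clear at linker_width/2."""
        if tree is None:
            return np.ones(len(pts), dtype=bool)
        out = np.empty(len(pts), dtype=bool)
        for j, p in enumerate(pts):
            seg = np.linalg.norm(p - a_pos)
            n_chk = max(2, int(np.ceil(seg / (grid_spacing / 2))) + 1)
            line = a_pos + np.linspace(0, 1, n_chk)[:, None] * (p - a_pos)
            d, i = tree.query(line, k=1)
            out[j] = bool(np.all(d - radii[i] >= dye.linker_width / 2))
        return out

    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    n_attempted = 0
    max_attempts = max_attempt_factor * n_samples
    while len(accepted) < n_samples and n_attempted < max_attempts:
        batch = min(4096, max_attempts - n_attempted)
        u = rng.normal(size=(batch, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = length * rng.uniform(0, 1, batch) ** (1 / 3)
        pts = a_pos + u * r[:, None]
        cell = np.rint((pts - a_pos) / grid_spacing).astype(int) + half
        np.clip(cell, 0, n_side - 1, out=cell)
        reach = geo[cell[:, 0], cell[:, 1], cell[:, 2]] <= length
        if tree is not None:
            d, i = tree.query(pts, k=1)
            clash_free = (d - radii[i]) >= dye.dye_radius
        else:
            clash_free = np.ones(batch, dtype=bool)
        # the coarse grid geodesic over-estimates path length; a clear
        # straight-line linker path also counts as reachable
        ok = reach.copy()
        retry = clash_free & ~reach
        if retry.any():
            ok[retry] = line_of_sight(pts[retry])
        ok &= clash_free
        # count only the attempts actually consumed
        acc_idx = np.flatnonzero(ok)
        need = n_samples - len(accepted)
        if len(acc_idx) >= need:
            accepted.extend(pts[acc_idx[:need]])
            n_attempted += int(acc_idx[need - 1]) + 1
        else:
            accepted.extend(pts[acc_idx])
            n_attempted += batch
    if not accepted:
        raise ValueError("labeling site fully buried: zero accepted dye positions")
    return AVCloud(
        attachment=f"{chain}/{res_num}/{atom_name}",
        attachment_pos=a_pos.copy(),
        positions=np.array(accepted),
        linker_length=dye.linker_length,
        linker_width=dye.linker_width,
        dye_radius=dye.dye_radius,
        n_attempted=n_attempted,
        n_accepted=len(accepted),
    )


def av_distance(
    cloud_a: AVCloud,
    cloud_b: AVCloud,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> DistanceSummary:
    """Inter-dye distance distribution between two accessible volumes.

    Mean and sd over all pairwise distances (subsampled with a seeded
    generator above ``max_pairs``); the centroid–centroid distance is
    reported alongside, matching the two readings of an "average distance
    between geometric centers".
    """
    pa, pb = cloud_a.positions, cloud_b.positions
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("empty accessible-volume cloud")
    n_pairs = len(pa) * len(pb)
    if n_pairs <= max_pairs:
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1).ravel()
    else:
        rng = np.random.default_rng(seed)
        ia = rng.integers(0, len(pa), max_pairs)
        ib = rng.integers(0, len(pb), max_pairs)
        d = np.linalg.norm(pa[ia] - pb[ib], axis=1)
    centroid_d = float(np.linalg.norm(cloud_a.centroid - cloud_b.centroid))
    keep = d if len(d) <= 10_000 else d[:: len(d) // 10_000 + 1]
    return DistanceSummary(
        mean=float(d.mean()),
        sd=float(d.std()),
        samples=keep.tolist(),
        centroid_distance=centroid_d,
    )


# ---------------------------------------------------------------------------
# output helpers

def write_pore_profile(profile: PoreProfile, path) -> None:
    """TSV: ``z  radius  n_lining  lining_residues``."""
    with open(path, "w") as fh:
        fh.write("z\tradius\tn_lining\tlining_residues\n")
        for z, r, lin in zip(profile.z_values, profile.radius, profile.lining):
            names = ",".join(f"{c}:{n}{rn}" for c, n, rn in lin)
            fh.write(f"{z:.3f}\t{r:.3f}\t{len(lin)}\t{names}\n")


def write_av_cloud_pdb(cloud: AVCloud, path) -> None:
    """Dye positions as HETATM pseudo-atoms (element D as dummy carbon)."""
    with open(path, "w") as fh:
        for i, p in enumerate(cloud.positions, 1):
            fh.write(
                f"HETATM{i % 100000:5d}  AV  DYE A{i % 10000:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
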