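"""Per-frame geometric observables of labelled protein-subunit trajectories.

Operations mirror the standard per-frame analyses of MreB molecular-dynamics
trajectories: subdomain-centroid opening/dihedral angles of the actin fold,
inter-subunit Euler bend/twist angles from body-frame triads, numerical
solvent-accessible surface area (buried SASA between interacting molecules),
and membrane-patch curvature from a quadratic surface fit.

All coordinates are in nm; all reported angles in degrees.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

SUBDOMAINS = ("IA", "IB", "IIA", "IIB")

#: van der Waals radii used when reading structures, nm (per element)
VDW_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
    "P": 0.180, "MG": 0.173, "NA": 0.227, "CL": 0.175,
}

#: water-probe radius for solvent-accessible surface area, nm (1.40 A)
PROBE_RADIUS_NM = 0.14

#: residues of the N-terminal amphipathic helix, excluded from subdomain centres
AMPHIPATHIC_HELIX_RESIDUES = range(1, 9)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class StructureFrame:
    """Labelled atom coordinates of one trajectory frame.

    ``subdomain`` entries are "IA"/"IB"/"IIA"/"IIB" or "none"; atoms of the
    amphipathic helix (residues 1-8) must carry "none" since they are excluded
    from subdomain centres.
    """

    coords: np.ndarray          # (n, 3), nm
    radii: np.ndarray           # (n,), nm
    subunit: np.ndarray         # (n,) labels
    subdomain: np.ndarray       # (n,) in SUBDOMAINS or "none"
    residue_index: np.ndarray   # (n,) 1-based
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.subunit = np.asarray(self.subunit)
        self.subdomain = np.asarray(self.subdomain)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        n = len(self.coords)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        for arr, name in ((self.radii, "radii"), (self.subunit, "subunit"),
                          (self.subdomain, "subdomain"),
                          (self.residue_index, "residue_index")):
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
        bad = set(np.unique(self.subdomain)) - set(SUBDOMAINS) - {"none"}
        if bad:
            raise ValueError(f"unknown subdomain labels: {sorted(bad)}")
        helix = np.isin(self.residue_index, list(AMPHIPATHIC_HELIX_RESIDUES))
        if np.any(helix & (self.subdomain != "none")):
            raise ValueError("amphipathic-helix residues (1-8) must be unlabelled")

    def select(self, subunit) -> np.ndarray:
        return np.flatnonzero(self.subunit == subunit)

    @property
    def subunits(self) -> list:
        return list(dict.fromkeys(self.subunit.tolist()))


@dataclass(frozen=True)
class SubunitTriad:
    """Body frame (d1, d2, d3) of one subunit (or subunit pair).

    d3 points along the filament axis (towards the next subunit), d2 is the
    component of the membrane normal perpendicular to d3, and d1 = d3 x d2 as
    in the source convention.  Note that the ordered triple (d1, d2, d3) built
    this way has determinant -1; the Euler decomposition accounts for it.
    """

    origin: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray

    def __post_init__(self) -> None:
        M = self.matrix
        if not np.allclose(M.T @ M, np.eye(3), atol=1e-8):
            raise ValueError("triad vectors must be orthonormal")
        if not np.allclose(self.d1, np.cross(self.d3, self.d2), atol=1e-8):
            raise ValueError("triad must satisfy d1 = d3 x d2")

    @property
    def matrix(self) -> np.ndarray:
        """Columns (d1, d2, d3)."""
        return np.column_stack([self.d1, self.d2, self.d3])

    def rotated(self, R: np.ndarray, origin: np.ndarray | None = None) -> "SubunitTriad":
        return SubunitTriad(
            origin=self.origin if origin is None else np.asarray(origin, float),
            d1=R @ self.d1, d2=R @ self.d2, d3=R @ self.d3)


@dataclass
class AngleSeries:
    """Time series of one named angle, degrees."""

    name: str
    times: np.ndarray    # ns, non-decreasing
    values: np.ndarray   # degrees

    VALID_NAMES = ("opening", "dihedral", "theta1", "theta2", "theta3")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def window(self, t_start: float, t_end: float) -> "AngleSeries":
        m = (self.times >= t_start) & (self.times <= t_end)
        return AngleSeries(self.name, self.times[m], self.values[m])

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter="\t", header=f"time_ns\t{self.name}_deg", comments="")

    @classmethod
    def from_tsv(cls, path, name: str) -> "AngleSeries":
        data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls(name, data[:, 0], data[:, 1])


# ---------------------------------------------------------------------------
# trajectory input
# ---------------------------------------------------------------------------


def read_pdb_frames(path, subdomain_map: dict, frame_dt_ns: float = 0.2,
                    radii: dict | None = None) -> list[StructureFrame]:
    """Read a multi-model PDB into labelled frames (coordinates in nm).

    Chains become subunits.  ``subdomain_map`` maps a subdomain name to an
    inclusive residue-id range, e.g. ``{"IA": (9, 32), "IB": (33, 60), ...}``;
    unmapped residues (and the amphipathic helix, residues 1-8) are labelled
    "none".  Frame times are ``model_index * frame_dt_ns``.
    """
    import biotite.structure.io.pdb as pdb

    stack = pdb.PDBFile.read(str(path)).get_structure()
    radii = radii or VDW_RADII_NM
    labels = np.full(stack.array_length(), "none", dtype=object)
    res_ids = stack.res_id
    for name, (lo, hi) in subdomain_map.items():
        if name not in SUBDOMAINS:
            raise ValueError(f"unknown subdomain {name!r}")
        sel = (res_ids >= lo) & (res_ids <= hi)
        sel &= ~np.isin(res_ids, list(AMPHIPATHIC_HELIX_RESIDUES))
        labels[sel] = name
    atom_radii = np.array([radii.get(el.upper(), 0.17) for el in stack.element])
    frames = []
    for m in range(stack.stack_depth()):
        frames.append(StructureFrame(
            coords=stack.coord[m] / 10.0,   # A -> nm
            radii=atom_radii,
            subunit=stack.chain_id.astype(object),
            subdomain=labels.copy(),
            residue_index=res_ids,
            time_ns=m * frame_dt_ns,
        ))
    return frames


# ---------------------------------------------------------------------------
# subdomain centres, opening and dihedral angles
# ---------------------------------------------------------------------------


def subdomain_centers(frame: StructureFrame, subunit,
                      weights: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Centroids of the four subdomains of one subunit, helix excluded.

    Unweighted by default; pass per-atom ``weights`` (e.g. masses) for a
    weighted centre of mass.
    """
    idx = frame.select(subunit)
    if idx.size == 0:
        raise ValueError(f"no atoms for subunit {subunit!r}")
    out = {}
    for name in SUBDOMAINS:
        sel = idx[frame.subdomain[idx] == name]
        if sel.size == 0:
            raise ValueError(f"subunit {subunit!r} is missing subdomain {name}")
        if weights is None:
            out[name] = frame.coords[sel].mean(axis=0)
        else:
            w = np.asarray(weights, float)[sel]
            out[name] = (frame.coords[sel] * w[:, None]).sum(axis=0) / w.sum()
    return out


def _vec_angle(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def opening_angle(centers: dict[str, np.ndarray]) -> float:
    """In-plane opening of the actin fold, degrees.

    Mean of the angle at IIA (between IIA->IIB and IIA->IA) and the angle at
    IA (between IA->IB and IA->IIA).
    """
    a1 = _vec_angle(centers["IIB"] - centers["IIA"], centers["IA"] - centers["IIA"])
    a2 = _vec_angle(centers["IB"] - centers["IA"], centers["IIA"] - centers["IA"])
    return 0.5 * (a1 + a2)


def dihedral_angle(centers: dict[str, np.ndarray]) -> float:
    """Out-of-plane dihedral of the fold, degrees in [0, 180].

    Angle between the normal of the (IA, IB, IIA) plane and the normal of the
    (IIB, IIA, IA) plane; coplanar centres give 0.
    """
    n1 = np.cross(centers["IB"] - centers["IA"], centers["IIA"] - centers["IA"])
    n2 = np.cross(centers["IIA"] - centers["IIB"], centers["IA"] - centers["IIB"])
    return _vec_angle(n1, n2)


# ---------------------------------------------------------------------------
# body-frame triads and Euler bend/twist angles
# ---------------------------------------------------------------------------


def reference_triad(frame: StructureFrame, subunit, partner,
                    membrane_normal) -> SubunitTriad:
    """Build the body frame of ``subunit`` on a reference structure.

    d3 runs from this subunit's centroid towards the partner subunit's
    centroid (the filament axis); d2 is the membrane normal orthogonalized
    against d3; d1 = d3 x d2.
    """
    com_self = frame.coords[frame.select(subunit)].mean(axis=0)
    com_partner = frame.coords[frame.select(partner)].mean(axis=0)
    d3 = com_partner - com_self
    n3 = np.linalg.norm(d3)
    if n3 == 0:
        raise ValueError("coincident subunit centroids")
    d3 = d3 / n3
    m = np.asarray(membrane_normal, float)
    d2 = m - np.dot(m, d3) * d3
    n2 = np.linalg.norm(d2)
    if n2 < 1e-12:
        raise ValueError("membrane normal is parallel to the filament axis")
    d2 = d2 / n2
    return SubunitTriad(origin=com_self, d1=np.cross(d3, d2), d2=d2, d3=d3)


def subunit_triad(frame: StructureFrame, subunit, reference: StructureFrame,
                  ref_triad: SubunitTriad) -> SubunitTriad:
    """Carry a reference triad onto a trajectory frame by rigid superposition.

    The rotation part of the least-squares superposition of the subunit onto
    its reference copy (Kabsch) rotates the reference triad; the origin moves
    to the frame centroid.  Atom ordering must match between frames.
    """
    sel_f = frame.select(subunit)
    sel_r = reference.select(subunit)
    if sel_f.size != sel_r.size or sel_f.size < 3:
        raise ValueError("subunit atom sets must match and contain >= 3 atoms")
    X = reference.coords[sel_r]
    Y = frame.coords[sel_f]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    R, _ = Rotation.align_vectors(Yc, Xc)
    return ref_triad.rotated(R.as_matrix(), origin=Y.mean(axis=0))


def compose_bend_twist(triad: SubunitTriad, theta1: float, theta2: float,
                       theta3: float) -> np.ndarray:
    """Rotation matrix for bend/twist angles (degrees) about the triad axes.

    Applies the twist about d3 first, then the in-plane bend about d2, then
    the towards-membrane bend about d1 (each about the body axis in its
    current orientation): R = R(d1, th1) R(d2, th2) R(d3, th3).
    """
    r3 = Rotation.from_rotvec(np.radians(theta3) * triad.d3)
    r2 = Rotation.from_rotvec(np.radians(theta2) * triad.d2)
    r1 = Rotation.from_rotvec(np.radians(theta1) * triad.d1)
    return (r1 * r2 * r3).as_matrix()


def euler_bend_twist(triad_minus: SubunitTriad,
                     triad_plus: SubunitTriad) -> tuple[float, float, float]:
    """Bend/twist Euler angles (theta1, theta2, theta3) in degrees.

    Decomposes the rotation carrying the minus-subunit triad onto the
    plus-subunit triad as twist about d3, then bending about d2 (parallel to
    the membrane plane), then bending about d1 (towards the membrane), all
    axes taken from the minus triad.  Identical triads give (0, 0, 0); the
    reference structure therefore defines the angle zero by construction.
    """
    Tm = triad_minus.matrix
    Tp = triad_plus.matrix
    R_local = Tm.T @ Tp
    s = 1.0 if np.linalg.det(Tm) > 0 else -1.0
    # conjugation by an improper basis matrix flips rotation angles
    angles = s * Rotation.from_matrix(R_local).as_euler("XYZ", degrees=True)
    th1, th2, th3 = (float(a) for a in angles)
    if abs(th2) > 80.0:
        warnings.warn("theta2 near gimbal lock (|theta2| > 80 deg); "
                      "decomposition ill-conditioned", RuntimeWarning)
    return th1, th2, th3


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(coords: np.ndarray, radii: np.ndarray,
         probe_radius: float = PROBE_RADIUS_NM, n_points: int = 960,
         per_atom: bool = False):
    """Rolling-probe solvent-accessible surface area, nm^2.

    Shrake-Rupley sampling: test points on each atom's probe-extended sphere
    are accessible unless inside any neighbour's extended sphere.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    ext = radii + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(coords))
    max_ext = ext.max()
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        nbrs = tree.query_ball_point(coords[i], ext[i] + max_ext)
        nbrs = [j for j in nbrs if j != i
                and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        acc = np.ones(n_points, dtype=bool)
        for j in nbrs:
            # tie-break exactly-overlapping surfaces (e.g. coincident atoms)
            # towards the lower atom index so shared area is counted once
            thr = ext[j] + 1e-9 if j < i else ext[j] - 1e-9
            acc &= np.linalg.norm(pts - coords[j], axis=1) >= thr
            if not acc.any():
                break
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * acc.mean()
    return areas if per_atom else float(areas.sum())


def buried_sasa(coords_a, radii_a, coords_b, radii_b,
                probe_radius: float = PROBE_RADIUS_NM, n_points: int = 960) -> float:
    """Contact area buried between two molecules, (A1 + A2 - A12) / 2, nm^2.

    Symmetric in its arguments; sampling noise can make the value slightly
    negative for non-contacting molecules, in which case it is clipped to 0.
    """
    a1 = sasa(coords_a, radii_a, probe_radius, n_points)
    a2 = sasa(coords_b, radii_b, probe_radius, n_points)
    both_c = np.vstack([coords_a, coords_b])
    both_r = np.concatenate([radii_a, radii_b])
    a12 = sasa(both_c, both_r, probe_radius, n_points)
    buried = 0.5 * (a1 + a2 - a12)
    if abs(buried) < 1e-9 * max(a1, a2):
        return 0.0
    if buried < 0:
        if buried < -1e-6 * max(a1, a2):
            warnings.warn(f"buried SASA slightly negative ({buried:.3g} nm^2) "
                          "from sampling noise; clipping to 0", RuntimeWarning)
        buried = 0.0
    return float(buried)


# ---------------------------------------------------------------------------
# membrane-patch curvature
# ---------------------------------------------------------------------------


def membrane_curvature(points: np.ndarray,
                       protein_side: np.ndarray | None = None) -> float:
    """Signed curvature (1/nm) of a membrane leaflet point cloud.

    Fits z = a x^2 + b x y + c y^2 + d x + e y + f in the principal-axes frame
    of the cloud and returns the principal curvature of largest magnitude at
    the centre of the fitted surface.  Positive sign means the surface bends
    towards ``protein_side`` (a lab-frame direction, e.g. the filament
    centroid minus the membrane centroid); without it the sign follows the
    arbitrary orientation of the fit normal.
    """
    P = np.asarray(points, float)
    if P.ndim != 2 or P.shape[1] != 3 or len(P) < 6:
        raise ValueError("need at least 6 points of shape (n, 3)")
    centroid = P.mean(axis=0)
    Q = P - centroid
    # principal axes: normal = least-variance direction
    _, _, Vt = np.linalg.svd(Q, full_matrices=False)
    axes = Vt  # rows: in-plane-1, in-plane-2, normal
    if np.linalg.det(axes) < 0:
        axes[2] *= -1.0
    if protein_side is not None:
        if np.dot(axes[2], np.asarray(protein_side, float)) < 0:
            axes[1] *= -1.0
            axes[2] *= -1.0
    uvw = Q @ axes.T
    x, y, z = uvw[:, 0], uvw[:, 1], uvw[:, 2]
    A = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    a, b, c, d, e, _f = coef
    # shape operator at the centre of the fitted surface (x=y=0)
    grad = np.array([d, e])
    H = np.array([[2 * a, b], [b, 2 * c]])
    g = np.eye(2) + np.outer(grad, grad)
    S = np.linalg.solve(g, H) / math.sqrt(1.0 + grad @ grad)
    eigs = np.linalg.eigvals(S)
    k = float(eigs[np.argmax(np.abs(eigs))].real)
    return k
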