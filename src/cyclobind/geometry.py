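"""Per-frame geometric descriptors of cyclodextrin inclusion complexes.

The host frame is anchored on the ring of glycosidic oxygens: its origin is
their unweighted centroid and its z-axis is the least-squares plane normal,
oriented from the secondary (wide, O2/O3) rim toward the primary (narrow, O6)
rim.  Against that frame the package computes

* the signed host-guest center-of-mass distance ``d`` (negative when the
  guest center sits nearer the secondary rim than the primary rim),
* the guest orientation ``theta``, the angle between a designated B->A guest
  atom vector and the cavity axis,
* per-glucose tilt angles ``tau`` between each pyran-ring plane and the
  glycosidic-oxygen plane, mapped to (0, 180) deg via radially oriented ring
  normals so that values above 90 deg mean the unit leans with its
  secondary-rim edge inward,
* the cavity circularity (axis ratio of the best-fit ellipse through the
  projected glycosidic oxygens; 1 for a perfect circle),
* a host-guest hydrogen-bond count, and
* the binding-mode label: UNBOUND beyond a 6.5 A cutoff on |d|, else BS for
  theta < 90 deg and BP for theta >= 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .structure import CDTopology, MolecularStructure, SelectionSpec

__all__ = [
    "BOUND_CUTOFF",
    "HostFrameBasis",
    "HBondCriteria",
    "GeometryDescriptors",
    "build_frame_basis",
    "signed_com_distance",
    "guest_orientation",
    "tilt_angles",
    "circularity",
    "count_hbonds",
    "classify_mode",
    "describe_frame",
    "describe_trajectory",
]

#: Cutoff (A) on |signed COM distance| separating bound from unbound frames.
BOUND_CUTOFF = 6.5


@dataclass(frozen=True)
class HostFrameBasis:
    """Right-handed orthonormal frame anchored on the glycosidic-oxygen ring."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (donor-acceptor distance, H-D-A angle)."""

    max_da_distance: float = 3.5  # A
    max_angle: float = 30.0  # deg

    def __post_init__(self):
        if self.max_da_distance <= 0 or self.max_angle <= 0:
            raise ValueError("hydrogen-bond criteria must be positive")


@dataclass
class GeometryDescriptors:
    """All per-frame descriptors computed against one internally consistent basis."""

    d_signed: float
    theta: float
    tau: np.ndarray
    tau_mean: float
    circularity: float
    n_hbonds: int | None
    mode: str


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (centroid, unit normal)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vh = np.linalg.svd(centered, full_matrices=False)
    if points.shape[0] < 3 or s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("points are collinear or coincident; no unique plane")
    return centroid, vh[2]


def build_frame_basis(structure: MolecularStructure,
                      topology: CDTopology) -> HostFrameBasis:
    """Host frame from the glycosidic-oxygen ring.

    z is the least-squares plane normal, sign-fixed so that it points from
    the secondary-rim oxygen centroid toward the primary-rim oxygen centroid;
    x points toward unit 1's glycosidic oxygen projected into the plane.
    """
    gly = structure.coords(topology.glycosidic_oxygens)
    origin, z = _fit_plane(gly)
    prim = structure.centroid(topology.prim_serials)
    sec = structure.centroid(topology.sec_serials)
    axis = prim - sec
    proj = float(z @ axis)
    if abs(proj) < 1e-12:
        raise GeometryError("rim oxygens do not resolve the cavity axis direction")
    if proj < 0:
        z = -z
    v = gly[0] - origin
    v = v - (v @ z) * z
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise GeometryError("unit-1 glycosidic oxygen coincides with the origin")
    x = v / norm
    y = np.cross(z, x)
    return HostFrameBasis(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def signed_com_distance(structure: MolecularStructure, topology: CDTopology,
                        selection: SelectionSpec,
                        basis: HostFrameBasis) -> float:
    """Signed distance (A) between the guest mass-weighted COM and the origin.

    Negative when the guest COM is farther from the primary-rim oxygen
    centroid than from the secondary-rim one (guest on the secondary side).
    """
    if not selection.guest:
        raise GeometryError("empty guest selection")
    com = structure.com(selection.guest)
    if not topology.prim_serials or not topology.sec_serials:
        raise GeometryError("topology lacks rim oxygens")
    d_prim = np.linalg.norm(com - structure.centroid(topology.prim_serials))
    d_sec = np.linalg.norm(com - structure.centroid(topology.sec_serials))
    sign = -1.0 if d_prim > d_sec else 1.0
    return sign * float(np.linalg.norm(com - basis.origin))


def guest_orientation(structure: MolecularStructure, selection: SelectionSpec,
                      basis: HostFrameBasis) -> float:
    """Angle theta (deg, in [0, 180]) between the guest B->A vector and +z."""
    tail, head = selection.guest_vector
    v = structure.atom(head).position - structure.atom(tail).position
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise GeometryError("guest orientation vector has zero length")
    cosang = np.clip(v @ basis.z_axis / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def tilt_angles(structure: MolecularStructure, topology: CDTopology,
                basis: HostFrameBasis) -> tuple[np.ndarray, float]:
    """Per-unit glucose tilt angles tau (deg) and their mean.

    Each pyran ring's least-squares plane normal is oriented to have a
    non-negative component along the unit's outward radial direction
    (projection of ring centroid - origin into the basis plane); tau is then
    the angle between that normal and +z.  A stave of a perfect cylinder
    gives 90 deg; smaller tau means the secondary rim opens outward.
    """
    taus = []
    for ring in topology.pyran_rings:
        pts = structure.coords(ring)
        centroid, normal = _fit_plane(pts)
        radial = centroid - basis.origin
        radial = radial - (radial @ basis.z_axis) * basis.z_axis
        rnorm = np.linalg.norm(radial)
        if rnorm < 1e-9:
            raise GeometryError("pyran ring centroid lies on the cavity axis")
        if normal @ (radial / rnorm) < 0:
            normal = -normal
        cosang = np.clip(normal @ basis.z_axis, -1.0, 1.0)
        taus.append(np.degrees(np.arccos(cosang)))
    taus = np.array(taus)
    return taus, float(taus.mean())


def circularity(structure: MolecularStructure, topology: CDTopology,
                basis: HostFrameBasis) -> float:
    """Cavity circularity: sqrt of the eigenvalue ratio of the 2x2 covariance
    of the glycosidic oxygens projected onto the basis plane (1 = circle)."""
    if len(topology.glycosidic_oxygens) < 5:
        raise GeometryError("need at least 5 glycosidic oxygens for circularity")
    pts = structure.coords(topology.glycosidic_oxygens) - basis.origin
    uv = np.column_stack([pts @ basis.x_axis, pts @ basis.y_axis])
    cov = np.cov(uv.T, bias=True)
    lam = np.linalg.eigvalsh(cov)
    if lam[1] < 1e-12:
        raise GeometryError("degenerate glycosidic-oxygen covariance")
    return float(np.sqrt(max(lam[0], 0.0) / lam[1]))


def _donors_with_h(structure: MolecularStructure, serials: set[int]):
    """(donor, [H...]) pairs: O/N atoms with an H within 1.2 A in the same set."""
    atoms = [structure.atom(s) for s in serials]
    hydrogens = [a for a in atoms if a.element.upper() == "H"]
    out = []
    for a in atoms:
        if a.element.upper() not in ("O", "N"):
            continue
        hs = [h for h in hydrogens
              if np.linalg.norm(h.position - a.position) <= 1.2]
        if hs:
            out.append((a, hs))
    return out


def count_hbonds(structure: MolecularStructure, selection: SelectionSpec,
                 criteria: HBondCriteria = HBondCriteria()) -> int:
    """Host-guest hydrogen bonds (both donation directions).

    A donor-acceptor pair counts once when the D-A distance is within
    ``max_da_distance`` and some donor hydrogen keeps the H-D-A angle within
    ``max_angle``.  Donors are O/N atoms with a covalently attached H;
    acceptors are O/N atoms of the opposite fragment.
    """
    if not any(a.element.upper() == "H" for a in structure.atoms):
        raise GeometryError(
            "hydrogen-bond counting requires explicit hydrogen atoms; "
            "the structure contains none"
        )
    count = 0
    for donor_set, acceptor_set in ((selection.host, selection.guest),
                                    (selection.guest, selection.host)):
        acceptors = [structure.atom(s) for s in acceptor_set
                     if structure.atom(s).element.upper() in ("O", "N")]
        for donor, hs in _donors_with_h(structure, donor_set):
            for acc in acceptors:
                da = acc.position - donor.position
                dist = np.linalg.norm(da)
                if dist > criteria.max_da_distance or dist < 1e-6:
                    continue
                for h in hs:
                    dh = h.position - donor.position
                    cosang = np.clip(
                        dh @ da / (np.linalg.norm(dh) * dist), -1.0, 1.0)
                    if np.degrees(np.arccos(cosang)) <= criteria.max_angle:
                        count += 1
                        break
    return count


def classify_mode(d_signed: float, theta: float,
                  cutoff: float = BOUND_CUTOFF) -> str:
    """Binding-mode label from the signed COM distance and guest orientation.

    UNBOUND when |d| exceeds the cutoff; otherwise BS for theta < 90 deg and
    BP for theta >= 90 deg (the exact 90 deg tie breaks to BP).
    """
    if abs(d_signed) > cutoff:
        return "UNBOUND"
    return "BS" if theta < 90.0 else "BP"


def describe_frame(structure: MolecularStructure, topology: CDTopology,
                   selection: SelectionSpec,
                   criteria: HBondCriteria | None = None,
                   cutoff: float = BOUND_CUTOFF) -> GeometryDescriptors:
    """All descriptors of one frame from a single host-frame basis.

    Hydrogen bonds are counted only when ``criteria`` is given (they need
    explicit hydrogens); otherwise ``n_hbonds`` is None.
    """
    basis = build_frame_basis(structure, topology)
    d = signed_com_distance(structure, topology, selection, basis)
    theta = guest_orientation(structure, selection, basis)
    taus, tau_mean = tilt_angles(structure, topology, basis)
    circ = circularity(structure, topology, basis)
    nhb = count_hbonds(structure, selection, criteria) if criteria else None
    return GeometryDescriptors(
        d_signed=d, theta=theta, tau=taus, tau_mean=tau_mean,
        circularity=circ, n_hbonds=nhb,
        mode=classify_mode(d, theta, cutoff=cutoff),
    )


def describe_trajectory(trajectory, topology: CDTopology,
                        selection: SelectionSpec,
                        criteria: HBondCriteria | None = None,
                        cutoff: float = BOUND_CUTOFF):
    """Per-frame descriptor table (pandas DataFrame, one row per frame)."""
    import pandas as pd

    rows = []
    for i, (frame, t) in enumerate(zip(trajectory.frames, trajectory.times)):
        d = describe_frame(frame, topology, selection, criteria=criteria,
                           cutoff=cutoff)
        rows.append({
            "frame": i, "time_ps": float(t), "d_signed": d.d_signed,
            "theta": d.theta, "tau_mean": d.tau_mean,
            "circularity": d.circularity,
            "n_hbonds": d.n_hbonds, "mode": d.mode,
        })
    return pd.DataFrame(rows)
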