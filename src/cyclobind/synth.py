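"""Ground-truth synthetic structures and trajectories.

Every analysis stage of the package is testable without a docking engine,
an MD engine, or downloads: this module builds truncated-cone
cyclodextrin-like hosts with exactly controllable glucose tilt and cavity
ellipticity, a rigid planar three-ring guest with labelled orientation
atoms, noisy two-state (plus unbound-excursion) descriptor trajectories
driven by a Markov chain, and random toy charge/LJ systems for the
pairwise-decomposition oracle.  All generators are pure functions of their
parameters and seed.

The synthetic host is geometric, not chemical: glycosidic oxygens sit on an
ellipse in the base plane (axis ratio = the requested ellipticity), each
planar six-atom pyran ring is constructed at exactly the requested tilt
angle under the analyzer's radial-normal convention, primary-rim O6 atoms
sit above the base plane (+z) and secondary-rim O2/O3 atoms below.  Bond
lengths are fixture constants; no chemically valid bond topology is
attempted (or needed by the descriptors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .geometry import build_frame_basis
from .structure import (
    AtomRecord,
    CDTopology,
    MolecularStructure,
    SelectionSpec,
    Trajectory,
)

__all__ = [
    "CDBuildParams",
    "TrajSimParams",
    "SimulatedTrajectory",
    "build_cd",
    "dopo_like_guest",
    "place_guest",
    "simulate_descriptor_trajectory",
    "toy_charge_system",
]

_PYRAN_RING_RADIUS = 1.45  # A, hexagon circumradius of the model pyran ring
_MODES = ("BS", "BP", "UNBOUND")


@dataclass(frozen=True)
class CDBuildParams:
    """Geometry of a synthetic cyclodextrin-like host.

    ``n_units`` is 6, 7, or 8 (alpha/beta/gamma); ``base_radius`` the major
    semi-axis (A) of the glycosidic-oxygen ellipse; ``ellipticity`` the
    minor/major axis ratio (1 = circular cavity); ``tilt_deg`` the exact
    per-unit glucose tilt angle; ``rim_offset`` the height (A) of rim
    oxygens above (+z, primary) and below (secondary) the base plane.
    """

    n_units: int = 7
    base_radius: float = 5.0
    ellipticity: float = 1.0
    tilt_deg: float = 80.0
    rim_offset: float = 1.3
    seed: int = 0

    def __post_init__(self):
        if self.n_units not in (6, 7, 8):
            raise ParameterError("n_units must be 6, 7, or 8")
        if self.base_radius <= 0:
            raise ParameterError("base_radius must be positive")
        if not 0 < self.ellipticity <= 1:
            raise ParameterError("ellipticity must be in (0, 1]")


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ParameterError("degenerate direction in synthetic geometry")
    return v / n


def build_cd(params: CDBuildParams) -> tuple[MolecularStructure, CDTopology]:
    """Build a synthetic host and its ground-truth topology.

    Each unit k owns the glycosidic O4 at ellipse angle 2*pi*k/n; its pyran
    ring is a planar hexagon centred between O4(k) and O4(k+1) with the C4
    vertex near the former and the C1 vertex near the next unit's oxygen, so
    that distance-based topology detection recovers the generator's serial
    lists exactly.  Raises on infeasible geometry (bridging distances beyond
    the covalent criterion).
    """
    n = params.n_units
    a = params.base_radius
    b = params.ellipticity * a
    tau = np.radians(params.tilt_deg)
    zhat = np.array([0.0, 0.0, 1.0])

    phi = 2.0 * np.pi * np.arange(n) / n
    gly = np.column_stack([a * np.cos(phi), b * np.sin(phi), np.zeros(n)])

    atoms: list[AtomRecord] = []
    serial = 0
    gly_serials: list[int] = []
    rings: list[list[int]] = []
    prim: list[list[int]] = []
    sec: list[list[int]] = []

    def add(name: str, element: str, res: int, pos: np.ndarray) -> int:
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(serial, name, "GLC", res, element, pos))
        return serial

    for k in range(n):
        res = k + 1
        g_k = gly[k]
        g_next = gly[(k + 1) % n]
        gly_serials.append(add("O4", "O", res, g_k))

        center = 0.5 * (g_k + g_next)
        radial = _normalize(np.array([center[0], center[1], 0.0]))
        normal = np.cos(tau) * zhat + np.sin(tau) * radial
        d = g_k - g_next
        u = _normalize(d - (d @ normal) * normal)  # in-plane, toward O4(k)
        w = np.cross(normal, u)

        # Hexagon vertices; C4 points at O4(k), C1 (opposite) at O4(k+1).
        vertex_names = ("C4", "C5", "O5", "C1", "C2", "C3")
        ring_serials = {}
        for j, nm in enumerate(vertex_names):
            ang = np.radians(60.0 * j)
            pos = center + _PYRAN_RING_RADIUS * (np.cos(ang) * u + np.sin(ang) * w)
            ring_serials[nm] = add(nm, nm[0], res, pos)
        rings.append([ring_serials[nm] for nm in ("O5", "C1", "C2", "C3", "C4", "C5")])

        c4_pos = atoms[ring_serials["C4"] - 1].position
        c1_pos = atoms[ring_serials["C1"] - 1].position
        if (np.linalg.norm(c4_pos - g_k) > 1.8
                or np.linalg.norm(c1_pos - g_next) > 1.8):
            raise ParameterError(
                "infeasible synthetic geometry: glycosidic bridging distance "
                "exceeds the covalent criterion (radius too large for n_units)"
            )

        prim.append([add("O6", "O", res,
                         center + 0.6 * radial + params.rim_offset * zhat)])
        sec.append([
            add("O2", "O", res,
                center + 0.5 * u + 0.6 * radial - params.rim_offset * zhat),
            add("O3", "O", res,
                center - 0.5 * u + 0.6 * radial - params.rim_offset * zhat),
        ])

    structure = MolecularStructure(atoms, label=f"synthetic-CD{n}")
    topology = CDTopology(
        n_units=n, glycosidic_oxygens=gly_serials, pyran_rings=rings,
        prim_rim_oxygens=prim, sec_rim_oxygens=sec,
    )
    return structure, topology


def dopo_like_guest(first_serial: int = 1001) -> tuple[MolecularStructure, tuple[int, int]]:
    """Rigid planar three-ring guest scaffold with labelled vector atoms.

    Mimics the A/B/C ring layout of a dibenzo-fused organophosphorus guest:
    ring A (aromatic carbons) on top, ring B (with phosphorus and its oxygen)
    at the bottom, ring C fused to the side.  Returns the structure and the
    (tail, head) serial pair of the B->A orientation vector, which points
    along +z in this canonical pose.  Bond lengths are fixture constants.
    """
    rho = 1.40
    angles = np.radians(60.0 * np.arange(6) + 30.0)
    hexagon = np.column_stack([rho * np.cos(angles), np.zeros(6),
                               rho * np.sin(angles)])  # in the x-z plane
    ring_a = hexagon + np.array([0.0, 0.0, 2.1])
    ring_b = hexagon + np.array([0.0, 0.0, -2.1])
    ring_c = hexagon + np.array([2.45, 0.0, 0.0])

    atoms: list[AtomRecord] = []
    serial = first_serial - 1

    def add(name: str, element: str, pos: np.ndarray) -> int:
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(serial, name, "DPO", 99, element, pos))
        return serial

    head = None
    for j, pos in enumerate(ring_a):
        s = add(f"CA{j + 1}", "C", pos)
        if j == 1:  # top vertex of ring A
            head = s
    tail = None
    for j, pos in enumerate(ring_b):
        if j == 4:  # bottom vertex of ring B carries the phosphorus
            tail = add("P1", "P", pos)
            add("O1", "O", pos + np.array([0.0, 0.0, -1.5]))
        else:
            add(f"CB{j + 1}", "C", pos)
    for j, pos in enumerate(ring_c):
        add(f"CC{j + 1}", "C", pos)

    return MolecularStructure(atoms, label="synthetic-guest"), (tail, head)


def _rotation_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotation_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def place_guest(host: MolecularStructure, topology: CDTopology,
                guest: MolecularStructure, guest_vector: tuple[int, int],
                d_signed: float, theta: float, azimuth: float = 0.0,
                ) -> tuple[MolecularStructure, SelectionSpec]:
    """Rigidly place the guest at a controlled depth and orientation.

    The guest's mass-weighted COM lands at ``origin + d_signed * z`` of the
    host frame and its B->A vector makes angle ``theta`` (deg) with +z,
    rotated by ``azimuth`` about the cavity axis.  The guest template must be
    in canonical pose (B->A vector along +z).
    """
    if not 0.0 <= theta <= 180.0:
        raise ParameterError("theta must lie in [0, 180] degrees")
    basis = build_frame_basis(host, topology)
    frame = np.column_stack([basis.x_axis, basis.y_axis, basis.z_axis])
    rot = frame @ _rotation_z(azimuth) @ _rotation_y(theta)
    com = guest.com()
    target = basis.origin + d_signed * basis.z_axis
    moved = guest.transformed(rotation=rot, translation=target - rot @ com)
    combined = MolecularStructure(host.atoms + moved.atoms,
                                  label=f"{host.label}+{guest.label}")
    selection = SelectionSpec(
        host=set(int(s) for s in host.serials),
        guest=set(int(s) for s in moved.serials),
        guest_vector=guest_vector,
    )
    return combined, selection


@dataclass(frozen=True)
class TrajSimParams:
    """Two-state binding dynamics with unbound excursions.

    A hidden Markov chain over (BS, BP, UNBOUND) evolves frame to frame; each
    frame draws (d_signed, theta) from that state's Gaussian.  Defaults
    emulate the mode-jumping seen in 100 ns host-guest simulations: BS around
    (-1.0 A, 20 deg) and BP around (+1.2 A, 152 deg) -- the docking-derived
    beta-/gamma-CD poses -- with occasional unbound excursions near 9 A, and
    sticky transitions so dwells last tens of frames.
    """

    n_frames: int = 1000
    dt_ps: float = 10.0
    transition_matrix: tuple = (
        (0.97, 0.02, 0.01),
        (0.02, 0.97, 0.01),
        (0.025, 0.025, 0.95),
    )
    state_means: tuple = ((-1.0, 20.0), (1.2, 152.0), (9.0, 90.0))
    state_sds: tuple = ((0.4, 6.0), (0.4, 6.0), (0.8, 35.0))
    initial_state: str = "BS"
    seed: int = 0

    def __post_init__(self):
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (3, 3) or np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0):
            raise ParameterError("transition_matrix must be 3x3 row-stochastic")
        if np.any(np.asarray(self.state_sds, dtype=float) < 0):
            raise ParameterError("state noise SDs must be non-negative")
        if self.initial_state not in _MODES:
            raise ParameterError(f"initial_state must be one of {_MODES}")


@dataclass
class SimulatedTrajectory:
    """Emitted trajectory (optional) plus the ground-truth per-frame log."""

    log: "object"  # pandas DataFrame: frame, time_ps, state, d_signed, theta
    trajectory: Trajectory | None = None
    selection: SelectionSpec | None = None


def simulate_descriptor_trajectory(params: TrajSimParams,
                                   host: MolecularStructure | None = None,
                                   topology: CDTopology | None = None,
                                   guest: MolecularStructure | None = None,
                                   guest_vector: tuple[int, int] | None = None,
                                   emit_structures: bool = False,
                                   ) -> SimulatedTrajectory:
    """Simulate the hidden binding-mode chain and per-frame descriptors.

    With ``emit_structures=True`` (requires host/topology/guest inputs) a
    multi-model structural trajectory is also emitted by rigidly placing the
    guest at each frame's sampled depth and orientation; tests may bypass
    emission for speed.  Reproducible bitwise for a fixed seed.
    """
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    tm = np.asarray(params.transition_matrix, dtype=float)
    means = np.asarray(params.state_means, dtype=float)
    sds = np.asarray(params.state_sds, dtype=float)

    state = _MODES.index(params.initial_state)
    states = np.empty(params.n_frames, dtype=int)
    d_vals = np.empty(params.n_frames)
    th_vals = np.empty(params.n_frames)
    for i in range(params.n_frames):
        states[i] = state
        d_vals[i] = rng.normal(means[state, 0], sds[state, 0])
        th_vals[i] = np.clip(rng.normal(means[state, 1], sds[state, 1]),
                             0.0, 180.0)
        state = rng.choice(3, p=tm[state])

    times = np.arange(params.n_frames) * params.dt_ps
    log = pd.DataFrame({
        "frame": np.arange(params.n_frames),
        "time_ps": times,
        "state": [_MODES[s] for s in states],
        "d_signed": d_vals,
        "theta": th_vals,
    })

    trajectory = None
    selection = None
    if emit_structures:
        if host is None or topology is None or guest is None or guest_vector is None:
            raise ParameterError(
                "structure emission requires host, topology, guest, guest_vector"
            )
        frames = []
        for d, th in zip(d_vals, th_vals):
            frame, selection = place_guest(host, topology, guest, guest_vector,
                                           d_signed=float(d), theta=float(th))
            frames.append(frame)
        trajectory = Trajectory(frames, times=times)
    return SimulatedTrajectory(log=log, trajectory=trajectory,
                               selection=selection)


def toy_charge_system(n_a: int, n_b: int, seed: int = 0):
    """Two random non-overlapping fragments with charges and LJ parameters.

    Coordinates keep a minimum separation of 2 A; charges are uniform in
    [-1, 1] e, well depths in [0, 0.3] kcal/mol, Rmin/2 in [1.2, 2.2] A.
    Intended as oracle fixtures for the pairwise decomposition.
    """
    from .edaff import ChargeSet, Fragment, LJParamSet

    if n_a < 1 or n_b < 1:
        raise ParameterError("fragments need at least one atom each")
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    box = 4.0 * n ** (1.0 / 3.0) + 4.0
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < n:
        p = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(p - q) >= 2.0 for q in coords):
            coords.append(p)
        attempts += 1
        if attempts > 100000:  # pragma: no cover
            raise ParameterError("could not place non-overlapping toy atoms")
    coords = np.asarray(coords)

    def fragment(xyz: np.ndarray, tag: str, first_serial: int) -> "Fragment":
        atoms = [AtomRecord(first_serial + i, f"X{i + 1}", tag, 1, "C", p)
                 for i, p in enumerate(xyz)]
        m = len(atoms)
        return Fragment(
            structure=MolecularStructure(atoms, label=tag),
            charges=ChargeSet(rng.uniform(-1.0, 1.0, size=m)),
            lj=LJParamSet(rng.uniform(0.0, 0.3, size=m),
                          rng.uniform(1.2, 2.2, size=m)),
        )

    return fragment(coords[:n_a], "FRA", 1), fragment(coords[n_a:], "FRB", 501)
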