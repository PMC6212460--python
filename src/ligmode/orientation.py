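"""Polar orientation collective variables and solid-angle-corrected maps.

The two CVs are the polar angles (theta, phi) of the unit vector from the
ligand hydroxyl oxygen to the bridging carbon, measured in the lab frame
of a declared reference structure after superposing each frame's protein
CA atoms onto it:

    theta = arccos(u_z)   in [0, 180] deg
    phi   = atan2(u_y, u_x)  in (-180, 180] deg, 0 at the poles

Bin counts on a (theta, phi) grid are converted to densities per
steradian by dividing by the exact spherical bin measure

    Omega = dphi_rad * (cos theta_lo - cos theta_hi),

so that maps with different binning are comparable and
sum(density * Omega) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StructureError, UsageError
from .trajio import MolecularSystem, Selection, Trajectory, superpose

__all__ = [
    "OrientationMap",
    "orientation_angles",
    "vector_angles",
    "build_orientation_map",
    "project_reference_poses",
]


def vector_angles(u: np.ndarray) -> tuple[float, float]:
    """(theta, phi) in degrees of a direction vector; phi = 0 at the poles."""
    u = np.asarray(u, dtype=np.float64)
    norm = np.linalg.norm(u)
    if norm < 1e-6:
        raise UsageError("degenerate (near-zero) orientation vector")
    u = u / norm
    theta = np.degrees(np.arccos(np.clip(u[2], -1.0, 1.0)))
    if abs(u[0]) < 1e-12 and abs(u[1]) < 1e-12:
        return float(theta), 0.0
    phi = np.degrees(np.arctan2(u[1], u[0]))
    if phi <= -180.0:
        phi = 180.0
    return float(theta), float(phi)


def _indices(sel) -> np.ndarray:
    return np.asarray(getattr(sel, "indices", sel), dtype=np.intp)


def orientation_angles(traj: Trajectory, oxygen_index: int, carbon_index: int,
                       fit_selection: Selection | np.ndarray,
                       reference: MolecularSystem | None = None
                       ) -> np.ndarray:
    """(n_frames, 2) array of (theta, phi) degrees for the O->C vector.

    Each frame is superposed on the reference structure (default: the
    trajectory topology) over ``fit_selection`` before the vector is
    read off in the reference's lab frame.
    """
    if oxygen_index == carbon_index:
        raise UsageError("oxygen and carbon atom must differ")
    fit = _indices(fit_selection)
    if len(fit) == 0:
        raise UsageError("fit selection is empty")
    ref_coords = (reference.coords if reference is not None
                  else traj.system.coords)
    out = np.empty((traj.n_frames, 2))
    for f in range(traj.n_frames):
        moved, _ = superpose(traj.coords[f], ref_coords, fit)
        out[f] = vector_angles(moved[carbon_index] - moved[oxygen_index])
    return out


@dataclass
class OrientationMap:
    """Binned orientation density on the sphere."""

    theta_edges: np.ndarray   # deg, spanning [0, 180]
    phi_edges: np.ndarray     # deg, spanning [-180, 180]
    counts: np.ndarray        # (n_theta, n_phi) int
    omega: np.ndarray         # steradian per bin
    density: np.ndarray       # per steradian
    n_samples: int

    def argmax_bin(self) -> tuple[int, int]:
        return tuple(np.unravel_index(np.argmax(self.density),
                                      self.density.shape))

    def bin_center(self, it: int, ip: int) -> tuple[float, float]:
        th = 0.5 * (self.theta_edges[it] + self.theta_edges[it + 1])
        ph = 0.5 * (self.phi_edges[ip] + self.phi_edges[ip + 1])
        return float(th), float(ph)

    def top_modes(self, k: int) -> list[tuple[int, int]]:
        """The k highest-density bins that are local maxima of density
        over their 8-neighborhood (phi wraps around)."""
        d = self.density
        nt, npb = d.shape
        peaks = []
        for it in range(nt):
            for ip in range(npb):
                val = d[it, ip]
                if val <= 0:
                    continue
                is_peak = True
                for dt in (-1, 0, 1):
                    for dp in (-1, 0, 1):
                        if dt == 0 and dp == 0:
                            continue
                        jt = it + dt
                        jp = (ip + dp) % npb
                        if 0 <= jt < nt and d[jt, jp] > val:
                            is_peak = False
                if is_peak:
                    peaks.append((val, it, ip))
        peaks.sort(reverse=True)
        return [(it, ip) for _v, it, ip in peaks[:k]]


def build_orientation_map(angle_series: np.ndarray,
                          dtheta: float = 10.0, dphi: float = 10.0
                          ) -> OrientationMap:
    """Histogram (theta, phi) samples and normalize by solid angle.

    density = counts / (n_total * Omega_bin); the polar bins use the
    exact cos-difference measure, so there is no 1/sin(theta) blow-up.
    """
    if dtheta <= 0 or dphi <= 0:
        raise UsageError("bin widths must be positive")
    angles = np.asarray(angle_series, dtype=np.float64)
    if angles.ndim != 2 or angles.shape[1] != 2:
        raise UsageError("angle series must have shape (n, 2)")
    theta, phi = angles[:, 0], angles[:, 1]
    if np.any((theta < 0) | (theta > 180)):
        raise UsageError("theta out of [0, 180]")
    if np.any((phi < -180) | (phi > 180)):
        raise UsageError("phi out of [-180, 180]")

    n_theta = int(round(180.0 / dtheta))
    n_phi = int(round(360.0 / dphi))
    if abs(n_theta * dtheta - 180.0) > 1e-9 or abs(n_phi * dphi - 360.0) > 1e-9:
        raise UsageError("bin widths must divide 180 (theta) and 360 (phi)")
    theta_edges = np.linspace(0.0, 180.0, n_theta + 1)
    phi_edges = np.linspace(-180.0, 180.0, n_phi + 1)
    counts, _, _ = np.histogram2d(theta, phi,
                                  bins=[theta_edges, phi_edges])
    counts = counts.astype(int)

    cos_lo = np.cos(np.radians(theta_edges[:-1]))
    cos_hi = np.cos(np.radians(theta_edges[1:]))
    omega = np.radians(dphi) * (cos_lo - cos_hi)[:, None] * np.ones((1, n_phi))
    n = len(angles)
    if n == 0:
        raise UsageError("empty angle series")
    density = counts / (n * omega)
    return OrientationMap(theta_edges=theta_edges, phi_edges=phi_edges,
                          counts=counts, omega=omega, density=density,
                          n_samples=n)


def project_reference_poses(reference_structures: list[MolecularSystem],
                            oxygen_name: str, carbon_name: str,
                            ligand_resname: str,
                            common_reference: MolecularSystem,
                            fit_expression: str = "protein and name CA"
                            ) -> list[tuple[float, float]]:
    """Project each reference pose onto the (theta, phi) plane.

    Each structure's CA atoms (matched to the common reference by
    chain/residue/atom keys) are superposed on the common reference, then
    the ligand O->C vector's angles are computed in that shared frame.
    """
    from .binding_site import _match_atoms
    from .trajio import select

    ref_sel = select(common_reference, fit_expression)
    out: list[tuple[float, float]] = []
    for struct in reference_structures:
        sel = select(struct, fit_expression)
        i_mob, i_ref = _match_atoms(struct, sel.indices,
                                    common_reference, ref_sel.indices)
        if len(i_mob) < 3:
            raise StructureError(
                f"only {len(i_mob)} matched fit atoms; need >= 3"
            )
        # fit on matched atoms, apply to the whole structure
        from .trajio import kabsch

        R, t = kabsch(struct.coords[i_mob], common_reference.coords[i_ref])
        moved = struct.coords @ R.T + t
        lig_mask = struct.res_names == ligand_resname
        o_idx = np.nonzero(lig_mask & (struct.names == oxygen_name))[0]
        c_idx = np.nonzero(lig_mask & (struct.names == carbon_name))[0]
        if len(o_idx) != 1 or len(c_idx) != 1:
            raise StructureError(
                f"expected one {oxygen_name} and one {carbon_name} atom in "
                f"residue {ligand_resname}"
            )
        out.append(vector_angles(moved[c_idx[0]] - moved[o_idx[0]]))
    return out
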