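"""Magneto-quasistatic induced-field solver (SPFD formulation).

At the stimulation frequencies the head does not perturb the source
field, so B is the coil field and the induced electric field is
E = -j omega A - grad(phi), with the scalar potential phi enforcing
charge conservation div(sigma* E) = 0 inside the conductor and an
insulating boundary (J.n = 0) toward air:

    div( sigma* (grad(phi) + j omega A) ) = 0 .

Discretization is the standard scalar-potential finite-difference
(impedance-method) scheme: potentials on voxel nodes, complex
conductivities sigma* = sigma + j omega eps0 eps_r on voxels,
edge conductances from the mean of the (up to) four voxels sharing an
edge.  Air voxels contribute nothing, which builds the insulating
boundary into the operator.  The resulting complex-symmetric system is
solved with a Jacobi-preconditioned conjugate-orthogonal CG (COCG)
iteration - identical to plain preconditioned CG when the operator is
real - from a zero initial guess, so solves are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import ConfigurationError, ConvergenceError, InvariantViolation

__all__ = [
    "SolverConfig",
    "SPFDSystem",
    "FieldSolution",
    "assemble_spfd",
    "solve",
    "fields_from_potential",
    "solve_band",
    "divergence_ratio",
]


@dataclass(frozen=True)
class SolverConfig:
    """Iterative-solve controls.

    ``tolerance`` is relative, enforced on both the 2-norm and the
    max-norm of the residual; the residual *is* the net nodal current
    imbalance, so the stopping rule directly bounds discrete div(J).
    """

    tolerance: float = 1e-9
    max_iterations: int = 30_000

    def __post_init__(self):
        if not (0.0 < self.tolerance < 1.0):
            raise ConfigurationError("tolerance must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be positive")


@dataclass
class SolverStats:
    iterations: int
    final_residual: float
    residual_history: list


@dataclass
class SPFDSystem:
    """Assembled sparse system over the conducting nodes of one frequency."""

    matrix: sparse.csr_matrix
    rhs: np.ndarray
    unknown_nodes: np.ndarray  # flat node indices into the node grid
    node_shape: tuple
    h_m: float  # voxel edge length in metres
    frequency: float
    sigma_star: np.ndarray  # per-voxel complex conductivity
    affine: np.ndarray
    a_field: object  # callable(points_mm) -> A per ampere (T m)
    current: float = 1.0

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


@dataclass
class FieldSolution:
    """Per-frequency complex field volumes (unit = per driving scenario).

    B is the unperturbed coil field (filled by :func:`solve_band` or by
    the caller); E in V/m, J in A/m^2, potential in V on the node grid.
    """

    frequency: float
    J_volume: np.ndarray  # (nx, ny, nz, 3) complex
    E_volume: np.ndarray | None
    potential: np.ndarray  # (nx+1, ny+1, nz+1) complex
    solver_stats: SolverStats
    B_volume: np.ndarray | None = None
    divergence_ratio: float | None = None


def _edge_conductance(sigma_star: np.ndarray, axis: int, h_m: float) -> np.ndarray:
    """Conductance (S) of node-to-node edges along ``axis``.

    The edge value is the mean sigma* of the voxels sharing the edge
    (air voxels count as zero); conductance = sigma_edge * h for cubic
    voxels.
    """
    trans = [a for a in range(3) if a != axis]
    pad = [(0, 0)] * 3
    for a in trans:
        pad[a] = (1, 1)
    sp = np.pad(sigma_star, pad)
    slices = []
    for d0 in (slice(None, -1), slice(1, None)):
        for d1 in (slice(None, -1), slice(1, None)):
            idx = [slice(None)] * 3
            idx[trans[0]] = d0
            idx[trans[1]] = d1
            slices.append(sp[tuple(idx)])
    return (slices[0] + slices[1] + slices[2] + slices[3]) / 4.0 * h_m


def _edge_midpoints_voxel_coords(edge_index, axis):
    """Voxel-grid coordinates of edge midpoints (voxel centers at ints)."""
    coords = edge_index.astype(float) - 0.5
    coords[:, axis] += 0.5
    return coords


def assemble_spfd(phantom, a_field, frequency: float,
                  include_displacement: bool = True,
                  current: float = 1.0) -> SPFDSystem:
    """Assemble the SPFD system for one frequency.

    ``a_field`` maps world points (mm) to the magnetic vector potential
    per ampere (T m / A); the drive ``current`` (amperes) scales the
    right-hand side linearly.
    """
    sigma_star = phantom.sigma_star_volume(
        frequency, include_displacement=include_displacement
    )
    if not np.any(sigma_star != 0):
        raise ConfigurationError("phantom has no conducting voxels")
    h_m = phantom.voxel_size * 1e-3
    node_shape = tuple(s + 1 for s in phantom.shape)
    n_nodes = int(np.prod(node_shape))
    omega = 2.0 * np.pi * frequency

    complex_system = include_displacement and frequency > 0
    dtype = complex if complex_system else float
    sigma_eff = sigma_star if complex_system else sigma_star.real

    rows, cols, vals = [], [], []
    b_full = np.zeros(n_nodes, dtype=complex)
    for axis in range(3):
        s = _edge_conductance(sigma_eff, axis, h_m)
        edge_idx = np.argwhere(s != 0)
        if len(edge_idx) == 0:
            continue
        s_e = s[edge_idx[:, 0], edge_idx[:, 1], edge_idx[:, 2]]
        n1 = np.ravel_multi_index(edge_idx.T, node_shape)
        step = edge_idx.copy()
        step[:, axis] += 1
        n2 = np.ravel_multi_index(step.T, node_shape)
        rows.extend([n1, n2, n1, n2])
        cols.extend([n1, n2, n2, n1])
        vals.extend([s_e, s_e, -s_e, -s_e])
        if omega > 0:
            mid = _edge_midpoints_voxel_coords(edge_idx, axis)
            world = phantom.voxel_to_world(mid)
            a_e = np.asarray(a_field(world))[:, axis]
            contrib = 1j * omega * s_e * a_e * h_m * current
            np.add.at(b_full, n1, contrib)
            np.add.at(b_full, n2, -contrib)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals).astype(dtype)
    matrix_full = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(n_nodes, n_nodes)
    ).tocsr()
    unknown = np.unique(rows)
    matrix = matrix_full[unknown][:, unknown]
    rhs = b_full[unknown]
    if not complex_system:
        # omega == 0 gives a zero RHS; keep the imaginary part only when
        # it exists (rhs is purely imaginary in the real-sigma case).
        rhs = rhs.astype(complex)
    return SPFDSystem(
        matrix=matrix,
        rhs=rhs,
        unknown_nodes=unknown,
        node_shape=node_shape,
        h_m=h_m,
        frequency=frequency,
        sigma_star=sigma_eff.astype(complex),
        affine=phantom.affine.copy(),
        a_field=a_field,
        current=current,
    )


def _cocg(matrix, b, tolerance, max_iterations):
    """Jacobi-preconditioned COCG for complex-symmetric systems.

    Uses the unconjugated bilinear form; for real SPD systems this is
    exactly preconditioned CG.  Deterministic: zero initial guess.
    """
    diag = matrix.diagonal()
    if np.any(diag == 0):
        raise InvariantViolation("zero diagonal entry in SPFD matrix")
    minv = 1.0 / diag
    x = np.zeros_like(b)
    r = b.copy()
    b2 = np.linalg.norm(b)
    binf = np.max(np.abs(b)) if len(b) else 0.0
    history = []
    if b2 == 0.0:
        return x, SolverStats(0, 0.0, history)
    z = minv * r
    rz = np.sum(r * z)
    p = z.copy()
    for it in range(1, max_iterations + 1):
        Ap = matrix @ p
        pAp = np.sum(p * Ap)
        alpha = rz / pAp
        x = x + alpha * p
        r = r - alpha * Ap
        rel2 = np.linalg.norm(r) / b2
        history.append(float(rel2))
        if rel2 <= tolerance and np.max(np.abs(r)) <= tolerance * binf:
            true_r = b - matrix @ x
            if (np.linalg.norm(true_r) / b2 <= tolerance
                    and np.max(np.abs(true_r)) <= tolerance * binf):
                return x, SolverStats(it, float(np.linalg.norm(true_r) / b2),
                                      history)
            r = true_r  # recurrence drifted; continue from true residual
        z = minv * r
        rz_new = np.sum(r * z)
        beta = rz_new / rz
        rz = rz_new
        p = z + beta * p
    raise ConvergenceError(
        f"COCG did not reach {tolerance} in {max_iterations} iterations "
        f"(last residual {history[-1]:.3e})",
        residual_history=history,
    )


def solve(system: SPFDSystem, config: SolverConfig | None = None):
    """Solve for the scalar potential on the conducting nodes.

    Returns ``(phi_nodes, stats)`` with ``phi_nodes`` scattered onto the
    full node grid (zero on non-conducting nodes, which carry no field).
    """
    config = config or SolverConfig()
    x, stats = _cocg(system.matrix, system.rhs, config.tolerance,
                     config.max_iterations)
    phi = np.zeros(int(np.prod(system.node_shape)), dtype=complex)
    phi[system.unknown_nodes] = x
    return phi.reshape(system.node_shape), stats


def _face_mean(phi: np.ndarray, axis: int) -> np.ndarray:
    """Mean of the 4 nodes of each voxel face transverse to ``axis``."""
    trans = [a for a in range(3) if a != axis]
    s0 = [slice(None)] * 3
    out = phi
    for a in trans:
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        out = (out[tuple(lo)] + out[tuple(hi)]) / 2.0
    return out


def fields_from_potential(phi_nodes: np.ndarray, system: SPFDSystem,
                          stats: SolverStats | None = None,
                          store_E: bool = True,
                          check_divergence: bool = True) -> FieldSolution:
    """E = -j omega A - grad(phi) at voxel centers; J = sigma* E."""
    omega = system.omega
    shape = tuple(s - 1 for s in system.node_shape)
    conducting = system.sigma_star != 0
    E = np.zeros(shape + (3,), dtype=complex)
    h = system.h_m
    for axis in range(3):
        fm = _face_mean(phi_nodes, axis)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        E[..., axis] = -(fm[tuple(hi)] - fm[tuple(lo)]) / h
    if omega > 0:
        idx = np.argwhere(conducting)
        # Voxel centers sit at integer grid coordinates.
        world = _voxel_centers_world(system.affine, idx)
        a_c = np.asarray(system.a_field(world)) * system.current
        E[idx[:, 0], idx[:, 1], idx[:, 2], :] += -1j * omega * a_c
    E[~conducting] = 0.0
    J = system.sigma_star[..., None] * E
    div = None
    if check_divergence:
        div = divergence_ratio(system, phi_nodes, J)
    solution = FieldSolution(
        frequency=system.frequency,
        J_volume=J,
        E_volume=E if store_E else None,
        potential=phi_nodes,
        solver_stats=stats or SolverStats(0, 0.0, []),
        divergence_ratio=div,
    )
    return solution


def _voxel_centers_world(affine, idx):
    hom = np.column_stack([idx.astype(float), np.ones(len(idx))])
    return (hom @ np.asarray(affine).T)[:, :3]


def divergence_ratio(system: SPFDSystem, phi_nodes: np.ndarray,
                     J: np.ndarray) -> float:
    """Discrete charge-conservation metric.

    The net current into each node, ``r = rhs - K phi`` (amperes), is
    normalized by ``max|J| * h^2`` (the current scale of one voxel
    face).  Values near solver tolerance certify div(J) = 0 discretely.
    """
    phi_local = phi_nodes.reshape(-1)[system.unknown_nodes]
    residual = system.rhs - system.matrix @ phi_local
    max_j = float(np.max(np.abs(J)))
    if max_j == 0.0:
        return 0.0
    return float(np.max(np.abs(residual)) / (max_j * system.h_m ** 2))


def solve_band(phantom, a_field, harmonics, config: SolverConfig | None = None,
               include_displacement: bool = True,
               fast_mode: bool = False,
               store_E: bool = False,
               current: float = 1.0,
               progress=None) -> list:
    """One unit-current FieldSolution per harmonic frequency.

    ``fast_mode`` performs a single solve at the first frequency and
    scales the solution linearly in omega; it is only valid (and only
    permitted) when the phantom's conductivities are frequency
    independent and displacement currents are excluded, making the
    operator frequency independent and the source linear in omega.
    """
    freqs = np.atleast_1d(np.asarray(harmonics.frequencies
                                     if hasattr(harmonics, "frequencies")
                                     else harmonics, dtype=float))
    if len(freqs) == 0:
        raise ConfigurationError("empty harmonic set")
    config = config or SolverConfig()

    if fast_mode:
        if include_displacement:
            raise ConfigurationError(
                "fast_mode requires displacement currents to be excluded"
            )
        for label, props in phantom.tissue_table.items():
            sig = props.conductivity_S_per_m
            if not np.allclose(sig, sig[0]):
                raise ConfigurationError(
                    f"fast_mode requires frequency-independent conductivity; "
                    f"tissue '{props.name}' is dispersive"
                )
        f0 = freqs[0]
        system = assemble_spfd(phantom, a_field, f0,
                               include_displacement=False, current=current)
        phi0, stats = solve(system, config)
        base = fields_from_potential(phi0, system, stats, store_E=store_E)
        solutions = []
        for f in freqs:
            scale = f / f0
            solutions.append(FieldSolution(
                frequency=float(f),
                J_volume=base.J_volume * scale,
                E_volume=None if base.E_volume is None else base.E_volume * scale,
                potential=base.potential * scale,
                solver_stats=stats,
                divergence_ratio=base.divergence_ratio,
            ))
            if progress is not None:
                progress(float(f), stats)
        return solutions

    solutions = []
    for f in freqs:
        system = assemble_spfd(phantom, a_field, float(f),
                               include_displacement=include_displacement,
                               current=current)
        phi, stats = solve(system, config)
        sol = fields_from_potential(phi, system, stats, store_E=store_E)
        solutions.append(sol)
        if progress is not None:
            progress(float(f), stats)
    return solutions
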