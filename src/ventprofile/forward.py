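"""Complete-electrode-model FEM forward problem and sensitivity computation.

The solver is real valued (conductivity only): difference imaging at a single
excitation frequency never uses the reactive part, so the 195 kHz carrier is
metadata.  Linear (P1) tetrahedral elements; the system is grounded by
constraining the sum of electrode potentials to zero through a Lagrange
multiplier, which leaves every measurable voltage unchanged.

Channel convention: with ``n`` electrodes and skip ``s``, drive ``k`` injects
between electrodes ``k`` and ``(k+s+1) mod n``; measurement ``j`` of drive
``k`` senses between electrodes ``j`` and ``(j+s+1) mod n``.  Channel
``c = n*k + j``.  A channel is invalid iff its measurement pair shares an
electrode with the drive pair; invalid channels are carried as NaN with a
validity mask rather than dropped, so frames keep the hardware-style layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Mesh, REGION_CODES

__all__ = [
    "StimulationScheme",
    "VoltageFrame",
    "CEMSystem",
    "SolverError",
    "skip4_scheme",
    "solve_forward",
    "jacobian",
    "weighted_background",
]

LUNG_WEIGHT = 0.2
HEART_WEIGHT = 1.5


class SolverError(RuntimeError):
    """The forward system is singular or otherwise unsolvable."""


@dataclass(frozen=True)
class StimulationScheme:
    """Pair-drive, pair-measurement stimulation pattern."""

    n_electrodes: int
    skip: int
    amplitude_mA: float

    @property
    def n_channels(self) -> int:
        return self.n_electrodes * self.n_electrodes

    @property
    def drive_pairs(self) -> np.ndarray:
        n, s = self.n_electrodes, self.skip
        k = np.arange(n)
        return np.column_stack([k, (k + s + 1) % n])

    @property
    def measurement_pairs(self) -> np.ndarray:
        return self.drive_pairs

    @property
    def valid(self) -> np.ndarray:
        """(n, n) boolean: valid[k, j] is False iff measurement j shares an
        electrode with drive k."""
        pairs = self.drive_pairs
        share = (
            (pairs[:, None, 0] == pairs[None, :, 0])
            | (pairs[:, None, 0] == pairs[None, :, 1])
            | (pairs[:, None, 1] == pairs[None, :, 0])
            | (pairs[:, None, 1] == pairs[None, :, 1])
        )
        return ~share

    @property
    def valid_flat(self) -> np.ndarray:
        return self.valid.ravel()

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def skip4_scheme(n_electrodes: int = 32, amplitude_mA: float = 3.0) -> StimulationScheme:
    """The skip-4 pattern: drive and measure across 4 skipped electrodes."""
    if amplitude_mA <= 0:
        raise ValueError("current amplitude must be positive")
    if n_electrodes < 8:
        raise ValueError("skip-4 needs at least 8 electrodes")
    return StimulationScheme(n_electrodes=n_electrodes, skip=4, amplitude_mA=amplitude_mA)


@dataclass
class VoltageFrame:
    """One frame of channel voltages, invalid channels as NaN."""

    channels: np.ndarray  # (n_el * n_el,)
    scheme: StimulationScheme

    def __post_init__(self) -> None:
        if len(self.channels) != self.scheme.n_channels:
            raise ValueError("channel count does not match the scheme")

    @property
    def valid_values(self) -> np.ndarray:
        return self.channels[self.scheme.valid_flat]


def weighted_background(m: Mesh, mode: Literal["uniform", "weighted"]) -> np.ndarray:
    """Per-element relative conductivity background.

    ``weighted`` assigns lungs 0.2 and heart 1.5 relative to unit background
    tissue, matching their lower / higher conductivity.
    """
    if mode == "uniform":
        return np.ones(m.n_elements)
    if mode != "weighted":
        raise ValueError(f"unknown background mode {mode!r}")
    if not (m.element_region != REGION_CODES["background"]).any():
        raise ValueError("weighted background requires lung/heart region labels")
    sigma = np.ones(m.n_elements)
    sigma[m.element_region == REGION_CODES["lung"]] = LUNG_WEIGHT
    sigma[m.element_region == REGION_CODES["heart"]] = HEART_WEIGHT
    return sigma


class CEMSystem:
    """Assembled complete-electrode-model operator for one mesh and scheme.

    Caches the mesh-dependent structure (element gradients, boundary
    integrals, sparsity pattern) so that repeated solves with different
    conductivities only reassemble the volume stiffness term.
    """

    def __init__(
        self,
        mesh: Mesh,
        scheme: StimulationScheme,
        contact_impedance: float = 0.05,
    ) -> None:
        if len(mesh.electrode_patches) != scheme.n_electrodes:
            raise ValueError("mesh electrode count does not match the scheme")
        self.mesh = mesh
        self.scheme = scheme
        self.contact_impedance = float(contact_impedance)
        self._n = len(mesh.nodes)
        self._L = scheme.n_electrodes
        self._precompute_volume()
        self._precompute_boundary()
        self._rhs = self._build_rhs()

    # -- assembly ---------------------------------------------------------

    def _precompute_volume(self) -> None:
        m = self.mesh
        x = m.nodes[m.elements]  # (M, 4, 3)
        d = x[:, 1:] - x[:, :1]  # (M, 3, 3)
        det = np.linalg.det(d)
        vol = np.abs(det) / 6.0
        if np.any(vol <= 0):
            raise SolverError("mesh contains zero-volume elements")
        inv = np.linalg.inv(d)  # rows: gradients of barycentric coords 1..3
        grads = np.empty((len(x), 4, 3))
        grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
        grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
        self.element_grads = grads
        self.element_vols = vol
        # local stiffness blocks per unit conductivity: (M, 4, 4)
        self._k_local = np.einsum("mid,mjd->mij", grads, grads) * vol[:, None, None]
        elems = m.elements
        self._rows = np.repeat(elems, 4, axis=1).ravel()
        self._cols = np.tile(elems, (1, 4)).ravel()

    def _precompute_boundary(self) -> None:
        m = self.mesh
        z = self.contact_impedance
        n, L = self._n, self._L
        rows, cols, vals = [], [], []
        w_rows, w_cols, w_vals = [], [], []
        diag = np.zeros(L)
        local_mass = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
        for l, faces in enumerate(m.electrode_patches):
            pts = m.nodes[faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0]), axis=1
            )
            diag[l] = areas.sum() / z
            for f, a in zip(faces, areas):
                block = local_mass * a / z
                rows.extend(np.repeat(f, 3))
                cols.extend(np.tile(f, 3))
                vals.extend(block.ravel())
                w_rows.extend(f)
                w_cols.extend([l] * 3)
                w_vals.extend([-a / (3.0 * z)] * 3)
        self._bnd_mass = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        self._W = sp.coo_matrix((w_vals, (w_rows, w_cols)), shape=(n, L)).tocsr()
        self._D = sp.diags(diag)

    def _build_rhs(self) -> np.ndarray:
        n, L = self._n, self._L
        amp = self.scheme.amplitude_mA * 1e-3
        rhs = np.zeros((n + L + 1, L))
        for k, (ea, eb) in enumerate(self.scheme.drive_pairs):
            rhs[n + ea, k] = amp
            rhs[n + eb, k] = -amp
        return rhs

    def _system(self, sigma: np.ndarray) -> sp.csc_matrix:
        n, L = self._n, self._L
        vals = (self._k_local * sigma[:, None, None]).ravel()
        K = sp.coo_matrix((vals, (self._rows, self._cols)), shape=(n, n)).tocsr()
        K = K + self._bnd_mass
        ones = np.ones((L, 1))
        A = sp.bmat(
            [
                [K, self._W, None],
                [self._W.T, self._D, ones],
                [None, ones.T, None],
            ],
            format="csc",
        )
        return A

    # -- solves -----------------------------------------------------------

    def solve_fields(self, sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Solve all drives at once; returns (node potentials (n, L),
        electrode potentials (L, L) with [:, k] for drive k)."""
        sigma = np.asarray(sigma, dtype=float)
        if len(sigma) != self.mesh.n_elements:
            raise ValueError("conductivity length must equal the element count")
        if np.any(sigma <= 0):
            raise SolverError("conductivity must be strictly positive")
        A = self._system(sigma)
        try:
            lu = splu(A)
        except RuntimeError as exc:
            raise SolverError(f"singular forward system: {exc}") from exc
        sol = lu.solve(self._rhs)
        n, L = self._n, self._L
        return sol[:n], sol[n : n + L]

    def solve(self, sigma: np.ndarray) -> VoltageFrame:
        _, V = self.solve_fields(sigma)
        return self._frame_from_electrode_potentials(V)

    def _frame_from_electrode_potentials(self, V: np.ndarray) -> VoltageFrame:
        s = self.scheme
        pairs = s.measurement_pairs
        # channels[k, j] = V[pair_j+, drive k] - V[pair_j-, drive k]
        ch = (V[pairs[:, 0], :] - V[pairs[:, 1], :]).T  # (drives, measurements)
        ch = ch.astype(float)
        ch[~s.valid] = np.nan
        return VoltageFrame(channels=ch.ravel(), scheme=s)

    def jacobian(self, sigma0: np.ndarray) -> np.ndarray:
        """Adjoint-method sensitivity: J[c, e] = dV_c / dsigma_e at sigma0.

        With the skip pattern, measurement fields coincide with drive fields,
        so the 32 forward solutions provide both factors of the adjoint
        product.  Rows are the valid channels in channel order.
        """
        u, _ = self.solve_fields(sigma0)
        m = self.mesh
        s = self.scheme
        amp = s.amplitude_mA * 1e-3
        # per-element gradient of each drive field: (M, 3, L)
        u_elem = u[m.elements]  # (M, 4, L)
        gvec = np.einsum("mid,mik->mdk", self.element_grads, u_elem)
        gv = gvec * self.element_vols[:, None, None]
        valid = s.valid
        rows = []
        for k in range(s.n_electrodes):
            # (measurements, elements) block for drive k
            block = -np.einsum("md,mdj->jm", gv[:, :, k], gvec) / amp
            rows.append(block[valid[k]])
        return np.vstack(rows)


def solve_forward(m: Mesh, sigma: np.ndarray, s: StimulationScheme, **kw) -> VoltageFrame:
    """One-shot forward solution (see :class:`CEMSystem` for repeated solves)."""
    return CEMSystem(m, s, **kw).solve(sigma)


def jacobian(m: Mesh, sigma0: np.ndarray, s: StimulationScheme, **kw) -> np.ndarray:
    """One-shot sensitivity matrix at ``sigma0`` (valid channels x elements)."""
    return CEMSystem(m, s, **kw).jacobian(sigma0)
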