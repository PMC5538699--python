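"""Linear difference-EIT reconstruction: GREIT training and one-step
regularized Gauss-Newton, with noise-figure-matched hyperparameters.

Noise figure convention
-----------------------
The noise figure of a reconstruction matrix ``R`` is the amplification-ratio
form

    nf = [ mean|R n| / mean|R y_c| ] / [ mean|n| / mean|y_c| ]

with ``n`` i.i.d. unit-variance channel noise and ``y_c`` the signature of a
small central conductivity target.  It is evaluated in closed form from row
norms (``E|z| = sqrt(2/pi) * std(z)`` for Gaussian ``z``), not by sampling;
image means run over in-body pixels, channel means over valid channels.
Absolute nf values depend on this convention, so matched settings are only
comparable within it.

Sign convention: training targets are conductivity *decreases* (contrast -1),
and the Gauss-Newton map carries an overall minus sign, so that ventilation
(inflation lowers lung conductivity) appears positive in reconstructed
difference images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Mesh, PixelGrid, ThoraxGeometry
from scipy.spatial import Delaunay

__all__ = [
    "GreitConfig",
    "GnConfig",
    "ReconstructionMatrix",
    "TrainingTargetSet",
    "CalibrationError",
    "make_training_targets",
    "greit_train",
    "GreitFamily",
    "GnFamily",
    "noise_figure",
    "calibrate_nf",
    "gn_matrix",
    "element_to_pixel",
    "pixel_map",
    "point_target_signature",
]

Reference = Literal["TD", "NTD"]
Background = Literal["uniform", "weighted"]


class CalibrationError(RuntimeError):
    """The requested noise figure is outside the achievable range."""


@dataclass(frozen=True)
class GreitConfig:
    """GREIT training settings (radii as fractions of the effective radius)."""

    nf: float = 0.15
    ts: float = 0.06
    rw: float = 0.15
    background: Background = "weighted"
    reference: Reference = "TD"

    def __post_init__(self) -> None:
        if self.nf <= 0:
            raise ValueError("nf must be positive")
        if not 0 < self.ts < 1:
            raise ValueError("ts must be in (0, 1)")
        if not 0 < self.rw < 1:
            raise ValueError("rw must be in (0, 1)")


@dataclass(frozen=True)
class GnConfig:
    """One-step Gauss-Newton settings."""

    nf: float = 0.15
    prior: Literal["laplace", "tikhonov", "noser"] = "laplace"
    background: Background = "weighted"
    reference: Reference = "TD"

    def __post_init__(self) -> None:
        if self.nf <= 0:
            raise ValueError("nf must be positive")


@dataclass
class ReconstructionMatrix:
    """Linear map from valid-channel difference voltages to 32x32 images."""

    matrix: np.ndarray  # (1024, n_valid_channels)
    body_mask: np.ndarray  # (32, 32) bool
    algorithm: str
    config: GreitConfig | GnConfig | None = None
    lam: float | None = None
    achieved_nf: float | None = None
    mesh_fingerprint: str = ""
    geometry_kind: str = ""
    n_electrodes: int = 32
    skip: int = 4

    def __post_init__(self) -> None:
        out = ~self.body_mask.ravel()
        if np.any(self.matrix[out] != 0.0):
            self.matrix = self.matrix.copy()
            self.matrix[out] = 0.0

    @property
    def n_valid_channels(self) -> int:
        return self.matrix.shape[1]

    def apply(self, voltages: np.ndarray) -> np.ndarray:
        """Apply to one valid-channel vector (or stacked frames) -> images."""
        v = np.asarray(voltages)
        if v.shape[-1] != self.n_valid_channels:
            raise ValueError("channel basis mismatch with the reconstruction matrix")
        img = v @ self.matrix.T
        return img.reshape(v.shape[:-1] + self.body_mask.shape)


@dataclass
class TrainingTargetSet:
    """GREIT test samples: point-target signatures and desired disc images."""

    centers: np.ndarray  # (K, 2)
    target_radius: float
    desired_radius: float
    signatures: np.ndarray  # (n_valid, K)
    desired_images: np.ndarray  # (1024, K)
    body_mask: np.ndarray

    @property
    def n_targets(self) -> int:
        return self.centers.shape[1] if self.centers.ndim == 1 else len(self.centers)

    def central_index(self) -> int:
        mid = self.centers.mean(axis=0)
        return int(np.argmin(np.linalg.norm(self.centers - mid, axis=1)))


def _target_weights(m: Mesh, center: np.ndarray, radius: float) -> np.ndarray:
    """Smooth per-element membership of a ball target at the mid-plane.

    A hard indicator on element centroids is heavily quantized when the
    target radius is comparable to the element size (small ``ts`` on a
    desk-scale mesh), which injects large position-dependent noise into the
    training signatures.  Elements instead get the fraction of a transition
    band of one element diameter centered on the ball surface.
    """
    cent = m.element_centroids
    d = np.linalg.norm(cent - np.array([center[0], center[1], 0.0]), axis=1)
    size = np.cbrt(6.0 * m.element_volumes)  # ~ element diameter
    w = np.clip((radius - d) / size + 0.5, 0.0, 1.0)
    if not np.any(w > 0):
        w = np.zeros(len(d))
        w[int(np.argmin(d))] = 1.0
    return w


def point_target_signature(
    m: Mesh, J: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    """Channel signature of a small conductivity-decrease target."""
    return -(J @ _target_weights(m, center, radius))


def make_training_targets(
    m: Mesh,
    g: ThoraxGeometry,
    cfg: GreitConfig,
    J: np.ndarray,
    grid: PixelGrid | None = None,
    spacing: int = 1,
) -> TrainingTargetSet:
    """Generate GREIT training targets on the in-body pixel lattice.

    Target signatures are simulated through the sensitivity matrix ``J``
    (computed on the configured background) with contrast -1; desired images
    are discs of radius ``rw * R_eff`` clipped to the body mask, with a
    one-pixel anti-aliasing band so the training stack does not inherit
    pixel-rasterization noise.
    """
    from .geometry import rasterize

    if grid is None:
        grid = rasterize(g)
    R_eff = g.effective_radius
    target_radius = cfg.ts * R_eff
    desired_radius = cfg.rw * R_eff
    X, Y = grid.pixel_centers()
    sel = np.zeros_like(grid.body_mask)
    sel[::spacing, ::spacing] = True
    sel &= grid.body_mask
    centers = np.column_stack([X[sel], Y[sel]])
    if len(centers) == 0:
        raise ValueError("spacing leaves no training targets inside the body")
    W = np.column_stack(
        [_target_weights(m, c, target_radius) for c in centers]
    )
    sigs = -(J @ W)
    px = np.column_stack([X.ravel(), Y.ravel()])
    body_flat = grid.body_mask.ravel()
    pitch = float(np.mean(grid.pixel_size))
    desired = np.zeros((px.shape[0], len(centers)))
    for t, c in enumerate(centers):
        dist = np.linalg.norm(px - c, axis=1)
        cov = np.clip((desired_radius - dist) / pitch + 0.5, 0.0, 1.0)
        desired[:, t] = cov * body_flat
    return TrainingTargetSet(
        centers=centers,
        target_radius=target_radius,
        desired_radius=desired_radius,
        signatures=sigs,
        desired_images=desired,
        body_mask=grid.body_mask,
    )


class GreitFamily:
    """The one-parameter family R(lambda) of GREIT matrices for one model.

    R = X W Y^T (Y W Y^T + lambda * Sigma_n)^{-1} with identity channel-noise
    covariance and per-sample weights W = diag(1/||y_k||^2), i.e. every
    training target contributes equally to the least-squares fit.  Without
    the weighting the high-sensitivity boundary targets dominate the stack
    (signature norms vary by two orders of magnitude across the domain) and
    the achievable noise-figure range collapses.  With unit-norm signatures
    the eigenvalues of Y W Y^T are O(1), so lambda is dimensionless.  An
    eigendecomposition of Y W Y^T makes evaluating R and its noise figure
    cheap across the whole lambda bracket.
    """

    algorithm = "greit"

    def __init__(self, targets: TrainingTargetSet, ref_signal: np.ndarray | None = None):
        w = 1.0 / np.linalg.norm(targets.signatures, axis=0)
        Y = targets.signatures * w
        X = targets.desired_images * w
        self.targets = targets
        self.body_mask = targets.body_mask
        evals, Q = np.linalg.eigh(Y @ Y.T)
        self._evals = np.clip(evals, 0.0, None)
        self._Q = Q
        self._U = (X @ Y.T) @ Q
        if ref_signal is None:
            ref_signal = Y[:, targets.central_index()]
        self.ref_signal = ref_signal
        self._qref = Q.T @ ref_signal
        self._body_rows = self.body_mask.ravel()

    def _filt(self, lam: float) -> np.ndarray:
        return 1.0 / (self._evals + lam)

    def matrix(self, lam: float) -> np.ndarray:
        return (self._U * self._filt(lam)) @ self._Q.T

    def noise_figure(self, lam: float) -> float:
        d = self._filt(lam)
        rows = np.sqrt(np.einsum("ik,k->i", self._U[self._body_rows] ** 2, d * d))
        img = self._U[self._body_rows] @ (d * self._qref)
        return float(
            rows.mean() * np.abs(self.ref_signal).mean() / np.abs(img).mean()
        )

    def materialize(self, lam: float, **meta) -> ReconstructionMatrix:
        return ReconstructionMatrix(
            matrix=self.matrix(lam),
            body_mask=self.body_mask,
            algorithm=self.algorithm,
            lam=lam,
            **meta,
        )


def greit_train(
    t: TrainingTargetSet,
    noise_cov: np.ndarray | None = None,
    lam: float = 1e-2,
) -> ReconstructionMatrix:
    """Train a GREIT matrix at a fixed regularization weight.

    ``noise_cov`` is the diagonal of the channel-noise covariance (identity
    by default).  Training samples are weighted to unit signature norm (see
    :class:`GreitFamily`).  For calibrated models use :class:`GreitFamily`
    with :func:`calibrate_nf` instead.
    """
    w = 1.0 / np.linalg.norm(t.signatures, axis=0)
    Y = t.signatures * w
    X = t.desired_images * w
    n = Y.shape[0]
    cov = np.ones(n) if noise_cov is None else np.asarray(noise_cov, dtype=float)
    if cov.ndim == 2:
        cov = np.diag(cov)
    A = Y @ Y.T + lam * np.diag(cov)
    try:
        R = np.linalg.solve(A.T, (X @ Y.T).T).T
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"singular GREIT training system: {exc}") from exc
    return ReconstructionMatrix(
        matrix=R, body_mask=t.body_mask, algorithm="greit", lam=lam
    )


def noise_figure(R: ReconstructionMatrix, ref_signal: np.ndarray) -> float:
    """Recompute the noise figure of a materialized matrix from its definition."""
    ref_signal = np.asarray(ref_signal, dtype=float)
    if not np.any(ref_signal):
        raise ValueError("reference signal is identically zero")
    rows = R.matrix[R.body_mask.ravel()]
    row_norms = np.linalg.norm(rows, axis=1)
    img = rows @ ref_signal
    return float(row_norms.mean() * np.abs(ref_signal).mean() / np.abs(img).mean())


def calibrate_nf(
    trainer: "GreitFamily | GnFamily | Callable[[float], ReconstructionMatrix]",
    target_nf: float,
    ref_signal: np.ndarray | None = None,
    bracket: tuple[float, float] = (1e-8, 1e4),
    rel_tol: float = 0.002,
    max_iter: int = 60,
) -> tuple[float, float]:
    """Choose the regularization weight whose noise figure matches ``target_nf``.

    Bisection on log(lambda); the noise figure decreases monotonically with
    lambda over the bracket.  Returns ``(lambda, achieved_nf)``.
    """
    if hasattr(trainer, "noise_figure") and not isinstance(trainer, ReconstructionMatrix):
        nf_fn = trainer.noise_figure
    else:
        if ref_signal is None:
            raise ValueError("ref_signal is required for a bare trainer callable")
        nf_fn = lambda lam: noise_figure(trainer(lam), ref_signal)
    lo, hi = bracket
    nf_lo, nf_hi = nf_fn(lo), nf_fn(hi)
    if not (nf_hi <= target_nf <= nf_lo):
        raise CalibrationError(
            f"target nf {target_nf} outside achievable range "
            f"[{nf_hi:.4g}, {nf_lo:.4g}] for bracket {bracket}"
        )
    llo, lhi = np.log(lo), np.log(hi)
    lam, achieved = lo, nf_lo
    for _ in range(max_iter):
        lmid = 0.5 * (llo + lhi)
        lam = float(np.exp(lmid))
        achieved = nf_fn(lam)
        if abs(achieved - target_nf) / target_nf < rel_tol:
            break
        if achieved > target_nf:
            llo = lmid
        else:
            lhi = lmid
    return lam, float(achieved)


# ---------------------------------------------------------------------------
# element space <-> pixel space


def pixel_map(m: Mesh, grid: PixelGrid, subsample: int = 4) -> sp.csr_matrix:
    """Sparse (1024, n_elements) area-weighted element-to-pixel projector.

    Pixel values are area-weighted averages over the vertical columns whose
    mid-plane projection intersects the pixel (columns sampled at
    ``subsample`` x ``subsample`` points per pixel); within a column,
    elements contribute by volume.  Pixels outside the body mask are zero.
    The map is cached on the mesh.
    """
    cache = getattr(m, "_pixel_map_cache", None)
    if cache is None:
        cache = {}
        m._pixel_map_cache = cache
    key = (grid.bounds, grid.shape, subsample)
    if key in cache:
        return cache[key]

    tri = Delaunay(m.points2d)
    X, Y = grid.subpixel_centers(subsample)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    simplex = tri.find_simplex(pts)
    col = np.where(simplex >= 0, m.kept_tri_index[simplex], -1)
    n_sub = grid.shape[0] * subsample
    sub_rows = np.arange(len(pts)) // n_sub
    sub_cols = np.arange(len(pts)) % n_sub
    pix = (sub_rows // subsample) * grid.shape[1] + (sub_cols // subsample)
    ok = col >= 0
    ok &= grid.body_mask.ravel()[pix]
    Pc = sp.coo_matrix(
        (np.ones(ok.sum()), (pix[ok], col[ok])),
        shape=(grid.shape[0] * grid.shape[1], len(m.triangles2d)),
    ).tocsr()
    row_tot = np.asarray(Pc.sum(axis=1)).ravel()
    inv = np.zeros_like(row_tot)
    inv[row_tot > 0] = 1.0 / row_tot[row_tot > 0]
    Pc = sp.diags(inv) @ Pc
    # column -> element volume weighting
    vols = m.element_volumes
    col_vol = np.bincount(m.element_column, weights=vols, minlength=len(m.triangles2d))
    C = sp.coo_matrix(
        (vols / col_vol[m.element_column], (m.element_column, np.arange(m.n_elements))),
        shape=(len(m.triangles2d), m.n_elements),
    ).tocsr()
    P = (Pc @ C).tocsr()
    cache[key] = P
    return P


def element_to_pixel(
    values: np.ndarray, m: Mesh, grid: PixelGrid, subsample: int = 4
) -> np.ndarray:
    """Project element-space values (vector or stacked columns) to pixels.

    A vector returns a (32, 32) image; an (n_elements, k) matrix returns the
    (1024, k) pixel-space matrix.
    """
    P = pixel_map(m, grid, subsample)
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        return (P @ v).reshape(grid.shape)
    return P @ v


# ---------------------------------------------------------------------------
# one-step Gauss-Newton


def _element_adjacency_laplacian(m: Mesh) -> sp.csr_matrix:
    faces = np.vstack(
        [
            m.elements[:, [0, 1, 2]],
            m.elements[:, [0, 1, 3]],
            m.elements[:, [0, 2, 3]],
            m.elements[:, [1, 2, 3]],
        ]
    )
    owner = np.tile(np.arange(m.n_elements), 4)
    faces = np.sort(faces, axis=1)
    order = np.lexsort(faces.T)
    faces = faces[order]
    owner = owner[order]
    same = np.all(faces[1:] == faces[:-1], axis=1)
    a = owner[:-1][same]
    b = owner[1:][same]
    i = np.concatenate([a, b])
    j = np.concatenate([b, a])
    A = sp.coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(m.n_elements, m.n_elements)
    ).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    return sp.diags(deg) - A


def gn_prior(J: np.ndarray, cfg: GnConfig, m: Mesh) -> sp.csr_matrix:
    """Regularization matrix P: identity (Tikhonov), graph-Laplacian
    squared (Laplace smoothness) or diag(J^T J) (NOSER)."""
    n = m.n_elements
    if cfg.prior == "tikhonov":
        return sp.eye(n, format="csr")
    if cfg.prior == "noser":
        d = np.einsum("ce,ce->e", J, J)
        d = np.maximum(d, 1e-300)
        return sp.diags(d).tocsr()
    if cfg.prior == "laplace":
        L = _element_adjacency_laplacian(m)
        return (L.T @ L).tocsr()
    raise ValueError(f"unknown prior {cfg.prior!r}")


class GnFamily:
    """One-parameter family of one-step Gauss-Newton reconstruction matrices.

    R(lambda) = -Pi (J^T J + lambda^2 s P)^{-1} J^T, evaluated through the
    Woodbury identity and an eigendecomposition of J P^{-1} J^T so that the
    noise-figure calibration scans lambda cheaply.  ``Pi`` is the element->
    pixel projector; the sign makes ventilation positive.  The scale
    ``s = mean eig(J P^{-1} J^T)`` makes lambda dimensionless, so the same
    calibration bracket applies regardless of voltage units.
    """

    algorithm = "gn"

    def __init__(
        self,
        J: np.ndarray,
        cfg: GnConfig,
        m: Mesh,
        g: ThoraxGeometry,
        grid: PixelGrid | None = None,
        ref_radius_fraction: float = 0.05,
    ):
        from .geometry import rasterize

        if grid is None:
            grid = rasterize(g)
        self.cfg = cfg
        self.body_mask = grid.body_mask
        P = gn_prior(J, cfg, m)
        eps = 1e-8 * (P.diagonal().mean() if P.nnz else 1.0)
        Pt = (P + eps * sp.eye(m.n_elements)).tocsc()
        if cfg.prior in ("tikhonov", "noser"):
            dinv = 1.0 / Pt.diagonal()
            K = J.T * dinv[:, None]
        else:
            lu = splu(Pt)
            K = lu.solve(J.T)
        G = J @ K
        G = 0.5 * (G + G.T)
        evals, Q = np.linalg.eigh(G)
        self._evals = np.clip(evals, 0.0, None)
        self._scale = float(self._evals.mean()) or 1.0
        self._Q = Q
        Pi = pixel_map(m, grid)
        self._U = -(Pi @ (K @ Q))  # ventilation-positive sign
        center = np.array(
            [(grid.bounds[0] + grid.bounds[2]) / 2.0, (grid.bounds[1] + grid.bounds[3]) / 2.0]
        )
        self.ref_signal = point_target_signature(
            m, J, center, ref_radius_fraction * g.effective_radius
        )
        self._qref = Q.T @ self.ref_signal
        self._body_rows = self.body_mask.ravel()

    def _filt(self, lam: float) -> np.ndarray:
        return 1.0 / (self._evals + lam * lam * self._scale)

    def matrix(self, lam: float) -> np.ndarray:
        return (self._U * self._filt(lam)) @ self._Q.T

    def noise_figure(self, lam: float) -> float:
        d = self._filt(lam)
        rows = np.sqrt(np.einsum("ik,k->i", self._U[self._body_rows] ** 2, d * d))
        img = self._U[self._body_rows] @ (d * self._qref)
        return float(
            rows.mean() * np.abs(self.ref_signal).mean() / np.abs(img).mean()
        )

    def materialize(self, lam: float, **meta) -> ReconstructionMatrix:
        return ReconstructionMatrix(
            matrix=self.matrix(lam),
            body_mask=self.body_mask,
            algorithm=self.algorithm,
            lam=lam,
            **meta,
        )


def gn_matrix(
    J: np.ndarray,
    cfg: GnConfig,
    lam: float,
    m: Mesh,
    g: ThoraxGeometry,
    grid: PixelGrid | None = None,
    sign: float = -1.0,
) -> ReconstructionMatrix:
    """One-step Gauss-Newton reconstruction matrix at fixed ``lam``.

    ``sign=-1`` (default) flips the element-space solution so ventilation
    appears positive; pass ``sign=+1`` for the raw regularized inverse.
    """
    fam = GnFamily(J, cfg, m, g, grid)
    R = fam.matrix(lam) * (-sign)  # family already carries the -1
    return ReconstructionMatrix(
        matrix=R, body_mask=fam.body_mask, algorithm="gn", config=cfg, lam=lam
    )
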