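"""Diffusion tensor estimation by weighted least squares and FA maps.

The single-tensor model relates the diffusion-weighted signal to the
symmetric 3×3 tensor D through the Stejskal–Tanner equation

    S(b, g) = S0 · exp(−b · gᵀ D g)

which is linear in log-signal.  Fitting is ordinary least squares on
``ln S`` followed by one reweighting pass with weights equal to the squared
predicted signals — the standard WLS variant for DTI.

Tensor components are stored per voxel in the order
``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` in mm²/s, on the same grid and affine as
the input volume.  The diagonal elements Dxx/Dyy/Dzz are the apparent
diffusivities along the grid axes; in an RAS-oriented atlas space they are
the left–right, anterior–posterior and inferior–superior diffusivities used
by the perivascular (ALPS) index.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientTable

__all__ = [
    "DiffusionVolume",
    "TensorVolume",
    "ScalarMap",
    "design_matrix",
    "fit_tensor_wls",
    "compute_fa",
]

log = logging.getLogger(__name__)

#: index order of the unique tensor components along the last axis
COMPONENT_NAMES = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")

#: NIfTI export order (lower-triangular, FSL/dtifit-compatible)
LOWER_TRI_ORDER = (0, 3, 1, 4, 5, 2)  # Dxx, Dxy, Dyy, Dxz, Dyz, Dzz


@dataclass
class DiffusionVolume:
    """A 4-D diffusion-weighted acquisition in atlas space.

    ``signal`` has shape (X, Y, Z, N) with N matching the gradient table.
    """

    signal: np.ndarray
    gradients: GradientTable
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[-1] != len(self.gradients):
            raise ValueError(
                f"{self.signal.shape[-1]} volumes but gradient table has "
                f"{len(self.gradients)} entries"
            )
        if np.any(self.signal < 0):
            raise ValueError("negative signal values")
        self.affine = np.asarray(self.affine, dtype=float)


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor on a 3-D grid.

    ``components`` has shape (X, Y, Z, 6) ordered (Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz); ``mask`` flags voxels where a fit was obtained.
    """

    components: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 4 or self.components.shape[-1] != 6:
            raise ValueError(
                f"components must be (X, Y, Z, 6), got {self.components.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.components.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.isfinite(self.components[self.mask])):
            raise ValueError("non-finite tensor components inside mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    @property
    def dxx(self) -> np.ndarray:
        return self.components[..., 0]

    @property
    def dyy(self) -> np.ndarray:
        return self.components[..., 1]

    @property
    def dzz(self) -> np.ndarray:
        return self.components[..., 2]

    def as_matrices(self) -> np.ndarray:
        """Expand to full (X, Y, Z, 3, 3) symmetric matrices."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.components, -1, 0)
        out = np.empty(self.shape + (3, 3), dtype=float)
        out[..., 0, 0] = dxx
        out[..., 1, 1] = dyy
        out[..., 2, 2] = dzz
        out[..., 0, 1] = out[..., 1, 0] = dxy
        out[..., 0, 2] = out[..., 2, 0] = dxz
        out[..., 1, 2] = out[..., 2, 1] = dyz
        return out

    def lower_triangular(self) -> np.ndarray:
        """Components reordered to (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) for NIfTI export."""
        return self.components[..., list(LOWER_TRI_ORDER)]


@dataclass
class ScalarMap:
    """A named per-voxel scalar image (e.g. FA) with its affine."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    name: str = "scalar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Log-linear DTI design matrix, one row per volume.

    Row i is ``[1, −b·gx², −b·gy², −b·gz², −2b·gx·gy, −2b·gx·gz, −2b·gy·gz]``
    so that ``X @ [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] = ln S``.
    """
    b = gtab.bvals
    gx, gy, gz = gtab.bvecs.T
    return np.stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ],
        axis=1,
    )


def _quadratic_forms(components: np.ndarray, gtab: GradientTable) -> np.ndarray:
    """gᵀDg for every voxel (…, 6) and every gradient row → (…, N)."""
    gx, gy, gz = gtab.bvecs.T
    coeffs = np.stack(
        [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1
    )  # (N, 6)
    return components @ coeffs.T


def fit_tensor_wls(
    dwi: DiffusionVolume,
    mask: np.ndarray | None = None,
    signal_floor: float = 1e-6,
) -> TensorVolume:
    """Fit the diffusion tensor per voxel by weighted least squares.

    The log-signal model is solved by OLS, predicted signals from that
    estimate define per-volume weights (squared predicted signal), and one
    WLS pass produces the final tensor.  Signals are clipped to
    ``signal_floor`` times the voxel's mean b0 signal before the log
    transform; voxels with no usable signal, or whose weighted normal
    equations are numerically singular, are excluded from the output mask
    (their count is logged).

    Parameters
    ----------
    dwi : DiffusionVolume
        Preprocessed single-shell acquisition with ≥ 1 b0 volume and ≥ 6
        distinct diffusion directions.
    mask : optional boolean array (X, Y, Z)
        Restrict fitting to these voxels; default: all voxels.
    signal_floor : float
        Relative clipping floor applied before the log transform.

    Returns
    -------
    TensorVolume
    """
    gtab = dwi.gradients
    if len(gtab) < 7:
        raise ValueError(f"need at least 7 volumes to fit a tensor, got {len(gtab)}")
    if not np.any(gtab.b0_mask):
        raise ValueError("gradient table contains no b=0 volume")
    if gtab.n_unique_directions() < 6:
        raise ValueError(
            f"need ≥ 6 distinct diffusion directions, got {gtab.n_unique_directions()}"
        )

    shape = dwi.signal.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape does not match the diffusion volume")

    signal = dwi.signal.reshape(-1, len(gtab))
    flat_mask = mask.ravel().copy()

    s0 = signal[:, gtab.b0_mask].mean(axis=1)
    usable = flat_mask & (s0 > 0) & np.all(np.isfinite(signal), axis=1)
    n_unusable = int(np.count_nonzero(flat_mask & ~usable))

    idx = np.where(usable)[0]
    y = np.log(np.maximum(signal[idx], signal_floor * s0[idx, None]))

    A = design_matrix(gtab)  # (N, 7)
    beta_ols = y @ np.linalg.pinv(A).T  # (V, 7)

    # one reweighting pass: weights = squared predicted signals
    w = np.exp(2.0 * (beta_ols @ A.T))
    atwa = np.einsum("ni,vn,nj->vij", A, w, A)
    atwy = np.einsum("ni,vn,vn->vi", A, w, y)
    beta, bad = _batch_solve(atwa, atwy)
    if np.any(bad):
        n_unusable += int(np.count_nonzero(bad))
        beta[bad] = np.nan

    components = np.zeros((signal.shape[0], 6), dtype=float)
    good = np.zeros(signal.shape[0], dtype=bool)
    good[idx] = ~bad
    components[idx[~bad]] = beta[~bad, 1:]

    if n_unusable:
        log.info("fit_tensor_wls: %d voxel(s) excluded from the fitted mask", n_unusable)

    return TensorVolume(
        components=components.reshape(shape + (6,)),
        affine=dwi.affine,
        mask=good.reshape(shape),
    )


def _batch_solve(mats: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve a stack of SPD systems, flagging numerically singular ones."""
    out = np.empty_like(rhs)
    bad = np.zeros(mats.shape[0], dtype=bool)
    try:
        out[:] = np.linalg.solve(mats, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        for i in range(mats.shape[0]):
            try:
                out[i] = np.linalg.solve(mats[i], rhs[i])
            except np.linalg.LinAlgError:
                bad[i] = True
                out[i] = np.nan
    nonfinite = ~np.all(np.isfinite(out), axis=1)
    bad |= nonfinite
    return out, bad


def compute_fa(tensor: TensorVolume) -> ScalarMap:
    """Fractional anisotropy from the tensor eigenvalues.

    FA = sqrt(½ · Σᵢⱼ (λᵢ−λⱼ)² / Σ λᵢ²) with eigenvalues clipped at zero
    beforehand; FA is defined as 0 where all eigenvalues vanish.  Values lie
    in [0, 1].
    """
    mats = tensor.as_matrices()[tensor.mask]
    if not np.all(np.isfinite(mats)):
        raise ValueError("non-finite tensor components inside mask")
    evals = np.clip(np.linalg.eigvalsh(mats), 0.0, None)

    l1, l2, l3 = evals[..., 2], evals[..., 1], evals[..., 0]
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    fa_masked = np.zeros(len(mats))
    nz = den > 0
    fa_masked[nz] = np.sqrt(0.5 * num[nz] / den[nz])

    fa = np.zeros(tensor.shape, dtype=float)
    fa[tensor.mask] = np.clip(fa_masked, 0.0, 1.0)
    return ScalarMap(values=fa, affine=tensor.affine, name="FA")
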