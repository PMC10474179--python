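"""Single-shell diffusion gradient tables in the FSL bval/bvec dialect.

A gradient table pairs one b-value (s/mm²) with one unit direction per
acquired volume.  Volumes with b below :data:`B0_THRESHOLD` are treated as
non-diffusion-weighted ("b0") reference volumes; their direction vector may
be the zero vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "B0_THRESHOLD",
    "GradientTable",
    "load_fsl_gradients",
    "save_fsl_gradients",
    "single_shell_table",
]

#: b-values (s/mm²) below this count as b=0 reference volumes.
B0_THRESHOLD = 50.0


@dataclass(frozen=True)
class GradientTable:
    """b-values and unit gradient directions, one row per DWI volume.

    Parameters
    ----------
    bvals : (N,) array of b-values in s/mm².  Must be nonnegative.
    bvecs : (N, 3) array of gradient directions.  Directions of
        diffusion-weighted volumes (b ≥ ``B0_THRESHOLD``) must be unit
        vectors to within 1e-6; b0 rows may be the zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-value in gradient table")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals >= B0_THRESHOLD
        bad = weighted & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            raise ValueError(
                f"non-unit gradient direction(s) at volume(s) {np.where(bad)[0]}"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    def n_unique_directions(self) -> int:
        """Number of distinct diffusion directions (antipodal pairs merged)."""
        vecs = self.bvecs[self.dwi_mask]
        if vecs.size == 0:
            return 0
        # canonicalize sign so g and -g collapse to one direction
        flip = vecs[:, [0]] < 0
        flip |= (vecs[:, [0]] == 0) & (vecs[:, [1]] < 0)
        canon = np.where(flip, -vecs, vecs)
        return np.unique(np.round(canon, 6), axis=0).shape[0]


def load_fsl_gradients(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read FSL-style ``.bval`` (one row) and ``.bvec`` (three rows) files."""
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is 3 rows of x/y/z components
        bvecs = bvecs.T
    return GradientTable(bvals, bvecs)


def save_fsl_gradients(
    gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write the table as FSL bval (1 × N) and bvec (3 × N) text files."""
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.8f")


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the upper hemisphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n  # upper hemisphere only: antipodal directions are redundant
    r = np.sqrt(1.0 - z**2)
    vecs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def single_shell_table(
    n_dirs: int = 32, b: float = 1500.0, n_b0: int = 1
) -> GradientTable:
    """Build a single-shell table: ``n_b0`` b0 volumes plus ``n_dirs``
    quasi-uniform directions at b-value ``b`` (default 1500 s/mm²)."""
    if n_dirs < 6:
        raise ValueError("at least 6 diffusion directions required")
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), _fibonacci_hemisphere(n_dirs)])
    return GradientTable(bvals, bvecs)
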