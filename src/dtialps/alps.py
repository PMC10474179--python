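"""The DTI-ALPS index: diffusivity along the perivascular space.

At the level of the lateral-ventricle body, deep medullary veins (and the
perivascular spaces that follow them) run left–right, perpendicular to both
the projection fibers of the corona radiata (inferior–superior, z) and the
association fibers of the superior longitudinal fasciculus
(anterior–posterior, y).  Water movement along the perivascular space
therefore contributes to the x-axis diffusivity in both fiber regions while
the fibers themselves dominate the orthogonal axes.  The index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

is the ratio of the x-axis diffusivity averaged over the two fiber ROIs to
the mean of each ROI's fiber-perpendicular, vein-perpendicular diffusivity.
Values near 1 indicate no preferential perivascular diffusion; healthy
older adults typically sit around 1.2–1.5.

ROIs are taken from an ICBM-DTI-81-style integer label volume, restricted
to one hemisphere and a band of x (left–right) voxel indices containing the
medullary veins, and masked to FA > 0.2 to exclude CSF-dominated voxels.
All volumes must share an RAS-oriented grid so that Dxx is the left–right
diffusivity.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .tensor import ScalarMap, TensorVolume

__all__ = ["ROIConfig", "ROIMasks", "ALPSResult", "select_alps_rois", "compute_alps", "alps_from_volumes"]


def check_ras(affine: np.ndarray) -> None:
    """Require an RAS-oriented, axis-aligned affine (first axis = left→right)."""
    import nibabel as nib

    if nib.aff2axcodes(np.asarray(affine, dtype=float)) != ("R", "A", "S"):
        raise ValueError(
            "volume is not RAS-oriented; reorient (e.g. nibabel "
            "as_closest_canonical) before computing the ALPS index"
        )


@dataclass(frozen=True)
class ROIConfig:
    """Selection rules for the projection- and association-fiber ROIs.

    Parameters
    ----------
    proj_label_ids, assoc_label_ids :
        Atlas label codes of the projection fibers (superior + posterior
        corona radiata) and association fibers (superior longitudinal
        fasciculus).
    hemisphere : {"left", "right", "both"}
        Which hemisphere's labels to keep, judged from the world x
        coordinate (RAS: left is x < 0).  Default "left", where the
        medullary-vein geometry of the index is defined.
    x_range : optional (lo, hi)
        Half-open interval of voxel indices along the left–right axis; the
        band lateral to the ventricle body through which the veins pass.
        ``None`` disables the restriction.
    fa_threshold : float
        Voxels must have FA strictly greater than this (default 0.2).
    min_voxels : int
        Reject ROIs smaller than this after filtering (default 5).
    """

    proj_label_ids: frozenset[int] = frozenset({1})
    assoc_label_ids: frozenset[int] = frozenset({2})
    hemisphere: str = "left"
    x_range: tuple[int, int] | None = None
    fa_threshold: float = 0.2
    min_voxels: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "proj_label_ids", frozenset(int(i) for i in self.proj_label_ids))
        object.__setattr__(self, "assoc_label_ids", frozenset(int(i) for i in self.assoc_label_ids))
        if self.hemisphere not in ("left", "right", "both"):
            raise ValueError(f"hemisphere must be left/right/both, got {self.hemisphere!r}")
        if not (0.0 <= self.fa_threshold < 1.0):
            raise ValueError("fa_threshold must lie in [0, 1)")
        if self.x_range is not None:
            lo, hi = self.x_range
            if hi <= lo:
                raise ValueError(f"empty x_range {self.x_range}")
            object.__setattr__(self, "x_range", (int(lo), int(hi)))

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "proj": sorted(self.proj_label_ids),
                "assoc": sorted(self.assoc_label_ids),
                "hemisphere": self.hemisphere,
                "x_range": self.x_range,
                "fa_threshold": self.fa_threshold,
                "min_voxels": self.min_voxels,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ROIMasks:
    """Boolean voxel masks of the two ALPS ROIs after all filters."""

    proj_mask: np.ndarray
    assoc_mask: np.ndarray
    config_hash: str = ""

    def __post_init__(self) -> None:
        self.proj_mask = np.asarray(self.proj_mask, dtype=bool)
        self.assoc_mask = np.asarray(self.assoc_mask, dtype=bool)
        if self.proj_mask.shape != self.assoc_mask.shape:
            raise ValueError("ROI masks must share a grid")
        if np.any(self.proj_mask & self.assoc_mask):
            raise ValueError("projection and association ROIs overlap")

    @property
    def n_proj(self) -> int:
        return int(np.count_nonzero(self.proj_mask))

    @property
    def n_assoc(self) -> int:
        return int(np.count_nonzero(self.assoc_mask))


@dataclass(frozen=True)
class ALPSResult:
    """The four ROI-mean diffusivities (mm²/s) and their ratio."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float
    alps_index: float
    n_proj: int = 0
    n_assoc: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "dxx_proj": self.dxx_proj,
            "dxx_assoc": self.dxx_assoc,
            "dyy_proj": self.dyy_proj,
            "dzz_assoc": self.dzz_assoc,
            "alps_index": self.alps_index,
            "n_proj": self.n_proj,
            "n_assoc": self.n_assoc,
        }


def select_alps_rois(
    labels: np.ndarray,
    fa: ScalarMap,
    cfg: ROIConfig,
    affine: np.ndarray | None = None,
) -> ROIMasks:
    """Build the projection/association ROI masks from atlas labels.

    A voxel enters an ROI when its label is in the configured id set, its FA
    strictly exceeds ``cfg.fa_threshold``, its left–right voxel index falls
    in ``cfg.x_range`` and it lies in the requested hemisphere.  Raises if
    the grids disagree or either filtered ROI holds fewer than
    ``cfg.min_voxels`` voxels.
    """
    labels = np.asarray(labels)
    if labels.shape != fa.values.shape:
        raise ValueError(
            f"label grid {labels.shape} does not match FA grid {fa.values.shape}"
        )
    if affine is None:
        affine = fa.affine
    elif not np.allclose(affine, fa.affine, atol=1e-4):
        raise ValueError("label and FA affines disagree beyond 1e-4")
    check_ras(affine)

    keep = fa.values > cfg.fa_threshold  # strict: FA exactly at threshold is excluded

    if cfg.x_range is not None:
        lo, hi = cfg.x_range
        xs = np.arange(labels.shape[0])
        keep &= ((xs >= lo) & (xs < hi))[:, None, None]

    if cfg.hemisphere != "both":
        # world x of each voxel column (axis-aligned RAS affine)
        world_x = affine[0, 0] * np.arange(labels.shape[0]) + affine[0, 3]
        hemi = world_x < 0 if cfg.hemisphere == "left" else world_x > 0
        keep &= hemi[:, None, None]

    proj = np.isin(labels, sorted(cfg.proj_label_ids)) & keep
    assoc = np.isin(labels, sorted(cfg.assoc_label_ids)) & keep

    for name, m in (("projection", proj), ("association", assoc)):
        if np.count_nonzero(m) < cfg.min_voxels:
            raise ValueError(
                f"{name} ROI has {np.count_nonzero(m)} voxel(s) after filtering, "
                f"fewer than min_voxels={cfg.min_voxels}"
            )
    return ROIMasks(proj_mask=proj, assoc_mask=assoc, config_hash=cfg.content_hash())


def compute_alps(tensor: TensorVolume, masks: ROIMasks) -> ALPSResult:
    """Compute the DTI-ALPS index over the given ROI masks.

    The numerator is the mean of the two ROI-level Dxx means and the
    denominator the mean of Dyy (projection ROI) and Dzz (association ROI);
    the two ROIs carry equal weight regardless of size.  Raises when the
    tensor is not finite on the masks or the denominator is not positive.
    """
    if masks.proj_mask.shape != tensor.shape:
        raise ValueError("ROI masks do not match the tensor grid")
    for name, m in (("projection", masks.proj_mask), ("association", masks.assoc_mask)):
        if not np.all(np.isfinite(tensor.components[m])):
            raise ValueError(f"non-finite tensor components in the {name} ROI")
        if not np.all(tensor.mask[m]):
            raise ValueError(f"{name} ROI includes voxels outside the fitted mask")

    dxx_proj = float(tensor.dxx[masks.proj_mask].mean())
    dxx_assoc = float(tensor.dxx[masks.assoc_mask].mean())
    dyy_proj = float(tensor.dyy[masks.proj_mask].mean())
    dzz_assoc = float(tensor.dzz[masks.assoc_mask].mean())

    denom = 0.5 * (dyy_proj + dzz_assoc)
    if denom <= 0:
        raise ValueError(
            f"non-physical ROI diffusivities: mean(Dyy_proj, Dzz_assoc) = {denom:g} ≤ 0"
        )
    index = 0.5 * (dxx_proj + dxx_assoc) / denom
    return ALPSResult(
        dxx_proj=dxx_proj,
        dxx_assoc=dxx_assoc,
        dyy_proj=dyy_proj,
        dzz_assoc=dzz_assoc,
        alps_index=index,
        n_proj=masks.n_proj,
        n_assoc=masks.n_assoc,
    )


def alps_from_volumes(
    tensor: TensorVolume, labels: np.ndarray, cfg: ROIConfig
) -> ALPSResult:
    """Convenience wrapper: FA map → ROI selection → ALPS index."""
    from .tensor import compute_fa

    fa = compute_fa(tensor)
    masks = select_alps_rois(labels, fa, cfg)
    return compute_alps(tensor, masks)
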