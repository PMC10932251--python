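"""Image/mask I/O on NIfTI grids and scan-quality exclusion rules.

The analysis consumes an already co-registered NCCT/CTA pair with a binary
thrombus mask on one voxel grid; no resampling or registration is performed
here, and a grid mismatch is an error rather than a fixable condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .cohort import Cohort, read_cohort, write_cohort  # noqa: F401  (re-export)
from .errors import RegistrationError, ThrombocharError, ValidationError


@dataclass
class VoxelVolumePair:
    """Co-registered NCCT and CTA volumes with a binary thrombus mask.

    All three arrays share one grid shape; ``spacing`` is the voxel size
    (dx, dy, dz) in mm.
    """

    ncct: np.ndarray
    cta: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.ncct = np.asarray(self.ncct, dtype=float)
        self.cta = np.asarray(self.cta, dtype=float)
        mask = np.asarray(self.mask)
        if self.ncct.ndim != 3:
            raise ValidationError("images must be 3-D")
        if not (self.ncct.shape == self.cta.shape == mask.shape):
            raise RegistrationError(
                f"grid shapes differ: ncct {self.ncct.shape}, "
                f"cta {self.cta.shape}, mask {mask.shape}"
            )
        vals = np.unique(mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValidationError(f"mask values outside {{0, 1}}: {vals[:10]}")
        self.mask = mask.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be three positive values, got {spacing}")
        self.spacing = spacing


@dataclass(frozen=True)
class ScanMetadata:
    """Acquisition metadata relevant to the image-quality exclusion rules."""

    cta_slice_thickness_mm: float
    ncct_slice_thickness_mm: float
    n_slices: int
    full_brain_coverage: bool = True
    sharp_kernel: bool = False
    motion_artefact: bool = False


@dataclass(frozen=True)
class QCDecision:
    included: bool
    reasons: tuple[str, ...]


def apply_scan_qc(meta: ScanMetadata) -> QCDecision:
    """Apply the scan-quality exclusion rules.

    A scan is excluded if any of the following fires: CTA slice thickness
    > 2 mm, NCCT slice thickness > 5 mm, fewer than 8 slices, incomplete
    brain coverage, a sharp reconstruction kernel, or motion artefacts.
    All thresholds are strict inequalities, so a 2.0 mm CTA and exactly 8
    slices both pass.
    """
    if meta.cta_slice_thickness_mm <= 0 or meta.ncct_slice_thickness_mm <= 0:
        raise ValidationError("slice thickness must be positive")
    if meta.n_slices < 1:
        raise ValidationError("n_slices must be >= 1")
    reasons = []
    if meta.cta_slice_thickness_mm > 2.0:
        reasons.append("CTA slice thickness > 2 mm")
    if meta.ncct_slice_thickness_mm > 5.0:
        reasons.append("NCCT slice thickness > 5 mm")
    if meta.n_slices < 8:
        reasons.append("number of slices < 8")
    if not meta.full_brain_coverage:
        reasons.append("incomplete brain coverage")
    if meta.sharp_kernel:
        reasons.append("sharp reconstruction kernel")
    if meta.motion_artefact:
        reasons.append("motion artefact")
    return QCDecision(included=not reasons, reasons=tuple(reasons))


def _load(path) -> nib.Nifti1Image:
    try:
        return nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        if isinstance(exc, ThrombocharError):
            raise
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc


def read_image_pair(path_ncct, path_cta, path_mask) -> VoxelVolumePair:
    """Load an NCCT/CTA/mask triplet and verify they share one grid.

    Spacing is taken from the NCCT header.  A shape or affine mismatch
    raises :class:`RegistrationError`; a mask with values outside {0, 1}
    raises :class:`ValidationError`.
    """
    img_n, img_c, img_m = _load(path_ncct), _load(path_cta), _load(path_mask)
    shapes = {img_n.shape, img_c.shape, img_m.shape}
    if len(shapes) != 1:
        raise RegistrationError(
            f"grid shapes differ: ncct {img_n.shape}, cta {img_c.shape}, "
            f"mask {img_m.shape}"
        )
    for other, label in ((img_c, "cta"), (img_m, "mask")):
        if not np.allclose(img_n.affine, other.affine, atol=1e-4):
            raise RegistrationError(f"affine of {label} differs from ncct")
    spacing = tuple(float(z) for z in img_n.header.get_zooms()[:3])
    return VoxelVolumePair(
        ncct=np.asanyarray(img_n.dataobj, dtype=float),
        cta=np.asanyarray(img_c.dataobj, dtype=float),
        mask=np.asanyarray(img_m.dataobj),
        spacing=spacing,
    )


def write_image_pair(pair: VoxelVolumePair, path_ncct, path_cta, path_mask) -> None:
    """Write a pair to three NIfTI files with a diagonal-spacing affine."""
    affine = np.diag(list(pair.spacing) + [1.0])
    nib.save(nib.Nifti1Image(pair.ncct.astype(np.float32), affine), str(path_ncct))
    nib.save(nib.Nifti1Image(pair.cta.astype(np.float32), affine), str(path_cta))
    nib.save(nib.Nifti1Image(pair.mask.astype(np.uint8), affine), str(path_mask))
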