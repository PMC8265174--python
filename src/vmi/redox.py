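"""Voxelwise mitochondrial redox-ratio (NADH/FAD) computation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from vmi.volume_io import ImageVolume, VesselMask

logger = logging.getLogger(__name__)


@dataclass
class RedoxVolume:
    """Voxelwise NADH/FAD ratio with a tissue mask and summary mean.

    ``rr`` holds NaN at undefined voxels (denominator at or below ``eps``);
    ``mean_rr`` averages defined ratios over tissue voxels only.
    """

    rr: np.ndarray
    defined: np.ndarray  # boolean: FAD above eps
    tissue_mask: VesselMask
    mean_rr: float
    label: str = "NADH/FAD"


def redox_ratio(
    nadh: ImageVolume,
    fad: ImageVolume,
    tissue: VesselMask | None = None,
    eps: float = 1.0,
    label: str = "NADH/FAD",
) -> RedoxVolume:
    """Compute the voxelwise redox ratio NADH/FAD.

    Voxels where the FAD denominator is ≤ ``eps`` are flagged undefined and
    excluded from ``mean_rr``.  Both channels should be flat-field corrected
    first (see :func:`vmi.volume_io.flat_field_correct`).  For FITC-injected
    lungs the denominator channel is contaminated; pass
    ``label="NADH/(FAD+FITC)"`` so outputs carry the caveat.

    Parameters
    ----------
    nadh, fad : ImageVolume
        Shape-matched channel volumes.
    tissue : VesselMask, optional
        Voxels over which ``mean_rr`` is computed; defaults to voxels where
        either channel is positive.
    eps : float
        Denominator floor in intensity counts (default 1).

    Raises
    ------
    ValueError
        On shape mismatch.
    """
    if nadh.shape != fad.shape:
        raise ValueError(f"shape mismatch: {nadh.shape} vs {fad.shape}")
    n = nadh.voxels.astype(np.float64)
    f = fad.voxels.astype(np.float64)
    defined = f > eps
    rr = np.full(n.shape, np.nan)
    np.divide(n, f, out=rr, where=defined)

    if tissue is None:
        tissue = VesselMask((n > 0) | (f > 0), nadh.spacing, nadh.channel)
    elif tissue.shape != nadh.shape:
        raise ValueError(f"tissue mask shape {tissue.shape} != volume shape {nadh.shape}")

    valid = tissue.voxels & defined
    if valid.any():
        mean_rr = float(rr[valid].mean())
    else:
        logger.warning("no defined tissue voxels; mean_rr set to NaN")
        mean_rr = float("nan")
    return RedoxVolume(rr=rr, defined=defined, tissue_mask=tissue, mean_rr=mean_rr, label=label)
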