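"""Per-field consensus parameters: TVD, FCD, PPV and field RBCv.

All densities refer to capillaries only (venules are detected and reported
but excluded from density metrics, since capillaries carry the diffusive
oxygen exchange). Lengths are micrometers internally and converted to
millimeters at aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection import VesselSegment


@dataclass
class FieldMetrics:
    tvd: float                    # mm mm^-2
    fcd: float                    # mm mm^-2
    ppv: float                    # in [0, 1]
    rbcv: float | None            # um/s, length-weighted; None if no vessel has one
    fov_area: float               # mm^2
    n_capillaries: int
    n_venules: int
    n_paths: int = 0


def _capillaries(vessels: Sequence[VesselSegment]) -> list[VesselSegment]:
    return [v for v in vessels if v.vessel_type == "capillary"]


def tvd(vessels: Sequence[VesselSegment], fov_area: float) -> float:
    """Total vessel density: summed capillary centerline length / area (mm mm^-2)."""
    if fov_area <= 0:
        raise ValueError("fov_area must be > 0")
    total_mm = sum(v.length for v in _capillaries(vessels)) / 1000.0
    return total_mm / fov_area


def fcd_ppv(vessels: Sequence[VesselSegment], fov_area: float) -> tuple[float, float]:
    """Functional capillary density and proportion of perfused vessels.

    FCD counts only capillaries classified perfused; PPV = FCD / TVD is the
    length-weighted perfused fraction (0 when TVD is 0). Capillaries with
    no perfusion assessment count as non-perfused.
    """
    if fov_area <= 0:
        raise ValueError("fov_area must be > 0")
    caps = _capillaries(vessels)
    perfused_mm = sum(v.length for v in caps if v.perfusion == "perfused") / 1000.0
    fcd = perfused_mm / fov_area
    total = tvd(vessels, fov_area)
    ppv = fcd / total if total > 0 else 0.0
    return fcd, ppv


def field_rbcv(vessels: Sequence[VesselSegment]) -> float | None:
    """Length-weighted mean capillary RBCv (um/s); None if no capillary has one.

    Length weighting prevents a capillary that the focal plane splits into
    several short segments from dominating the field average.
    """
    caps = [v for v in _capillaries(vessels) if v.rbcv is not None]
    if not caps:
        return None
    lengths = np.array([v.length for v in caps])
    vels = np.array([v.rbcv for v in caps])
    if lengths.sum() <= 0:
        return None
    return float(np.average(vels, weights=lengths))


def compute_field_metrics(vessels: Sequence[VesselSegment], fov_area: float,
                          n_paths: int = 0) -> FieldMetrics:
    caps = _capillaries(vessels)
    fcd, ppv = fcd_ppv(vessels, fov_area)
    return FieldMetrics(
        tvd=tvd(vessels, fov_area),
        fcd=fcd,
        ppv=ppv,
        rbcv=field_rbcv(vessels),
        fov_area=fov_area,
        n_capillaries=len(caps),
        n_venules=len(vessels) - len(caps),
        n_paths=n_paths,
    )
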