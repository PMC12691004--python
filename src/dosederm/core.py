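"""Core in-memory containers shared by every stage of the pipeline.

Conventions (used consistently across the package):

* Grids are axis-aligned with identity orientation.  ``values`` is indexed
  ``[z, y, x]``; ``spacing`` and ``origin`` are ``(z, y, x)`` in mm.  World
  coordinates refer to voxel centers.  Oblique acquisitions are rejected at
  load time.
* Volumes are reported in cc = voxel count x voxel volume (mm^3) / 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageGrid:
    """Axis-aligned 3-D scalar grid (CT in HU, dose in Gy)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("ImageGrid requires a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def world_coords(self, index: tuple[float, float, float]) -> np.ndarray:
        """World (z, y, x) mm of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


@dataclass
class StructureMask:
    """Named binary mask congruent with a reference :class:`ImageGrid`."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            uniq = np.unique(self.mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be in {0,1}")
            self.mask = self.mask.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_cc(self, grid: ImageGrid) -> float:
        if self.mask.shape != grid.shape:
            raise ValueError("mask shape does not match reference grid")
        return self.voxel_count * grid.voxel_volume_cc


AJCC_LEVELS = (0, 1, 2, 3, 4)
SURGERY_LEVELS = ("TM/MRM", "BCS")
LATERALITY_LEVELS = ("left", "right")


@dataclass
class ClinicalRecord:
    """One patient's clinical covariates plus the dermatitis outcome."""

    patient_id: str
    age: float
    bmi: float
    laterality: str
    surgery: str
    ajcc_stage: int
    scf: bool
    imn: bool
    chemotherapy: bool
    rd_grade_ge2: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be > 0")
        if not self.bmi > 10:
            raise ValueError("bmi must be > 10")
        if self.laterality not in LATERALITY_LEVELS:
            raise ValueError(f"laterality must be one of {LATERALITY_LEVELS}")
        if self.surgery not in SURGERY_LEVELS:
            raise ValueError(f"surgery must be one of {SURGERY_LEVELS}")
        if int(self.ajcc_stage) not in AJCC_LEVELS:
            raise ValueError(f"ajcc_stage must be one of {AJCC_LEVELS}")
        self.ajcc_stage = int(self.ajcc_stage)
        self.scf = bool(self.scf)
        self.imn = bool(self.imn)
        self.chemotherapy = bool(self.chemotherapy)
        self.rd_grade_ge2 = bool(self.rd_grade_ge2)
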