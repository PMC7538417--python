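"""Voxel-grid container for multi-section microscopy data.

An :class:`ImageStack` is a plain (sections, rows, cols) array plus the two
physical calibrations everything downstream depends on: the lateral pixel
size and the (axially corrected) spacing between optical sections, both in
micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A single-channel Z-stack.

    Parameters
    ----------
    data : ndarray, shape (n_sections, n_rows, n_cols)
        Intensity values, one 2D image per optical section.
    pixel_size : float
        Lateral size of a pixel in µm.
    z_spacing : float
        Distance between adjacent optical sections in µm.  This must be the
        axially *corrected* spacing when an axial distance correction factor
        applies; see :mod:`spherotome.calibration`.
    z_offset : int
        Index of the first section relative to the original acquisition, so
        that stacks cropped by channel Z-shifts keep track of their valid
        range.
    """

    data: np.ndarray
    pixel_size: float
    z_spacing: float
    z_offset: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 3D (sections, rows, cols); got shape {self.data.shape}"
            )
        if self.pixel_size <= 0 or self.z_spacing <= 0:
            raise ValueError("pixel_size and z_spacing must be positive")

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def section(self, i: int) -> np.ndarray:
        return self.data[i]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.pixel_size**2 * self.z_spacing

    def with_data(self, data: np.ndarray, z_offset: int | None = None) -> "ImageStack":
        return replace(
            self, data=data, z_offset=self.z_offset if z_offset is None else z_offset
        )
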