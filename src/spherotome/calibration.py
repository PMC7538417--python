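"""Image corrections applied to raw stacks before any segmentation.

Three camera/optics corrections are supported:

* **dark-noise subtraction + flat-field division** — undoes non-uniform
  illumination.  The flat-field frame is dark-subtracted and normalized to
  mean 1, then every raw section is dark-subtracted and divided by it.
* **axial chromatic shift** — light of different wavelengths focuses onto
  different optical sections; each channel is shifted by an integer number
  of sections (measured externally, e.g. from multi-spectral beads) and all
  channels are later cropped to their common Z overlap.
* **axial distance correction** — widefield systems can stretch objects
  along Z.  The nominal section spacing is multiplied by a correction
  factor (the width/height ratio of an imaged spherical bead) and that
  corrected spacing is the only Z spacing used by extrusion and volume
  computation.

The corrections only *apply* externally measured values; estimating the
shift or the factor from bead images is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack import ImageStack

__all__ = [
    "CalibrationConfig",
    "correct_flatfield",
    "shift_channel_z",
    "corrected_z_spacing",
]


@dataclass
class CalibrationConfig:
    """Calibration inputs for one acquisition.

    ``axial_factor`` is dimensionless and must be positive; a factor of 1
    leaves the nominal spacing unchanged.  ``dark_noise`` and
    ``flatfield`` are 2D frames matching the raw XY dimensions; either may
    be None, in which case that correction is skipped (a zero dark frame /
    uniform flat are assumed).
    """

    nominal_z_spacing: float  # µm
    axial_factor: float = 1.0
    dark_noise: np.ndarray | None = None
    flatfield: np.ndarray | None = None
    z_shift: int = 0  # sections, per channel

    def __post_init__(self) -> None:
        if self.nominal_z_spacing <= 0:
            raise ValueError("nominal_z_spacing must be positive")
        if self.axial_factor <= 0:
            raise ValueError("axial_factor must be positive")


def corrected_z_spacing(config: CalibrationConfig) -> float:
    """Z distance between sections after axial distance correction (µm)."""
    return config.nominal_z_spacing * config.axial_factor


def correct_flatfield(raw: ImageStack, config: CalibrationConfig) -> ImageStack:
    """Dark-noise subtraction and flat-field division, per section.

    output = (raw − dark) / norm_flat with norm_flat = (flat − dark) /
    mean(flat − dark).  Negative dark-subtracted values are clamped to 0
    (camera counts are non-negative).
    """
    frame = raw.frame_shape
    dark = np.zeros(frame) if config.dark_noise is None else np.asarray(
        config.dark_noise, float
    )
    if dark.shape != frame:
        raise ValueError(
            f"dark-noise frame {dark.shape} does not match stack XY {frame}"
        )
    data = np.clip(raw.data.astype(float) - dark, 0.0, None)
    if config.flatfield is not None:
        flat = np.asarray(config.flatfield, float)
        if flat.shape != frame:
            raise ValueError(
                f"flat-field frame {flat.shape} does not match stack XY {frame}"
            )
        flat = flat - dark
        mean = flat.mean()
        if mean <= 0:
            raise ValueError(
                "degenerate calibration: flat-field minus dark has non-positive mean"
            )
        norm_flat = flat / mean
        with np.errstate(divide="ignore", invalid="ignore"):
            data = np.where(norm_flat > 0, data / norm_flat, 0.0)
    return raw.with_data(data)


def shift_channel_z(stack: ImageStack, n_sections: int) -> ImageStack:
    """Shift a channel along Z by an integer number of sections.

    Section ``i`` of the output is section ``i − n_sections`` of the input;
    sections shifted out of range are dropped and the output's ``z_offset``
    records the reduced valid range so that all channels can later be
    cropped to their common overlap.
    """
    n = int(n_sections)
    depth = stack.n_sections
    if abs(n) >= depth:
        raise ValueError(
            f"Z shift of {n} sections leaves no overlap for a {depth}-section stack"
        )
    if n == 0:
        return stack
    if n > 0:
        # aligned[i] = raw[i + n]; valid aligned indices start at 0
        return stack.with_data(stack.data[n:], z_offset=stack.z_offset)
    # aligned[i] = raw[i + n]; the first valid aligned index is |n|
    return stack.with_data(stack.data[:n], z_offset=stack.z_offset + abs(n))
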