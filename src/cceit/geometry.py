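"""Sensor, grid, field-of-view and measurement-pair geometry.

The sensor is a ring of K area electrodes on the inner wall of an insulating
sleeve, surrounded by a grounded screen.  All lengths are normalized so the
inner wall of the sleeve (the electrode surface) sits at radius 1.0.  The
simulation runs on a uniform fine Cartesian grid covering the screen circle;
images are reconstructed on a coarser ``recon_n`` x ``recon_n`` grid (64 x 64
by default), of which only pixels inside a circular field of view (FOV) are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default number of electrodes.
DEFAULT_K = 32

#: Calibrated FOV circle on the 64x64 reconstruction grid, in pixel units.
#: The radius and the quarter-pixel row offset of the centre are frozen so the
#: pixel-centre-inside count equals 1856 exactly; no circle centred on the
#: grid centre hits that count on a 64x64 lattice.
FOV_RADIUS_PX = 24.30
FOV_CENTER_ROW_PX = 32.25
FOV_CENTER_COL_PX = 32.00

#: Number of reconstructed pixels at the calibrated default FOV.
N_FOV = 1856


class InvalidGeometryError(ValueError):
    """Raised for unbuildable sensor configurations."""


@dataclass(frozen=True)
class SensorGeometry:
    """Circular K-electrode sensor layout.

    ``electrode_angular_spans`` holds K ``(start, stop)`` angle intervals in
    radians, increasing, with electrode 0 centred at pi/2 (top of the image,
    anterior chest wall of a supine patient).
    """

    K: int = DEFAULT_K
    sensor_radius: float = 1.0
    electrode_coverage: float = 0.8
    electrode_thickness: float = 0.04
    insulation_thickness: float = 0.10
    screen_radius: float = 1.15
    electrode_angular_spans: tuple[tuple[float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.K < 2:
            raise InvalidGeometryError(f"need at least 2 electrodes, got {self.K}")
        if not 0.0 < self.electrode_coverage < 1.0:
            raise InvalidGeometryError(
                f"electrode coverage must be in (0,1), got {self.electrode_coverage}"
            )
        if self.screen_radius <= self.sensor_radius + self.insulation_thickness:
            raise InvalidGeometryError("screen must lie outside the insulation layer")
        if not self.electrode_angular_spans:
            object.__setattr__(
                self, "electrode_angular_spans", tuple(self._compute_spans())
            )

    def _compute_spans(self) -> list[tuple[float, float]]:
        pitch = 2.0 * np.pi / self.K
        half = 0.5 * self.electrode_coverage * pitch
        spans = []
        for k in range(self.K):
            center = np.pi / 2.0 + k * pitch
            spans.append((center - half, center + half))
        return spans

    @property
    def electrode_centers(self) -> np.ndarray:
        """Centre angle of each electrode, radians."""
        return np.array([0.5 * (a + b) for a, b in self.electrode_angular_spans])


def build_sensor(
    K: int = DEFAULT_K,
    electrode_coverage: float = 0.8,
    electrode_thickness: float = 0.04,
    insulation_thickness: float = 0.10,
    screen_radius: float = 1.15,
) -> SensorGeometry:
    """Build an evenly spaced circular sensor.

    Electrode 0 is centred at angle pi/2; spans are returned in increasing
    angle.  Raises :class:`InvalidGeometryError` for K < 2 or coverage
    outside (0, 1).
    """
    return SensorGeometry(
        K=K,
        electrode_coverage=electrode_coverage,
        electrode_thickness=electrode_thickness,
        insulation_thickness=insulation_thickness,
        screen_radius=screen_radius,
    )


@dataclass(frozen=True)
class Grid:
    """Uniform square grids for simulation (fine) and reconstruction.

    Both grids span the square ``[-half_width, half_width]^2`` centred on the
    sensor axis.  ``fine_n`` must be an integer multiple of ``recon_n`` so
    that reduced pixels are exact blocks of fine cells.  Row 0 is the top of
    the image (anterior chest wall); physical y increases upward.
    """

    fine_n: int = 256
    recon_n: int = 64
    half_width: float = 1.2

    def __post_init__(self) -> None:
        if self.fine_n % self.recon_n != 0:
            raise InvalidGeometryError("fine_n must be a multiple of recon_n")

    @property
    def block(self) -> int:
        return self.fine_n // self.recon_n

    @property
    def fine_h(self) -> float:
        return 2.0 * self.half_width / self.fine_n

    @property
    def recon_h(self) -> float:
        return 2.0 * self.half_width / self.recon_n

    def fine_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of fine-cell centres, shape (n, n).

        Row index increases downward, y upward.
        """
        c = (np.arange(self.fine_n) + 0.5) * self.fine_h - self.half_width
        x = np.broadcast_to(c, (self.fine_n, self.fine_n))
        y = np.broadcast_to(-c[:, None], (self.fine_n, self.fine_n))
        return x, y

    def recon_centers(self) -> tuple[np.ndarray, np.ndarray]:
        c = (np.arange(self.recon_n) + 0.5) * self.recon_h - self.half_width
        x = np.broadcast_to(c, (self.recon_n, self.recon_n))
        y = np.broadcast_to(-c[:, None], (self.recon_n, self.recon_n))
        return x, y

    @property
    def fov_radius(self) -> float:
        """Physical radius of the calibrated default FOV circle.

        The calibration constants are expressed in 64-grid pixel units; the
        physical circle is the same whatever ``recon_n`` is.
        """
        return FOV_RADIUS_PX * (2.0 * self.half_width / 64.0)

    @property
    def fov_center(self) -> tuple[float, float]:
        """Physical (x, y) of the FOV circle centre."""
        scale = 2.0 * self.half_width / 64.0
        x = (FOV_CENTER_COL_PX - 32.0) * scale
        y = -(FOV_CENTER_ROW_PX - 32.0) * scale
        return x, y


@dataclass(frozen=True)
class FOVMask:
    """Boolean reconstruction-grid mask with a flat index for in-FOV pixels.

    ``pixel_index_map`` maps flat row-major pixel index on the full grid to
    0..n_fov-1 for in-FOV pixels and -1 elsewhere.
    """

    mask: np.ndarray
    n_fov: int
    pixel_index_map: np.ndarray

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a length-n_fov vector (or batch) into full-grid images."""
        values = np.asarray(values)
        n = self.mask.shape[0]
        if values.ndim == 1:
            out = np.full((n, n), fill, dtype=values.dtype)
            out[self.mask] = values
            return out
        out = np.full(values.shape[:-1] + (n, n), fill, dtype=values.dtype)
        out[..., self.mask] = values
        return out

    def extract(self, image: np.ndarray) -> np.ndarray:
        """Gather in-FOV pixels (row-major) from full-grid image(s)."""
        return np.asarray(image)[..., self.mask]


def build_fov_mask(
    grid: Grid,
    fov_radius_px: float | None = None,
    center_px: tuple[float, float] | None = None,
) -> FOVMask:
    """Build the circular FOV mask on the reconstruction grid.

    A pixel is in-FOV iff its centre lies strictly inside the circle given in
    pixel units of the reconstruction grid.  The index map is row-major over
    in-FOV pixels.  Defaults are the calibrated constants rescaled from their
    64-grid pixel units.
    """
    n = grid.recon_n
    s = n / 64.0
    if fov_radius_px is None:
        fov_radius_px = FOV_RADIUS_PX * s
    if center_px is None:
        center_px = (FOV_CENTER_ROW_PX * s, FOV_CENTER_COL_PX * s)
    rows = np.arange(n) + 0.5
    cols = np.arange(n) + 0.5
    dr = rows[:, None] - center_px[0]
    dc = cols[None, :] - center_px[1]
    mask = dr * dr + dc * dc < fov_radius_px * fov_radius_px
    n_fov = int(mask.sum())
    index_map = np.full(n * n, -1, dtype=np.int64)
    index_map[np.flatnonzero(mask.ravel())] = np.arange(n_fov)
    return FOVMask(mask=mask, n_fov=n_fov, pixel_index_map=index_map)


@dataclass(frozen=True)
class MeasurementIndex:
    """Ordered (excite, sense) electrode pairs defining the measurement vector.

    With repetitions the ordering is row-major over the K x K matrix with the
    diagonal skipped: (0,1), (0,2), ..., (1,0), (1,2), ...  Without
    repetitions only i < j pairs are kept.
    """

    pairs: tuple[tuple[int, int], ...]
    K: int
    with_repetitions: bool

    @property
    def M(self) -> int:
        return len(self.pairs)


def measurement_count(K: int, with_repetitions: bool = True) -> int:
    """Number of mutual-capacitance measurements for K electrodes.

    K(K-1) when each pair is measured in both directions, K(K-1)/2 otherwise.
    """
    if K < 2:
        raise ValueError(f"need at least 2 electrodes, got {K}")
    return K * (K - 1) if with_repetitions else K * (K - 1) // 2


def build_measurement_index(K: int = DEFAULT_K, with_repetitions: bool = True) -> MeasurementIndex:
    if K < 2:
        raise ValueError(f"need at least 2 electrodes, got {K}")
    if with_repetitions:
        pairs = tuple((i, j) for i in range(K) for j in range(K) if j != i)
    else:
        pairs = tuple((i, j) for i in range(K) for j in range(i + 1, K))
    return MeasurementIndex(pairs=pairs, K=K, with_repetitions=with_repetitions)
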