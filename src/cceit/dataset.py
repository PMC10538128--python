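"""Labeled dataset generation, noise injection, splitting and persistence.

Each sample pairs a normalized complex capacitance vector (length M = 992 at
defaults) with the complex relative permittivity of the in-FOV pixels of the
reduced image (length N = 1856) and a class label 1..17.  Composition
defaults mirror the study conditions: 9375 training samples for each of the
16 lung-state classes plus 44,000 random-ellipse samples (194,000 total) and
2500 test samples for each of the 17 classes (42,500 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import h5py
import numpy as np

from .forward import (
    MeasurementFrame,
    calibration_frames,
    capacitance_frame,
    normalize_channels,
)
from .geometry import (
    FOVMask,
    Grid,
    MeasurementIndex,
    SensorGeometry,
    build_fov_mask,
    build_measurement_index,
    build_sensor,
)
from .phantom import N_CLASSES, OMEGA_DEFAULT, rasterize, sample_phantom

#: Study-condition dataset compositions: samples per class.
DEFAULT_TRAIN_COMPOSITION = {**{c: 9375 for c in range(1, 17)}, 17: 44000}
DEFAULT_TEST_COMPOSITION = {c: 2500 for c in range(1, 18)}


def composition_total(composition: dict[int, int]) -> int:
    """Total sample count of a composition (validates the class ids)."""
    for c, n in composition.items():
        if not 1 <= c <= N_CLASSES:
            raise ValueError(f"unknown class {c}")
        if n < 0:
            raise ValueError(f"negative count for class {c}")
    return sum(composition.values())


@dataclass(frozen=True)
class Sample:
    """One measurement/image pair."""

    measurements: np.ndarray  # complex, length M, normalized
    image: np.ndarray  # complex relative permittivity, length n_fov
    class_label: int
    phantom_seed: int
    snr_db: float | None = None


@dataclass
class DatasetStore:
    """In-memory dataset: stacked sample arrays plus generation metadata."""

    measurements: np.ndarray  # complex (n, M)
    images: np.ndarray  # complex (n, n_fov)
    labels: np.ndarray  # int (n,)
    seeds: np.ndarray  # int (n,)
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.labels.shape[0]

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("measurements_real", data=self.measurements.real)
            f.create_dataset("measurements_imag", data=self.measurements.imag)
            f.create_dataset("images_real", data=self.images.real)
            f.create_dataset("images_imag", data=self.images.imag)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("seeds", data=self.seeds)
            f.attrs["config"] = json.dumps(self.config)

    @classmethod
    def load(cls, path: str) -> "DatasetStore":
        with h5py.File(path, "r") as f:
            meas = f["measurements_real"][:] + 1j * f["measurements_imag"][:]
            imgs = f["images_real"][:] + 1j * f["images_imag"][:]
            return cls(
                measurements=meas,
                images=imgs,
                labels=f["labels"][:],
                seeds=f["seeds"][:],
                config=json.loads(f.attrs.get("config", "{}")),
            )


class DatasetGenerator:
    """Generates samples through the forward pipeline with cached calibration."""

    def __init__(
        self,
        sensor: SensorGeometry | None = None,
        grid: Grid | None = None,
        omega: float = OMEGA_DEFAULT,
        high_tissue: str = "effusion_fluid",
        phantom_ranges: dict | None = None,
    ):
        self.sensor = sensor if sensor is not None else build_sensor()
        self.grid = grid if grid is not None else Grid()
        self.omega = omega
        self.fov: FOVMask = build_fov_mask(self.grid)
        self.index: MeasurementIndex = build_measurement_index(self.sensor.K)
        self.phantom_ranges = phantom_ranges
        self.c_low, self.c_high = calibration_frames(
            self.sensor, self.grid, omega, high_tissue
        )

    def sample(self, class_label: int, rng: np.random.Generator) -> Sample:
        spec = sample_phantom(class_label, rng, self.phantom_ranges)
        eps_map = rasterize(spec, self.grid, self.sensor, self.omega)
        raw = capacitance_frame(eps_map, self.sensor, self.grid, self.index)
        norm = normalize_channels(raw, self.c_low, self.c_high)
        image = eps_map.recon_map[self.fov.mask]
        return Sample(
            measurements=norm.c,
            image=image,
            class_label=class_label,
            phantom_seed=spec.rng_seed,
        )

    def generate(
        self,
        composition: dict[int, int],
        master_seed: int,
        snr_db: float | None = None,
    ) -> DatasetStore:
        """Generate a dataset with the given per-class composition.

        Deterministic under ``master_seed``: each sample gets an independent
        child seed, so regeneration is bit-identical.  If ``snr_db`` is set,
        measurement noise at that SNR is injected into each stored frame.
        """
        total = composition_total(composition)
        meas = np.empty((total, self.index.M), dtype=np.complex128)
        imgs = np.empty((total, self.fov.n_fov), dtype=np.complex128)
        labels = np.empty(total, dtype=np.int64)
        seeds = np.empty(total, dtype=np.int64)
        ss = np.random.SeedSequence(master_seed)
        children = ss.spawn(total)
        k = 0
        for class_label in sorted(composition):
            for _ in range(composition[class_label]):
                rng = np.random.default_rng(children[k])
                s = self.sample(class_label, rng)
                if snr_db is not None and np.isfinite(snr_db):
                    frame = MeasurementFrame(c=s.measurements, kind="normalized", index=self.index)
                    s_noisy = add_noise(frame, snr_db, rng)
                    meas[k] = s_noisy.c
                else:
                    meas[k] = s.measurements
                imgs[k] = s.image
                labels[k] = s.class_label
                seeds[k] = s.phantom_seed
                k += 1
        return DatasetStore(
            measurements=meas,
            images=imgs,
            labels=labels,
            seeds=seeds,
            config={
                "composition": {str(c): n for c, n in composition.items()},
                "master_seed": master_seed,
                "snr_db": snr_db,
                "fine_n": self.grid.fine_n,
                "recon_n": self.grid.recon_n,
                "K": self.sensor.K,
            },
        )


def generate_dataset(
    composition: dict[int, int],
    master_seed: int,
    generator: DatasetGenerator | None = None,
    snr_db: float | None = None,
) -> DatasetStore:
    """Generate a dataset (convenience wrapper around DatasetGenerator)."""
    if generator is None:
        generator = DatasetGenerator()
    return generator.generate(composition, master_seed, snr_db)


def add_noise(
    frame: MeasurementFrame, snr_db: float, rng: np.random.Generator
) -> MeasurementFrame:
    """Additive white Gaussian noise at a prescribed SNR.

    The noise power is set against the mean square of the imaginary
    component of the measurement vector (the channel used downstream):
    sigma^2 = P_imag / 10^(snr_db / 10), i.i.d. per component, added to the
    imaginary part.  ``snr_db = inf`` returns the frame unchanged.
    """
    if np.isinf(snr_db):
        return frame
    p_signal = float(np.mean(frame.c.imag**2))
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    noisy = frame.c + 1j * rng.normal(0.0, sigma, size=frame.c.shape)
    return MeasurementFrame(
        c=noisy, kind=frame.kind, index=frame.index, noise_snr_db=snr_db
    )


def add_noise_array(
    imag_measurements: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    """Noise injection on a batch of real (imaginary-component) vectors.

    SNR is defined per vector, matching :func:`add_noise`.
    """
    if np.isinf(snr_db):
        return imag_measurements
    p = np.mean(imag_measurements**2, axis=-1, keepdims=True)
    sigma = np.sqrt(p / 10.0 ** (snr_db / 10.0))
    return imag_measurements + sigma * rng.standard_normal(imag_measurements.shape)


def split_train_val(
    n_or_labels, ratio: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive split; returns (learning, validation) indices.

    ``ratio`` is the learning fraction; the learning size is
    ``floor(ratio * n)``.  Accepts a sample count or an array whose leading
    dimension is the sample count.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = int(n_or_labels) if np.isscalar(n_or_labels) else len(n_or_labels)
    perm = rng.permutation(n)
    n_learn = int(np.floor(ratio * n))
    return np.sort(perm[:n_learn]), np.sort(perm[n_learn:])


@dataclass(frozen=True)
class MeasurementMatrixView:
    """K x K matrix layout of a measurement vector.

    Rows index the excitation electrode, columns the sensing electrode; the
    diagonal is zero.
    """

    m: np.ndarray
    index: MeasurementIndex


def to_matrix_view(
    values: np.ndarray, index: MeasurementIndex
) -> MeasurementMatrixView:
    """Reshape a length-M measurement vector to its K x K matrix view."""
    values = np.asarray(values)
    if values.shape[-1] != index.M:
        raise ValueError(f"expected length {index.M}, got {values.shape[-1]}")
    K = index.K
    m = np.zeros(values.shape[:-1] + (K, K), dtype=values.dtype)
    rows = [p[0] for p in index.pairs]
    cols = [p[1] for p in index.pairs]
    m[..., rows, cols] = values
    return MeasurementMatrixView(m=m, index=index)


def from_matrix_view(view: MeasurementMatrixView) -> np.ndarray:
    """Inverse of :func:`to_matrix_view` (drops the zero diagonal)."""
    rows = [p[0] for p in view.index.pairs]
    cols = [p[1] for p in view.index.pairs]
    return view.m[..., rows, cols]
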