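"""Parametric thorax phantoms and their complex-permittivity rasterization.

A phantom is a 2D transversal slice of a supine patient's thorax built from
ellipses: a fat-bounded thorax outline containing two lungs, the heart, the
aorta and the spine.  Each lung can be affected by pneumothorax (air pocket,
collects at the anterior wall = top of the image), pleural effusion (free
fluid, collects dorsally = bottom of the image), or both at once
(hydropneumothorax, air above a horizontal fluid level).  Tissue electrical
properties are tabulated at 100 MHz.

Geometry is expressed in FOV-radius units: the calibrated field-of-view
circle has radius 1 and is centred at the origin, x to the right, y upward
(toward the anterior wall).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math

import numpy as np

from .geometry import Grid, SensorGeometry

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
OMEGA_DEFAULT = 2.0 * math.pi * 1.0e8  # 100 MHz excitation


@dataclass(frozen=True)
class TissueProperties:
    """Relative permittivity and conductivity (S/m) of one tissue."""

    name: str
    rel_permittivity: float
    conductivity: float


# Tabulated tissue properties at 100 MHz.
TISSUES: dict[str, TissueProperties] = {
    t.name: t
    for t in [
        TissueProperties("air", 1.0, 0.0),
        TissueProperties("lung_inspiration", 31.6, 0.306),
        TissueProperties("lung_expiration", 67.1, 0.559),
        TissueProperties("pneumothorax_air", 1.0, 1.0e-15),
        TissueProperties("effusion_fluid", 70.0, 1.4),
        TissueProperties("electrode_metal", 1.0, 0.0643),
        TissueProperties("insulation_plastic", 2.0, 1.0e-21),
        TissueProperties("spine", 10.53, 0.0643),
        TissueProperties("heart", 90.8, 0.733),
        TissueProperties("fat", 12.7, 0.068),
    ]
}

#: Tissues a random-ellipse phantom may draw from (the organ/disease set).
RANDOM_ELLIPSE_TISSUES = (
    "lung_inspiration",
    "lung_expiration",
    "pneumothorax_air",
    "effusion_fluid",
    "spine",
    "heart",
    "fat",
)

DISEASE_KINDS = ("none", "pneumothorax", "effusion", "hydro")

N_CLASSES = 17


def complex_permittivity(tissue: TissueProperties, omega: float = OMEGA_DEFAULT) -> complex:
    """Complex relative permittivity eps' - j sigma/(omega eps0)."""
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    return tissue.rel_permittivity - 1j * tissue.conductivity / (omega * EPS0)


@dataclass(frozen=True)
class EllipseRegion:
    """Rotated ellipse in FOV-radius units, tagged with a tissue name."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    tissue: str

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (x, y in FOV units)."""
        dx = x - self.center[0]
        dy = y - self.center[1]
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def shifted(self, dx: float, dy: float) -> "EllipseRegion":
        return EllipseRegion(
            (self.center[0] + dx, self.center[1] + dy), self.semi_axes, self.rotation, self.tissue
        )


@dataclass(frozen=True)
class DiseaseSpec:
    """Disease state of one lung: kind, clipping ellipse, fluid level."""

    kind: str = "none"
    clip: EllipseRegion | None = None
    split_y: float | None = None


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one phantom.

    ``organs`` are painted in order (later regions override earlier ones):
    fat outline, lungs, heart, aorta, spine — or fat plus random ellipses for
    class 17.  ``class_label`` is 1..16 for the left x right lung-state
    combinations and 17 for random ellipses.
    """

    organs: tuple[EllipseRegion, ...]
    disease_left: DiseaseSpec
    disease_right: DiseaseSpec
    respiration_phase: str
    class_label: int
    rng_seed: int

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, EllipseRegion) or isinstance(o, DiseaseSpec):
                return asdict(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=enc)


@dataclass(frozen=True)
class ComplexPermittivityMap:
    """Complex relative permittivity on the fine grid and the reduced grid."""

    fine_map: np.ndarray
    recon_map: np.ndarray
    omega: float = OMEGA_DEFAULT


# --- default anatomy (FOV-radius units) ------------------------------------

def _default_organs(lung_tissue: str) -> dict[str, EllipseRegion]:
    deg = math.pi / 180.0
    return {
        "fat": EllipseRegion((0.0, 0.0), (0.95, 0.78), 0.0, "fat"),
        "lung_left": EllipseRegion((-0.42, 0.02), (0.34, 0.48), 15 * deg, lung_tissue),
        "lung_right": EllipseRegion((0.42, 0.02), (0.34, 0.48), -15 * deg, lung_tissue),
        "heart": EllipseRegion((0.10, -0.05), (0.22, 0.26), 0.0, "heart"),
        "aorta": EllipseRegion((-0.02, -0.25), (0.06, 0.06), 0.0, "heart"),
        "spine": EllipseRegion((0.0, -0.60), (0.13, 0.10), 0.0, "spine"),
    }


#: Organ randomization ranges (uniform): centre jitter, rotation jitter,
#: per-axis scale, diseased-fraction range.
DEFAULT_RANGES = {
    "center_jitter": 0.05,
    "rotation_jitter": 10 * math.pi / 180.0,
    "scale_low": 0.9,
    "scale_high": 1.1,
    "disease_fraction_low": 0.1,
    "disease_fraction_high": 0.6,
}


def class_to_states(class_label: int) -> tuple[str, str]:
    """Map class 1..16 to (left, right) lung disease kinds."""
    if not 1 <= class_label <= 16:
        raise ValueError(f"no lung states for class {class_label}")
    left = DISEASE_KINDS[(class_label - 1) // 4]
    right = DISEASE_KINDS[(class_label - 1) % 4]
    return left, right


def states_to_class(left: str, right: str) -> int:
    return 1 + 4 * DISEASE_KINDS.index(left) + DISEASE_KINDS.index(right)


def _jitter(e: EllipseRegion, rng: np.random.Generator, cfg: dict) -> EllipseRegion:
    j = cfg["center_jitter"]
    rot = cfg["rotation_jitter"]
    cx = e.center[0] + rng.uniform(-j, j)
    cy = e.center[1] + rng.uniform(-j, j)
    a = e.semi_axes[0] * rng.uniform(cfg["scale_low"], cfg["scale_high"])
    b = e.semi_axes[1] * rng.uniform(cfg["scale_low"], cfg["scale_high"])
    th = e.rotation + rng.uniform(-rot, rot)
    return EllipseRegion((cx, cy), (a, b), th, e.tissue)


def _lung_fraction_outside(lung: EllipseRegion, clip: EllipseRegion, n: int = 96) -> float:
    """Fraction of lung area not covered by the clip ellipse (rasterized)."""
    a = max(lung.semi_axes)
    xs = np.linspace(lung.center[0] - a, lung.center[0] + a, n)
    ys = np.linspace(lung.center[1] - a, lung.center[1] + a, n)
    x, y = np.meshgrid(xs, ys)
    inside = lung.contains(x, y)
    total = int(inside.sum())
    if total == 0:
        return 0.0
    return float((inside & ~clip.contains(x, y)).sum() / total)


class DegeneratePhantomError(RuntimeError):
    """Clip ellipse failed to overlap the lung."""


def _make_clip(
    lung: EllipseRegion, kind: str, fraction: float, rng: np.random.Generator
) -> tuple[EllipseRegion, float | None]:
    """Build a clipping ellipse whose complement covers ``fraction`` of the lung.

    The clip is a copy of the lung shifted along the disease direction: down
    and toward the body midline for pneumothorax (air remains on top), up and
    toward the midline for effusion (fluid remains below), toward the midline
    for hydropneumothorax.  The shift distance is found by bisection on the
    rasterized uncovered fraction.
    """
    sx = -math.copysign(1.0, lung.center[0])  # toward the midline
    if kind == "pneumothorax":
        d = np.array([0.3 * sx, -1.0])
    elif kind == "effusion":
        d = np.array([0.3 * sx, 1.0])
    elif kind == "hydro":
        d = np.array([sx, -0.2])
    else:  # pragma: no cover - guarded by caller
        raise ValueError(kind)
    d = d / np.linalg.norm(d)
    lo, hi = 0.0, 2.5 * max(lung.semi_axes)
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        clip = lung.shifted(mid * d[0], mid * d[1])
        if _lung_fraction_outside(lung, clip) < fraction:
            lo = mid
        else:
            hi = mid
    shift = 0.5 * (lo + hi)
    clip = lung.shifted(shift * d[0], shift * d[1])
    if _lung_fraction_outside(lung, clip) >= 0.999:
        raise DegeneratePhantomError("clip ellipse does not overlap the lung")

    split_y = None
    if kind == "hydro":
        # fluid level: a y-quantile of the diseased part of the lung
        a = max(lung.semi_axes)
        xs = np.linspace(lung.center[0] - a, lung.center[0] + a, 96)
        ys = np.linspace(lung.center[1] - a, lung.center[1] + a, 96)
        x, y = np.meshgrid(xs, ys)
        diseased = lung.contains(x, y) & ~clip.contains(x, y)
        u = rng.uniform(0.3, 0.7)
        if diseased.any():
            split_y = float(np.quantile(y[diseased], u))
        else:
            split_y = float(lung.center[1])
    return clip, split_y


def sample_phantom(
    class_label: int,
    rng: np.random.Generator,
    ranges: dict | None = None,
) -> PhantomSpec:
    """Draw a randomized phantom of the given class.

    Organ centres, rotations and per-axis sizes are independently uniform
    within the configured ranges; disease clip ellipses are sized so the
    diseased lung fraction is uniform in its configured range.  The same
    generator state yields an identical spec.
    """
    if not 1 <= class_label <= N_CLASSES:
        raise ValueError(f"unknown class label {class_label}")
    cfg = dict(DEFAULT_RANGES)
    if ranges:
        cfg.update(ranges)
    seed = int(rng.integers(0, 2**31 - 1))
    phase = "inspiration" if rng.random() < 0.5 else "expiration"
    lung_tissue = f"lung_{phase}"

    if class_label == N_CLASSES:
        base = _default_organs(lung_tissue)
        organs = [_jitter(base["fat"], rng, cfg)]
        for _ in range(int(rng.integers(1, 5))):
            tissue = RANDOM_ELLIPSE_TISSUES[int(rng.integers(len(RANDOM_ELLIPSE_TISSUES)))]
            center = rng.uniform(-0.6, 0.6, size=2)
            axes = rng.uniform(0.05, 0.3, size=2)
            organs.append(
                EllipseRegion(tuple(center), tuple(axes), rng.uniform(0, math.pi), tissue)
            )
        return PhantomSpec(
            organs=tuple(organs),
            disease_left=DiseaseSpec(),
            disease_right=DiseaseSpec(),
            respiration_phase=phase,
            class_label=class_label,
            rng_seed=seed,
        )

    left_kind, right_kind = class_to_states(class_label)
    base = _default_organs(lung_tissue)
    organs = {name: _jitter(e, rng, cfg) for name, e in base.items()}

    diseases = {}
    for side, kind in (("left", left_kind), ("right", right_kind)):
        if kind == "none":
            diseases[side] = DiseaseSpec()
            continue
        lung = organs[f"lung_{side}"]
        frac = rng.uniform(cfg["disease_fraction_low"], cfg["disease_fraction_high"])
        clip, split_y = _make_clip(lung, kind, frac, rng)
        diseases[side] = DiseaseSpec(kind=kind, clip=clip, split_y=split_y)

    ordered = tuple(
        organs[k] for k in ("fat", "lung_left", "lung_right", "heart", "aorta", "spine")
    )
    return PhantomSpec(
        organs=ordered,
        disease_left=diseases["left"],
        disease_right=diseases["right"],
        respiration_phase=phase,
        class_label=class_label,
        rng_seed=seed,
    )


def apply_disease(
    lung_mask: np.ndarray,
    clip_mask: np.ndarray,
    kind: str,
    y: np.ndarray,
    split_y: float | None = None,
) -> dict[str, np.ndarray]:
    """Partition a rasterized lung into kept tissue, air and fluid.

    ``lung_mask`` and ``clip_mask`` are boolean rasters on a common grid with
    per-point y coordinates ``y`` (increasing toward the anterior wall).  The
    intersection with the clip keeps lung tissue.  The remainder becomes air
    (pneumothorax), fluid (effusion), or is split at ``split_y`` into air
    above and fluid below (hydropneumothorax).  The three parts partition the
    lung exactly.
    """
    kept = lung_mask & clip_mask
    rest = lung_mask & ~clip_mask
    zero = np.zeros_like(lung_mask)
    if kind == "none":
        return {"lung": lung_mask, "air": zero, "fluid": zero}
    if kind == "pneumothorax":
        return {"lung": kept, "air": rest, "fluid": zero}
    if kind == "effusion":
        return {"lung": kept, "air": zero, "fluid": rest}
    if kind == "hydro":
        if split_y is None:
            raise ValueError("hydropneumothorax requires a split level")
        return {"lung": kept, "air": rest & (y > split_y), "fluid": rest & (y <= split_y)}
    raise ValueError(f"unknown disease kind {kind!r}")


def _block_mean(a: np.ndarray, block: int) -> np.ndarray:
    n = a.shape[0] // block
    return a.reshape(n, block, n, block).mean(axis=(1, 3))


def rasterize(
    spec: PhantomSpec,
    grid: Grid,
    sensor: SensorGeometry | None = None,
    omega: float = OMEGA_DEFAULT,
) -> ComplexPermittivityMap:
    """Rasterize a phantom to complex permittivity on the fine grid.

    Paint order: air background, organs in spec order, disease partitions.
    A pixel's tissue is decided by its centre.  The sensor hardware
    (electrodes, insulation, screen region) is painted by the forward solver,
    not here; everything outside the thorax outline is air.  The reduced map
    is the block average of the fine map.
    """
    x, y = grid.fine_centers()
    R = grid.fov_radius
    cx, cy = grid.fov_center
    u = (x - cx) / R
    v = (y - cy) / R

    eps = np.full(
        (grid.fine_n, grid.fine_n),
        complex_permittivity(TISSUES["air"], omega),
        dtype=np.complex128,
    )
    lung_masks: dict[str, np.ndarray] = {}
    for organ in spec.organs:
        m = organ.contains(u, v)
        eps[m] = complex_permittivity(TISSUES[organ.tissue], omega)
        if spec.class_label < N_CLASSES:
            # identify lungs by position for later disease painting
            if organ.tissue.startswith("lung"):
                side = "left" if organ.center[0] < 0 else "right"
                lung_masks[side] = m

    for side in ("left", "right"):
        disease: DiseaseSpec = getattr(spec, f"disease_{side}")
        if disease.kind == "none":
            continue
        lung_mask = lung_masks[side]
        clip_mask = disease.clip.contains(u, v)
        parts = apply_disease(lung_mask, clip_mask, disease.kind, v, disease.split_y)
        eps[parts["air"]] = complex_permittivity(TISSUES["pneumothorax_air"], omega)
        eps[parts["fluid"]] = complex_permittivity(TISSUES["effusion_fluid"], omega)

    recon = _block_mean(eps, grid.block)
    return ComplexPermittivityMap(fine_map=eps, recon_map=recon, omega=omega)


def conductivity_image(eps_map: np.ndarray, omega: float = OMEGA_DEFAULT) -> np.ndarray:
    """Conductivity (S/m) from a complex relative permittivity image."""
    return -np.imag(eps_map) * omega * EPS0
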