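"""Synthetic rod-cell populations, measurements and rendered images.

The generator emulates the statistical structure of a length-heterogeneous
rod-shaped bacterial population in which the septum position depends on the
mother-cell length: short cells divide at mid-cell (fraction 1/2), cells
longer than ~5 µm near 1/3, and cells longer than ~8 µm near 1/4 of their
length.  A rare inert spherical-cell class (default 0.7% of the population)
and optional polar spherical appendages are included; neither ever carries
a division site.

Pole-to-septum distances are observed with additive Gaussian noise per
manual measurement; distances longer than one measurement span are emulated
as several summed sub-measurements, each with independent noise, so the
noise variance grows linearly with the number of segments.

Images are rendered as phase-contrast-like grayscale scenes: dark
spherocylinders on a bright background, with a Gaussian-profile width
constriction at the true division plane of dividing cells, blurred by a
Gaussian PSF and corrupted by additive Gaussian noise.  Each scene carries
an unblurred integer label mask and a ground-truth table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from rodfission.errors import ConfigurationError, PlacementError, ValidationError

# length classes, in order of increasing length
SHORT, MID, LONG = "short", "mid", "long"

DEFAULT_LENGTH_DISTRIBUTION = {
    "name": "lognormal",
    "mean": 2.0,          # µm, population mean of the lognormal body
    "sd": 0.6,            # µm, population SD of the lognormal body
    "tail_fraction": 0.08,  # probability of drawing from the long-cell tail
    "tail_low": 5.0,      # µm, uniform tail lower bound
    "tail_high": 12.0,    # µm, uniform tail upper bound
}


@dataclass(frozen=True)
class TrueCell:
    """Ground-truth description of one generated cell.

    ``division_fraction`` is the relative position of the true division
    plane in (0, 0.5] measured from the nearer pole; ``None`` for cells
    without a septum.  Spheres and appendaged poles never divide.
    """

    cell_id: str
    length: float       # µm, pole to pole
    width: float        # µm, diameter
    division_fraction: Optional[float] = None
    is_sphere: bool = False
    appendage: bool = False
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValidationError(f"cell {self.cell_id}: non-positive dimensions")
        if not self.is_sphere and self.length < self.width:
            raise ValidationError(f"cell {self.cell_id}: rod with length < width")
        f = self.division_fraction
        if f is not None and not (0.0 < f <= 0.5):
            raise ValidationError(
                f"cell {self.cell_id}: division_fraction {f} outside (0, 0.5]"
            )

    @property
    def length_class(self) -> str:
        return classify_length(self.length)


def classify_length(length: float, boundaries: Sequence[float] = (5.0, 8.0)) -> str:
    """Length-class interval rule: L <= b1 short, b1 < L <= b2 mid, L > b2 long."""
    b1, b2 = boundaries
    if length <= b1:
        return SHORT
    if length <= b2:
        return MID
    return LONG


@dataclass
class PopulationConfig:
    """Parameters of the synthetic population generator.

    ``class_fractions`` maps length class to the canonical division
    fraction placed in that class; ``dividing_probability`` is the
    per-class probability that a cell of the class shows a septum.
    ``segment_length`` is the longest distance covered by a single manual
    measurement: longer distances are measured as summed sub-measurements
    with independent noise.
    """

    n_cells: int = 300
    length_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    class_boundaries: tuple[float, float] = (5.0, 8.0)
    class_fractions: dict = field(
        default_factory=lambda: {SHORT: 0.5, MID: 1.0 / 3.0, LONG: 0.25}
    )
    dividing_probability: dict = field(
        default_factory=lambda: {SHORT: 0.3, MID: 0.6, LONG: 0.6}
    )
    sphere_rate: float = 0.007
    appendage_rate: float = 0.02
    noise_sd: float = 0.05       # µm per single measurement
    segment_length: float = 10.0  # µm
    width_mean: float = 0.5      # µm
    width_sd: float = 0.05       # µm
    sphere_diameter: float = 0.8  # µm
    replicate: str = "r1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sphere_rate", "appendage_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for cls, p in self.dividing_probability.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"dividing_probability[{cls}]={p} outside [0, 1]")
        b1, b2 = self.class_boundaries
        if not b1 < b2:
            raise ConfigurationError("class_boundaries must be strictly increasing")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.segment_length <= 0:
            raise ConfigurationError("segment_length must be > 0")


@dataclass
class ImageSpec:
    """Rendering parameters for synthetic phase-contrast-like scenes."""

    pixel_size: float = 0.029          # µm per pixel
    image_shape: tuple[int, int] = (512, 512)
    background_level: float = 0.8
    cell_level: float = 0.5            # subtracted inside cells (cells darker)
    psf_sigma: float = 1.0             # pixels
    noise_sigma: float = 0.01          # intensity units
    constriction_depth: float = 0.3    # relative width reduction in (0, 1)
    constriction_sigma: float = 0.15   # µm, Gaussian half-width of the dip
    appendage_diameter: float = 0.8    # µm
    max_placement_attempts: int = 2000

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if not (0.0 < self.constriction_depth < 1.0):
            raise ConfigurationError("constriction_depth must be in (0, 1)")


@dataclass
class RenderedScene:
    """A rendered grayscale image with its ground truth."""

    image: np.ndarray
    truth_mask: np.ndarray
    truth_table: pd.DataFrame
    pixel_size: float


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Natural-scale mean/SD -> lognormal (mu, sigma)."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _sample_length(rng: np.random.Generator, dist: dict) -> float:
    name = dist.get("name")
    if name == "lognormal":
        tail = dist.get("tail_fraction", 0.0)
        if tail and rng.random() < tail:
            return float(rng.uniform(dist["tail_low"], dist["tail_high"]))
        mu, sigma = _lognormal_params(dist["mean"], dist["sd"])
        return float(rng.lognormal(mu, sigma))
    if name == "uniform":
        return float(rng.uniform(dist["low"], dist["high"]))
    raise ConfigurationError(f"unknown length distribution: {name!r}")


def sample_population(config: PopulationConfig) -> list[TrueCell]:
    """Draw a ground-truth cell population.

    Each cell is a sphere with probability ``sphere_rate``; otherwise a rod
    whose length class (via ``class_boundaries``) sets its canonical
    division fraction and its probability of carrying a septum.  The draw
    is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cells: list[TrueCell] = []
    for i in range(config.n_cells):
        cid = f"cell{i:05d}"
        if rng.random() < config.sphere_rate:
            d = max(0.1, float(rng.normal(config.sphere_diameter, 0.05)))
            cells.append(
                TrueCell(cid, length=d, width=d, is_sphere=True,
                         replicate=config.replicate)
            )
            continue
        length = _sample_length(rng, config.length_distribution)
        width = float(
            np.clip(rng.normal(config.width_mean, config.width_sd), 0.2, None)
        )
        length = max(length, width)  # rods are at least as long as wide
        cls = classify_length(length, config.class_boundaries)
        appendage = rng.random() < config.appendage_rate
        fraction = None
        # appendaged poles never divide: the polar sphere is inert
        if not appendage and rng.random() < config.dividing_probability.get(cls, 0.0):
            fraction = float(config.class_fractions[cls])
        cells.append(
            TrueCell(cid, length=length, width=width, division_fraction=fraction,
                     appendage=appendage, replicate=config.replicate)
        )
    return cells


def observe_measurements(cells: Sequence[TrueCell], config: PopulationConfig):
    """Simulate manual pole-to-septum measurements for dividing cells.

    For a dividing cell of length L with true fraction f the two pole
    distances are d1 = f·L + e and d2 = (1-f)·L + e', with e drawn as the
    sum of k independent N(0, noise_sd²) errors when the distance spans
    k measurement segments (k = ceil(d / segment_length)).  Non-dividing
    cells emit no record.  Returns a list of MeasurementRecord.
    """
    from rodfission.divsite import MeasurementRecord

    rng = np.random.default_rng([1, config.seed])
    records = []
    for cell in cells:
        f = cell.division_fraction
        if f is None:
            continue
        dists = []
        for d_true in (f * cell.length, (1.0 - f) * cell.length):
            k = max(1, math.ceil(d_true / config.segment_length))
            noise = rng.normal(0.0, config.noise_sd, size=k).sum() if config.noise_sd else 0.0
            dists.append(max(1e-6, d_true + float(noise)))
        records.append(
            MeasurementRecord(cell_id=cell.cell_id, replicate=cell.replicate,
                              d1=dists[0], d2=dists[1])
        )
    return records


def _place_cells(
    cells: Sequence[TrueCell], spec: ImageSpec, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping poses (row, col, angle) in pixels."""
    nrow, ncol = spec.image_shape
    poses: list[tuple[float, float, float]] = []
    radii: list[float] = []
    for cell in cells:
        r_px = (cell.length / 2.0 + cell.width) / spec.pixel_size
        if cell.appendage:
            r_px += spec.appendage_diameter / spec.pixel_size
        placed = False
        for _ in range(spec.max_placement_attempts):
            row = rng.uniform(r_px, nrow - r_px) if nrow > 2 * r_px else nrow / 2.0
            col = rng.uniform(r_px, ncol - r_px) if ncol > 2 * r_px else ncol / 2.0
            angle = rng.uniform(0.0, math.pi)
            if nrow <= 2 * r_px or ncol <= 2 * r_px:
                break
            ok = all(
                math.hypot(row - pr, col - pc) > r_px + rr
                for (pr, pc, _), rr in zip(poses, radii)
            )
            if ok:
                placed = True
                break
        if not placed and (nrow > 2 * r_px and ncol > 2 * r_px and poses):
            raise PlacementError(
                f"could not place {len(cells)} cells in a "
                f"{nrow}x{ncol} image without overlap"
            )
        poses.append((row, col, angle))
        radii.append(r_px)
    return poses


def _cell_mask(
    cell: TrueCell, pose: tuple[float, float, float], spec: ImageSpec,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean mask of one cell (spherocylinder, constriction, appendage)."""
    px = spec.pixel_size
    row0, col0, angle = pose
    half_len = cell.length / 2.0 / px
    radius = cell.width / 2.0 / px

    pad = int(math.ceil(half_len + radius + spec.appendage_diameter / px)) + 2
    r_lo = max(0, int(row0) - pad)
    r_hi = min(shape[0], int(row0) + pad + 1)
    c_lo = max(0, int(col0) - pad)
    c_hi = min(shape[1], int(col0) + pad + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dy = rr - row0
    dx = cc - col0
    u = (math.cos(angle), math.sin(angle))
    t = dy * u[0] + dx * u[1]          # axial coordinate, px
    p = np.abs(-dy * u[1] + dx * u[0])  # perpendicular distance, px

    if cell.is_sphere:
        inside = dy**2 + dx**2 <= radius**2
    else:
        h = max(0.0, half_len - radius)  # half-length of the cylindrical part
        local_r = np.full_like(p, radius, dtype=float)
        if cell.division_fraction is not None:
            # Gaussian dip centred at the true division plane
            t0 = (cell.division_fraction - 0.5) * cell.length / px
            sig = spec.constriction_sigma / px
            dip = spec.constriction_depth * np.exp(-((t - t0) ** 2) / (2.0 * sig**2))
            local_r = radius * (1.0 - dip)
        cyl = (np.abs(t) <= h) & (p <= local_r)
        cap = (np.abs(t) > h) & (((np.abs(t) - h) ** 2 + p**2) <= radius**2)
        inside = cyl | cap
        if cell.appendage:
            r_app = spec.appendage_diameter / 2.0 / px
            # tangent disk at one pole, on the cell axis
            ay = row0 + (half_len + r_app) * u[0]
            ax = col0 + (half_len + r_app) * u[1]
            inside |= (rr - ay) ** 2 + (cc - ax) ** 2 <= r_app**2

    full = np.zeros(shape, dtype=bool)
    full[r_lo:r_hi, c_lo:c_hi] = inside
    return full


def render_population_image(
    cells: Sequence[TrueCell], spec: ImageSpec, seed: int = 0
) -> RenderedScene:
    """Render cells into a grayscale scene with ground-truth mask and table.

    Cells are drawn darker than the background (phase-contrast-like), the
    image is blurred with a Gaussian PSF and corrupted by additive Gaussian
    noise; the label mask is unblurred and label k corresponds to the k-th
    cell in the truth table.
    """
    shape = tuple(spec.image_shape)
    rng = np.random.default_rng([2, seed])
    poses = _place_cells(cells, spec, rng)

    mask = np.zeros(shape, dtype=np.uint16)
    rows = []
    for k, (cell, pose) in enumerate(zip(cells, poses), start=1):
        m = _cell_mask(cell, pose, spec, shape)
        mask[m] = k
        rows.append(
            {
                "label": k,
                "cell_id": cell.cell_id,
                "length_um": cell.length,
                "width_um": cell.width,
                "division_fraction": cell.division_fraction,
                "is_sphere": cell.is_sphere,
                "appendage": cell.appendage,
                "centroid_row": pose[0],
                "centroid_col": pose[1],
                "orientation_rad": pose[2],
            }
        )

    image = np.full(shape, spec.background_level, dtype=float)
    image[mask > 0] -= spec.cell_level
    if spec.psf_sigma > 0 and mask.any():
        image = ndimage.gaussian_filter(image, spec.psf_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)

    truth = pd.DataFrame(
        rows,
        columns=[
            "label", "cell_id", "length_um", "width_um", "division_fraction",
            "is_sphere", "appendage", "centroid_row", "centroid_col",
            "orientation_rad",
        ],
    )
    return RenderedScene(image=image, truth_mask=mask, truth_table=truth,
                         pixel_size=spec.pixel_size)


def make_reference_measurements(
    seed: int = 0,
    n_short: int = 200,
    n_mid: int = 70,
    n_long: int = 30,
    noise_sd: float = 0.05,
    replicate: str = "r1",
):
    """Dividing-cell dataset with the canonical 300-cell composition.

    Mimics a division-site study of 300 septate cells: ~200 short cells
    dividing at 1/2, ~70 mid-length cells (5-8 µm) at 1/3 and ~30 long
    cells (>8 µm) at 1/4, with 0.05 µm measurement noise per pole distance.
    Returns (cells, measurement records).
    """
    rng = np.random.default_rng([3, seed])
    cells: list[TrueCell] = []
    plan = [
        (n_short, 1.5, 5.0, 0.5),
        (n_mid, 5.2, 8.0, 1.0 / 3.0),
        (n_long, 8.2, 12.0, 0.25),
    ]
    i = 0
    for n, lo, hi, frac in plan:
        for _ in range(n):
            length = float(rng.uniform(lo, hi))
            cells.append(
                TrueCell(f"cell{i:05d}", length=length, width=0.5,
                         division_fraction=frac, replicate=replicate)
            )
            i += 1
    cfg = PopulationConfig(n_cells=len(cells), noise_sd=noise_sd, seed=seed,
                           replicate=replicate)
    return cells, observe_measurements(cells, cfg)


# ---------------------------------------------------------------------------
# I/O helpers


def measurements_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cell_id": r.cell_id, "replicate": r.replicate,
             "d1_um": r.d1, "d2_um": r.d2}
            for r in records
        ],
        columns=["cell_id", "replicate", "d1_um", "d2_um"],
    )


def write_measurements_csv(records, path) -> None:
    measurements_to_frame(records).to_csv(path, index=False)


def read_measurements_csv(path):
    from rodfission.divsite import MeasurementRecord

    df = pd.read_csv(path)
    return [
        MeasurementRecord(cell_id=str(r.cell_id), replicate=str(r.replicate),
                          d1=float(r.d1_um), d2=float(r.d2_um))
        for r in df.itertuples(index=False)
    ]


def write_truth_csv(cells: Sequence[TrueCell], path) -> None:
    pd.DataFrame(
        [
            {"cell_id": c.cell_id, "replicate": c.replicate,
             "length_um": c.length, "width_um": c.width,
             "division_fraction": c.division_fraction,
             "is_sphere": c.is_sphere, "appendage": c.appendage}
            for c in cells
        ]
    ).to_csv(path, index=False)


def write_scene(scene: RenderedScene, image_path, mask_path=None,
                truth_path=None) -> None:
    tifffile.imwrite(str(image_path), scene.image.astype(np.float32))
    if mask_path is not None:
        tifffile.imwrite(str(mask_path), scene.truth_mask.astype(np.uint16))
    if truth_path is not None:
        scene.truth_table.to_csv(truth_path, index=False)


def load_population_config(path) -> PopulationConfig:
    """Read a PopulationConfig from a YAML or JSON file (keys mirror fields)."""
    data = _load_config_dict(path)
    if "class_boundaries" in data:
        data["class_boundaries"] = tuple(data["class_boundaries"])
    return PopulationConfig(**data)


def load_image_spec(path) -> ImageSpec:
    data = _load_config_dict(path)
    if "image_shape" in data:
        data["image_shape"] = tuple(data["image_shape"])
    return ImageSpec(**data)


def _load_config_dict(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
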