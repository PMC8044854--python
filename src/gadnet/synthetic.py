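"""Seeded synthetic multi-channel micrographs with ground truth.

Emulates the statistical regime of two-class (GAD67-positive vs -negative)
neuron populations imaged in three fluorescence channels:

* channel 1 (GAD67-analog): within-cell mean intensity separated between the
  classes but with overlapping tails, so the marginal alone is informative yet
  imperfect;
* channels 2-3 (NeuN/Nissl analogs): per-class marginal intensity histograms
  are indistinguishable, but the two channels share a within-cell spatial
  texture whose *sign of correlation* carries the class — a joint two-channel
  signal invisible to any single-channel summary;
* a configurable fraction of cells is placed as touching pairs that fuse into
  one connected component of the binary mask;
* per-plane multiplicative gain drift across the z-stack plus additive noise.

Cells are soft-edged ellipses; area and circularity are class-independent.
Intensities are quantized to the 16-bit grid at generation time so that disk
round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from gadnet.preprocess import MicrographStack

CHANNEL_ORDER = ("gad67", "neun", "nissl")

MAX_INTENSITY = 65535.0


class OvercrowdedError(ValueError):
    """Requested cells could not be placed within the retry budget."""


@dataclass(frozen=True)
class ChannelModel:
    """Per-class distribution of within-cell mean intensity (arbitrary units)."""

    positive_mean: float
    positive_sd: float
    negative_mean: float
    negative_sd: float

    def draw(self, rng: np.random.Generator, positive: bool) -> float:
        if positive:
            return float(rng.normal(self.positive_mean, self.positive_sd))
        return float(rng.normal(self.negative_mean, self.negative_sd))


def default_channel_models() -> dict:
    return {
        # separated but overlapping marginals
        "gad67": ChannelModel(5200.0, 800.0, 2400.0, 650.0),
        # identical marginals for both classes; class lives in the joint texture
        "neun": ChannelModel(3000.0, 700.0, 3000.0, 700.0),
        "nissl": ChannelModel(3000.0, 700.0, 3000.0, 700.0),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic micrograph generator.

    ``joint_signal_strength`` scales the amplitude of the spatial texture that
    channels 2 and 3 share within each cell (correlated for positive cells,
    anti-correlated for negative cells); 0 removes the joint class signal
    entirely. ``joint_flip_fraction`` is the fraction of cells whose
    correlation sign is reversed for their class — per-cell heterogeneity that
    puts an irreducible error floor on classification from the joint signal
    alone. ``plane_drift`` is the (low, high) multiplicative gain applied
    linearly across the z-planes.
    """

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 200
    positive_fraction: float = 0.15
    channel_models: dict = field(default_factory=default_channel_models)
    joint_signal_strength: float = 1.0
    joint_texture_amplitude: float = 500.0
    joint_flip_fraction: float = 0.1
    touching_pair_fraction: float = 0.1
    cell_area_mean: float = 320.0
    cell_area_sd: float = 60.0
    noise_sd: float = 120.0
    background: float = 500.0
    plane_drift: tuple[float, float] = (0.9, 1.1)
    n_planes: int = 10
    seed: int = 0
    max_placement_retries: int = 200

    def validate(self) -> None:
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie strictly in (0, 1)")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if not (0.0 <= self.touching_pair_fraction <= 1.0):
            raise ValueError("touching_pair_fraction must lie in [0, 1]")
        if not (0.0 <= self.joint_flip_fraction < 0.5):
            raise ValueError("joint_flip_fraction must lie in [0, 0.5)")
        if set(self.channel_models) != set(CHANNEL_ORDER):
            raise ValueError(f"channel_models must define exactly {CHANNEL_ORDER}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["channel_models"] = {k: dataclasses.asdict(v) for k, v in self.channel_models.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SynthConfig":
        d = json.loads(text)
        d["channel_models"] = {k: ChannelModel(**v) for k, v in d["channel_models"].items()}
        d["image_size"] = tuple(d["image_size"])
        d["plane_drift"] = tuple(d["plane_drift"])
        return cls(**d)


@dataclass
class CellTruth:
    """Ground truth for one placed cell."""

    cell_id: int
    label: str  # "positive" | "negative"
    centroid: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]
    orientation: float  # radians
    bbox: tuple[int, int, int, int]  # (row, col, height, width), half-open
    patch: np.ndarray  # boolean support within bbox
    mask_label: int = 0  # connected-component label in the fused mask
    paired_with: int | None = None

    @property
    def area(self) -> int:
        return int(self.patch.sum())


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    labeled_mask: np.ndarray  # H x W int, 0 = background, fused pairs share a label

    @property
    def binary_mask(self) -> np.ndarray:
        return self.labeled_mask > 0

    def cell_mask(self, cell_id: int) -> np.ndarray:
        """Full-frame boolean support of one cell."""
        cell = self.cells[cell_id]
        out = np.zeros(self.labeled_mask.shape, dtype=bool)
        r, c, h, w = cell.bbox
        out[r : r + h, c : c + w] = cell.patch
        return out


def _ellipse_patch(a: float, b: float, theta: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Boolean ellipse support and soft interior profile on a tight grid.

    Returns (support, profile, half_extent). The profile is 1 in the core and
    falls off as a Gaussian near the rim (soft edge), 0 outside the support.
    """
    half = int(np.ceil(max(a, b))) + 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx * ct + yy * st) / a
    v = (-xx * st + yy * ct) / b
    rho = np.sqrt(u * u + v * v)
    support = rho <= 1.0
    profile = np.where(rho <= 0.7, 1.0, np.exp(-(((rho - 0.7) / 0.25) ** 2)))
    profile = np.where(support, profile, 0.0)
    return support, profile, half


def _radius_along(a: float, b: float, theta: float, phi: float) -> float:
    """Support radius of an ellipse (semi-axes a, b, orientation theta) in
    direction phi."""
    c, s = np.cos(phi - theta), np.sin(phi - theta)
    return float(a * b / np.sqrt((b * c) ** 2 + (a * s) ** 2))


def _place_cells(cfg: SynthConfig, rng: np.random.Generator) -> list[CellTruth]:
    """Place ellipses without unintended overlap; paired cells overlap slightly."""
    H, W = cfg.image_size
    n_paired = int(round(cfg.touching_pair_fraction * cfg.n_cells / 2.0)) * 2
    cells: list[CellTruth] = []
    centers: list[tuple[float, float, float]] = []  # (row, col, radius)

    def ellipse_params() -> tuple[float, float, float]:
        area = max(float(rng.normal(cfg.cell_area_mean, cfg.cell_area_sd)), 60.0)
        q = float(rng.uniform(0.65, 1.0))  # axis ratio -> unimodal circularity
        a = np.sqrt(area / (np.pi * q))
        return a, a * q, float(rng.uniform(0.0, np.pi))

    def fits(r: float, c: float, rad: float, ignore: int | None = None) -> bool:
        margin = rad + 2
        if not (margin <= r < H - margin and margin <= c < W - margin):
            return False
        for i, (rr, cc, rrad) in enumerate(centers):
            if i == ignore:
                continue
            if (rr - r) ** 2 + (cc - c) ** 2 < (rad + rrad + 3.0) ** 2:
                return False
        return True

    budget = cfg.max_placement_retries * cfg.n_cells
    tries = 0
    cid = 0
    while cid < cfg.n_cells:
        pair = cid < n_paired and cid + 1 < cfg.n_cells
        a1, b1, t1 = ellipse_params()
        rad1 = max(a1, b1)
        placed = False
        while tries < budget and not placed:
            tries += 1
            r1 = float(rng.uniform(0, H))
            c1 = float(rng.uniform(0, W))
            if not fits(r1, c1, rad1):
                continue
            if not pair:
                placed = True
                centers.append((r1, c1, rad1))
                cells.append(_make_cell(cid, r1, c1, a1, b1, t1, cfg))
                cid += 1
            else:
                a2, b2, t2 = ellipse_params()
                rad2 = max(a2, b2)
                # partner placed so the supports just fuse (slight overlap
                # along the contact axis) rather than merging deeply
                phi = float(rng.uniform(0, 2 * np.pi))
                d = 0.92 * (_radius_along(a1, b1, t1, phi) + _radius_along(a2, b2, t2, phi))
                r2, c2 = r1 + d * np.sin(phi), c1 + d * np.cos(phi)
                margin2 = rad2 + 2
                if not (margin2 <= r2 < H - margin2 and margin2 <= c2 < W - margin2):
                    continue
                ok = all(
                    (rr - r2) ** 2 + (cc - c2) ** 2 >= (rad2 + rrad + 3.0) ** 2
                    for (rr, cc, rrad) in centers
                )
                if not ok:
                    continue
                placed = True
                centers.append((r1, c1, rad1))
                centers.append((r2, c2, rad2))
                cells.append(_make_cell(cid, r1, c1, a1, b1, t1, cfg, paired_with=cid + 1))
                cells.append(_make_cell(cid + 1, r2, c2, a2, b2, t2, cfg, paired_with=cid))
                cid += 2
        if not placed:
            raise OvercrowdedError(
                f"could only place {cid} of {cfg.n_cells} cells in a "
                f"{H}x{W} field within the retry budget; reduce n_cells or "
                f"cell_area_mean, or enlarge image_size"
            )
    return cells


def _make_cell(
    cid: int,
    r: float,
    c: float,
    a: float,
    b: float,
    theta: float,
    cfg: SynthConfig,
    paired_with: int | None = None,
) -> CellTruth:
    H, W = cfg.image_size
    support, _, half = _ellipse_patch(a, b, theta)
    r0, c0 = int(round(r)) - half, int(round(c)) - half
    # clip patch to the frame
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1 = min(r0 + support.shape[0], H)
    cc1 = min(c0 + support.shape[1], W)
    patch = support[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
    return CellTruth(
        cell_id=cid,
        label="",
        centroid=(r, c),
        semi_axes=(a, b),
        orientation=theta,
        bbox=(rr0, cc0, rr1 - rr0, cc1 - cc0),
        patch=patch,
        paired_with=paired_with,
    )


def _draw_labels(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    labels = rng.random(n) < p
    # both classes must be represented for any downstream learning to be defined
    if not labels.any():
        labels[int(rng.integers(n))] = True
    elif labels.all():
        labels[int(rng.integers(n))] = False
    return labels


def generate_micrograph(cfg: SynthConfig) -> tuple[MicrographStack, GroundTruth, pd.DataFrame]:
    """Generate a seeded synthetic z-stack, its ground truth, and annotations.

    Returns a ``MicrographStack`` of shape (3 channels, n_planes, H, W), a
    ``GroundTruth`` with per-cell supports and the fused labeled mask, and an
    annotation table (cell_id, label, centroid_x, centroid_y, area_px2).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_size

    cells = _place_cells(cfg, rng)
    labels = _draw_labels(cfg.n_cells, cfg.positive_fraction, rng)
    for cell, pos in zip(cells, labels):
        cell.label = "positive" if pos else "negative"

    # noiseless scene per channel (single 2-D section shared by all planes)
    scene = np.zeros((len(CHANNEL_ORDER), H, W), dtype=np.float64)
    amp = cfg.joint_texture_amplitude * cfg.joint_signal_strength
    for cell in cells:
        pos = cell.label == "positive"
        a, b = cell.semi_axes
        support, profile, half = _ellipse_patch(a, b, cell.orientation)
        r0 = int(round(cell.centroid[0])) - half
        c0 = int(round(cell.centroid[1])) - half
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1 = min(r0 + support.shape[0], H)
        cc1 = min(c0 + support.shape[1], W)
        ps = np.s_[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        fs = np.s_[rr0:rr1, cc0:cc1]
        prof = profile[ps]
        sup = support[ps]

        # shared smooth zero-mean unit-SD texture carried by channels 2 and 3
        noise = rng.normal(size=prof.shape)
        texture = ndimage.gaussian_filter(noise, sigma=1.5)
        inside = texture[sup]
        sd = inside.std()
        if sd > 0:
            texture = (texture - inside.mean()) / sd
        sign = 1.0 if pos else -1.0
        if rng.random() < cfg.joint_flip_fraction:
            sign = -sign

        for k, ch in enumerate(CHANNEL_ORDER):
            mean = max(cfg.channel_models[ch].draw(rng, pos), 0.0)
            field2d = mean * prof
            if ch == "neun":
                field2d = field2d + amp * texture * prof
            elif ch == "nissl":
                field2d = field2d + sign * amp * texture * prof
            scene[k][fs] = np.where(sup, np.maximum(scene[k][fs], field2d), scene[k][fs])

    # fused mask (geometric union of supports) and per-cell mask labels
    binary = np.zeros((H, W), dtype=bool)
    for cell in cells:
        r, c, h, w = cell.bbox
        binary[r : r + h, c : c + w] |= cell.patch
    labeled, _ = ndimage.label(binary, structure=np.ones((3, 3), dtype=bool))
    for cell in cells:
        rr, cc = int(round(cell.centroid[0])), int(round(cell.centroid[1]))
        rr = min(max(rr, 0), H - 1)
        cc = min(max(cc, 0), W - 1)
        lab = int(labeled[rr, cc])
        if lab == 0:  # centroid rounded off-support; fall back to patch mode
            r, c, h, w = cell.bbox
            region = labeled[r : r + h, c : c + w][cell.patch]
            lab = int(np.bincount(region[region > 0]).argmax()) if (region > 0).any() else 0
        cell.mask_label = lab

    # z-stack: per-plane multiplicative gain drift + additive noise, 16-bit grid
    gains = np.linspace(cfg.plane_drift[0], cfg.plane_drift[1], cfg.n_planes)
    stack = np.empty((len(CHANNEL_ORDER), cfg.n_planes, H, W), dtype=np.float64)
    for k in range(len(CHANNEL_ORDER)):
        for p in range(cfg.n_planes):
            plane = gains[p] * (cfg.background + scene[k])
            plane = plane + rng.normal(0.0, cfg.noise_sd, size=(H, W))
            stack[k, p] = np.clip(np.round(plane), 0.0, MAX_INTENSITY)

    truth = GroundTruth(cells=cells, labeled_mask=labeled)
    annotations = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "label": [c.label for c in cells],
            "centroid_x": [c.centroid[1] for c in cells],
            "centroid_y": [c.centroid[0] for c in cells],
            "area_px2": [c.area for c in cells],
        }
    )
    micrograph = MicrographStack(intensities=stack, channel_names=CHANNEL_ORDER)
    return micrograph, truth, annotations


def write_fixture(
    stack: MicrographStack,
    truth: GroundTruth,
    annotations: pd.DataFrame,
    out_dir: str | Path,
    cfg: SynthConfig | None = None,
) -> dict[str, Path]:
    """Write a fixture directory: per-channel multi-page TIFFs, labeled-mask
    TIFF, annotation CSV and a JSON sidecar with the generating config.

    Returns the mapping of artifact name to path. Reading the directory back
    with :func:`read_fixture` round-trips the pixel data bit-exactly.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for k, ch in enumerate(stack.channel_names):
            p = out / f"{ch}.tif"
            tifffile.imwrite(p, stack.intensities[k].astype(np.uint16))
            paths[ch] = p
        mask_path = out / "mask.tif"
        tifffile.imwrite(mask_path, truth.labeled_mask.astype(np.uint16))
        paths["mask"] = mask_path
        csv_path = out / "annotations.csv"
        annotations.to_csv(csv_path, index=False)
        paths["annotations"] = csv_path
        if cfg is not None:
            cfg_path = out / "config.json"
            cfg_path.write_text(cfg.to_json())
            paths["config"] = cfg_path
        return paths
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out}: {exc}") from exc


def read_fixture(in_dir: str | Path) -> tuple[MicrographStack, np.ndarray, pd.DataFrame]:
    """Read a fixture directory written by :func:`write_fixture`.

    Returns (stack, labeled_mask, annotations); intensities come back as
    float64 on the 16-bit integer grid, matching the written values exactly.
    """
    src = Path(in_dir)
    channels = [ch for ch in CHANNEL_ORDER if (src / f"{ch}.tif").exists()]
    if not channels:
        raise FileNotFoundError(f"no channel TIFFs found under {src}")
    planes = [tifffile.imread(src / f"{ch}.tif").astype(np.float64) for ch in channels]
    planes = [p[None, :, :] if p.ndim == 2 else p for p in planes]
    stack = np.stack(planes)
    mask = tifffile.imread(src / "mask.tif").astype(np.int64)
    annotations = pd.read_csv(src / "annotations.csv")
    return MicrographStack(intensities=stack, channel_names=tuple(channels)), mask, annotations
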