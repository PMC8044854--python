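"""Assembly of labeled cell crops into balanced, fold-assigned, padded batches.

Conventions match the training protocol: 20% of *cells* (not crops) held out
for validation, the rest split into five cross-validation segments at the cell
level so that both z-plane crops of one physical cell always share a fold;
the majority class of a training set is randomly downsampled to a 1:1 ratio
and re-weighted by the downsampling factor so that effective class masses are
preserved and outputs stay probability-calibrated; batches of 8 are
zero-padded (bottom/right) to the largest height and width in the batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CHANNEL_ORDER: tuple[str, ...] = ("gad67", "neun", "nissl")

POSITIVE, NEGATIVE = "positive", "negative"
LABEL_TO_INDEX = {NEGATIVE: 0, POSITIVE: 1}


def all_channel_combos() -> list[tuple[str, ...]]:
    """The seven nonempty channel subsets, in canonical order."""
    combos = []
    for size in (3, 2, 1):
        if size == 3:
            combos.append(CHANNEL_ORDER)
        elif size == 2:
            combos.extend(
                [
                    ("neun", "nissl"),
                    ("gad67", "nissl"),
                    ("gad67", "neun"),
                ]
            )
        else:
            combos.extend([("gad67",), ("neun",), ("nissl",)])
    return combos


def canonical_combo(channels) -> tuple[str, ...]:
    subset = set(channels)
    unknown = subset - set(CHANNEL_ORDER)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    if not subset:
        raise ValueError("channel combo must be nonempty")
    return tuple(ch for ch in CHANNEL_ORDER if ch in subset)


@dataclass
class CellImage:
    """A variable-size multi-channel crop of one cell on one z-plane."""

    values: np.ndarray  # (n_channels, h, w) normalized floats
    channels: tuple[str, ...]
    cell_id: int
    label: str = "unknown"  # positive | negative | unknown
    plane_index: int = 0
    fold_id: str = "unassigned"  # validation | fold-1..fold-5 | unassigned
    sample_weight: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_channels, h, w)")
        if self.values.shape[0] != len(self.channels):
            raise ValueError("channel axis must match channels tuple")
        if self.values.shape[1] < 1 or self.values.shape[2] < 1:
            raise ValueError("crop height and width must be >= 1")

    @property
    def label_index(self) -> int:
        return LABEL_TO_INDEX[self.label]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class FoldPlan:
    """Cell-level split: a validation hold-out and five CV segments."""

    validation: frozenset[int]
    folds: tuple[frozenset[int], ...]
    seed: int

    def fold_of(self, cell_id: int) -> str:
        if cell_id in self.validation:
            return "validation"
        for i, f in enumerate(self.folds, start=1):
            if cell_id in f:
                return f"fold-{i}"
        return "unassigned"

    def training_cells(self, test_fold: int) -> frozenset[int]:
        """Cells of the four segments other than ``test_fold`` (1-based)."""
        out: set[int] = set()
        for i, f in enumerate(self.folds, start=1):
            if i != test_fold:
                out |= f
        return frozenset(out)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "validation": sorted(self.validation),
                "folds": [sorted(f) for f in self.folds],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(
            validation=frozenset(d["validation"]),
            folds=tuple(frozenset(f) for f in d["folds"]),
            seed=d["seed"],
        )


def make_fold_plan(cell_ids, seed: int, n_folds: int = 5, validation_fraction: float = 0.2) -> FoldPlan:
    """Assign cells to a 20% validation hold-out and five CV segments.

    Assignment is at the cell level: every crop of a cell inherits the cell's
    fold, so no cell can appear on both sides of a split. Deterministic for a
    given seed.
    """
    ids = sorted(set(int(c) for c in cell_ids))
    if len(ids) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} distinct cells to fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_val = int(np.floor(validation_fraction * len(ids)))
    validation = frozenset(shuffled[:n_val])
    rest = shuffled[n_val:]
    folds = tuple(frozenset(rest[i::n_folds]) for i in range(n_folds))
    return FoldPlan(validation=validation, folds=folds, seed=seed)


def assign_folds(images: list[CellImage], plan: FoldPlan) -> list[CellImage]:
    """Stamp each crop with its cell's fold id (in place; returns the list)."""
    for img in images:
        img.fold_id = plan.fold_of(img.cell_id)
    return images


def balance_downsample(
    images: list[CellImage], seed: int
) -> tuple[list[CellImage], dict[str, float], float]:
    """Downsample the majority class to 1:1 and upweight it by the factor.

    Sampling is without replacement and seeded. The retained majority crops get
    ``sample_weight = n_majority_before / n_majority_after`` so that weighted
    effective class counts equal the pre-balance counts; minority crops keep
    weight 1. Crop values are never modified. Returns (balanced list, class
    weight map, downsampling factor). Order of survivors follows the input.
    """
    by_class: dict[str, list[int]] = {POSITIVE: [], NEGATIVE: []}
    for i, img in enumerate(images):
        if img.label not in by_class:
            raise ValueError(f"unlabeled crop (cell {img.cell_id}) cannot be balanced")
        by_class[img.label].append(i)
    n_pos, n_neg = len(by_class[POSITIVE]), len(by_class[NEGATIVE])
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    if n_pos == n_neg:
        weights = {POSITIVE: 1.0, NEGATIVE: 1.0}
        out = [_reweighted(img, 1.0) for img in images]
        return out, weights, 1.0
    majority = NEGATIVE if n_neg > n_pos else POSITIVE
    minority = POSITIVE if majority == NEGATIVE else NEGATIVE
    n_min = min(n_pos, n_neg)
    rng = np.random.default_rng(seed)
    keep_majority = set(rng.choice(by_class[majority], size=n_min, replace=False).tolist())
    factor = len(by_class[majority]) / n_min
    weights = {minority: 1.0, majority: factor}
    out = []
    for i, img in enumerate(images):
        if img.label == minority:
            out.append(_reweighted(img, 1.0))
        elif i in keep_majority:
            out.append(_reweighted(img, factor))
    return out, weights, factor


def _reweighted(img: CellImage, weight: float) -> CellImage:
    return CellImage(
        values=img.values,
        channels=img.channels,
        cell_id=img.cell_id,
        label=img.label,
        plane_index=img.plane_index,
        fold_id=img.fold_id,
        sample_weight=weight,
    )


def select_channels(images: list[CellImage], combo) -> list[CellImage]:
    """Restrict crops to a channel subset, in canonical channel order."""
    combo = canonical_combo(combo)
    out = []
    for img in images:
        try:
            idx = [img.channels.index(ch) for ch in combo]
        except ValueError as exc:
            raise ValueError(f"crop for cell {img.cell_id} lacks a requested channel: {exc}")
        out.append(
            CellImage(
                values=img.values[idx],
                channels=combo,
                cell_id=img.cell_id,
                label=img.label,
                plane_index=img.plane_index,
                fold_id=img.fold_id,
                sample_weight=img.sample_weight,
            )
        )
    return out


@dataclass
class Batch:
    """A zero-padded batch: content anchored top-left, zeros bottom/right."""

    values: np.ndarray  # (n, c, H, W)
    labels: np.ndarray  # (n,) int, -1 for unknown
    weights: np.ndarray  # (n,)
    shapes: list[tuple[int, int]]  # original (h, w) per sample
    cell_ids: list[int]

    def __len__(self) -> int:
        return self.values.shape[0]

    def unpad(self, i: int) -> np.ndarray:
        h, w = self.shapes[i]
        return self.values[i, :, :h, :w]


def pad_stack(images: list[CellImage]) -> Batch:
    """Stack variable-size crops into one array padded to the batch max h, w."""
    n = len(images)
    c = images[0].values.shape[0]
    hmax = max(img.values.shape[1] for img in images)
    wmax = max(img.values.shape[2] for img in images)
    values = np.zeros((n, c, hmax, wmax), dtype=np.float32)
    shapes = []
    for i, img in enumerate(images):
        _, h, w = img.values.shape
        values[i, :, :h, :w] = img.values
        shapes.append((h, w))
    labels = np.array(
        [LABEL_TO_INDEX.get(img.label, -1) for img in images], dtype=np.int64
    )
    weights = np.array([img.sample_weight for img in images], dtype=np.float64)
    return Batch(
        values=values,
        labels=labels,
        weights=weights,
        shapes=shapes,
        cell_ids=[img.cell_id for img in images],
    )


def make_batches(images: list[CellImage], batch_size: int = 8, seed: int | None = None) -> list[Batch]:
    """Shuffle (when seeded) and group crops into zero-padded batches of 8.

    Each batch is padded to the largest height and width *within that batch*;
    the final partial batch is kept. Per-sample weights ride along.
    """
    if not images:
        raise ValueError("cannot batch an empty image list")
    order = list(range(len(images)))
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(images)).tolist()
    batches = []
    for start in range(0, len(order), batch_size):
        chunk = [images[i] for i in order[start : start + batch_size]]
        batches.append(pad_stack(chunk))
    return batches
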