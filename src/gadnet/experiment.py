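"""End-to-end experiment harness: preprocessing to channel-ablation tables.

`prepare_cell_images` turns a micrograph stack + mask + annotation table into
labeled multi-channel crops (one per cell per selected z-plane).
`run_experiment` trains both classifiers (FCN and PCA-SVM) for every requested
channel combination under 5-fold cross-validation — per fold: train on four
segments (majority class downsampled 1:1 and upweighted), checkpoint on the
held-out fold segment, score on the untouched 20% validation hold-out at its
natural class ratio — and `compare_models` runs the paired fold-wise t-tests
with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gadnet import preprocess as pp
from gadnet.dataset import (
    CHANNEL_ORDER,
    CellImage,
    FoldPlan,
    all_channel_combos,
    assign_folds,
    balance_downsample,
    canonical_combo,
    make_fold_plan,
    select_channels,
)
from gadnet.fcn import FcnClassifier, FcnSpec, TrainConfig
from gadnet.metrics import bonferroni_adjust, paired_t_test, score_predictions
from gadnet.svm import PcaSvmModel


def match_rois_to_annotations(rois, annotations: pd.DataFrame) -> dict[int, tuple[int, str]]:
    """Map each ROI to the annotated cell whose centroid lies inside it.

    When several centroids fall inside one ROI (an unsplit fused pair), the
    one closest to the ROI centroid wins. ROIs containing no centroid are
    left unmatched (excluded from the returned mapping).
    """
    out: dict[int, tuple[int, str]] = {}
    cy = annotations["centroid_y"].to_numpy(dtype=float)
    cx = annotations["centroid_x"].to_numpy(dtype=float)
    ids = annotations["cell_id"].to_numpy()
    labels = annotations["label"].to_numpy()
    for roi in rois:
        r0, c0 = roi.offset
        h, w = roi.patch.shape
        rr = np.round(cy).astype(int)
        cc = np.round(cx).astype(int)
        inside = (
            (rr >= r0) & (rr < r0 + h) & (cc >= c0) & (cc < c0 + w)
        )
        idx = np.where(inside)[0]
        idx = idx[[roi.patch[rr[i] - r0, cc[i] - c0] for i in idx]]
        if idx.size == 0:
            continue
        if idx.size > 1:
            ys, xs = np.nonzero(roi.patch)
            roi_centroid = (r0 + ys.mean(), c0 + xs.mean())
            d2 = (cy[idx] - roi_centroid[0]) ** 2 + (cx[idx] - roi_centroid[1]) ** 2
            idx = idx[[int(np.argmin(d2))]]
        i = int(idx[0])
        out[roi.roi_id] = (int(ids[i]), str(labels[i]))
    return out


def prepare_cell_images(
    stack: pp.MicrographStack,
    annotations: pd.DataFrame,
    external_mask: np.ndarray | None = None,
    cfg: pp.PreprocessConfig | None = None,
) -> tuple[list[CellImage], pd.DataFrame]:
    """Run the preprocessing pipeline and return labeled crops plus ROI stats.

    One segmentation mask (external, or the internal fallback on the
    detection channel of the first selected plane) defines the ROI set; the
    same ROIs are cropped from every selected plane so that the crops of one
    physical cell share its cell id. Crops carry all channels of the stack;
    select a combination later with :func:`gadnet.dataset.select_channels`.
    """
    cfg = cfg or pp.PreprocessConfig()
    plane_idx, _ = pp.extract_planes(stack, cfg)

    det = stack.plane(cfg.detection_channel, plane_idx[0])
    mask = pp.segment_cells(det, external_mask=external_mask, plane_index=plane_idx[0])
    rois = pp.split_rois_erosion_dilation(mask, cfg)
    rois = pp.filter_rois_by_area(rois, cfg)
    matches = match_rois_to_annotations(rois, annotations)

    images: list[CellImage] = []
    stats_rows = []
    for p in plane_idx:
        raw_planes = {ch: stack.plane(ch, p) for ch in stack.channel_names}
        norm_planes = {ch: pp.normalize_plane(raw_planes[ch]) for ch in stack.channel_names}
        matched = [roi for roi in rois if roi.roi_id in matches]
        labels = {roi.roi_id: matches[roi.roi_id][1] for roi in matched}
        crops = pp.crop_cell_images(
            matched, norm_planes, tuple(stack.channel_names), plane_index=p, labels=labels
        )
        for crop, roi in zip(crops, matched):
            crop.cell_id = matches[roi.roi_id][0]
        images.extend(crops)
        for roi in rois:
            row = pp.compute_roi_stats(roi, raw_planes)
            row.update(
                roi_id=roi.roi_id,
                plane=p,
                cell_id=matches.get(roi.roi_id, (-1, "unknown"))[0],
                label=matches.get(roi.roi_id, (-1, "unknown"))[1],
                split_lineage=roi.split_lineage,
            )
            stats_rows.append(row)
    return images, pd.DataFrame(stats_rows)


@dataclass(frozen=True)
class ExperimentConfig:
    """Channel-ablation experiment settings (desk-scale 50-epoch preset)."""

    combos: tuple = tuple(all_channel_combos())
    models: tuple[str, ...] = ("fcn", "pca-svm")
    epochs: int = 50
    optimizer: str = "adam"
    n_folds: int = 5
    seed: int = 0
    block_features: tuple[int, int, int] = (16, 32, 64)
    dropout_rate: float = 0.25


@dataclass
class MetricReport:
    """Scores of one (model, channel combination, fold) run."""

    model: str
    combo: tuple[str, ...]
    fold: int
    seed: int
    weighted_f1: float  # on the 20% hold-out, natural class ratio
    weighted_f1_test_segment: float  # on the fold's test segment
    precision_positive: float
    recall_positive: float
    f1_positive: float
    precision_negative: float
    recall_negative: float
    f1_negative: float
    n_positive: int
    n_negative: int
    checkpoint_epoch: int | None = None

    @property
    def combo_name(self) -> str:
        return "+".join(self.combo)


def _derived_seed(base: int, combo_index: int, model_index: int, fold: int) -> int:
    return (base * 9973 + combo_index * 211 + model_index * 37 + fold) % (2**31 - 1)


def _score(model, images: list[CellImage]) -> dict:
    truth = np.array([img.label_index for img in images])
    if isinstance(model, FcnClassifier):
        pred, _ = model.predict(images)
    else:
        pred = model.predict(images)
    return score_predictions(pred, truth)


def run_experiment(
    images: list[CellImage],
    plan: FoldPlan,
    cfg: ExperimentConfig | None = None,
) -> list[MetricReport]:
    """Train and score every (channel combination, model, fold) cell.

    Returns one MetricReport per combination x model x fold (e.g. 7 x 2 x 5 =
    70 reports at the defaults).
    """
    cfg = cfg or ExperimentConfig()
    labeled = [img for img in images if img.label in ("positive", "negative")]
    assign_folds(labeled, plan)
    validation = [img for img in labeled if img.fold_id == "validation"]
    if not validation:
        raise ValueError("fold plan assigns no validation cells")

    reports: list[MetricReport] = []
    for ci, combo in enumerate(cfg.combos):
        combo = canonical_combo(combo)
        combo_imgs = select_channels(labeled, combo)
        val = [img for img in combo_imgs if img.fold_id == "validation"]
        for mi, model_name in enumerate(cfg.models):
            for fold in range(1, cfg.n_folds + 1):
                seed = _derived_seed(cfg.seed, ci, mi, fold)
                train = [
                    img
                    for img in combo_imgs
                    if img.fold_id not in ("validation", f"fold-{fold}", "unassigned")
                ]
                test = [img for img in combo_imgs if img.fold_id == f"fold-{fold}"]
                if model_name == "fcn":
                    balanced, _, _ = balance_downsample(train, seed)
                    spec = FcnSpec(
                        n_input_channels=len(combo),
                        block_features=cfg.block_features,
                        dropout_rate=cfg.dropout_rate,
                    )
                    model = FcnClassifier(spec, seed=seed)
                    tc = TrainConfig(
                        optimizer=cfg.optimizer, epochs=cfg.epochs, seed=seed
                    )
                    history = model.fit(balanced, test, tc)
                    checkpoint = history.checkpoint_epoch
                elif model_name == "pca-svm":
                    model = PcaSvmModel().fit(train)
                    checkpoint = None
                else:
                    raise ValueError(f"unknown model {model_name!r}")
                hold = _score(model, val)
                seg = _score(model, test)
                reports.append(
                    MetricReport(
                        model="FCN" if model_name == "fcn" else "PCA-SVM",
                        combo=combo,
                        fold=fold,
                        seed=seed,
                        weighted_f1=hold["weighted_f1"],
                        weighted_f1_test_segment=seg["weighted_f1"],
                        precision_positive=hold["per_class"][1]["precision"],
                        recall_positive=hold["per_class"][1]["recall"],
                        f1_positive=hold["per_class"][1]["f1"],
                        precision_negative=hold["per_class"][0]["precision"],
                        recall_negative=hold["per_class"][0]["recall"],
                        f1_negative=hold["per_class"][0]["f1"],
                        n_positive=hold["n_by_class"][1],
                        n_negative=hold["n_by_class"][0],
                        checkpoint_epoch=checkpoint,
                    )
                )
    return reports


def reports_to_frame(reports: list[MetricReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.model,
                "combo": r.combo_name,
                "fold": r.fold,
                "seed": r.seed,
                "weighted_f1": r.weighted_f1,
                "weighted_f1_test_segment": r.weighted_f1_test_segment,
                "precision_positive": r.precision_positive,
                "recall_positive": r.recall_positive,
                "f1_positive": r.f1_positive,
                "precision_negative": r.precision_negative,
                "recall_negative": r.recall_negative,
                "f1_negative": r.f1_negative,
                "n_positive": r.n_positive,
                "n_negative": r.n_negative,
                "checkpoint_epoch": r.checkpoint_epoch,
            }
            for r in reports
        ]
    )


def summarize_reports(reports: list[MetricReport]) -> pd.DataFrame:
    """Mean +/- SD of hold-out weighted F1 per (combo, model) over folds."""
    df = reports_to_frame(reports)
    return (
        df.groupby(["combo", "model"])["weighted_f1"]
        .agg(mean="mean", sd="std", n_folds="count")
        .reset_index()
    )


def compare_models(
    reports: list[MetricReport], m: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired fold-wise t-test (FCN vs PCA-SVM) per combo, Bonferroni-adjusted.

    ``m`` defaults to the number of combos compared simultaneously.
    """
    df = reports_to_frame(reports)
    combos = list(dict.fromkeys(df["combo"]))
    rows = []
    raw_ps = []
    for combo in combos:
        sub = df[df["combo"] == combo].sort_values("fold")
        a = sub[sub["model"] == "FCN"]["weighted_f1"].to_numpy()
        b = sub[sub["model"] == "PCA-SVM"]["weighted_f1"].to_numpy()
        if len(a) == 0 or len(b) == 0 or len(a) != len(b):
            continue
        t, dof, p = paired_t_test(a, b)
        rows.append(
            {
                "combo": combo,
                "fcn_mean": a.mean(),
                "fcn_sd": a.std(ddof=1),
                "svm_mean": b.mean(),
                "svm_sd": b.std(ddof=1),
                "t": t,
                "df": dof,
                "p_raw": p,
            }
        )
        raw_ps.append(p)
    adjusted = bonferroni_adjust(raw_ps, m=m if m is not None else len(raw_ps))
    for row, p_adj in zip(rows, adjusted):
        row["p_bonferroni"] = p_adj
        row["significant"] = p_adj < alpha
    return pd.DataFrame(rows)
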