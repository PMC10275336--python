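"""Pixel-wise and fascicle-wise segmentation evaluation.

Pixel level: Dice similarity coefficient, precision/recall, and a
precision-recall sweep over binarization thresholds 0 to 1 in steps of 0.02
(51 points) with trapezoidal AUC and the Dice-optimal threshold.

Fascicle level: ground-truth and predicted masks are decomposed into
connected components (8-connected by default); every true/predicted pair
gets an intersection-over-union entry

    IoU[i, j] = |True_i ∩ Pred_j| / |True_i ∪ Pred_j|.

A true fascicle counts as detected (TP) when its row maximum reaches the
matching threshold ``t``; undetected rows are misses (FN) and unmatched
columns are additions (FP), summarized by the detection F1

    F1 = TP / (TP + (FP + FN) / 2).

Rows with more than one entry above an effective overlap threshold (0.1)
flag split fascicles; such columns flag merges. Errors are stratified by
fascicle cross-section area: large (>= 300,000 um^2), medium (>= 90,000),
small (>= 20,000) and tiny (< 20,000), with misses/splits sized by the true
fascicle and additions/merges by the predicted one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SizeClass",
    "MERGE_SPLIT_IOU",
    "dice_coefficient",
    "pixel_precision_recall",
    "pr_curve",
    "label_fascicles",
    "iou_matrix",
    "classify_fascicles",
    "f1_fascicle",
    "fascicle_area_um2",
    "size_class_of",
    "error_breakdown",
    "evaluate_stack",
]

MERGE_SPLIT_IOU = 0.1  # effective IoU above which overlaps count toward merges/splits

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


class SizeClass(Enum):
    """Fascicle size classes by cross-section area (um^2, half-open bins)."""

    LARGE = "large"  # [300,000, inf)
    MEDIUM = "medium"  # [90,000, 300,000)
    SMALL = "small"  # [20,000, 90,000)
    TINY = "tiny"  # (0, 20,000)

    @property
    def bounds(self) -> tuple[float, float]:
        return {
            SizeClass.LARGE: (300_000.0, np.inf),
            SizeClass.MEDIUM: (90_000.0, 300_000.0),
            SizeClass.SMALL: (20_000.0, 90_000.0),
            SizeClass.TINY: (0.0, 20_000.0),
        }[self]


def size_class_of(area_um2: float) -> SizeClass:
    """Classify a fascicle area (um^2) into its size class."""
    if area_um2 <= 0:
        raise ValueError(f"fascicle area must be positive, got {area_um2}")
    for cls in SizeClass:
        lo, hi = cls.bounds
        if lo <= area_um2 < hi:
            return cls
    raise AssertionError("size bins must partition (0, inf)")  # pragma: no cover


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice_coefficient(truth: np.ndarray, prediction: np.ndarray) -> float:
    """Dice similarity coefficient 2|T∩P| / (|T| + |P|); both empty -> 1."""
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(prediction, dtype=bool)
    _check_same_shape(t, p)
    nt, np_ = int(t.sum()), int(p.sum())
    if nt + np_ == 0:
        return 1.0
    return 2.0 * int((t & p).sum()) / (nt + np_)


def pixel_precision_recall(truth: np.ndarray, prediction: np.ndarray) -> tuple[float, float]:
    """Pixel precision |T∩P|/|P| and recall |T∩P|/|T|.

    An empty denominator yields 1 when the other set is also empty, else 0.
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(prediction, dtype=bool)
    _check_same_shape(t, p)
    inter = int((t & p).sum())
    nt, np_ = int(t.sum()), int(p.sum())
    precision = inter / np_ if np_ else (1.0 if nt == 0 else 0.0)
    recall = inter / nt if nt else (1.0 if np_ == 0 else 0.0)
    return float(precision), float(recall)


@dataclass
class PRCurve:
    """Precision-recall sweep over probability thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    dice: np.ndarray
    auc: float
    optimal_threshold: float

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "dice": self.dice.tolist(),
            "auc": self.auc,
            "optimal_threshold": self.optimal_threshold,
        }


def pr_curve(truth_stack: np.ndarray, probability_stack: np.ndarray, step: float = 0.02) -> PRCurve:
    """Sweep binarization thresholds 0..1 and aggregate pixel metrics.

    At each threshold the probability maps are binarized at ``p > thr`` and
    precision, recall and Dice are computed over all pixels of the stack
    pooled together. The AUC integrates precision over recall by the
    trapezoid rule; thresholds with empty predictions contribute the
    limiting precision 1 to the integral (their reported curve value keeps
    the 0-convention of :func:`pixel_precision_recall`). The optimal
    threshold maximizes Dice over the grid.
    """
    t = np.asarray(truth_stack, dtype=bool)
    p = np.asarray(probability_stack, dtype=np.float64)
    if t.size == 0:
        raise ValueError("empty stack")
    _check_same_shape(t, p)
    n_steps = int(round(1.0 / step)) + 1
    thresholds = np.linspace(0.0, 1.0, n_steps)
    precision = np.empty(n_steps)
    recall = np.empty(n_steps)
    dice = np.empty(n_steps)
    auc_precision = np.empty(n_steps)
    for k, thr in enumerate(thresholds):
        pred = p > thr
        precision[k], recall[k] = pixel_precision_recall(t, pred)
        dice[k] = dice_coefficient(t, pred)
        auc_precision[k] = precision[k] if pred.any() or not t.any() else 1.0
    order = np.argsort(recall, kind="stable")
    r_sorted = recall[order]
    p_sorted = auc_precision[order]
    if np.ptp(r_sorted) > 0:
        auc = float(np.trapezoid(p_sorted, r_sorted))
    else:  # degenerate single-recall curve: rectangle
        auc = float(r_sorted[0] * p_sorted.max())
    best = int(np.argmax(dice))
    return PRCurve(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        dice=dice,
        auc=auc,
        optimal_threshold=float(thresholds[best]),
    )


@dataclass
class LabelMap:
    """Connected-component labeling of a binary mask.

    Labels run 1..K in raster order of each component's first pixel;
    0 is background.
    """

    labels: np.ndarray
    n_labels: int
    connectivity: int = 8

    @property
    def shape(self):
        return self.labels.shape

    def areas_px(self) -> np.ndarray:
        """Pixel counts of labels 1..K."""
        return np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)[1:]


def label_fascicles(mask: np.ndarray, connectivity: int = 8) -> LabelMap:
    """Label connected components of a binary mask (8-connected by default)."""
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    struct = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    raw, n = ndimage.label(mask, structure=struct)
    if n > 1:
        # renumber in raster order of first pixel (scipy already scans in
        # raster order, but the contract should not rely on that detail)
        flat = raw.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        idx = np.nonzero(flat)[0]
        np.minimum.at(first, flat[idx], idx)
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=raw.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        raw = remap[raw]
    return LabelMap(labels=raw, n_labels=int(n), connectivity=connectivity)


def iou_matrix(truth: LabelMap, prediction: LabelMap) -> np.ndarray:
    """Pairwise IoU of every (true fascicle, predicted fascicle) pair.

    Returns an ``(n_true, n_pred)`` array with entries
    |True_i ∩ Pred_j| / |True_i ∪ Pred_j|.
    """
    if truth.shape != prediction.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {prediction.shape}")
    nt, npred = truth.n_labels, prediction.n_labels
    if nt == 0 or npred == 0:
        return np.zeros((nt, npred))
    tl = truth.labels.ravel()
    pl = prediction.labels.ravel()
    pair = tl.astype(np.int64) * (npred + 1) + pl
    counts = np.bincount(pair, minlength=(nt + 1) * (npred + 1)).reshape(nt + 1, npred + 1)
    inter = counts[1:, 1:].astype(np.float64)
    area_t = truth.areas_px().astype(np.float64)[:, None]
    area_p = prediction.areas_px().astype(np.float64)[None, :]
    union = area_t + area_p - inter
    return inter / union


@dataclass
class FascicleMatchResult:
    """Instance-level matching of one slice at threshold ``t``."""

    threshold_t: float
    tp: int
    fp: int
    fn: int
    split_true_ids: list[int] = field(default_factory=list)
    merged_pred_ids: list[int] = field(default_factory=list)
    row_max_iou: np.ndarray = field(default_factory=lambda: np.zeros(0))
    col_max_iou: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_true(self) -> int:
        return self.tp + self.fn

    def f1(self) -> float:
        return f1_fascicle(self.tp, self.fp, self.fn)


def classify_fascicles(
    matrix: np.ndarray, t: float, merge_split_iou: float = MERGE_SPLIT_IOU
) -> FascicleMatchResult:
    """Detection taxonomy from an IoU matrix at matching threshold ``t``.

    A true fascicle (row) is TP when its max IoU >= t, else FN; a predicted
    fascicle (column) with max IoU < t is FP. Rows/columns with more than one
    entry above ``merge_split_iou`` flag split/merged fascicles (1-based ids,
    matching the label maps).
    """
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold t must lie in (0, 1), got {t}")
    m = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    nt, npred = m.shape
    row_max = m.max(axis=1) if npred else np.zeros(nt)
    col_max = m.max(axis=0) if nt else np.zeros(npred)
    tp = int((row_max >= t).sum()) if nt else 0
    fn = nt - tp
    fp = int((col_max < t).sum()) if npred else 0
    split = [int(i) + 1 for i in range(nt) if (m[i] > merge_split_iou).sum() > 1]
    merged = [int(j) + 1 for j in range(npred) if (m[:, j] > merge_split_iou).sum() > 1]
    return FascicleMatchResult(
        threshold_t=float(t),
        tp=tp,
        fp=fp,
        fn=fn,
        split_true_ids=split,
        merged_pred_ids=merged,
        row_max_iou=row_max,
        col_max_iou=col_max,
    )


def f1_fascicle(tp: int, fp: int, fn: int) -> float:
    """Detection F1 = TP / (TP + (FP + FN)/2); all-zero counts -> 1."""
    if min(tp, fp, fn) < 0:
        raise ValueError(f"counts must be nonnegative, got tp={tp} fp={fp} fn={fn}")
    if tp + fp + fn == 0:
        warnings.warn("no fascicles in truth or prediction; F1 defined as 1", stacklevel=2)
        return 1.0
    return tp / (tp + 0.5 * (fp + fn))


def fascicle_area_um2(label: int, label_map: LabelMap, pixel_spacing: float) -> float:
    """Cross-section area of one labeled fascicle: pixel count x spacing^2."""
    if not (1 <= label <= label_map.n_labels):
        raise ValueError(f"label {label} not present (map has {label_map.n_labels} labels)")
    count = int((label_map.labels == label).sum())
    return count * pixel_spacing**2


_ERROR_KINDS = ("missed", "added", "split", "merged")


@dataclass
class FascicleErrorReport:
    """Size-stratified fascicle error taxonomy over a slice set.

    ``true_counts`` / ``pred_counts`` hold the number of true / predicted
    fascicles per size class; ``error_counts[kind][cls]`` the affected
    instances. Misses and splits are sized by (and counted against) the true
    fascicles of a class; additions and merges by the predicted ones.
    """

    true_counts: dict[str, int]
    pred_counts: dict[str, int]
    error_counts: dict[str, dict[str, int]]
    threshold_t: float

    def percentage(self, kind: str, cls: SizeClass | str) -> float:
        """Percent of the class's fascicles affected by ``kind`` (0 if none exist)."""
        cls = cls.value if isinstance(cls, SizeClass) else cls
        denom = self.true_counts[cls] if kind in ("missed", "split") else self.pred_counts[cls]
        if denom == 0:
            return 0.0
        return 100.0 * self.error_counts[kind][cls] / denom

    def totals(self) -> dict[str, float]:
        """Percent of all fascicles affected by each error type."""
        n_true = sum(self.true_counts.values())
        n_pred = sum(self.pred_counts.values())
        out = {}
        for kind in _ERROR_KINDS:
            denom = n_true if kind in ("missed", "split") else n_pred
            total = sum(self.error_counts[kind].values())
            out[kind] = 100.0 * total / denom if denom else 0.0
        return out

    def to_dict(self) -> dict:
        return {
            "threshold_t": self.threshold_t,
            "true_counts": self.true_counts,
            "pred_counts": self.pred_counts,
            "error_counts": self.error_counts,
            "percentages": {
                kind: {cls.value: self.percentage(kind, cls) for cls in SizeClass} for kind in _ERROR_KINDS
            },
            "totals": self.totals(),
        }


def error_breakdown(
    truth_maps: list[LabelMap],
    pred_maps: list[LabelMap],
    pixel_spacing: float,
    t: float = 0.4,
    merge_split_iou: float = MERGE_SPLIT_IOU,
) -> FascicleErrorReport:
    """Aggregate the size-stratified error taxonomy over paired label maps."""
    if len(truth_maps) != len(pred_maps):
        raise ValueError(f"slice count mismatch: {len(truth_maps)} truth vs {len(pred_maps)} prediction")
    classes = [c.value for c in SizeClass]
    true_counts = dict.fromkeys(classes, 0)
    pred_counts = dict.fromkeys(classes, 0)
    errors = {kind: dict.fromkeys(classes, 0) for kind in _ERROR_KINDS}
    for tm, pm in zip(truth_maps, pred_maps):
        m = iou_matrix(tm, pm)
        res = classify_fascicles(m, t, merge_split_iou)
        t_areas = tm.areas_px() * pixel_spacing**2
        p_areas = pm.areas_px() * pixel_spacing**2
        t_cls = [size_class_of(a).value for a in t_areas]
        p_cls = [size_class_of(a).value for a in p_areas]
        for c in t_cls:
            true_counts[c] += 1
        for c in p_cls:
            pred_counts[c] += 1
        for i in range(tm.n_labels):
            if res.row_max_iou[i] < t:
                errors["missed"][t_cls[i]] += 1
        for i in res.split_true_ids:
            errors["split"][t_cls[i - 1]] += 1
        for j in range(pm.n_labels):
            if res.col_max_iou[j] < t:
                errors["added"][p_cls[j]] += 1
        for j in res.merged_pred_ids:
            errors["merged"][p_cls[j - 1]] += 1
    return FascicleErrorReport(
        true_counts=true_counts, pred_counts=pred_counts, error_counts=errors, threshold_t=t
    )


def evaluate_stack(
    truth_stack: np.ndarray,
    prediction_stack: np.ndarray,
    t_values: list[float] = (0.4,),
    pixel_spacing: float = 10.0,
    connectivity: int = 8,
) -> dict:
    """Full per-stack evaluation report.

    ``truth_stack`` and ``prediction_stack`` are ``(n, H, W)`` binary mask
    arrays (binarize probability maps first). Returns a dict with per-slice
    Dice, pooled and per-slice-mean fascicle F1 at each ``t``, Dice summary
    statistics (mean, 5th and 95th percentile), and the size-stratified
    error report at the smallest ``t``.
    """
    truth = np.asarray(truth_stack, dtype=bool)
    pred = np.asarray(prediction_stack, dtype=bool)
    if truth.shape != pred.shape:
        raise ValueError(f"stack shape mismatch: {truth.shape} vs {pred.shape}")
    if truth.ndim != 3 or truth.shape[0] == 0:
        raise ValueError(f"expected a nonempty (n, H, W) stack, got shape {truth.shape}")
    t_values = sorted(float(t) for t in t_values)

    dice_per_slice = [dice_coefficient(truth[z], pred[z]) for z in range(truth.shape[0])]
    truth_maps = [label_fascicles(truth[z], connectivity) for z in range(truth.shape[0])]
    pred_maps = [label_fascicles(pred[z], connectivity) for z in range(truth.shape[0])]
    matrices = [iou_matrix(tm, pm) for tm, pm in zip(truth_maps, pred_maps)]

    f1_curve = {}
    f1_per_slice = {}
    for t in t_values:
        results = [classify_fascicles(m, t) for m in matrices]
        tp = sum(r.tp for r in results)
        fp = sum(r.fp for r in results)
        fn = sum(r.fn for r in results)
        f1_curve[t] = f1_fascicle(tp, fp, fn) if tp + fp + fn else 1.0
        f1_per_slice[t] = [r.f1() for r in results]

    report = error_breakdown(truth_maps, pred_maps, pixel_spacing, t=t_values[0])
    return {
        "dice_per_slice": dice_per_slice,
        "dice_mean": float(np.mean(dice_per_slice)),
        "dice_p5": float(np.percentile(dice_per_slice, 5)),
        "dice_p95": float(np.percentile(dice_per_slice, 95)),
        "f1_pooled": f1_curve,
        "f1_per_slice_mean": {t: float(np.mean(v)) for t, v in f1_per_slice.items()},
        "f1_per_slice": f1_per_slice,
        "error_report": report.to_dict(),
    }


def plot_report(report: dict, out_dir: str | Path, pr: "PRCurve | None" = None) -> list[Path]:
    """Write summary figures for an :func:`evaluate_stack` report.

    Produces a per-slice Dice histogram, the detection-F1-versus-threshold
    curve, a per-size-class error bar chart, and (if ``pr`` is given) the
    precision-recall sweep. Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(report["dice_per_slice"], bins=20, range=(0, 1), color="#4878a8")
    ax.axvline(report["dice_mean"], color="k", ls="--", label=f"mean {report['dice_mean']:.2f}")
    ax.set_xlabel("Dice coefficient")
    ax.set_ylabel("slices")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = out / "dice_histogram.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(4, 3))
    ts = sorted(report["f1_pooled"])
    ax.plot(ts, [report["f1_pooled"][t] for t in ts], "o-", color="#4878a8")
    ax.set_xlabel("IoU matching threshold t")
    ax.set_ylabel("fascicle F1")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    path = out / "f1_vs_threshold.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    pcts = report["error_report"]["percentages"]
    classes = [c.value for c in SizeClass]
    fig, ax = plt.subplots(figsize=(5, 3))
    width = 0.2
    for k, kind in enumerate(_ERROR_KINDS):
        ax.bar(np.arange(len(classes)) + (k - 1.5) * width, [pcts[kind][c] for c in classes],
               width, label=kind)
    ax.set_xticks(range(len(classes)), classes)
    ax.set_ylabel("% of class affected")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = out / "error_breakdown.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    if pr is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(pr.recall, pr.precision, "-", color="#4878a8")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title(f"AUC = {pr.auc:.3f}", fontsize=9)
        ax.set_xlim(0, 1.02)
        ax.set_ylim(0, 1.05)
        fig.tight_layout()
        path = out / "pr_curve.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def save_report(report: dict, out_dir: str | Path) -> None:
    """Serialize an :func:`evaluate_stack` report to CSV + JSON."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_slice = pd.DataFrame({"dice": report["dice_per_slice"]})
    for t, vals in report["f1_per_slice"].items():
        per_slice[f"f1_t{t:g}"] = vals
    per_slice.index.name = "slice"
    per_slice.to_csv(out / "per_slice.csv")
    summary = {k: v for k, v in report.items() if k not in ("dice_per_slice", "f1_per_slice")}
    summary["f1_pooled"] = {str(k): v for k, v in summary["f1_pooled"].items()}
    summary["f1_per_slice_mean"] = {str(k): v for k, v in summary["f1_per_slice_mean"].items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
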