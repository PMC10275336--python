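"""Brute-force pixel-set oracle for the segmentation metrics.

Everything here works on explicit Python sets of pixel coordinates and
scalar arithmetic — no numpy vectorization, no shared code with the package
implementation — so it can serve as an independent cross-check.
"""

from __future__ import annotations


def pixel_set(mask) -> set[tuple[int, int]]:
    rows = len(mask)
    cols = len(mask[0]) if rows else 0
    return {(r, c) for r in range(rows) for c in range(cols) if mask[r][c]}


def dice(truth, prediction) -> float:
    t, p = pixel_set(truth), pixel_set(prediction)
    if not t and not p:
        return 1.0
    return 2 * len(t & p) / (len(t) + len(p))


def precision_recall(truth, prediction) -> tuple[float, float]:
    t, p = pixel_set(truth), pixel_set(prediction)
    inter = len(t & p)
    precision = inter / len(p) if p else (1.0 if not t else 0.0)
    recall = inter / len(t) if t else (1.0 if not p else 0.0)
    return precision, recall


def components(mask, connectivity: int = 8) -> list[set[tuple[int, int]]]:
    """Connected components by BFS, returned in raster order of first pixel."""
    todo = pixel_set(mask)
    if connectivity == 8:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for start in sorted(todo):  # raster order
        if not any(start in c for c in comps):
            comp = {start}
            queue = [start]
            while queue:
                r, c = queue.pop()
                for dr, dc in neigh:
                    q = (r + dr, c + dc)
                    if q in todo and q not in comp:
                        comp.add(q)
                        queue.append(q)
            comps.append(comp)
    return comps


def iou_matrix(true_comps, pred_comps) -> list[list[float]]:
    return [
        [len(t & p) / len(t | p) if t | p else 0.0 for p in pred_comps]
        for t in true_comps
    ]


def classify(matrix, t: float, merge_split_iou: float = 0.1, n_pred: int | None = None) -> dict:
    n_true = len(matrix)
    if n_pred is None:
        n_pred = len(matrix[0]) if n_true else 0
    tp = sum(1 for row in matrix if row and max(row) >= t)
    fn = n_true - tp
    fp = sum(
        1
        for j in range(n_pred)
        if not matrix or max(matrix[i][j] for i in range(n_true)) < t
    ) if n_pred else 0
    split = [i + 1 for i, row in enumerate(matrix) if sum(1 for v in row if v > merge_split_iou) > 1]
    merged = [
        j + 1
        for j in range(n_pred)
        if sum(1 for i in range(n_true) if matrix[i][j] > merge_split_iou) > 1
    ]
    return {"tp": tp, "fp": fp, "fn": fn, "split": split, "merged": merged}


def f1(tp: int, fp: int, fn: int) -> float:
    if tp + fp + fn == 0:
        return 1.0
    return tp / (tp + 0.5 * (fp + fn))


def size_class(area_um2: float) -> str:
    if area_um2 >= 300_000:
        return "large"
    if area_um2 >= 90_000:
        return "medium"
    if area_um2 >= 20_000:
        return "small"
    return "tiny"
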