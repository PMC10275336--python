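"""Stack IO, the along-nerve down-sampling rule, and grouped LOOCV splits.

Images are 16-bit grayscale TIFFs (multi-page or one file per slice); masks
are 8-bit 0/255 TIFFs binarized at >0 on read. Per-slice files follow the
convention ``<nerve_id>_slice_<index:04d>.tif`` with mask layers suffixed
``_fascicle`` / ``_epineurium``; slice indices are 1-based in filenames and
0-based in memory.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from fasciseg.synthetic import NerveStack

__all__ = ["SplitPlan", "read_stack", "write_stack", "downsample_stack", "make_loocv_splits"]

_SLICE_RE = re.compile(r"^(?P<nerve>.+)_slice_(?P<index>\d+)(?P<layer>_fascicle|_epineurium)?\.tiff?$")


def write_stack(stack: NerveStack, out: str | Path, multipage: bool = True) -> Path:
    """Write a stack as TIFF plus a JSON sidecar of its metadata.

    With ``multipage=True`` (default) writes ``<nerve_id>.tif`` (16-bit image
    pages) and ``<nerve_id>_fascicle.tif`` / ``<nerve_id>_epineurium.tif``
    (8-bit 0/255 mask pages). Otherwise writes one file per slice under the
    naming convention. Returns the output directory.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    f8 = (stack.fascicle_masks.astype(np.uint8)) * 255
    e8 = (stack.epineurium_masks.astype(np.uint8)) * 255
    if multipage:
        kw = dict(photometric="minisblack")
        tifffile.imwrite(out / f"{stack.nerve_id}.tif", stack.images.astype(np.uint16), **kw)
        tifffile.imwrite(out / f"{stack.nerve_id}_fascicle.tif", f8, **kw)
        tifffile.imwrite(out / f"{stack.nerve_id}_epineurium.tif", e8, **kw)
    else:
        for z in range(stack.n_slices):
            idx = z + 1  # 1-based in filenames
            tifffile.imwrite(out / f"{stack.nerve_id}_slice_{idx:04d}.tif", stack.images[z].astype(np.uint16))
            tifffile.imwrite(out / f"{stack.nerve_id}_slice_{idx:04d}_fascicle.tif", f8[z])
            tifffile.imwrite(out / f"{stack.nerve_id}_slice_{idx:04d}_epineurium.tif", e8[z])
    sidecar = {
        "nerve_id": stack.nerve_id,
        "pixel_spacing": stack.pixel_spacing,
        "slice_spacing": stack.slice_spacing,
        "n_slices": stack.n_slices,
        "meta": stack.meta,
    }
    (out / f"{stack.nerve_id}_meta.json").write_text(json.dumps(sidecar, indent=2))
    return out


def _check_16bit(arr: np.ndarray, path: Path) -> None:
    if arr.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit image data, got dtype {arr.dtype}")


def read_stack(path: str | Path, nerve_id: str | None = None) -> NerveStack:
    """Read a stack written by :func:`write_stack` (either layout).

    ``path`` may be a directory (containing a multi-page TIFF set or
    per-slice files) or a multi-page image TIFF file whose mask companions
    sit alongside it. Masks are binarized at >0. Mixed slice dimensions or
    non-16-bit image data are rejected with the offending path and shapes.
    """
    path = Path(path)
    if path.is_file():
        return _read_multipage(path)
    if not path.is_dir():
        raise FileNotFoundError(f"{path}: no such file or directory")

    multi = sorted(
        p for p in path.glob("*.tif*")
        if not _SLICE_RE.match(p.name) and not p.stem.endswith(("_fascicle", "_epineurium"))
    )
    if nerve_id is not None:
        multi = [p for p in multi if p.stem == nerve_id]
    if multi:
        if len(multi) > 1:
            raise ValueError(f"{path}: multiple candidate stacks {sorted(p.name for p in multi)}; pass nerve_id")
        return _read_multipage(multi[0])

    # per-slice layout
    entries: dict[int, dict[str, Path]] = {}
    nerve = nerve_id
    for p in sorted(path.glob("*.tif*")):
        m = _SLICE_RE.match(p.name)
        if not m:
            continue
        if nerve_id is not None and m.group("nerve") != nerve_id:
            continue
        nerve = nerve or m.group("nerve")
        if m.group("nerve") != nerve:
            raise ValueError(f"{path}: slices from multiple nerves ({nerve!r}, {m.group('nerve')!r}); pass nerve_id")
        layer = (m.group("layer") or "_image").lstrip("_")
        entries.setdefault(int(m.group("index")), {})[layer] = p
    if not entries:
        raise FileNotFoundError(f"{path}: no TIFF slices found")

    images, fascs, epis, shapes = [], [], [], {}
    for idx in sorted(entries):
        rec = entries[idx]
        if "image" not in rec:
            raise ValueError(f"{path}: slice {idx} has masks but no image file")
        img = tifffile.imread(rec["image"])
        _check_16bit(img, rec["image"])
        shapes[rec["image"].name] = img.shape
        images.append(img)
        fascs.append(tifffile.imread(rec["fascicle"]) > 0 if "fascicle" in rec else np.zeros(img.shape, bool))
        epis.append(tifffile.imread(rec["epineurium"]) > 0 if "epineurium" in rec else np.zeros(img.shape, bool))
    uniq = set(shapes.values())
    if len(uniq) > 1:
        detail = ", ".join(f"{n}: {s}" for n, s in shapes.items() if s in uniq)
        raise ValueError(f"{path}: mixed slice dimensions {sorted(uniq)} ({detail})")

    meta = _read_sidecar(path, nerve)
    return NerveStack(
        nerve_id=nerve,
        images=np.stack(images),
        fascicle_masks=np.stack(fascs),
        epineurium_masks=np.stack(epis),
        pixel_spacing=meta.get("pixel_spacing", 10.0),
        slice_spacing=meta.get("slice_spacing", 100.0),
        meta=meta.get("meta", {}),
    )


def _read_sidecar(dirpath: Path, nerve_id: str | None) -> dict:
    for cand in ([dirpath / f"{nerve_id}_meta.json"] if nerve_id else []) + sorted(dirpath.glob("*_meta.json")):
        if cand.exists():
            return json.loads(cand.read_text())
    return {}


def _read_multipage(img_path: Path) -> NerveStack:
    images = tifffile.imread(img_path)
    _check_16bit(images, img_path)
    if images.ndim == 2:
        images = images[None]
    nerve_id = img_path.stem
    parent = img_path.parent

    def read_mask(suffix: str) -> np.ndarray:
        p = parent / f"{nerve_id}{suffix}{img_path.suffix}"
        if p.exists():
            m = tifffile.imread(p)
            if m.ndim == 2:
                m = m[None]
            if m.shape != images.shape:
                raise ValueError(f"{p}: mask shape {m.shape} does not match image shape {images.shape}")
            return m > 0
        return np.zeros(images.shape, bool)

    meta = _read_sidecar(parent, nerve_id)
    return NerveStack(
        nerve_id=nerve_id,
        images=images,
        fascicle_masks=read_mask("_fascicle"),
        epineurium_masks=read_mask("_epineurium"),
        pixel_spacing=meta.get("pixel_spacing", 10.0),
        slice_spacing=meta.get("slice_spacing", 100.0),
        meta=meta.get("meta", {}),
    )


def downsample_stack(stack: NerveStack, factor: int = 10) -> NerveStack:
    """Down-sample along the nerve axis by copying every ``factor``-th slice.

    Keeps the slices at 1-based positions ``factor, 2*factor, ...`` so a
    512-slice volume at the default factor 10 yields 51 slices. Masks are
    down-sampled identically; slice spacing scales by ``factor``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    idx = np.arange(factor - 1, stack.n_slices, factor)
    if len(idx) == 0:
        warnings.warn(
            f"down-sampling a {stack.n_slices}-slice stack by {factor} leaves 0 slices",
            stacklevel=2,
        )
        empty = np.empty((0,) + stack.shape, dtype=stack.images.dtype)
        return NerveStack(
            nerve_id=stack.nerve_id,
            images=empty,
            fascicle_masks=empty.astype(bool),
            epineurium_masks=empty.astype(bool),
            pixel_spacing=stack.pixel_spacing,
            slice_spacing=stack.slice_spacing * factor,
            meta=dict(stack.meta),
        )
    return NerveStack(
        nerve_id=stack.nerve_id,
        images=stack.images[idx].copy(),
        fascicle_masks=stack.fascicle_masks[idx].copy(),
        epineurium_masks=stack.epineurium_masks[idx].copy(),
        pixel_spacing=stack.pixel_spacing,
        slice_spacing=stack.slice_spacing * factor,
        meta=dict(stack.meta),
    )


@dataclass
class SplitPlan:
    """Leave-one-nerve-out cross-validation plan.

    Each fold holds out one whole nerve as validation; all slices of a nerve
    stay on the same side of every split. An optional test nerve appears in
    no fold.
    """

    folds: list[tuple[list[str], str]] = field(default_factory=list)
    test_nerve_id: str | None = None

    def validate(self) -> None:
        seen_val = [v for _, v in self.folds]
        if len(set(seen_val)) != len(seen_val):
            raise ValueError(f"validation nerves repeat across folds: {seen_val}")
        for train, val in self.folds:
            if val in train:
                raise ValueError(f"nerve {val!r} appears in both train and validation of one fold")
            if self.test_nerve_id is not None and (self.test_nerve_id in train or self.test_nerve_id == val):
                raise ValueError(f"test nerve {self.test_nerve_id!r} appears inside a fold")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"folds": [{"train": t, "validation": v} for t, v in self.folds], "test": self.test_nerve_id},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "SplitPlan":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        plan = cls(folds=[(f["train"], f["validation"]) for f in d["folds"]], test_nerve_id=d.get("test"))
        plan.validate()
        return plan


def make_loocv_splits(nerve_ids: list[str], test_id: str | None = None) -> SplitPlan:
    """Build leave-one-nerve-out folds over ``nerve_ids``.

    Fold *k* trains on every non-test nerve except nerve *k* and validates on
    nerve *k*. ``test_id``, if given, is removed from ``nerve_ids`` first and
    appears in no fold.
    """
    ids = list(nerve_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate nerve ids: {dupes}")
    if test_id is not None and test_id in ids:
        ids = [x for x in ids if x != test_id]
    cv_ids = ids
    if len(cv_ids) < 2:
        raise ValueError(f"need at least 2 non-test nerves for leave-one-out, got {len(cv_ids)}")
    folds = [([t for t in cv_ids if t != v], v) for v in cv_ids]
    plan = SplitPlan(folds=folds, test_nerve_id=test_id)
    plan.validate()
    return plan
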