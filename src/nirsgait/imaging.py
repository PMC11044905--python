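"""Encode hemoglobin task epochs as 3 x 224 x 224 images.

Each accepted epoch becomes a 3-channel image: channel 0 the HbO2 rows
(voxel 1 at the top), channel 1 the Hb rows, channel 2 the oxygen index
HbO2 - Hb (or HbO2 + Hb in the ablation variant). The time axis is zero
padded or truncated to 224 columns by default, which deliberately preserves
task completion time and pace as visible structure (the padding boundary),
and the 16 voxel rows are expanded to 224 either by interpolation
(bilinear/bicubic, with or without corner alignment) or by exact 14x
interleave repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .preprocess import TaskEpoch

TARGET = (224, 224)
MAX_MISSING = 3  # screening threshold on missing voxel locations
ROW_MODES = ("bilinear", "bicubic", "interleave")
TIME_MODES = ("pad_truncate", "interpolate")
CHANNEL_NAMES = ("hbo2", "hb", "third")
ABLATION_TARGETS = ("hbo2", "hb", "third", "left", "right")


@dataclass(frozen=True)
class ResizeConfig:
    """One of the five image-processing configurations.

    row_mode x corner alignment gives bilinear/bicubic aligned/unaligned;
    ``interleave`` duplicates each of the 16 rows exactly 14 times (alignment
    does not apply). ``time_mode`` is pad/truncate by default, interpolation
    as the ablation variant.
    """

    row_mode: str = "bilinear"
    align_corners: bool = True
    time_mode: str = "pad_truncate"
    target: tuple[int, int] = TARGET

    def __post_init__(self) -> None:
        if self.row_mode not in ROW_MODES:
            raise ValueError(f"row_mode must be one of {ROW_MODES}")
        if self.time_mode not in TIME_MODES:
            raise ValueError(f"time_mode must be one of {TIME_MODES}")
        if self.row_mode == "interleave" and self.target[0] % 16 != 0:
            raise ValueError("interleave requires the row target to be a multiple of 16")

    @property
    def name(self) -> str:
        if self.row_mode == "interleave":
            base = "interleave"
        else:
            base = f"{self.row_mode}_{'aligned' if self.align_corners else 'unaligned'}"
        return base if self.time_mode == "pad_truncate" else f"{base}_{self.time_mode}"


#: The five row-resize configurations swept in the ablation study.
SWEEP_CONFIGS = (
    ResizeConfig("bilinear", True),
    ResizeConfig("bilinear", False),
    ResizeConfig("bicubic", True),
    ResizeConfig("bicubic", False),
    ResizeConfig("interleave"),
)


@dataclass
class SampleImage:
    pixels: np.ndarray  # [3, 224, 224] float32
    label: str
    third_kind: str = "diff"  # "diff" (HbO2 - Hb) | "sum"
    metadata: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (3, *TARGET):
            raise ValueError(f"image must be 3x{TARGET[0]}x{TARGET[1]}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite values")


def screen_sample(epoch: TaskEpoch) -> bool:
    """Accept iff the epoch has no more than 3 missing voxel locations."""
    return len(epoch.missing_voxels) <= MAX_MISSING


def impute_missing_rows(epoch: TaskEpoch, n_voxels: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct full [16, L] arrays by interpolating over voxel index.

    Missing rows are filled by linear interpolation between the nearest
    valid rows above and below (per chromophore, per time sample); at the
    edges the nearest valid row is extended. Valid rows pass through
    untouched. Raises when the epoch fails screening.
    """
    if not screen_sample(epoch):
        raise ValueError(
            f"cannot impute a rejected sample ({len(epoch.missing_voxels)} missing voxels)"
        )
    idx = np.asarray([v - 1 for v in epoch.voxels], dtype=float)
    want = np.clip(np.arange(n_voxels, dtype=float), idx.min(), idx.max())
    out = []
    for data in (epoch.hbo2, epoch.hb):
        if len(idx) == n_voxels:
            out.append(data.astype(float, copy=True))
            continue
        # vectorized linear interpolation over the voxel axis
        pos = np.interp(want, idx, np.arange(len(idx), dtype=float))
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, len(idx) - 1)
        w = (pos - lo)[:, None]
        out.append((1.0 - w) * data[lo] + w * data[hi])
    return out[0], out[1]


def build_channel_stack(
    hbo2: np.ndarray, hb: np.ndarray, third: str = "diff"
) -> np.ndarray:
    """Stack [3, 16, L]: (HbO2, Hb, HbO2 -/+ Hb)."""
    hbo2 = np.asarray(hbo2, dtype=float)
    hb = np.asarray(hb, dtype=float)
    if hbo2.shape != hb.shape:
        raise ValueError("HbO2 and Hb arrays must have identical shapes")
    if third == "diff":
        extra = hbo2 - hb
    elif third == "sum":
        extra = hbo2 + hb
    else:
        raise ValueError("third channel kind must be 'diff' or 'sum'")
    return np.stack([hbo2, hb, extra])


def conform_time_axis(stack: np.ndarray, cfg: ResizeConfig) -> np.ndarray:
    """Bring the time axis to 224 columns.

    pad_truncate: keep the first min(L, 224) columns, zero-fill the rest
    (completion time stays encoded as the padding boundary). interpolate:
    linearly resample the full length onto 224 columns.
    """
    stack = np.asarray(stack, dtype=float)
    n_t = cfg.target[1]
    length = stack.shape[-1]
    if cfg.time_mode == "pad_truncate":
        out = np.zeros((*stack.shape[:-1], n_t))
        keep = min(length, n_t)
        out[..., :keep] = stack[..., :keep]
        return out
    old = np.arange(length, dtype=float)
    new = np.linspace(0.0, length - 1.0, n_t)
    flat = stack.reshape(-1, length)
    res = np.empty((flat.shape[0], n_t))
    for i, row in enumerate(flat):
        res[i] = np.interp(new, old, row)
    return res.reshape(*stack.shape[:-1], n_t)


def _row_coords(n_in: int, n_out: int, align_corners: bool) -> np.ndarray:
    if align_corners:
        return np.linspace(0.0, n_in - 1.0, n_out)
    coords = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    return np.clip(coords, 0.0, n_in - 1.0)


def resize_rows(stack: np.ndarray, cfg: ResizeConfig) -> np.ndarray:
    """Expand the 16 voxel rows to 224.

    interleave: bit-exact duplication, row r of the output is input row
    r // 14 (visible borders between voxels). bilinear/bicubic: separable
    interpolation along the row axis; with corner alignment the first and
    last input rows map exactly onto the first and last output rows.
    """
    stack = np.asarray(stack, dtype=float)
    n_rows, n_out = stack.shape[-2], cfg.target[0]
    if cfg.row_mode == "interleave":
        if n_rows != 16:
            raise ValueError("interleave repetition requires exactly 16 voxel rows")
        return np.repeat(stack, n_out // n_rows, axis=-2)
    coords = _row_coords(n_rows, n_out, cfg.align_corners)
    order = 1 if cfg.row_mode == "bilinear" else 3
    flat = stack.reshape(-1, n_rows, stack.shape[-1])
    out = np.empty((flat.shape[0], n_out, stack.shape[-1]))
    cols = np.arange(stack.shape[-1], dtype=float)
    grid = np.meshgrid(coords, cols, indexing="ij")
    for i, plane in enumerate(flat):
        out[i] = map_coordinates(plane, grid, order=order, mode="nearest")
    return out.reshape(*stack.shape[:-2], n_out, stack.shape[-1])


def ablate(x: np.ndarray, drop: str) -> np.ndarray:
    """Zero out one channel or one hemisphere, preserving shape.

    ``drop`` is one of ``hbo2``/``hb``/``third`` (channel index 0/1/2) or
    ``left``/``right`` (voxel rows 1-8 / 9-16, 1-based). Hemisphere ablation
    expects the 16-row stack (applied before row resizing so interpolation
    cannot leak across hemispheres) but also accepts 224-row images, zeroing
    the corresponding half. Idempotent.
    """
    x = np.asarray(x, dtype=float).copy()
    if drop in CHANNEL_NAMES:
        x[CHANNEL_NAMES.index(drop)] = 0.0
        return x
    if drop in ("left", "right"):
        n_rows = x.shape[-2]
        half = n_rows // 2
        sl = slice(0, half) if drop == "left" else slice(half, n_rows)
        x[..., sl, :] = 0.0
        return x
    raise ValueError(f"unknown ablation target {drop!r}; use one of {ABLATION_TARGETS}")


def make_image(
    epoch: TaskEpoch,
    cfg: ResizeConfig | None = None,
    third: str = "diff",
    drop: str | None = None,
) -> SampleImage | None:
    """screen -> impute -> stack -> conform time -> resize rows.

    Returns ``None`` for epochs rejected by screening. ``drop`` applies the
    requested ablation at the appropriate stage (hemispheres before row
    resizing, channels on the final image).
    """
    cfg = cfg or ResizeConfig()
    if not screen_sample(epoch):
        return None
    hbo2, hb = impute_missing_rows(epoch)
    stack = build_channel_stack(hbo2, hb, third)
    if drop in ("left", "right"):
        stack = ablate(stack, drop)
    stack = conform_time_axis(stack, cfg)
    img = resize_rows(stack, cfg)
    if drop in CHANNEL_NAMES:
        img = ablate(img, drop)
    return SampleImage(
        pixels=img.astype(np.float32),
        label=epoch.condition,
        third_kind=third,
        metadata=dict(epoch.metadata),
        provenance={
            "resize": cfg.name,
            "third": third,
            "drop": drop,
            "duration": epoch.duration,
            "n_missing": len(epoch.missing_voxels),
        },
    )


def make_dataset(
    epochs: list[TaskEpoch],
    cfg: ResizeConfig | None = None,
    third: str = "diff",
    drop: str | None = None,
) -> tuple[np.ndarray, np.ndarray, list, int]:
    """Encode a list of epochs; returns (images [N,3,224,224], labels, meta, n_rejected)."""
    images, labels, meta = [], [], []
    rejected = 0
    for ep in epochs:
        img = make_image(ep, cfg, third, drop)
        if img is None:
            rejected += 1
            continue
        images.append(img.pixels)
        labels.append(img.label)
        meta.append(img.metadata)
    x = np.stack(images).astype(np.float32) if images else np.empty((0, 3, *TARGET), np.float32)
    return x, np.asarray(labels), meta, rejected
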