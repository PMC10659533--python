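"""Block-occlusion interpretability maps.

Blocks of the (already normalized) input volumes are systematically set to
0 and the drop in the correct-class progression probability is recorded:
for an early-AD subject the importance of a block is
``p(progression | intact) - p(progression | block zeroed)``, for a non-AD
subject the same difference of ``1 - p``.  Tiling the whole grid gives a
block-resolution importance map; averaging over subjects and fold models
gives the cohort-level atrophy pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, DataError
from .multitask_cnn import DeepDataset

__all__ = [
    "OcclusionConfig",
    "OcclusionHeatmap",
    "occlude_block",
    "occlusion_map",
    "average_heatmaps",
    "heatmap_to_nifti",
]


@dataclass(frozen=True)
class OcclusionConfig:
    block_size: tuple[int, int, int] = (4, 4, 4)
    stride: tuple[int, int, int] | None = None  # default: non-overlapping tiling
    channel: str = "both"  # "mri" | "jd" | "both"
    #: False (default): drop of the correct-class probability.
    #: True: signed change of p_progression regardless of the label.
    signed_delta: bool = False

    def resolved_stride(self) -> tuple[int, int, int]:
        return self.stride if self.stride is not None else self.block_size

    def validate(self, grid_shape: Sequence[int]) -> None:
        if self.channel not in ("mri", "jd", "both"):
            raise ConfigurationError(f"channel must be mri/jd/both, got {self.channel!r}")
        for b, s, n in zip(self.block_size, self.resolved_stride(), grid_shape):
            if b < 1 or b > n:
                raise ConfigurationError(
                    f"block size {self.block_size} incompatible with grid {tuple(grid_shape)}")
            if s < 1:
                raise ConfigurationError("stride must be >= 1")


@dataclass
class OcclusionHeatmap:
    importance: np.ndarray  # block-resolution grid
    block_size: tuple[int, int, int]
    stride: tuple[int, int, int]
    channel: str
    grid_shape: tuple[int, int, int]
    subject_ids: list[str] = field(default_factory=list)
    fold_ids: list[int] = field(default_factory=list)

    def geometry(self) -> tuple:
        return (self.importance.shape, self.block_size, self.stride,
                self.channel, self.grid_shape)

    def top_block_origin(self) -> tuple[int, ...]:
        """Voxel origin of the highest-importance block."""
        idx = np.unravel_index(int(np.argmax(self.importance)), self.importance.shape)
        return tuple(i * s for i, s in zip(idx, self.stride))


def occlude_block(volume: np.ndarray, block_origin, block_size) -> np.ndarray:
    """Copy of ``volume`` with the given block set to 0; other voxels untouched."""
    v = np.asarray(volume)
    slices = []
    for o, b, n in zip(block_origin, block_size, v.shape[-3:]):
        if o < 0 or b < 1 or o + b > n:
            raise DataError(
                f"block origin {tuple(block_origin)} size {tuple(block_size)} "
                f"outside grid {v.shape[-3:]}")
        slices.append(slice(o, o + b))
    out = v.copy()
    out[(..., *slices)] = 0.0
    return out


def _block_origins(n: int, b: int, s: int) -> list[int]:
    origins = list(range(0, max(n - b, 0) + 1, s))
    if origins[-1] + b < n:  # clip a final block to the boundary
        origins.append(n - b)
    return origins


def occlusion_map(
    fold_model, subject_inputs: DeepDataset, config: OcclusionConfig,
    fold_id: int | None = None,
) -> OcclusionHeatmap:
    """Importance map of one fold model, averaged over the given subjects.

    ``fold_model`` must expose ``predict(DeepDataset) -> DeepOutputs``.  The
    occlusion is applied to the normalized inputs, exactly what the network
    consumes.
    """
    if not hasattr(fold_model, "predict"):
        raise DataError("fold_model must expose a predict method (is it trained?)")
    if len(subject_inputs) == 0:
        raise DataError("no subjects supplied")
    ref = subject_inputs.mri if subject_inputs.mri is not None else subject_inputs.jd
    if ref is None:
        raise DataError("subject_inputs carries no image channel")
    grid_shape = ref.shape[-3:]
    config.validate(grid_shape)
    stride = config.resolved_stride()
    bsz = config.block_size

    y = subject_inputs.y_progression.astype(float)
    sign = np.ones_like(y) if config.signed_delta else np.where(y == 1, 1.0, -1.0)

    base_p = fold_model.predict(subject_inputs).p_progression
    origins = [_block_origins(n, b, s) for n, b, s in zip(grid_shape, bsz, stride)]
    imp = np.zeros((len(origins[0]), len(origins[1]), len(origins[2])))
    channels = ("mri", "jd") if config.channel == "both" else (config.channel,)
    for i, oi in enumerate(origins[0]):
        for j, oj in enumerate(origins[1]):
            for k, ok in enumerate(origins[2]):
                occluded = DeepDataset(
                    clinical=subject_inputs.clinical,
                    y_progression=subject_inputs.y_progression,
                    y_slope=subject_inputs.y_slope,
                    y_hippocampus=subject_inputs.y_hippocampus,
                    mri=subject_inputs.mri, jd=subject_inputs.jd,
                    subject_ids=subject_inputs.subject_ids,
                )
                for ch in channels:
                    vol = getattr(occluded, ch)
                    if vol is not None:
                        setattr(occluded, ch, occlude_block(vol, (oi, oj, ok), bsz))
                p = fold_model.predict(occluded).p_progression
                # importance: drop of the correct-class output
                imp[i, j, k] = float(np.mean(sign * (base_p - p)))
    return OcclusionHeatmap(
        importance=imp, block_size=tuple(bsz), stride=tuple(stride),
        channel=config.channel, grid_shape=tuple(grid_shape),
        subject_ids=list(subject_inputs.subject_ids),
        fold_ids=[fold_id] if fold_id is not None else [],
    )


def average_heatmaps(maps: Sequence[OcclusionHeatmap]) -> OcclusionHeatmap:
    """Block-wise arithmetic mean of geometrically identical maps."""
    maps = list(maps)
    if not maps:
        raise DataError("no heatmaps to average")
    geo = maps[0].geometry()
    for m in maps[1:]:
        if m.geometry() != geo:
            raise DataError("heatmap geometry mismatch; cannot average")
    mean = np.mean([m.importance for m in maps], axis=0)
    subj = sorted({s for m in maps for s in m.subject_ids})
    fids = sorted({f for m in maps for f in m.fold_ids})
    out = maps[0]
    return OcclusionHeatmap(importance=mean, block_size=out.block_size,
                            stride=out.stride, channel=out.channel,
                            grid_shape=out.grid_shape, subject_ids=subj,
                            fold_ids=fids)


def heatmap_to_nifti(heatmap: OcclusionHeatmap, voxel_size_mm: float, path,
                     upsample: bool = True) -> None:
    """Write the map as NIfTI, optionally nearest-neighbour upsampled to the
    input grid for overlay."""
    data = heatmap.importance
    if upsample:
        full = np.zeros(heatmap.grid_shape, dtype=np.float32)
        for i in range(data.shape[0]):
            for j in range(data.shape[1]):
                for k in range(data.shape[2]):
                    o = (i * heatmap.stride[0], j * heatmap.stride[1], k * heatmap.stride[2])
                    sl = tuple(slice(oo, min(oo + b, n))
                               for oo, b, n in zip(o, heatmap.block_size, heatmap.grid_shape))
                    full[sl] = data[i, j, k]
        data, zoom = full, voxel_size_mm
    else:
        zoom = voxel_size_mm * heatmap.stride[0]
    affine = np.diag([zoom] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)
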