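"""Tiling, foreground detection and patch featurization.

Images are tiled into a non-overlapping 224x224 grid, tissue-bearing patches
are kept by an HSV-saturation criterion, and each patch is embedded by a
pluggable featurizer. Two featurizers exist:

* ``toy`` — a deterministic, weight-free summary of the H-DAB stain
  deconvolution (optical-density statistics plus the DAB-positive pixel
  fraction). This is the tested default and carries the positivity signal
  the MIL regressor learns from.
* ``backbone`` — the interface for a pretrained convolutional backbone
  whose residual blocks 1-4 yield 256/512/1024/2048-dimensional spatially
  averaged embeddings. It requires torch + torchvision with weights; when
  those are unavailable it raises :class:`FeaturizerUnavailableError`
  rather than silently falling back.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from skimage.color import hdx_from_rgb, rgb2hsv
from skimage.filters import threshold_otsu

PATCH_SIZE = 224
BACKBONE_BLOCK_DIMS = {1: 256, 2: 512, 3: 1024, 4: 2048}

# DAB optical density above this value counts a pixel as positive-stained.
DAB_OD_CUT = 0.15
# Saturation floor: Otsu's threshold is never allowed below this, and images
# whose saturation never exceeds it are treated as having no tissue.
SATURATION_FLOOR = 0.05


class FeaturizerUnavailableError(RuntimeError):
    """Raised when the backbone featurizer (torch + weights) is requested
    but cannot be loaded. Never a silent fallback."""


@dataclasses.dataclass(frozen=True)
class Patch:
    """A square tile with 0-based, top-left, half-open pixel extent."""

    row: int
    col: int
    size: int = PATCH_SIZE
    magnification_tag: str = "20x"

    @property
    def origin(self) -> tuple[int, int]:
        return (self.row, self.col)

    @property
    def center(self) -> tuple[float, float]:
        return (self.row + self.size / 2.0, self.col + self.size / 2.0)

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.row : self.row + self.size, self.col : self.col + self.size]


@dataclasses.dataclass
class InstanceEmbedding:
    """One feature vector per patch; dim is fixed by the featurizer/block."""

    vector: np.ndarray
    patch: Patch

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding contains non-finite entries")


def tile_patches(image: np.ndarray, patch_size: int = PATCH_SIZE) -> list[Patch]:
    """Exhaustive non-overlapping grid of patches; partial edge tiles dropped.

    Raises ``ValueError`` if the image is smaller than one patch in either
    dimension.
    """
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image {h}x{w} smaller than one {patch_size}-pixel patch"
        )
    return [
        Patch(row=r, col=c, size=patch_size)
        for r in range(0, h - patch_size + 1, patch_size)
        for c in range(0, w - patch_size + 1, patch_size)
    ]


def _saturation_cut(sat: np.ndarray) -> float:
    """Otsu threshold on saturation, floored; degenerate images get no tissue."""
    if sat.max() <= SATURATION_FLOOR:
        return np.inf
    try:
        cut = threshold_otsu(sat)
    except ValueError:  # constant image
        return np.inf
    return max(cut, SATURATION_FLOOR)


def foreground_patches(
    image: np.ndarray,
    patches: list[Patch],
    tissue_threshold: float = 0.1,
) -> list[Patch]:
    """Keep patches whose tissue-pixel fraction is at least the threshold.

    Tissue pixels are those whose HSV saturation exceeds an Otsu-derived cut
    computed once on the whole image (stained nuclei are saturated, the
    near-white background is not). May return an empty list.
    """
    if not 0.0 <= tissue_threshold <= 1.0:
        raise ValueError("tissue_threshold must be in [0, 1]")
    sat = rgb2hsv(image)[..., 1]
    cut = _saturation_cut(sat)
    if not np.isfinite(cut):
        return []
    tissue = sat > cut
    kept = []
    for p in patches:
        frac = p.crop(tissue).mean()
        if frac >= tissue_threshold:
            kept.append(p)
    return kept


def _optical_density(patch_rgb: np.ndarray) -> np.ndarray:
    """H-DAB stain separation of an sRGB patch; channels (H, DAB, residual).

    Unmixes in conventional log10 optical-density units with the standard
    published H-DAB matrix, so the 0.15 DAB-positive cut is on the usual OD
    scale (skimage's separate_stains rescales by a log-adjust constant,
    which would shift the cut).
    """
    rgb = np.maximum(patch_rgb.astype(np.float64) / 255.0, 1e-6)
    od = -np.log10(rgb)
    return od @ hdx_from_rgb


def toy_features(patch_rgb: np.ndarray) -> np.ndarray:
    """Weight-free stain-deconvolution summary of one patch (13-dim).

    Per-channel optical-density means and upper percentiles for the
    hematoxylin and DAB channels, the DAB-positive pixel fraction (OD >
    0.15), stained-tissue pixel fraction and saturation statistics.
    Deterministic; identical input gives identical output. The summary
    deliberately stays at raw appearance statistics — positivity relative
    to tissue content is for the downstream model to infer, as it would be
    with a learned backbone.
    """
    od = _optical_density(patch_rgb)
    h, dab = od[..., 0], od[..., 1]
    sat = rgb2hsv(patch_rgb)[..., 1]
    tissue = (h > DAB_OD_CUT) | (dab > DAB_OD_CUT)
    dab_pos = dab > DAB_OD_CUT
    feats = np.array(
        [
            h.mean(),
            np.percentile(h, 75),
            np.percentile(h, 90),
            h.max(),
            dab.mean(),
            np.percentile(dab, 75),
            np.percentile(dab, 90),
            dab.max(),
            dab_pos.mean(),
            tissue.mean(),
            sat.mean(),
            np.percentile(sat, 90),
            sat.max(),
        ]
    )
    return feats


TOY_DIM = 13


def _load_backbone(block: int):
    if block not in BACKBONE_BLOCK_DIMS:
        raise ValueError(f"block must be in 1-4, got {block}")
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise FeaturizerUnavailableError(
            "backbone featurizer requires torch and torchvision with "
            "pretrained weights; install them or use featurizer='toy'"
        ) from exc
    from torchvision.models import ResNet50_Weights, resnet50

    model = resnet50(weights=ResNet50_Weights.IMAGENET1K_V1).eval()
    return model


def _backbone_features(patch_rgb: np.ndarray, model, block: int) -> np.ndarray:
    import torch

    x = torch.from_numpy(patch_rgb.astype(np.float32) / 255.0)
    mean = torch.tensor([0.485, 0.456, 0.406])
    std = torch.tensor([0.229, 0.224, 0.225])
    x = ((x - mean) / std).permute(2, 0, 1).unsqueeze(0)
    with torch.no_grad():
        x = model.maxpool(model.relu(model.bn1(model.conv1(x))))
        for i, layer in enumerate(
            [model.layer1, model.layer2, model.layer3, model.layer4], start=1
        ):
            x = layer(x)
            if i == block:
                break
    return x.mean(dim=(2, 3)).squeeze(0).numpy()


def extract_features(
    patches: list[Patch],
    image: np.ndarray,
    featurizer: str = "toy",
    block: int = 3,
) -> list[InstanceEmbedding]:
    """Embed each patch. ``featurizer`` is 'toy' or 'backbone' (block 1-4).

    The backbone path spatially averages the selected residual block's
    feature map, yielding 256/512/1024/2048-dim vectors for blocks 1-4; it
    raises :class:`FeaturizerUnavailableError` when torch or the weights
    are missing.
    """
    if featurizer == "toy":
        return [
            InstanceEmbedding(vector=toy_features(p.crop(image)), patch=p)
            for p in patches
        ]
    if featurizer == "backbone":
        model = _load_backbone(block)
        embs = [
            InstanceEmbedding(
                vector=_backbone_features(p.crop(image), model, block), patch=p
            )
            for p in patches
        ]
        expected = BACKBONE_BLOCK_DIMS[block]
        for e in embs:
            assert e.vector.shape == (expected,)
        return embs
    raise ValueError(f"unknown featurizer {featurizer!r}")


def downscale_to_20x(image_40x: np.ndarray) -> np.ndarray:
    """Realize 20x from a 40x raster by 2x block averaging."""
    h, w = image_40x.shape[:2]
    h2, w2 = h - h % 2, w - w % 2
    img = image_40x[:h2, :w2].astype(np.float64)
    out = img.reshape(h2 // 2, 2, w2 // 2, 2, -1).mean(axis=(1, 3))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def embeddings_to_frame(embeddings: list[InstanceEmbedding]) -> tuple[np.ndarray, pd.DataFrame]:
    """Split embeddings into a feature matrix and a patch-origin table."""
    X = np.stack([e.vector for e in embeddings])
    meta = pd.DataFrame(
        {
            "patch_id": np.arange(len(embeddings)),
            "row": [e.patch.row for e in embeddings],
            "col": [e.patch.col for e in embeddings],
            "size": [e.patch.size for e in embeddings],
        }
    )
    return X, meta
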