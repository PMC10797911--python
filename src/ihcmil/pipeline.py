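"""Image-to-bag plumbing shared by the CLI, examples and tests.

Turns rendered cores/slides into MIL bags via tiling, foreground detection
and the toy featurizer, and provides end-to-end helpers: train on a set of
labeled core images, then score slides through the mini-bag tessellation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Bag, GatedAttentionParams, TrainConfig, train
from .patches import extract_features, foreground_patches, tile_patches
from .synthetic import CoreImage, SyntheticSlide, generate_core, generate_slide
from .wsi import MiniBagPartition, SlideScore, cluster_coordinates, score_slide

log = logging.getLogger("ihcmil")


def image_to_bag(
    image: np.ndarray,
    bag_id: str,
    label: float,
    marker: str = "c-MYC",
    patch_size: int = 224,
    tissue_threshold: float = 0.1,
    featurizer: str = "toy",
    block: int = 3,
) -> Bag:
    """Tile, filter foreground and featurize one image into a Bag."""
    patches = tile_patches(image, patch_size)
    fg = foreground_patches(image, patches, tissue_threshold)
    if not fg:
        raise ValueError(f"no foreground patches in bag {bag_id!r}")
    embs = extract_features(fg, image, featurizer=featurizer, block=block)
    X = np.stack([e.vector for e in embs])
    return Bag(bag_id=bag_id, instances=X, label=label, marker=marker)


def cores_to_bags(
    cores: list[tuple[str, CoreImage]], marker: str = "c-MYC", **kwargs
) -> list[Bag]:
    return [
        image_to_bag(c.pixels, bag_id, c.true_fraction, marker=marker, **kwargs)
        for bag_id, c in cores
    ]


def train_on_cores(
    cores: list[tuple[str, CoreImage]],
    config: TrainConfig | None = None,
    marker: str = "c-MYC",
) -> GatedAttentionParams:
    """Featurize labeled cores and fit the attention regressor."""
    bags = cores_to_bags(cores, marker=marker)
    log.info("training on %d core bags (%s)", len(bags), marker)
    return train(bags, config)


def score_synthetic_slide(
    slide: SyntheticSlide,
    models,
    marker: str = "c-MYC",
    target_size: int = 45,
    seed: int = 0,
    patch_size: int = 224,
    tissue_threshold: float = 0.1,
) -> tuple[SlideScore, MiniBagPartition, list]:
    """Full slide path: tile -> foreground -> featurize -> tessellate -> score."""
    patches = tile_patches(slide.pixels, patch_size)
    fg = foreground_patches(slide.pixels, patches, tissue_threshold)
    if not fg:
        raise ValueError("slide has no foreground patches")
    embs = extract_features(fg, slide.pixels, featurizer="toy")
    partition = cluster_coordinates(fg, target_size=target_size, seed=seed)
    score = score_slide(partition, embs, models, marker=marker)
    return score, partition, embs


def simulate_core_cohort(
    n_per_decile: int,
    seed: int,
    size: int = 672,
    occupancy: tuple[float, float] = (0.4, 0.9),
    diameter_frac: tuple[float, float] = (0.7, 1.0),
    marker: str = "c-MYC",
) -> list[tuple[str, CoreImage]]:
    """Cores spanning every decile label, n_per_decile replicates each.

    Core diameter and cellularity vary between cores (uniform over the
    given relative ranges), as they do across a real TMA: partial punches
    and variable cell density leave some patches background-dominated,
    which is what teaches the attention branch to weight tissue.
    """
    from .synthetic import core_capacity

    rng = np.random.default_rng(seed)
    cores = []
    i = 0
    for frac in range(0, 101, 10):
        for _ in range(n_per_decile):
            diam = rng.uniform(*diameter_frac) * size
            n_cells = max(1, int(rng.uniform(*occupancy)
                                 * core_capacity(size, diam)))
            cores.append(
                (
                    f"core{i:04d}",
                    generate_core(frac, n_cells, seed=int(rng.integers(2**31)),
                                  size=size, diameter=diam),
                )
            )
            i += 1
    return cores


def simulate_slide_cohort(
    n_slides: int,
    seed: int,
    n_regions: int = 4,
    cells_per_region: int = 600,
    region_size: int = 448,
    heterogeneity: float = 15.0,
):
    """Slides whose mean fractions span 0-100 with regional heterogeneity.

    Region fractions are the slide's target fraction plus a uniform
    +-heterogeneity jitter, clipped to [0, 100]; ground truth is recomputed
    from the rendered cells.
    """
    rng = np.random.default_rng(seed)
    slides = []
    targets = np.linspace(0.0, 100.0, n_slides)
    for i, t in enumerate(targets):
        fr = np.clip(
            t + rng.uniform(-heterogeneity, heterogeneity, size=n_regions), 0, 100
        )
        slides.append(
            generate_slide(
                fr,
                cells_per_region,
                seed=int(rng.integers(2**31)),
                region_size=region_size,
            )
        )
    return slides


def simulate_localization_slides(
    n_slides: int,
    seed: int,
    region_size: int = 448,
    rich_fraction: float = 75.0,
    poor_fraction: float = 5.0,
):
    """Slides with one dense, positive-rich region among sparse
    low-positivity regions, for probing where the attention mass goes.

    Returns ``(slides, rich_region_index)`` with the rich region always at
    index 0 (top-left).
    """
    from .synthetic import core_capacity

    cap = core_capacity(region_size)
    rng = np.random.default_rng(seed)
    slides = []
    for _ in range(n_slides):
        cells = [int(0.8 * cap), int(0.35 * cap), int(0.35 * cap),
                 int(0.35 * cap)]
        slides.append(
            generate_slide(
                [rich_fraction, poor_fraction, poor_fraction, poor_fraction],
                cells,
                seed=int(rng.integers(2**31)),
                region_size=region_size,
            )
        )
    return slides, 0


def write_cohort(cores, out_dir: str | Path, marker: str, params: dict) -> Path:
    """Write cores as PNGs plus a truth table and a JSON parameter sidecar."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case_id, core in cores:
        iio.imwrite(out / f"{case_id}.png", core.pixels)
        rows.append(
            {"case_id": case_id, "marker": marker, "true_fraction": core.true_fraction}
        )
    truth = out / "truth.csv"
    pd.DataFrame(rows).to_csv(truth, index=False)
    (out / "config.json").write_text(json.dumps(params, indent=2, sort_keys=True))
    return truth


def load_cohort_bags(images_dir: str | Path, **kwargs) -> list[Bag]:
    """Rebuild bags from a written cohort (PNGs + truth.csv)."""
    import imageio.v3 as iio

    images_dir = Path(images_dir)
    truth = pd.read_csv(images_dir / "truth.csv")
    bags = []
    for _, row in truth.iterrows():
        img = iio.imread(images_dir / f"{row.case_id}.png")
        bags.append(
            image_to_bag(
                np.asarray(img)[..., :3],
                row.case_id,
                float(row.true_fraction),
                marker=row.marker,
                **kwargs,
            )
        )
    return bags
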