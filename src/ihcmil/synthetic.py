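"""Synthetic IHC cores, pseudo-whole-slides, embedding bags and survival tables.

Every downstream stage of the pipeline (patching, featurization, the MIL
regressor, slide translation, concordance and survival statistics) is
exercised on data from this module, for which the ground truth — the true
percent of positive cells per core, per region and per slide — is known
exactly.

The image model is deliberately minimal: nuclei are antialiased discs on a
near-white background, negative nuclei in a hematoxylin-like blue-purple and
positive nuclei in a DAB-like brown. Two linearly separable chromogens are
all the pipeline requires; no texture or morphology is simulated.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

# Reference chromogen colors (sRGB 0-255). Hematoxylin counterstain is a
# blue-purple, DAB a warm brown; values chosen to be well separated under
# the standard H-DAB optical-density deconvolution.
HEMATOXYLIN_RGB = (72, 61, 139)
DAB_RGB = (140, 81, 30)
BACKGROUND_RGB = (246, 246, 244)

DECILES = tuple(range(0, 101, 10))


@dataclasses.dataclass
class CoreImage:
    """A rendered synthetic TMA core with per-cell ground truth.

    ``true_fraction`` is the percent of rendered cells that are positive;
    by construction the positive-cell count is ``round(true_fraction / 100
    * n_cells)`` exactly, so the achievable fraction may differ from the
    requested one by sub-percent rounding.
    """

    pixels: np.ndarray  # H x W x 3 uint8
    cell_centers: np.ndarray  # n_cells x 2 (row, col) float
    cell_labels: np.ndarray  # n_cells bool, True = positive
    true_fraction: float  # percent in [0, 100]

    def __post_init__(self) -> None:
        n = len(self.cell_labels)
        if n:
            achieved = 100.0 * self.cell_labels.sum() / n
            assert abs(achieved - self.true_fraction) < 1e-9


@dataclasses.dataclass
class SyntheticSlide:
    """A pseudo-WSI tiled from core-like regions with known region fractions.

    ``region_map`` labels every pixel with its region index (-1 for the
    inter-region background gutter, of which there is none in the default
    tiling — regions abut). ``true_slide_fraction`` is the cell-weighted
    mean of the region fractions.
    """

    pixels: np.ndarray
    region_map: np.ndarray  # H x W int
    region_fractions: np.ndarray  # percent per region
    true_slide_fraction: float
    cell_centers: np.ndarray
    cell_labels: np.ndarray
    cell_regions: np.ndarray


def _disc_patch(radius: float) -> np.ndarray:
    """Antialiased coverage mask for a disc of given radius."""
    r_int = int(math.ceil(radius)) + 1
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    dist = np.hypot(yy, xx)
    # linear edge ramp one pixel wide
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return cov


def core_capacity(size: int, diameter: float | None = None,
                  radius: float = 5.0) -> int:
    """Number of non-overlapping nuclei a core raster can hold."""
    if diameter is None:
        diameter = size
    pitch = int(2 * radius + 3)
    per_side = size // pitch
    idx = np.arange(per_side * per_side)
    cy = (idx // per_side) * pitch + pitch / 2.0
    cx = (idx % per_side) * pitch + pitch / 2.0
    inside = (cy - size / 2.0) ** 2 + (cx - size / 2.0) ** 2 <= (
        diameter / 2.0 - radius
    ) ** 2
    return int(inside.sum())


def generate_core(
    true_fraction: float,
    n_cells: int,
    seed: int,
    size: int = 448,
    radius: float = 5.0,
    diameter: float | None = None,
    clustered: bool = True,
) -> CoreImage:
    """Render a synthetic IHC core with an exact positive-cell count.

    Cells are placed on a jittered grid (guaranteeing no overlap) inside a
    circular tissue disc — the punch geometry of a real TMA core — and
    exactly ``round(true_fraction / 100 * n_cells)`` of them are drawn in
    DAB brown, the rest in hematoxylin blue. With ``clustered`` (the
    default) positive cells concentrate around one or two random foci,
    mimicking the focal, spatially correlated positivity of real tissue;
    with ``clustered=False`` positives are scattered uniformly. Identical
    seeds give bit-identical rasters.

    Parameters
    ----------
    true_fraction : percent of positive cells requested, in [0, 100].
    n_cells : number of nuclei to render (>= 1).
    seed : RNG seed; the determinism contract is bit-exact.
    size : square raster side in pixels.
    radius : nucleus radius in pixels.
    diameter : tissue disc diameter in pixels (default: the full raster).
    clustered : concentrate positive cells around random foci.
    """
    if not 0.0 <= true_fraction <= 100.0:
        raise ValueError(f"true_fraction must be in [0, 100], got {true_fraction}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if diameter is None:
        diameter = size
    pitch = int(2 * radius + 3)
    per_side = size // pitch
    idx = np.arange(per_side * per_side)
    cy = (idx // per_side) * pitch + pitch / 2.0
    cx = (idx % per_side) * pitch + pitch / 2.0
    inside = (cy - size / 2.0) ** 2 + (cx - size / 2.0) ** 2 <= (
        diameter / 2.0 - radius
    ) ** 2
    avail = idx[inside]
    if n_cells > len(avail):
        raise ValueError(
            f"n_cells={n_cells} exceeds packing capacity {len(avail)} for "
            f"size={size}, diameter={diameter:g}"
        )
    rng = np.random.default_rng(seed)
    cells = rng.choice(avail, size=n_cells, replace=False)
    rows = cells // per_side
    cols = cells % per_side
    jitter = rng.uniform(-1.0, 1.0, size=(n_cells, 2))
    centers = np.stack(
        [
            rows * pitch + pitch / 2.0 + jitter[:, 0],
            cols * pitch + pitch / 2.0 + jitter[:, 1],
        ],
        axis=1,
    )
    n_pos = round(true_fraction / 100.0 * n_cells)
    if clustered and 0 < n_pos < n_cells:
        # positives are the n_pos cells nearest (with jitter) to random foci
        n_foci = int(rng.integers(1, 3))
        foci = centers[rng.choice(n_cells, size=n_foci, replace=False)]
        dist = np.min(
            np.linalg.norm(centers[:, None, :] - foci[None, :, :], axis=2), axis=1
        )
        dist = dist + rng.normal(0.0, max(dist.std(), 1e-9) * 0.2, size=n_cells)
        labels = np.zeros(n_cells, dtype=bool)
        labels[np.argsort(dist)[:n_pos]] = True
    else:
        labels = np.zeros(n_cells, dtype=bool)
        labels[rng.choice(n_cells, size=n_pos, replace=False)] = True

    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    cov = _disc_patch(radius)
    half = cov.shape[0] // 2
    for (r, c), pos in zip(centers, labels):
        color = np.array(DAB_RGB if pos else HEMATOXYLIN_RGB, dtype=np.float64)
        ri, ci = int(round(r)), int(round(c))
        r0, r1 = max(ri - half, 0), min(ri + half + 1, size)
        c0, c1 = max(ci - half, 0), min(ci + half + 1, size)
        sub = cov[r0 - ri + half : r1 - ri + half, c0 - ci + half : c1 - ci + half]
        img[r0:r1, c0:c1] = (
            img[r0:r1, c0:c1] * (1 - sub[..., None]) + color * sub[..., None]
        )
    achieved = 100.0 * n_pos / n_cells
    return CoreImage(
        pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
        cell_centers=centers,
        cell_labels=labels,
        true_fraction=achieved,
    )


def generate_slide(
    region_fractions,
    cells_per_region,
    seed: int,
    region_size: int = 448,
    n_cols: int | None = None,
) -> SyntheticSlide:
    """Tile core-like regions into a pseudo-WSI with spatial heterogeneity.

    Each region is rendered like a core with its own positive fraction, so
    positivity varies across the slide the way it does across real tissue.
    ``cells_per_region`` may be a single count or one per region (sparser
    regions emulate background-dominated tissue). The slide-level truth is
    the cell-weighted mean of the region fractions — the plain mean when
    the cell count is constant.
    """
    region_fractions = np.asarray(region_fractions, dtype=float)
    if region_fractions.size == 0:
        raise ValueError("at least one region is required")
    if np.any((region_fractions < 0) | (region_fractions > 100)):
        raise ValueError("region fractions must be in [0, 100]")
    n_regions = region_fractions.size
    cells_arr = np.broadcast_to(
        np.asarray(cells_per_region, dtype=int), (n_regions,)
    )
    if n_cols is None:
        n_cols = int(math.ceil(math.sqrt(n_regions)))
    n_rows = int(math.ceil(n_regions / n_cols))

    H, W = n_rows * region_size, n_cols * region_size
    pixels = np.empty((H, W, 3), dtype=np.uint8)
    pixels[:] = BACKGROUND_RGB
    region_map = np.full((H, W), -1, dtype=int)
    centers, labels, regions = [], [], []
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = ss.generate_state(n_regions)
    total_pos = 0
    total_cells = 0
    for i, frac in enumerate(region_fractions):
        rr, cc = divmod(i, n_cols)
        core = generate_core(
            frac, int(cells_arr[i]), seed=int(child_seeds[i]), size=region_size
        )
        r0, c0 = rr * region_size, cc * region_size
        pixels[r0 : r0 + region_size, c0 : c0 + region_size] = core.pixels
        region_map[r0 : r0 + region_size, c0 : c0 + region_size] = i
        centers.append(core.cell_centers + [r0, c0])
        labels.append(core.cell_labels)
        regions.append(np.full(int(cells_arr[i]), i))
        total_pos += int(core.cell_labels.sum())
        total_cells += int(cells_arr[i])
    true_slide_fraction = 100.0 * total_pos / total_cells
    return SyntheticSlide(
        pixels=pixels,
        region_map=region_map,
        region_fractions=region_fractions,
        true_slide_fraction=true_slide_fraction,
        cell_centers=np.concatenate(centers),
        cell_labels=np.concatenate(labels),
        cell_regions=np.concatenate(regions),
    )


def generate_embedding_bags(
    n_bags: int,
    dim: int = 64,
    instances_per_bag: tuple[int, int] = (30, 60),
    noise_sd: float = 0.5,
    seed: int = 0,
    skew_low: bool = False,
):
    """Image-free MIL fixture: bags of prototype-drawn instance embeddings.

    Each bag gets a decile label; a matching fraction of its instances is
    drawn from a "positive" latent prototype and the rest from a "negative"
    one (unit offset along each coordinate, isotropic Gaussian noise). The
    returned list pairs ``(instances, label_percent, instance_is_positive)``.

    ``skew_low`` samples labels preferentially from 10-40% to mimic the
    label imbalance typical of clinically scored cohorts.
    """
    if n_bags < 1 or dim < 2:
        raise ValueError("n_bags >= 1 and dim >= 2 required")
    lo, hi = instances_per_bag
    if lo < 1 or hi < lo:
        raise ValueError("invalid instances_per_bag range")
    rng = np.random.default_rng(seed)
    deciles = np.array(DECILES, dtype=float)
    if skew_low:
        w = np.where((deciles >= 10) & (deciles <= 40), 4.0, 1.0)
        probs = w / w.sum()
    else:
        probs = None
    neg_proto = np.zeros(dim)
    pos_proto = np.ones(dim)
    out = []
    for _ in range(n_bags):
        label = float(rng.choice(deciles, p=probs))
        k = int(rng.integers(lo, hi + 1))
        n_pos = round(label / 100.0 * k)
        is_pos = np.zeros(k, dtype=bool)
        is_pos[rng.choice(k, size=n_pos, replace=False)] = True
        proto = np.where(is_pos[:, None], pos_proto, neg_proto)
        inst = proto + rng.normal(0.0, noise_sd, size=(k, dim))
        out.append((inst, label, is_pos))
    return out


def _uniform_censor_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound c of U(0, c) censoring achieving the target censor rate.

    For T ~ Exp(rate) and C ~ U(0, c), P(C < T) = (1 - e^{-rate c})/(rate c);
    averaged over the subject mix, solved by root finding.
    """

    def censored_prob(c):
        x = rates * c
        return np.mean((1.0 - np.exp(-x)) / x) - target

    # censored_prob -> 0 as c -> inf and -> 1 as c -> 0
    lo, hi = 1e-9, 1.0
    while censored_prob(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(censored_prob, lo, hi)


def generate_survival(
    n: int,
    hazard_ratio: float,
    censor_rate: float = 0.2,
    de_prevalence: float = 0.3,
    seed: int = 0,
    base_rate: float = 0.2,
) -> pd.DataFrame:
    """Simulate (time, event, group) records for a two-group survival study.

    Event times are exponential; the double-expressor group's hazard is the
    base rate multiplied by ``hazard_ratio``. Censoring is independent
    U(0, c) with c solved so the expected censored fraction equals
    ``censor_rate``. Returns a DataFrame with columns
    ``case_id, time, event, group`` where group is "DE" or "non-DE".
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not (0.0 <= censor_rate < 1.0) or not (0.0 <= de_prevalence <= 1.0):
        raise ValueError("rates must be in [0, 1] (censor_rate < 1)")
    rng = np.random.default_rng(seed)
    is_de = rng.random(n) < de_prevalence
    rates = np.where(is_de, base_rate * hazard_ratio, base_rate)
    times = rng.exponential(1.0 / rates)
    if censor_rate > 0.0:
        c = _uniform_censor_bound(rates, censor_rate)
        censor_times = rng.uniform(0.0, c, size=n)
        event = (times <= censor_times).astype(int)
        obs = np.minimum(times, censor_times)
    else:
        event = np.ones(n, dtype=int)
        obs = times
    obs = np.maximum(obs, 1e-9)  # times strictly positive
    return pd.DataFrame(
        {
            "case_id": [f"S{i:04d}" for i in range(n)],
            "time": obs,
            "event": event,
            "group": np.where(is_de, "DE", "non-DE"),
        }
    )


# ---------------------------------------------------------------------------
# disk I/O


def save_core(core: CoreImage, path: str | Path, case_id: str, marker: str) -> None:
    """Write a core as PNG plus truth CSV row and a JSON parameter sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, core.pixels)
    truth = path.with_suffix(".truth.csv")
    pd.DataFrame(
        [{"case_id": case_id, "marker": marker, "true_fraction": core.true_fraction}]
    ).to_csv(truth, index=False)
    sidecar = {
        "case_id": case_id,
        "marker": marker,
        "n_cells": int(len(core.cell_labels)),
        "true_fraction": core.true_fraction,
        "size": [int(s) for s in core.pixels.shape[:2]],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def linear_probe_accuracy(bags, seed: int = 0) -> float:
    """Accuracy of a linear classifier separating instance prototypes.

    Used to verify embedding-bag separability: as noise_sd -> 0 this
    approaches 1.0.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.concatenate([inst for inst, _, _ in bags])
    y = np.concatenate([is_pos for _, _, is_pos in bags])
    if y.all() or not y.any():
        warnings.warn("single-class instance set; probe accuracy trivially 1")
        return 1.0
    clf = LogisticRegression(max_iter=1000, random_state=seed).fit(X, y)
    return float(clf.score(X, y))
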