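"""Spatial co-occurrence of toxins across gland sections.

Each toxin contributes one 2-D ion-intensity grid over a shared tissue
mask. Co-occurrence is the Pearson correlation of two toxins' intensities
over masked pixels (optionally after per-pixel total-ion-current
normalization; a cosine-similarity alternative is exposed). Localization
along the anterior-posterior axis is summarized by the intensity-weighted
centroid of the normalized axis coordinate (anterior = 0, posterior = 1),
and group differences are tested by one-way analysis of variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import PairMatrix

__all__ = [
    "IonImageStack",
    "LocationTestResult",
    "spatial_correlation",
    "axis_localization",
    "group_location_test",
]


@dataclass
class IonImageStack:
    images: dict[str, np.ndarray]
    mask: np.ndarray
    axis: int = 1  # grid dimension running anterior (index 0) -> posterior

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("mask must be non-empty")
        for name, img in self.images.items():
            img = np.asarray(img, dtype=float)
            if img.shape != self.mask.shape:
                raise ValueError(f"image {name!r} shape {img.shape} != mask {self.mask.shape}")
            if (img[self.mask] < 0).any():
                raise ValueError(f"image {name!r} has negative intensities")
            self.images[name] = img
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 or 1")

    @property
    def toxins(self) -> list[str]:
        return list(self.images)

    def transpose(self) -> "IonImageStack":
        return IonImageStack(
            {k: v.T.copy() for k, v in self.images.items()}, self.mask.T.copy(), 1 - self.axis
        )


def spatial_correlation(
    stack: IonImageStack, normalize: str = "none", method: str = "pearson"
) -> PairMatrix:
    """Pairwise co-occurrence of toxin intensities over masked pixels.
    ``normalize='tic'`` divides each pixel by its total intensity across the
    stack first; ``method`` is 'pearson' (default) or 'cosine'."""
    names = stack.toxins
    if len(names) < 2:
        raise ValueError("need at least 2 toxins")
    X = np.vstack([stack.images[n][stack.mask] for n in names]).astype(float)
    if normalize == "tic":
        tic = X.sum(axis=0)
        tic[tic == 0] = 1.0
        X = X / tic
    elif normalize != "none":
        raise ValueError("normalize must be 'tic' or 'none'")
    const = X.std(axis=1) == 0
    if const.any():
        warnings.warn(f"constant image(s): {[n for n, c in zip(names, const) if c]}")
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(X)
    elif method == "cosine":
        norms = np.linalg.norm(X, axis=1)
        norms[norms == 0] = 1.0
        c = (X @ X.T) / np.outer(norms, norms)
    else:
        raise ValueError("method must be 'pearson' or 'cosine'")
    c[const, :] = np.nan
    c[:, const] = np.nan
    np.fill_diagonal(c, np.where(const, np.nan, 1.0))
    return PairMatrix(names, c, measure=f"spatial_{method}", kind="similarity")


def axis_localization(stack: IonImageStack) -> pd.Series:
    """Intensity-weighted mean of the normalized anterior-posterior
    coordinate over masked pixels, per toxin; all-zero images are missing."""
    n_axis = stack.mask.shape[stack.axis]
    coord_1d = np.arange(n_axis) / max(n_axis - 1, 1)
    coord = (
        np.broadcast_to(coord_1d[None, :], stack.mask.shape)
        if stack.axis == 1
        else np.broadcast_to(coord_1d[:, None], stack.mask.shape)
    )
    out = {}
    for name, img in stack.images.items():
        w = img[stack.mask]
        total = w.sum()
        if total == 0:
            warnings.warn(f"image {name!r} is all-zero: centroid undefined")
            out[name] = np.nan
        else:
            out[name] = float((w * coord[stack.mask]).sum() / total)
    return pd.Series(out, name="axis_centroid")


@dataclass
class LocationTestResult:
    centroids: pd.Series
    groups: pd.Series
    f_statistic: float
    p_value: float
    group_means: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"centroid": self.centroids, "group": self.groups})


def group_location_test(centroids: pd.Series, groups: pd.Series) -> LocationTestResult:
    """One-way ANOVA of axis centroids across toxin groups."""
    groups = groups.reindex(centroids.index)
    ok = centroids.notna()
    centroids, groups = centroids[ok], groups[ok]
    by_group = {g: centroids[groups == g].to_numpy() for g in sorted(groups.unique())}
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in by_group.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} has no members")
    f, p = scipy.stats.f_oneway(*by_group.values())
    means = pd.Series({g: v.mean() for g, v in by_group.items()}, name="group_mean")
    return LocationTestResult(centroids, groups, float(f), float(p), means)
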