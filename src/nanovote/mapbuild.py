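"""From per-cell channel maps to the fused pixel-level list dataset.

A force-volume map of a single cell yields four co-registered channels
(Adh, MechH, MechL, Morpho).  Dividing the map into pixels multiplies the
number of training examples by the cell's pixel count but discards where
each pixel sits in the cell, so two normalized spatial features are added:

``ND``
    Euclidean distance from the pixel to the height-weighted cell centre,
    divided by the cell's maximum such distance (the farthest pixel has
    ND = 1).
``NDR``
    the pixel's 1-based ascending rank of that distance divided by the
    cell's pixel count, so the NDR values of an n-pixel cell are exactly
    {1/n, 2/n, ..., 1}.

Unlike whole-cell descriptors (area, volume, mean modulus), ND and NDR
vary from pixel to pixel, so they enlarge the dataset without collapsing
it back into one row per cell.

The module also manages cell-level train/validation/test splitting (no
pixel of one cell may appear in two splits) and [-1, 1] min-max feature
normalization fitted on the training split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FEATURES",
    "NanomechMap",
    "Normalizer",
    "segment_cell",
    "cell_center",
    "compute_nd",
    "compute_ndr",
    "build_pixel_table",
    "split_by_cell",
    "fit_normalizer",
    "apply_normalizer",
    "write_pixel_table",
    "read_pixel_table",
]

#: Feature columns of the pixel table, in canonical order.
FEATURES = ("Adh", "MechH", "MechL", "Morpho", "ND", "NDR")
_TABLE_COLUMNS = FEATURES + ("Category",)


@dataclass
class NanomechMap:
    """Per-cell grid of the four channels plus mask, label and identity."""

    channels: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    valid: np.ndarray | None = None
    label: str = "unknown"
    cell_id: str = ""

    def __post_init__(self) -> None:
        shapes = {k: v.shape for k, v in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.valid is None:
            self.valid = np.ones(self.grid_shape, dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def segment_cell(
    nmap: NanomechMap, height_threshold: float = 200.0
) -> np.ndarray:
    """Cell mask: largest 4-connected component of Morpho > threshold.

    Only pixels with valid channel extraction participate.  Raises
    ``ValueError`` when nothing exceeds the threshold (all-substrate map).
    """
    fg = (nmap.channels["Morpho"] > height_threshold) & nmap.valid
    labels, n = ndimage.label(fg)  # default structure = 4-connectivity
    if n == 0:
        raise ValueError("segmentation failure: no pixel above height threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def cell_center(nmap: NanomechMap, mask: np.ndarray | None = None) -> tuple[float, float]:
    """Height-weighted centroid (row, col) of the cell, in continuous
    pixel coordinates (pixel centres at integer coordinates)."""
    mask = nmap.mask if mask is None else mask
    if mask is None or not mask.any():
        raise ValueError("empty mask")
    morpho = nmap.channels["Morpho"]
    w = morpho[mask]
    total = float(w.sum())
    if total <= 0:
        raise ValueError("mask has non-positive total height")
    rows, cols = np.nonzero(mask)
    return float(np.dot(rows, w) / total), float(np.dot(cols, w) / total)


def _distances(mask: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.hypot(rows - center[0], cols - center[1])


def compute_nd(mask: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """ND for every mask pixel (row-major order): distance to the centre
    divided by the cell's maximum distance.  A single-pixel cell gets 0."""
    d = _distances(mask, center)
    dmax = d.max()
    if dmax == 0:
        return np.zeros_like(d)
    return d / dmax


def compute_ndr(mask: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """NDR for every mask pixel (row-major order): 1-based ascending rank
    of the centre distance divided by the pixel count.  Ties are broken by
    row-major pixel order, so the value multiset is exactly {k/n}."""
    d = _distances(mask, center)
    n = len(d)
    order = np.argsort(d, kind="stable")  # stable = row-major tie-break
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return ranks / n


def build_pixel_table(maps: Iterable[NanomechMap]) -> pd.DataFrame:
    """Fuse maps into the list dataset: one row per cell-mask pixel with
    columns Adh, MechH, MechL, Morpho, ND, NDR, Category plus provenance
    (cell_id, row, col).

    Pixels flagged invalid during curve analysis are excluded from the
    mask and hence from the centre, ND and NDR computations as well.
    """
    frames = []
    for nmap in maps:
        mask = (nmap.mask if nmap.mask is not None else segment_cell(nmap))
        mask = mask & nmap.valid
        if not mask.any():
            continue
        center = cell_center(nmap, mask)
        rows, cols = np.nonzero(mask)
        frames.append(
            pd.DataFrame(
                {
                    "Adh": nmap.channels["Adh"][mask],
                    "MechH": nmap.channels["MechH"][mask],
                    "MechL": nmap.channels["MechL"][mask],
                    "Morpho": nmap.channels["Morpho"][mask],
                    "ND": compute_nd(mask, center),
                    "NDR": compute_ndr(mask, center),
                    "Category": nmap.label,
                    "cell_id": nmap.cell_id,
                    "row": rows,
                    "col": cols,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=list(_TABLE_COLUMNS) + ["cell_id", "row", "col"]
        )
    return pd.concat(frames, ignore_index=True)


def split_by_cell(
    cell_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Random cell-level train/validation/test partition.

    Splitting happens before pixel expansion so no pixel of one cell can
    leak across splits.  Counts follow the largest-remainder rounding of
    ``ratios``; deterministic given ``seed``.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    ids = list(cell_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell ids")
    if len(ids) < 3:
        raise ValueError(f"need at least 3 cells to split, got {len(ids)}")
    exact = np.array(ratios) * len(ids)
    counts = np.floor(exact).astype(int)
    for _ in range(len(ids) - counts.sum()):
        counts[int(np.argmax(exact - counts))] += 1
    if (counts == 0).any():
        raise ValueError(f"a split would be empty with {len(ids)} cells and ratios {ratios}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    train = perm[: counts[0]]
    val = perm[counts[0] : counts[0] + counts[1]]
    test = perm[counts[0] + counts[1] :]
    return train, val, test


@dataclass
class Normalizer:
    """Per-feature min-max scaler onto [-1, 1], fitted on training rows.

    The affine map sends the training minimum to -1 and maximum to +1;
    applied unchanged to validation/test rows, whose values may fall
    outside [-1, 1] (they are not clipped).
    """

    minima: dict[str, float] = field(default_factory=dict)
    maxima: dict[str, float] = field(default_factory=dict)

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        out = records.copy()
        for feat in self.minima:
            lo, hi = self.minima[feat], self.maxima[feat]
            out[feat] = 2.0 * (records[feat] - lo) / (hi - lo) - 1.0
        return out

    def to_json(self) -> str:
        return json.dumps({"minima": self.minima, "maxima": self.maxima})

    @classmethod
    def from_json(cls, text: str) -> "Normalizer":
        d = json.loads(text)
        return cls(minima=d["minima"], maxima=d["maxima"])


def fit_normalizer(
    records: pd.DataFrame, features: Sequence[str] = FEATURES
) -> Normalizer:
    """Learn per-feature (min, max) from training records.

    Raises ``ValueError`` naming the feature if one is constant.
    """
    norm = Normalizer()
    for feat in features:
        lo, hi = float(records[feat].min()), float(records[feat].max())
        if not hi > lo:
            raise ValueError(f"feature {feat!r} is constant (min == max == {lo})")
        norm.minima[feat] = lo
        norm.maxima[feat] = hi
    return norm


def apply_normalizer(records: pd.DataFrame, normalizer: Normalizer) -> pd.DataFrame:
    """Apply a fitted normalizer; alias for ``normalizer.transform``."""
    return normalizer.transform(records)


def write_pixel_table(
    table: pd.DataFrame, path, provenance: bool = False
) -> None:
    """Write the pixel table CSV with the canonical header
    ``Adh,MechH,MechL,Morpho,ND,NDR,Category`` (plus cell_id,row,col when
    ``provenance`` is set)."""
    cols = list(_TABLE_COLUMNS) + (["cell_id", "row", "col"] if provenance else [])
    table[cols].to_csv(path, index=False, float_format="%.10g")


def read_pixel_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
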