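"""In vitro quantifications: ΔΔCT relative expression and cell-area
morphometry from labeled segmentation masks.

ΔΔCT assumes perfect doubling per PCR cycle: ΔCT = Ct(target) −
Ct(housekeeping), ΔΔCT = ΔCT − mean ΔCT of the reference group, and the
relative quantity is RQ = 2^(−ΔΔCT).  Morphometry operates on integer
label masks (0 = background, k > 0 = cell k) from any segmenter: cell area
is pixel count × pixel area, and the epithelial-to-mesenchymal-transition
readout is the fraction of cells whose area exceeds 5,000 µm².
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "LabelMask",
    "ddct_relative_expression",
    "area_fraction_above",
    "read_ct_table",
]

CT_COLUMNS = [
    "sample_id",
    "group",
    "target_gene",
    "housekeeping_gene",
    "ct_target",
    "ct_housekeeping",
]


@dataclass
class CtTable:
    """qPCR Ct records; ``group`` is "reference" or "test"."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"Ct table lacks column(s): {sorted(missing)}")
        for col in ("ct_target", "ct_housekeeping"):
            bad = self.table.loc[~np.isfinite(self.table[col].astype(float)), "sample_id"]
            if len(bad):
                raise ValueError(f"non-finite {col} for sample(s): {list(bad)[:5]}")
        if not (self.table["group"] == "reference").any():
            raise ValueError("Ct table has no reference-group samples")


def read_ct_table(path) -> CtTable:
    """Read a Ct CSV with columns sample_id, group, target_gene,
    housekeeping_gene, ct_target, ct_housekeeping."""
    return CtTable(pd.read_csv(path))


def ddct_relative_expression(table: CtTable | pd.DataFrame) -> pd.DataFrame:
    """Relative quantities by the ΔΔCT method, per target gene.

    ΔΔCT is taken against the mean reference-group ΔCT of the same target
    gene; RQ = 2^(−ΔΔCT).  A single-sample reference group therefore has
    RQ exactly 1.  Returns the input rows plus ``dct``, ``ddct`` and ``rq``.
    """
    if isinstance(table, pd.DataFrame):
        table = CtTable(table)
    df = table.table.copy()
    df["dct"] = df["ct_target"].astype(float) - df["ct_housekeeping"].astype(float)
    out = []
    for gene, sub in df.groupby("target_gene", sort=False):
        ref = sub.loc[sub["group"] == "reference", "dct"]
        if ref.empty:
            raise ValueError(f"no reference samples for target gene {gene!r}")
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - ref.mean()
        sub["rq"] = 2.0 ** (-sub["ddct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


@dataclass
class LabelMask:
    """Integer-labeled segmentation image with physical pixel size."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative integers")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @classmethod
    def read(cls, path, pixel_size_um: float) -> "LabelMask":
        """Read a single-channel TIFF or PNG label image."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            img = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            img = iio.imread(path)
        return cls(labels=np.asarray(img).astype(np.int64), pixel_size_um=pixel_size_um)

    def write(self, path) -> None:
        path = Path(path)
        data = self.labels.astype(np.uint16 if self.labels.max() < 2**16 else np.int32)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, data)
        else:
            import imageio.v3 as iio

            iio.imwrite(path, data.astype(np.uint16))


def _border_labels(labels: np.ndarray) -> set:
    edges = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return set(np.unique(edges)) - {0}


def area_fraction_above(
    mask: LabelMask,
    threshold_um2: float = 5000.0,
    exclude_border: bool = True,
) -> tuple:
    """Fraction of cells with area strictly above ``threshold_um2``.

    Cell area is pixel count × pixel_size_um².  Cells touching the image
    border are excluded by default (partial cells bias areas down).
    Returns ``(result, areas)`` where ``result`` has keys ``percent,
    numerator, denominator, missing`` and ``areas`` is a per-cell table
    (label, area_um2, on_border).
    """
    labels = mask.labels
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    border = _border_labels(labels)
    areas = pd.DataFrame(
        {
            "label": ids,
            "area_um2": counts * mask.pixel_size_um**2,
            "on_border": [int(i) in border for i in ids],
        }
    )
    usable = areas.loc[~areas["on_border"]] if exclude_border else areas
    denom = len(usable)
    if denom == 0:
        return ({"percent": float("nan"), "numerator": 0, "denominator": 0, "missing": True}, areas)
    num = int((usable["area_um2"] > threshold_um2).sum())
    return (
        {"percent": 100.0 * num / denom, "numerator": num, "denominator": denom, "missing": False},
        areas,
    )
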