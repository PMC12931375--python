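"""Space Ranger-style Visium I/O, spot QC and multi-sample containers.

A Visium capture area is a hexagonal lattice of 55-µm barcoded spots; Space
Ranger emits, per sample, a Matrix Market count matrix with companion
``features.tsv`` / ``barcodes.tsv`` files and a ``tissue_positions.csv``
table mapping each barcode to its array and full-resolution pixel
coordinates.  This module reads and writes that layout (gzipped or plain,
pre- and post-Space Ranger-2.0 position dialects), applies the detected-gene
spot filter, ingests cluster/compartment annotations and merges samples onto
a shared gene universe.
"""

from __future__ import annotations

import gzip
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpotMatrix",
    "SpotAnnotation",
    "SampleSet",
    "read_spaceranger",
    "qc_filter_spots",
    "read_annotations",
    "merge_samples",
]

COMPARTMENTS = ("epidermis", "dermis", "other")

# tissue_positions.csv header introduced with Space Ranger 2.0; older
# releases shipped a headerless tissue_positions_list.csv with the same
# column order.
_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


@dataclass
class SpotMatrix:
    """Sparse gene × spot count matrix with spot coordinates for one sample.

    Attributes
    ----------
    counts
        Nonnegative integer sparse matrix, genes on rows, spots on columns.
    gene_ids, gene_symbols
        Parallel per-gene identifier and symbol lists.
    barcodes
        Unique spot barcodes (column labels).
    array_row, array_col
        Integer lattice coordinates (Visium hex-grid convention: column
        parity matches row parity).
    pxl_row, pxl_col
        Full-resolution pixel centroids of each spot.
    in_tissue
        Space Ranger's tissue-detection flag per spot.
    sample_id
        Sample identifier; used to prefix barcodes when merging.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    pxl_row: np.ndarray
    pxl_col: np.ndarray
    in_tissue: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise ValueError(
                f"gene annotation length mismatch: matrix has {n_genes} genes"
            )
        if len(self.barcodes) != n_spots:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {n_spots} matrix columns"
            )
        if len(set(self.barcodes)) != n_spots:
            raise ValueError(f"duplicate barcodes in sample {self.sample_id!r}")
        for name in ("array_row", "array_col", "pxl_row", "pxl_col", "in_tissue"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_spots,):
                raise ValueError(f"{name} must have one entry per spot")
            setattr(self, name, arr)
        self.in_tissue = self.in_tissue.astype(bool)

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def detected_genes_per_spot(self) -> np.ndarray:
        """Number of genes with UMI count >= 1 in each spot."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def symbol_index(self) -> dict:
        """Map gene symbol -> row index (duplicates suffixed by gene_id)."""
        idx: dict = {}
        seen: dict = {}
        for i, sym in enumerate(self.gene_symbols):
            if sym in seen:
                idx[f"{sym}_{self.gene_ids[i]}"] = i
            else:
                seen[sym] = i
                idx[sym] = i
        return idx

    def subset_spots(self, mask: np.ndarray) -> "SpotMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return SpotMatrix(
            counts=self.counts[:, cols],
            gene_ids=self.gene_ids,
            gene_symbols=self.gene_symbols,
            barcodes=self.barcodes[cols],
            array_row=self.array_row[cols],
            array_col=self.array_col[cols],
            pxl_row=self.pxl_row[cols],
            pxl_col=self.pxl_col[cols],
            in_tissue=self.in_tissue[cols],
            sample_id=self.sample_id,
        )

    def subset_genes(self, rows: np.ndarray) -> "SpotMatrix":
        rows = np.asarray(rows)
        return replace(
            self,
            counts=self.counts[rows],
            gene_ids=self.gene_ids[rows],
            gene_symbols=self.gene_symbols[rows],
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (spots × genes) for interop."""
        import anndata as ad

        obs = pd.DataFrame(
            {
                "array_row": self.array_row,
                "array_col": self.array_col,
                "in_tissue": self.in_tissue,
                "sample_id": self.sample_id,
            },
            index=pd.Index(self.barcodes.astype(str), name="barcode"),
        )
        var = pd.DataFrame(
            {"gene_ids": self.gene_ids},
            index=pd.Index(self.gene_symbols.astype(str), name="symbol"),
        )
        adata = ad.AnnData(X=self.counts.T.tocsr(), obs=obs, var=var)
        adata.obsm["spatial"] = np.column_stack([self.pxl_col, self.pxl_row])
        return adata

    def equals(self, other: "SpotMatrix") -> bool:
        """Exact equality of counts, annotation and coordinates."""
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.gene_symbols, other.gene_symbols)
            and np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.array_row, other.array_row)
            and np.array_equal(self.array_col, other.array_col)
            and np.allclose(self.pxl_row, other.pxl_row)
            and np.allclose(self.pxl_col, other.pxl_col)
            and np.array_equal(self.in_tissue, other.in_tissue)
        )


@dataclass
class SpotAnnotation:
    """Per-spot cluster labels and histological compartments.

    ``table`` is indexed by ``(sample_id, barcode)`` with columns
    ``cluster_id`` and ``compartment``; the compartment derives
    deterministically from ``cluster_map`` (unmapped clusters → "other").
    """

    table: pd.DataFrame
    cluster_map: dict = field(default_factory=dict)

    def compartment_of(self, sample_id: str, barcodes: Iterable[str]) -> np.ndarray:
        sub = self.table.loc[self.table["sample_id"] == sample_id].set_index("barcode")
        return sub.reindex(list(barcodes))["compartment"].fillna("other").to_numpy()

    def cluster_of(self, sample_id: str, barcodes: Iterable[str]) -> np.ndarray:
        sub = self.table.loc[self.table["sample_id"] == sample_id].set_index("barcode")
        return sub.reindex(list(barcodes))["cluster_id"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class SampleSet:
    """Ordered collection of per-sample SpotMatrix with a group label each."""

    samples: list
    groups: list

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample_ids: {ids}")
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label required per sample")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, key):
        if isinstance(key, str):
            for s in self.samples:
                if s.sample_id == key:
                    return s
            raise KeyError(key)
        return self.samples[key]

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    def group_of(self, sample_id: str) -> str:
        return self.groups[self.sample_ids.index(sample_id)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found under {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_spaceranger(directory, keep_all_spots: bool = False) -> SpotMatrix:
    """Read one Space Ranger-style sample directory into a :class:`SpotMatrix`.

    Expects ``matrix.mtx[.gz]``, ``features.tsv[.gz]``, ``barcodes.tsv[.gz]``
    and a positions table (``tissue_positions.csv[.gz]`` with header, or the
    pre-2.0 headerless ``tissue_positions_list.csv``), either at top level or
    with the matrix trio under a ``filtered_feature_bc_matrix``-style
    subdirectory.

    Parameters
    ----------
    directory
        Sample directory.
    keep_all_spots
        Keep spots with ``in_tissue == 0`` (default drops them, mirroring the
        filtered matrix most analyses start from).
    """
    directory = Path(directory)
    mat_dir = directory
    for sub in ("filtered_feature_bc_matrix", "raw_feature_bc_matrix"):
        if (directory / sub).is_dir():
            mat_dir = directory / sub
            break

    mtx_path = _find(mat_dir, "matrix.mtx")
    try:
        with _open_text(mtx_path) as fh:
            counts = sp.csr_matrix(scipy.io.mmread(fh))
    except ValueError as exc:
        raise ValueError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    counts.data = counts.data.astype(np.int64)

    with _open_text(_find(mat_dir, "features.tsv")) as fh:
        feats = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    with _open_text(_find(mat_dir, "barcodes.tsv")) as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None, dtype=str)[0].to_numpy()

    if counts.shape != (len(feats), len(barcodes)):
        raise ValueError(
            f"matrix {counts.shape} does not match {len(feats)} features × "
            f"{len(barcodes)} barcodes"
        )

    positions = _read_positions(directory)
    pos = positions.set_index("barcode")
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise ValueError(
            f"barcode(s) in matrix but absent from tissue positions: {missing[:5]}"
        )
    pos = pos.loc[barcodes]

    sm = SpotMatrix(
        counts=counts,
        gene_ids=feats[0].to_numpy(),
        gene_symbols=feats[1].to_numpy() if feats.shape[1] > 1 else feats[0].to_numpy(),
        barcodes=np.asarray(barcodes, dtype=object),
        array_row=pos["array_row"].to_numpy(int),
        array_col=pos["array_col"].to_numpy(int),
        pxl_row=pos["pxl_row_in_fullres"].to_numpy(float),
        pxl_col=pos["pxl_col_in_fullres"].to_numpy(float),
        in_tissue=pos["in_tissue"].to_numpy(int).astype(bool),
        sample_id=directory.name,
    )
    if not keep_all_spots:
        sm = sm.subset_spots(sm.in_tissue)
    return sm


def _read_positions(directory: Path) -> pd.DataFrame:
    spatial = directory / "spatial"
    search = [directory, spatial] if spatial.is_dir() else [directory]
    for d in search:
        for name in (
            "tissue_positions.csv",
            "tissue_positions.csv.gz",
            "tissue_positions_list.csv",
            "tissue_positions_list.csv.gz",
        ):
            p = d / name
            if p.exists():
                headerless = "list" in name
                df = pd.read_csv(p, header=None if headerless else 0)
                if headerless:
                    df.columns = _POSITION_COLUMNS
                else:
                    df = df.rename(columns={df.columns[0]: "barcode"})
                missing = set(_POSITION_COLUMNS) - set(df.columns)
                if missing:
                    raise ValueError(f"positions file {p} lacks columns {missing}")
                return df
    raise FileNotFoundError(f"no tissue positions file under {directory}")


def write_spaceranger(sample: SpotMatrix, directory, compress: bool = False) -> Path:
    """Write ``sample`` as a Space Ranger-style directory (inverse of
    :func:`read_spaceranger`); MTX entries are written 1-based per the
    Matrix Market convention."""
    if sample.n_spots < 1:
        raise ValueError("cannot write a sample with zero spots")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    coo = sample.counts.tocoo()
    mtx_path = directory / f"matrix.mtx{suffix}"
    opener = gzip.open if compress else open
    with opener(mtx_path, "wt") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{sample.n_genes} {sample.n_spots} {coo.nnz}\n")
        order = np.lexsort((coo.row, coo.col))
        for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{r + 1} {c + 1} {int(v)}\n")

    feats = pd.DataFrame(
        {
            "id": sample.gene_ids,
            "symbol": sample.gene_symbols,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(directory / f"features.tsv{suffix}", sep="\t", header=False, index=False)
    pd.Series(sample.barcodes).to_csv(
        directory / f"barcodes.tsv{suffix}", sep="\t", header=False, index=False
    )
    pos = pd.DataFrame(
        {
            "barcode": sample.barcodes,
            "in_tissue": sample.in_tissue.astype(int),
            "array_row": sample.array_row,
            "array_col": sample.array_col,
            "pxl_row_in_fullres": sample.pxl_row,
            "pxl_col_in_fullres": sample.pxl_col,
        }
    )
    pos.to_csv(directory / "tissue_positions.csv", index=False)
    return directory


# ---------------------------------------------------------------------------
# QC / annotation / merging
# ---------------------------------------------------------------------------


def qc_filter_spots(sample: SpotMatrix, min_genes: int = 200):
    """Remove spots with fewer than ``min_genes`` detected genes.

    A gene is "detected" in a spot when its UMI count is >= 1.  Spots with a
    detected-gene count strictly below ``min_genes`` are removed; retained
    counts are untouched and genes are unchanged.

    Returns
    -------
    filtered : SpotMatrix
    removed : pandas.DataFrame
        Removal log with the barcode and detected-gene count of each
        discarded spot.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    detected = sample.detected_genes_per_spot()
    keep = detected >= min_genes
    removed = pd.DataFrame(
        {
            "sample_id": sample.sample_id,
            "barcode": sample.barcodes[~keep],
            "detected_genes": detected[~keep],
        }
    )
    return sample.subset_spots(keep), removed


def read_annotations(annotation_csv, cluster_map_csv, samples: SampleSet) -> SpotAnnotation:
    """Load per-spot cluster annotations and a cluster→compartment map.

    ``annotation_csv`` needs columns ``sample_id, barcode, cluster_id``;
    ``cluster_map_csv`` needs ``cluster_id, compartment``.  Clusters without
    a map entry land in compartment "other" with a warning; annotation rows
    naming a barcode not present in ``samples`` raise.
    """
    ann = pd.read_csv(annotation_csv, dtype={"sample_id": str, "barcode": str})
    cmap_df = pd.read_csv(cluster_map_csv)
    cluster_map = dict(zip(cmap_df["cluster_id"].astype(str), cmap_df["compartment"]))
    bad = set(cmap_df["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown compartment(s) in cluster map: {sorted(bad)}")
    if ann.empty:
        warnings.warn("empty annotation CSV", stacklevel=2)
        ann = pd.DataFrame(columns=["sample_id", "barcode", "cluster_id"])
    known = {(s.sample_id, b) for s in samples for b in s.barcodes}
    offenders = [
        (r.sample_id, r.barcode)
        for r in ann.itertuples()
        if (r.sample_id, r.barcode) not in known
    ]
    if offenders:
        raise ValueError(f"annotation references unknown barcode(s): {offenders[:5]}")
    unmapped = sorted(set(ann["cluster_id"].astype(str)) - set(cluster_map))
    if unmapped:
        warnings.warn(
            f"clusters without compartment mapping assigned 'other': {unmapped}",
            stacklevel=2,
        )
    ann = ann.copy()
    ann["compartment"] = (
        ann["cluster_id"].astype(str).map(cluster_map).fillna("other")
    )
    return SpotAnnotation(table=ann, cluster_map=cluster_map)


def annotation_from_arrays(samples: SampleSet, clusters: dict, cluster_map: dict) -> SpotAnnotation:
    """Build a SpotAnnotation from in-memory per-sample cluster label arrays."""
    rows = []
    for s in samples:
        labels = np.asarray(clusters[s.sample_id])
        if labels.shape != (s.n_spots,):
            raise ValueError(f"cluster labels misaligned for {s.sample_id}")
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "barcode": s.barcodes,
                    "cluster_id": labels,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["compartment"] = (
        table["cluster_id"].astype(str).map({str(k): v for k, v in cluster_map.items()}).fillna("other")
    )
    return SpotAnnotation(table=table, cluster_map=cluster_map)


def merge_samples(samples: SampleSet) -> SpotMatrix:
    """Concatenate samples over the intersection of their gene symbols.

    Barcodes are prefixed ``<sample_id>_`` to keep them unique; the gene
    universe is the (ordered by the first sample) intersection of symbols.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    shared = set(samples[0].gene_symbols)
    for s in samples:
        shared &= set(s.gene_symbols)
    if not shared:
        raise ValueError("gene symbol intersection across samples is empty")
    order = [g for g in samples[0].gene_symbols if g in shared]

    blocks, barcodes, a_row, a_col, p_row, p_col, tissue = [], [], [], [], [], [], []
    for s in samples:
        pos = {g: i for i, g in enumerate(s.gene_symbols)}
        rows = np.array([pos[g] for g in order])
        blocks.append(s.counts[rows])
        barcodes.append([f"{s.sample_id}_{b}" for b in s.barcodes])
        a_row.append(s.array_row)
        a_col.append(s.array_col)
        p_row.append(s.pxl_row)
        p_col.append(s.pxl_col)
        tissue.append(s.in_tissue)

    first = samples[0]
    fpos = {g: i for i, g in enumerate(first.gene_symbols)}
    gene_ids = first.gene_ids[[fpos[g] for g in order]]
    return SpotMatrix(
        counts=sp.hstack(blocks).tocsr(),
        gene_ids=gene_ids,
        gene_symbols=np.asarray(order, dtype=object),
        barcodes=np.concatenate(barcodes),
        array_row=np.concatenate(a_row),
        array_col=np.concatenate(a_col),
        pxl_row=np.concatenate(p_row),
        pxl_col=np.concatenate(p_col),
        in_tissue=np.concatenate(tissue),
        sample_id="merged",
    )
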