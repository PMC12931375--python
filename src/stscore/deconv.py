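"""Per-spot cell-type prediction scores by nonnegative signature regression.

Each spot's CP10K expression profile is regressed onto reference cell-type
signature columns (per-type mean profiles, unit L1 norm) under a
nonnegativity constraint; the coefficients, normalized to sum to one, act
as per-spot prediction scores in [0, 1] for every reference type.  This is
a deliberately simple stand-in for anchor-based label transfer: it keeps
the same output contract (one probability-like score per spot per
reference cluster) while being exactly testable by mixture recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls

from .io import SpotAnnotation, SpotMatrix

__all__ = [
    "SignatureMatrix",
    "DeconvScores",
    "build_signatures",
    "score_spots",
    "fraction_above",
]


@dataclass
class SignatureMatrix:
    """Gene × cell-type reference signature profiles (unit L1 columns)."""

    profiles: pd.DataFrame  # index: gene symbols, columns: cell types

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy(float)
        if (vals < 0).any():
            raise ValueError("signature profiles must be nonnegative")
        colsums = vals.sum(axis=0)
        if np.any(colsums == 0):
            dead = list(self.profiles.columns[colsums == 0])
            raise ValueError(f"all-zero signature column(s): {dead}")

    @property
    def celltypes(self) -> list:
        return list(self.profiles.columns)

    @property
    def genes(self) -> list:
        return list(self.profiles.index)

    def to_csv(self, path) -> None:
        self.profiles.to_csv(path)


@dataclass
class DeconvScores:
    """Spot × cell-type prediction scores; rows sum to 1 unless flagged."""

    scores: pd.DataFrame  # index: barcodes, columns: cell types
    all_zero: np.ndarray  # flag: NNLS returned the zero vector
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(float)
        ok = ~np.asarray(self.all_zero, bool)
        if vals.size and ((vals < -1e-12).any() or (vals > 1 + 1e-12).any()):
            raise ValueError("scores must lie in [0, 1]")
        if ok.any() and not np.allclose(vals[ok].sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("unflagged score rows must sum to 1")

    def to_csv(self, path) -> None:
        out = self.scores.copy()
        out["all_zero"] = self.all_zero
        out.to_csv(path)


def build_signatures(profiles, celltypes=None, cell_counts=None) -> SignatureMatrix:
    """Build a :class:`SignatureMatrix` from per-type mean profiles.

    ``profiles`` is a genes × types DataFrame (or array with ``celltypes``
    names); each column is scaled to unit L1 norm.  ``cell_counts`` (per
    type) guards against reference types backed by zero cells.
    """
    if not isinstance(profiles, pd.DataFrame):
        profiles = pd.DataFrame(np.asarray(profiles, float), columns=celltypes)
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    names = list(profiles.columns)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate cell type names: {names}")
    if cell_counts is not None:
        empty = [t for t in names if cell_counts.get(t, 0) == 0]
        if empty:
            raise ValueError(f"cell type(s) with zero cells: {empty}")
    vals = profiles.to_numpy(float)
    colsums = vals.sum(axis=0)
    if np.any(colsums == 0):
        raise ValueError(
            f"all-zero profile column(s): {list(profiles.columns[colsums == 0])}"
        )
    return SignatureMatrix(profiles=profiles / colsums)


def score_spots(sample: SpotMatrix, signatures: SignatureMatrix) -> DeconvScores:
    """Nonnegative least-squares prediction scores for every spot.

    The spot's counts on the genes shared with the signatures are scaled to
    CP10K (using the spot's total over shared genes), regressed onto the
    signature columns with NNLS, and the coefficients normalized to sum to
    one.  Spots whose NNLS solution is identically zero (e.g. empty spots)
    are flagged rather than normalized.
    """
    shared = [g for g in signatures.genes if g in set(sample.gene_symbols)]
    if not shared:
        raise ValueError("no genes shared between sample and signatures")
    sym_idx = sample.symbol_index()
    rows = np.array([sym_idx[g] for g in shared])
    X = sample.counts[rows].toarray().astype(float)  # shared genes × spots
    scores, all_zero = score_profiles(X, signatures.profiles.loc[shared].to_numpy(float))
    return DeconvScores(
        scores=pd.DataFrame(scores, index=list(sample.barcodes), columns=signatures.celltypes),
        all_zero=all_zero,
        sample_id=sample.sample_id,
    )


def score_profiles(profiles: np.ndarray, signatures: np.ndarray):
    """NNLS scores for raw genes × spots profiles against genes × types
    signature columns; profiles are depth-normalized to CP10K first.

    Returns ``(scores, all_zero)`` with scores rows normalized to sum 1.
    """
    profiles = np.asarray(profiles, float)
    S = np.asarray(signatures, float)
    n_spots = profiles.shape[1]
    totals = profiles.sum(axis=0)
    coefs = np.zeros((n_spots, S.shape[1]))
    for j in range(n_spots):
        if totals[j] == 0:
            continue
        coefs[j], _ = nnls(S, profiles[:, j] * (1e4 / totals[j]))
    sums = coefs.sum(axis=1)
    all_zero = sums == 0
    scores = np.divide(
        coefs, sums[:, None], out=np.zeros_like(coefs), where=~all_zero[:, None]
    )
    return scores, all_zero


def fraction_above(
    scores: DeconvScores,
    celltype: str,
    threshold: float = 0.5,
    annotation: SpotAnnotation | None = None,
    scope: str = "total",
    strict: bool = True,
) -> dict:
    """Percentage of spots in scope whose ``celltype`` score exceeds
    ``threshold`` (strict ``>`` by default, matching "above 0.5").

    Returns ``{"percent", "numerator", "denominator", "missing"}``; an empty
    scope yields a flagged missing value, never a silent zero.
    """
    if celltype not in scores.scores.columns:
        raise KeyError(f"cell type {celltype!r} not in scores")
    vals = scores.scores[celltype].to_numpy(float)
    mask = np.ones(len(vals), dtype=bool)
    if scope != "total":
        if annotation is None:
            raise ValueError("annotation required for compartment scopes")
        comp = annotation.compartment_of(scores.sample_id, scores.scores.index)
        mask = comp == scope
    denom = int(mask.sum())
    if denom == 0:
        return {"percent": float("nan"), "numerator": 0, "denominator": 0, "missing": True}
    hits = vals[mask] > threshold if strict else vals[mask] >= threshold
    num = int(hits.sum())
    return {
        "percent": 100.0 * num / denom,
        "numerator": num,
        "denominator": denom,
        "missing": False,
    }
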