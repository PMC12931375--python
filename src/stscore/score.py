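"""Spot-level gene-set statistics: positivity, stratification, polarization,
co-occurrence and group comparisons.

These are the figure-level quantities of the spatial analysis: the percent
of spots in a biopsy (or one skin layer, cluster, or anchor-positive
stratum) positive for a gene panel under a k-of-n raw-count rule; the
M1-only / M2-only / both polarization split within CD68-positive spots;
conditional co-occurrence of apoptosis markers with the ISG signature; and
two-tailed t (or permutation) comparisons of per-sample percentages
between control and lesion groups.

Positivity is called on raw post-QC UMI counts (count ≥ 1 by default):
"expresses gene X" is read as a nonzero UMI observation, the only
threshold-free interpretation, and the rule is configurable through
``GeneSetPanel.min_count``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleSet, SpotAnnotation, SpotMatrix
from .panels import GeneSetPanel

__all__ = [
    "ScoreRecord",
    "GroupComparison",
    "positivity_matrix",
    "geneset_percent",
    "conditional_polarization",
    "conditional_percent",
    "cooccurrence_percent",
    "compare_groups",
]

SCORE_COLUMNS = [
    "sample_id",
    "group",
    "panel",
    "scope",
    "percent",
    "numerator",
    "denominator",
    "missing",
]


def _record(sample_id, group, panel, scope, numerator, denominator) -> dict:
    missing = denominator == 0
    return {
        "sample_id": sample_id,
        "group": group,
        "panel": panel,
        "scope": scope,
        "percent": float("nan") if missing else 100.0 * numerator / denominator,
        "numerator": int(numerator),
        "denominator": int(denominator),
        "missing": missing,
    }


ScoreRecord = dict
"""One ScoreReport row; see ``SCORE_COLUMNS``."""


def positivity_matrix(sample: SpotMatrix, panel: GeneSetPanel) -> np.ndarray:
    """Boolean per-spot panel positivity under the k-of-n rule.

    A spot is positive when at least ``panel.k_required`` panel genes have
    raw count ≥ ``panel.min_count``.  Panel genes absent from the sample's
    gene universe are dropped with a warning; if none remain this raises.
    """
    sym_idx = sample.symbol_index()
    rows = [sym_idx[g] for g in panel.genes if g in sym_idx]
    absent = [g for g in panel.genes if g not in sym_idx]
    if not rows:
        raise ValueError(f"no genes of panel {panel.name!r} present in sample")
    if absent:
        warnings.warn(
            f"panel {panel.name!r}: gene(s) absent from sample dropped: {absent}",
            stacklevel=2,
        )
    sub = sample.counts[np.asarray(rows)]
    n_hit = np.asarray((sub >= panel.min_count).sum(axis=0)).ravel()
    return n_hit >= panel.k_required


def _scope_mask(
    sample: SpotMatrix, annotation: SpotAnnotation | None, scope: str
) -> np.ndarray:
    if scope == "total":
        return np.ones(sample.n_spots, dtype=bool)
    if annotation is None:
        raise ValueError(f"annotation required for scope {scope!r}")
    if scope.startswith("cluster:"):
        wanted = scope.split(":", 1)[1]
        clusters = annotation.cluster_of(sample.sample_id, sample.barcodes)
        return np.array([str(c) == wanted for c in clusters])
    if scope in ("epidermis", "dermis", "other"):
        comp = annotation.compartment_of(sample.sample_id, sample.barcodes)
        return comp == scope
    raise ValueError(f"unknown scope {scope!r}")


def geneset_percent(
    samples: SampleSet,
    panel: GeneSetPanel,
    annotation: SpotAnnotation | None = None,
    scope: str = "total",
    per_gene: bool = False,
) -> pd.DataFrame:
    """Per-sample percent of scoped spots positive for ``panel``.

    ``scope`` is ``total``, ``epidermis``, ``dermis``, ``other`` or
    ``cluster:<id>``.  With ``per_gene=True`` each panel gene is reported as
    its own single-gene panel (per-gene ISG report style).  Empty scopes
    yield flagged missing records, never silent zeros.
    """
    panels = panel.single_gene_panels() if per_gene else [panel]
    rows = []
    for s in samples:
        mask = _scope_mask(s, annotation, scope)
        for p in panels:
            pos = positivity_matrix(s, p)
            rows.append(
                _record(
                    s.sample_id,
                    samples.group_of(s.sample_id),
                    p.name,
                    scope,
                    int((pos & mask).sum()),
                    int(mask.sum()),
                )
            )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def conditional_polarization(
    sample: SpotMatrix,
    anchor: GeneSetPanel,
    set_a: GeneSetPanel,
    set_b: GeneSetPanel,
    denominator: str = "marker_positive",
) -> dict:
    """A-only / B-only / both split among anchor-positive spots.

    Classifies each anchor-positive spot by which of the two (disjoint)
    marker panels it is positive for.  With the default denominator the
    three fractions are computed over anchor-positive spots positive for at
    least one panel, so they sum to exactly 100 (counts are kept as exact
    rationals until the final division); ``denominator="anchor"`` divides
    by all anchor-positive spots instead, adding a ``none`` remainder.
    """
    if set(set_a.genes) & set(set_b.genes):
        raise ValueError(
            f"panels {set_a.name!r} and {set_b.name!r} share genes; "
            "classification would be ambiguous"
        )
    if denominator not in ("marker_positive", "anchor"):
        raise ValueError(f"unknown denominator {denominator!r}")
    anchor_pos = positivity_matrix(sample, anchor)
    n_anchor = int(anchor_pos.sum())
    if n_anchor == 0:
        return {
            "sample_id": sample.sample_id,
            "a_only": float("nan"),
            "b_only": float("nan"),
            "both": float("nan"),
            "denominator": 0,
            "missing": True,
        }
    a = positivity_matrix(sample, set_a) & anchor_pos
    b = positivity_matrix(sample, set_b) & anchor_pos
    n_a_only = int((a & ~b).sum())
    n_b_only = int((b & ~a).sum())
    n_both = int((a & b).sum())
    denom = n_a_only + n_b_only + n_both if denominator == "marker_positive" else n_anchor
    if denom == 0:
        return {
            "sample_id": sample.sample_id,
            "a_only": float("nan"),
            "b_only": float("nan"),
            "both": float("nan"),
            "denominator": 0,
            "missing": True,
        }
    # exact rational fractions; the last share is taken as the float
    # complement so the reported percentages sum to exactly 100.0
    a_pct = float(100 * Fraction(n_a_only, denom))
    b_pct = float(100 * Fraction(n_b_only, denom))
    out = {
        "sample_id": sample.sample_id,
        "a_only": a_pct,
        "b_only": b_pct,
        "both": 100.0 - a_pct - b_pct
        if denominator == "marker_positive"
        else float(100 * Fraction(n_both, denom)),
        "denominator": denom,
        "missing": False,
    }
    if denominator == "anchor":
        out["none"] = 100.0 - a_pct - b_pct - out["both"]
    return out


def conditional_percent(
    sample: SpotMatrix, anchor: GeneSetPanel, target: GeneSetPanel
) -> dict:
    """Percent of anchor-positive spots that are also target-positive."""
    anchor_pos = positivity_matrix(sample, anchor)
    denom = int(anchor_pos.sum())
    if denom == 0:
        return _record(sample.sample_id, None, target.name, f"anchor:{anchor.name}+", 0, 0)
    target_pos = positivity_matrix(sample, target)
    return _record(
        sample.sample_id,
        None,
        target.name,
        f"anchor:{anchor.name}+",
        int((anchor_pos & target_pos).sum()),
        denom,
    )


def cooccurrence_percent(
    sample: SpotMatrix, conditioning: GeneSetPanel, outcome: GeneSetPanel
) -> dict:
    """Outcome-panel positivity inside vs outside the conditioning stratum.

    Returns the outcome-positive percentage among conditioning-positive and
    among conditioning-negative spots, each with its counts; an empty
    stratum is flagged missing.
    """
    cond = positivity_matrix(sample, conditioning)
    out_pos = positivity_matrix(sample, outcome)
    res = {"sample_id": sample.sample_id}
    for label, mask in (("positive", cond), ("negative", ~cond)):
        denom = int(mask.sum())
        num = int((out_pos & mask).sum())
        res[f"percent_in_{label}"] = float("nan") if denom == 0 else 100.0 * num / denom
        res[f"numerator_{label}"] = num
        res[f"denominator_{label}"] = denom
        res[f"missing_{label}"] = denom == 0
    return res


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Two-group comparison of per-sample percentages."""

    group_a: np.ndarray
    group_b: np.ndarray
    method: str
    statistic: float
    df: float
    p: float
    n_perm: int | None = None
    exact_permutations: bool = False

    def significance_label(self) -> str:
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return "ns"


def _t_statistic(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple:
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_groups(
    control,
    lesion,
    method: str = "student",
    n_perm: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Two-sided comparison of two groups of per-sample percentages.

    ``student`` is the pooled-variance two-sample t test (the default, as
    in common Prism workflows), ``welch`` drops the equal-variance
    assumption, and ``permutation`` uses the difference-of-means null: all
    C(n, k) relabelings exactly when they fit within ``n_perm``, otherwise
    ``n_perm`` Monte Carlo draws with the add-one estimator
    ``(1 + #{|T| ≥ |T_obs|}) / (1 + n_perm)``.
    """
    a = np.asarray(control, float)
    b = np.asarray(lesion, float)
    if method in ("student", "welch"):
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                "t tests need >= 2 samples per group; use method='permutation'"
            )
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # zero within-group variance: define t = 0, p = 1 for equal
            # means and a degenerate certain difference otherwise
            df = len(a) + len(b) - 2.0
            if a.mean() == b.mean():
                return GroupComparison(a, b, method, 0.0, df, 1.0)
            return GroupComparison(
                a, b, method, math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
            )
        t, df, p = _t_statistic(a, b, equal_var=(method == "student"))
        return GroupComparison(a, b, method, t, df, p)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate([a, b])
    n, k = len(pooled), len(a)
    obs = abs(a.mean() - b.mean())
    n_comb = math.comb(n, k)
    if n_comb <= n_perm:
        hits = 0
        for idx in combinations(range(n), k):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            t_perm = abs(pooled[sel].mean() - pooled[~sel].mean())
            if t_perm >= obs - 1e-12:
                hits += 1
        return GroupComparison(
            a, b, method, obs, float("nan"), hits / n_comb, n_comb, True
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:k].mean() - perm[k:].mean()) >= obs - 1e-12:
            hits += 1
    return GroupComparison(
        a, b, method, obs, float("nan"), (1 + hits) / (1 + n_perm), n_perm, False
    )
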