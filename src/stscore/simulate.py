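"""Synthetic Visium-like data with known ground truth.

The generator emulates the structure of a skin spatial-transcriptomics study
of a type I interferonopathy: several samples of hex-gridded spots split
into an epidermal band and a dermal remainder; a planted per-sample fraction
of "IFN-I inflamed" spots in which a six-gene interferon-stimulated-gene
(ISG) panel is boosted; macrophage-anchor (CD68) spots with conditional
M1-only / M2-only / both polarization marker co-expression; apoptosis-marker
positivity correlated with ISG status; optional rectangular myeloid
hot-spot blocks; a matched single-cell reference with disjoint planted
cluster markers; qPCR Ct tables with known fold changes; and labeled
segmentation masks with known cell areas.

Counts are negative binomial with variance mu + mu^2/theta.  "Positive"
spots receive a multiplicative mean boost rather than guaranteed nonzero
counts, so downstream positivity calling stays genuinely statistical; the
default 50x boost over a 0.05 baseline mean makes planted positives
near-deterministic while negatives stay sparse.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import SampleSet, SpotAnnotation, SpotMatrix, annotation_from_arrays
from .io import write_spaceranger as write_spaceranger_layout  # noqa: F401  re-export

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_scrna_reference",
    "generate_label_mask",
    "simulate_mixtures",
    "simulate_ct_table",
    "write_spaceranger_layout",
]

DEFAULT_ISG_PANEL = ["IFIT1", "USP18", "MX1", "IFI27", "IFI44L", "OAS1"]
DEFAULT_APOPTOSIS_PANEL = ["CASP3", "CASP8", "BAX", "BAK1", "CYCS"]
DEFAULT_M1_PANEL = ["FCGR3A", "FCGR1A"]
DEFAULT_M2_PANEL = ["CD163", "ARG1"]
DEFAULT_M1_CYTOKINES = ["IL1B", "TNF", "IL12B", "IL18"]
DEFAULT_M2_CYTOKINES = ["IL10", "ARG1", "TGFB1"]


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-sample Visium generator.

    Per-sample planted fractions follow the study design this generator
    emulates: three control biopsies with low background ISG positivity and
    three lesional biopsies planted at the lesion percentages the analysis
    should recover (0.90, 0.61, 0.90).
    """

    n_samples: int = 6
    groups: tuple = ("control", "control", "control", "lesion", "lesion", "lesion")
    grid_rows: int = 40
    grid_cols: int = 50
    epidermis_band_rows: int = 8
    inflamed_fraction: tuple = (0.05, 0.05, 0.05, 0.90, 0.61, 0.90)
    isg_panel: tuple = tuple(DEFAULT_ISG_PANEL)
    apoptosis_panel: tuple = tuple(DEFAULT_APOPTOSIS_PANEL)
    anchor_gene: str = "CD68"
    m1_panel: tuple = tuple(DEFAULT_M1_PANEL)
    m2_panel: tuple = tuple(DEFAULT_M2_PANEL)
    m1_cytokines: tuple = tuple(DEFAULT_M1_CYTOKINES)
    m2_cytokines: tuple = tuple(DEFAULT_M2_CYTOKINES)
    extra_panel_genes: tuple = ("IFNB1", "TGFB1", "ZBP1", "RIPK1", "MLKL")
    baseline_mean: float = 0.05
    panel_background_mean: float = 1e-4
    nb_dispersion: float = 10.0
    positive_boost: float = 50.0
    anchor_fraction: float = 0.25
    m1_given_anchor: float = 0.05
    m2_given_anchor: float = 0.75
    both_given_anchor: float = 0.05
    apoptosis_given_isg_pos: float = 0.6
    apoptosis_given_isg_neg: float = 0.2
    hotspot_blocks: int = 0
    hotspot_size: tuple = (5, 5)
    n_background_genes: int = 6000
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = np.atleast_1d(np.asarray(self.inflamed_fraction, dtype=float))
        if fracs.size == 1:
            fracs = np.repeat(fracs, self.n_samples)
        if fracs.size != self.n_samples:
            raise ValueError("inflamed_fraction must have one value per sample")
        self.inflamed_fraction = tuple(float(f) for f in fracs)
        props = {
            "anchor_fraction": self.anchor_fraction,
            "m1_given_anchor": self.m1_given_anchor,
            "m2_given_anchor": self.m2_given_anchor,
            "both_given_anchor": self.both_given_anchor,
            "apoptosis_given_isg_pos": self.apoptosis_given_isg_pos,
            "apoptosis_given_isg_neg": self.apoptosis_given_isg_neg,
            **{f"inflamed_fraction[{i}]": f for i, f in enumerate(fracs)},
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.m1_given_anchor + self.m2_given_anchor + self.both_given_anchor > 1 + 1e-12:
            raise ValueError("M1 + M2 + both conditional proportions exceed 1")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.epidermis_band_rows > self.grid_rows:
            raise ValueError("epidermis_band_rows exceeds grid_rows")
        if self.baseline_mean < 0 or self.nb_dispersion <= 0 or self.positive_boost <= 0:
            raise ValueError("baseline_mean >= 0, dispersion and boost > 0 required")
        if len(self.groups) != self.n_samples:
            raise ValueError("groups must have one label per sample")

    # -- gene universe --------------------------------------------------
    def panel_genes(self) -> list:
        seen: dict = {}
        for g in (
            list(self.isg_panel)
            + list(self.apoptosis_panel)
            + [self.anchor_gene]
            + list(self.m1_panel)
            + list(self.m2_panel)
            + list(self.m1_cytokines)
            + list(self.m2_cytokines)
            + list(self.extra_panel_genes)
        ):
            seen.setdefault(g, None)
        return list(seen)

    def gene_universe(self) -> list:
        background = [f"BG{i:05d}" for i in range(self.n_background_genes)]
        return self.panel_genes() + background

    def validate_panels(self) -> None:
        universe = set(self.gene_universe())
        for name in ("isg_panel", "apoptosis_panel", "m1_panel", "m2_panel",
                     "m1_cytokines", "m2_cytokines"):
            for g in getattr(self, name):
                if g not in universe:
                    raise ValueError(f"panel gene {g!r} ({name}) absent from gene universe")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload = {k: list(v) if isinstance(v, tuple) else v for k, v in payload.items()}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        payload = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - fields
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class GroundTruth:
    """Planted truth of one generated dataset, for recovery tests.

    ``spots`` holds one row per generated spot (sample_id, barcode,
    compartment, isg_positive, anchor, m1, m2, apoptosis flags);
    ``sample_fractions`` the planted per-sample fractions; ``scrna_markers``
    planted marker lists per reference cluster; ``mask_areas_um2`` true cell
    areas for generated label masks.
    """

    spots: pd.DataFrame
    sample_fractions: pd.DataFrame
    scrna_markers: dict = field(default_factory=dict)
    mask_areas_um2: dict = field(default_factory=dict)

    def export(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.spots.to_csv(directory / "truth_spots.csv", index=False)
        self.sample_fractions.to_csv(directory / "truth_fractions.csv", index=False)
        meta = {
            "scrna_markers": {str(k): list(v) for k, v in self.scrna_markers.items()},
            "mask_areas_um2": {str(k): [float(a) for a in v] for k, v in self.mask_areas_um2.items()},
        }
        (directory / "truth_meta.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# spot datasets
# ---------------------------------------------------------------------------


def _hex_positions(rows: int, cols: int):
    """Visium-style hex lattice: array_col parity matches array_row parity;
    pixel coordinates are an affine map of array coordinates."""
    r = np.repeat(np.arange(rows), cols)
    c = 2 * np.tile(np.arange(cols), rows) + (r % 2)
    pxl_row = 1000.0 + 120.0 * r
    pxl_col = 800.0 + 70.0 * c
    return r, c, pxl_row, pxl_col


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial draws with variance mu + mu^2/theta."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = theta / (theta + mean[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def generate_dataset(config: SimConfig):
    """Generate a multi-sample Visium-like dataset with planted truth.

    Returns ``(samples, annotation, truth)``: a :class:`SampleSet` of
    negative-binomial count matrices on hex grids, a compartment annotation
    (epidermal band vs dermis, cluster 0/1), and the :class:`GroundTruth`
    of every planted flag.  Bit-reproducible for a fixed ``config.seed``.
    """
    config.validate_panels()
    rng = np.random.default_rng(config.seed)
    genes = np.asarray(config.gene_universe(), dtype=object)
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    n_spots = config.grid_rows * config.grid_cols
    a_row, a_col, p_row, p_col = _hex_positions(config.grid_rows, config.grid_cols)
    compartment = np.where(a_row < config.epidermis_band_rows, "epidermis", "dermis")

    isg_rows = np.array([gidx[g] for g in config.isg_panel])
    apo_rows = np.array([gidx[g] for g in config.apoptosis_panel])
    anchor_row = gidx[config.anchor_gene]
    m1_rows = np.array([gidx[g] for g in set(config.m1_panel) | set(config.m1_cytokines)])
    m2_rows = np.array([gidx[g] for g in set(config.m2_panel) | set(config.m2_cytokines)])

    samples, truth_rows, frac_rows, clusters = [], [], {}, {}
    for s in range(config.n_samples):
        sample_id = f"{config.groups[s]}{sum(1 for g in config.groups[: s + 1] if g == config.groups[s])}"
        planted = config.inflamed_fraction[s]

        # exact-count planting: the planted fraction is the recovery target,
        # so it is realized exactly rather than as a Bernoulli draw
        isg_pos = np.zeros(n_spots, dtype=bool)
        isg_pos[rng.permutation(n_spots)[: round(planted * n_spots)]] = True
        anchor_pos = rng.random(n_spots) < config.anchor_fraction
        if config.hotspot_blocks:
            anchor_pos |= _hotspot_mask(config, a_row, a_col, rng)
        u = rng.random(n_spots)
        m1 = anchor_pos & (u < config.m1_given_anchor)
        m2 = anchor_pos & (u >= config.m1_given_anchor) & (
            u < config.m1_given_anchor + config.m2_given_anchor
        )
        both = anchor_pos & (u >= config.m1_given_anchor + config.m2_given_anchor) & (
            u < config.m1_given_anchor + config.m2_given_anchor + config.both_given_anchor
        )
        p_apo = np.where(isg_pos, config.apoptosis_given_isg_pos, config.apoptosis_given_isg_neg)
        apo_pos = rng.random(n_spots) < p_apo

        mean = np.full((n_genes, n_spots), config.baseline_mean)
        # panel genes are biologically near-silent in spots not flagged for
        # them (ISGs without IFN signaling, polarization markers outside
        # macrophage spots); flagged spots get the boosted mean
        positive_mean = config.baseline_mean * config.positive_boost
        for rows in (isg_rows, apo_rows, [anchor_row], m1_rows, m2_rows):
            mean[np.asarray(rows)] = config.panel_background_mean
        mean[np.ix_(isg_rows, np.flatnonzero(isg_pos))] = positive_mean
        mean[anchor_row, anchor_pos] = positive_mean
        mean[np.ix_(m1_rows, np.flatnonzero(m1 | both))] = positive_mean
        mean[np.ix_(m2_rows, np.flatnonzero(m2 | both))] = positive_mean
        mean[np.ix_(apo_rows, np.flatnonzero(apo_pos))] = positive_mean

        counts = sp.csr_matrix(_nb_sample(rng, mean, config.nb_dispersion))
        barcodes = np.array(
            [f"BC{r:03d}x{c:03d}-1" for r, c in zip(a_row, a_col)], dtype=object
        )
        samples.append(
            SpotMatrix(
                counts=counts,
                gene_ids=np.array([f"SYN{i:05d}" for i in range(n_genes)], dtype=object),
                gene_symbols=genes,
                barcodes=barcodes,
                array_row=a_row,
                array_col=a_col,
                pxl_row=p_row,
                pxl_col=p_col,
                in_tissue=np.ones(n_spots, dtype=bool),
                sample_id=sample_id,
            )
        )
        clusters[sample_id] = np.where(compartment == "epidermis", 0, 1)
        truth_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "barcode": barcodes,
                    "compartment": compartment,
                    "isg_positive": isg_pos,
                    "anchor": anchor_pos,
                    "m1": m1,
                    "m2": m2,
                    "both": both,
                    "apoptosis": apo_pos,
                }
            )
        )
        frac_rows[sample_id] = {
            "group": config.groups[s],
            "inflamed_fraction": planted,
            "anchor_fraction": config.anchor_fraction,
            "m1_given_anchor": config.m1_given_anchor,
            "m2_given_anchor": config.m2_given_anchor,
            "both_given_anchor": config.both_given_anchor,
            "apoptosis_given_isg_pos": config.apoptosis_given_isg_pos,
            "apoptosis_given_isg_neg": config.apoptosis_given_isg_neg,
        }

    sample_set = SampleSet(samples=samples, groups=list(config.groups))
    annotation = annotation_from_arrays(
        sample_set, clusters, cluster_map={0: "epidermis", 1: "dermis"}
    )
    truth = GroundTruth(
        spots=pd.concat(truth_rows, ignore_index=True),
        sample_fractions=pd.DataFrame.from_dict(frac_rows, orient="index")
        .rename_axis("sample_id")
        .reset_index(),
    )
    return sample_set, annotation, truth


def _hotspot_mask(config: SimConfig, a_row, a_col, rng) -> np.ndarray:
    mask = np.zeros(len(a_row), dtype=bool)
    h, w = config.hotspot_size
    for _ in range(config.hotspot_blocks):
        r0 = rng.integers(0, max(1, config.grid_rows - h))
        c0 = rng.integers(0, max(1, config.grid_cols - w))
        mask |= (
            (a_row >= r0)
            & (a_row < r0 + h)
            & (a_col // 2 >= c0)
            & (a_col // 2 < c0 + w)
        )
    return mask


# ---------------------------------------------------------------------------
# single-cell reference
# ---------------------------------------------------------------------------


def generate_scrna_reference(
    config: SimConfig,
    n_clusters: int = 5,
    markers_per_cluster: int = 40,
    cells_per_cluster: int = 100,
    marker_fold: float = 8.0,
    baseline_mean: float = 3.0,
):
    """Generate a single-cell reference with disjoint planted cluster markers.

    Returns ``(profiles, cells, labels, markers)``: per-cluster mean
    expression profiles (genes × clusters DataFrame), a sampled cell-level
    count matrix (genes × cells), per-cell cluster labels, and the planted
    marker dict.  Each cluster's markers have their mean multiplied by
    ``marker_fold`` in that cluster only.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 reference clusters")
    genes = np.asarray(config.gene_universe(), dtype=object)
    need = n_clusters * markers_per_cluster
    background = [g for g in genes if g.startswith("BG")]
    if need > len(background):
        raise ValueError(
            f"{need} requested markers exceed {len(background)} background genes"
        )
    rng = np.random.default_rng(config.seed + 1)
    chosen = rng.choice(len(background), size=need, replace=False)
    marker_genes = np.asarray(background, dtype=object)[np.sort(chosen)]
    markers = {
        f"scCluster{k}": list(marker_genes[k * markers_per_cluster : (k + 1) * markers_per_cluster])
        for k in range(n_clusters)
    }

    gidx = {g: i for i, g in enumerate(genes)}
    # reference baseline ~3 UMI/cell/gene over the expressed-gene panel
    # (≈18k UMIs/cell): deep enough that the rank test's normal
    # approximation is well calibrated in the far tail
    base = baseline_mean
    profiles = np.full((len(genes), n_clusters), base)
    for k, (name, mlist) in enumerate(markers.items()):
        rows = [gidx[g] for g in mlist]
        profiles[rows, k] *= marker_fold

    labels = np.repeat(np.arange(n_clusters), cells_per_cluster)
    mean = profiles[:, labels]
    cells = _nb_sample(rng, mean, config.nb_dispersion)
    profile_df = pd.DataFrame(profiles, index=genes, columns=list(markers))
    return profile_df, sp.csr_matrix(cells), labels, markers


# ---------------------------------------------------------------------------
# deconvolution mixtures
# ---------------------------------------------------------------------------


def simulate_mixtures(
    signatures: np.ndarray,
    weights: np.ndarray,
    depth: float = 2000.0,
    noise: str | None = "nb",
    theta: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate spot profiles as convex mixtures of signature columns.

    ``signatures`` is genes × types with unit-L1 columns; ``weights`` is
    spots × types with rows summing to 1.  Each spot's expected profile is
    ``depth * signatures @ w``; with ``noise="nb"`` counts are negative
    binomial around it, with ``None`` the expectation is returned exactly.
    """
    signatures = np.asarray(signatures, float)
    weights = np.asarray(weights, float)
    expected = depth * signatures @ weights.T  # genes × spots
    if noise is None:
        return expected
    if noise != "nb":
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    return _nb_sample(rng, expected, theta).astype(float)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    fold_changes: dict,
    n_replicates: int = 3,
    target_gene: str = "PDGFA",
    housekeeping_gene: str = "GAPDH",
    base_ct_target: float = 27.0,
    base_ct_housekeeping: float = 18.0,
    ct_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with known fold changes vs a reference group.

    ``fold_changes`` maps group name → true relative quantity (the reference
    group "reference" is implied at 1.0 and always generated).  A fold
    change F shifts the target Ct by −log2(F) relative to the reference
    ΔCT, so ΔΔCT recovery returns F exactly when ``ct_sd == 0``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    all_groups = {"reference": 1.0, **fold_changes}
    for group, fold in all_groups.items():
        if fold <= 0:
            raise ValueError(f"fold change for {group!r} must be positive")
        for i in range(n_replicates):
            ct_hk = base_ct_housekeeping + rng.normal(0.0, ct_sd)
            ct_t = base_ct_target - np.log2(fold) + (ct_hk - base_ct_housekeeping)
            ct_t += rng.normal(0.0, ct_sd)
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1}",
                    "group": "reference" if group == "reference" else "test",
                    "condition": group,
                    "target_gene": target_gene,
                    "housekeeping_gene": housekeeping_gene,
                    "ct_target": ct_t,
                    "ct_housekeeping": ct_hk,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# label masks
# ---------------------------------------------------------------------------


def generate_label_mask(
    n_cells: int,
    areas_um2: np.ndarray | None = None,
    mean_area_um2: float = 4000.0,
    sd_log_area: float = 0.35,
    pixel_size_um: float = 1.0,
    seed: int = 0,
    shape: tuple | None = None,
    max_tries: int = 200,
):
    """Render non-overlapping labeled disks with known areas.

    Cells are disks; ``areas_um2`` gives target areas directly, otherwise
    areas are log-normal around ``mean_area_um2``.  Returns ``(mask,
    true_areas_um2)`` where the truth is the *rendered* pixel count times
    the pixel area, so morphometry recovers it exactly.

    Raises if the requested cells cannot be placed without overlap.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    rng = np.random.default_rng(seed)
    if areas_um2 is None:
        areas_um2 = np.exp(
            rng.normal(np.log(mean_area_um2), sd_log_area, size=n_cells)
        )
    else:
        areas_um2 = np.asarray(areas_um2, float)
        if len(areas_um2) != n_cells:
            raise ValueError("areas_um2 length must equal n_cells")
    radii_px = np.sqrt(areas_um2 / np.pi) / pixel_size_um

    if shape is None:
        # size the canvas to keep packing density comfortably below ~30 %
        total_px = float(np.sum(np.pi * radii_px**2)) if n_cells else 10000.0
        side = int(np.ceil(np.sqrt(total_px / 0.25))) + int(2 * (radii_px.max() if n_cells else 10) + 4)
        shape = (side, side)
    mask = np.zeros(shape, dtype=np.int32)
    if n_cells and 2 * (radii_px.max() + 1) >= min(shape):
        raise RuntimeError(
            f"cell radius {radii_px.max():.0f}px does not fit canvas {shape}; "
            "enlarge the canvas or lower the areas"
        )

    centers = []
    for k, r in enumerate(radii_px, start=1):
        placed = False
        for _ in range(max_tries):
            cy = rng.uniform(r + 1, shape[0] - r - 1)
            cx = rng.uniform(r + 1, shape[1] - r - 1)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + 1.0) ** 2
                   for oy, ox, orad in centers):
                centers.append((cy, cx, r))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {k} of {n_cells} without overlap; "
                "lower the density or enlarge the canvas"
            )
        cy, cx, _ = centers[-1]
        y0, y1 = int(cy - r) - 1, int(cy + r) + 2
        x0, x1 = int(cx - r) - 1, int(cx + r) + 2
        yy, xx = np.ogrid[y0:y1, x0:x1]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        mask[y0:y1, x0:x1][disk] = k

    true_areas = np.array(
        [np.count_nonzero(mask == k) * pixel_size_um**2 for k in range(1, n_cells + 1)]
    )
    return mask, true_areas
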