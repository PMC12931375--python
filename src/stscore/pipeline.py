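"""End-to-end orchestration: simulate/read → QC → cluster → markers →
MIA/deconvolution → spot scores → group comparisons, with a run manifest.

The pipeline is deterministic under a fixed configuration and seed: every
random stage (simulation, k-means, permutation tests) derives its seed from
``PipelineConfig.seed``, and outputs are plain CSV/JSON so reruns are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconv import build_signatures, fraction_above, score_spots
from .io import SampleSet, read_spaceranger, qc_filter_spots
from .markers import cluster_spots, find_markers, normalize_counts, reduce_and_correct
from .mia import mia_enrichment
from .panels import GeneSetPanel, default_panels, load_panels
from .score import (
    compare_groups,
    conditional_percent,
    conditional_polarization,
    cooccurrence_percent,
    geneset_percent,
)
from .simulate import SimConfig, generate_dataset, generate_scrna_reference
from .io import merge_samples

logger = logging.getLogger("stscore")

# Figure-level statistic → the emitted report that carries it.
FIGURE_REPORT_MAP = {
    "per-gene ISG percent, total biopsy": "isg_per_gene_total",
    "any-of-six ISG percent, total": "isg_any_total",
    "any-of-six ISG percent, epidermis": "isg_any_epidermis",
    "any-of-six ISG percent, dermis": "isg_any_dermis",
    "IFNB1 percent, total": "ifnb1_total",
    "IFNB1 percent, epidermis": "ifnb1_epidermis",
    "IFNB1 percent, dermis": "ifnb1_dermis",
    "myeloid score above 0.5, total": "deconv_fraction_above",
    "M1/M2/both polarization within CD68+": "polarization_in_anchor",
    "M1 cytokines within CD68+": "conditional_in_anchor",
    "M2 cytokines within CD68+": "conditional_in_anchor",
    "TGFB1 percent, total biopsy": "tgfb1_total",
    "TGFB1 within CD68+": "conditional_in_anchor",
    "TGFB1 within cluster": "tgfb1_by_cluster",
    "apoptosis any-marker percent, total": "apoptosis_k1_total",
    "apoptosis 2-of-5 percent by layer": "apoptosis_k2_total",
    "apoptosis 5-of-5 percent by layer": "apoptosis_k5_total",
    "necroptosis any-marker percent, total": "necroptosis_k1_total",
    "necroptosis per-gene percent": "necroptosis_per_gene_total",
    "apoptosis/ISG co-occurrence": "apoptosis_isg_cooccurrence",
    "ZBP1 percent by layer": "zbp1_total",
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``sample_dirs``/``groups`` point at Space Ranger-style
    directories, or ``simulate`` carries a :class:`SimConfig` and the input
    data are generated.  Thresholds mirror the analysis defaults: spot QC
    at 200 detected genes, raw-count positivity at 1 UMI, deconvolution
    threshold 0.5, MIA top 300 markers, Wilcoxon marker filters
    min_pct 0.25 / log2fc 0.25 / adjusted p 0.05.
    """

    out_dir: str = "stscore_run"
    sample_dirs: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    simulate: SimConfig | None = None
    panels_yaml: str | None = None
    min_genes: int = 200
    min_count: int = 1
    deconv_threshold: float = 0.5
    mia_top_n: int = 300
    marker_min_pct: float = 0.25
    marker_min_log2fc: float = 0.25
    marker_alpha: float = 0.05
    n_clusters: int = 2
    n_dims: int = 20
    seed: int = 0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        sim = payload.pop("simulate", None)
        cfg = cls(**payload)
        if sim is not None:
            cfg.simulate = SimConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
        return cfg


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_samples(config: PipelineConfig):
    if config.simulate is not None:
        samples, annotation, truth = generate_dataset(config.simulate)
        return samples, annotation, truth
    if not config.sample_dirs:
        raise PipelineError("input", "neither sample_dirs nor simulate configured")
    if len(config.groups) != len(config.sample_dirs):
        raise PipelineError("input", "one group label required per sample directory")
    mats = [read_spaceranger(d) for d in config.sample_dirs]
    return SampleSet(samples=mats, groups=list(config.groups)), None, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of output DataFrames and
    writes everything under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {}
    try:
        panels = load_panels(config.panels_yaml) if config.panels_yaml else default_panels()

        logger.info("stage input: loading samples")
        samples, annotation, truth = _load_samples(config)
        if truth is not None:
            truth.export(out / "ground_truth")

        logger.info("stage qc: min_genes=%d", config.min_genes)
        kept, logs = [], []
        for s in samples:
            f, removed = qc_filter_spots(s, min_genes=config.min_genes)
            if f.n_spots == 0:
                raise PipelineError("qc", f"no spots remain in sample {s.sample_id}")
            kept.append(f)
            logs.append(removed)
        samples = SampleSet(samples=kept, groups=list(samples.groups))
        pd.concat(logs, ignore_index=True).to_csv(out / "qc_removed_spots.csv", index=False)

        logger.info("stage cluster: merged embedding, k=%d", config.n_clusters)
        merged = merge_samples(samples)
        normalized = normalize_counts(merged.counts, method="log_cp10k")
        batches = np.array([b.split("_", 1)[0] for b in merged.barcodes])
        emb = reduce_and_correct(normalized, batches, n_dims=min(config.n_dims, merged.n_spots - 1))
        labels = cluster_spots(emb, k=config.n_clusters, seed=config.seed)
        pd.DataFrame(
            {"barcode": merged.barcodes, "batch": batches, "cluster": labels}
        ).to_csv(out / "clusters.csv", index=False)

        logger.info("stage markers: spatial clusters")
        st_markers = find_markers(
            normalized,
            labels,
            min_pct=config.marker_min_pct,
            min_log2fc=config.marker_min_log2fc,
            alpha=config.marker_alpha,
            gene_symbols=merged.gene_symbols,
        )
        st_markers.to_csv(out / "st_markers.csv", index=False)

        sim = config.simulate or SimConfig(seed=config.seed)
        logger.info("stage reference: synthetic single-cell reference")
        profiles, cells, cell_labels, planted = generate_scrna_reference(sim)
        sc_norm = normalize_counts(cells, method="log_cp10k")
        sc_markers = find_markers(
            sc_norm,
            cell_labels,
            min_pct=config.marker_min_pct,
            min_log2fc=config.marker_min_log2fc,
            alpha=config.marker_alpha,
            gene_symbols=np.asarray(profiles.index, dtype=object),
        )
        sc_markers["cluster_id"] = [f"scCluster{c}" for c in sc_markers["cluster_id"]]
        sc_markers.to_csv(out / "sc_markers.csv", index=False)

        logger.info("stage mia")
        universe = set(merged.gene_symbols[np.asarray((merged.counts > 0).sum(axis=1)).ravel() > 0])
        universe &= set(profiles.index)
        mia = mia_enrichment(
            st_markers, sc_markers, universe, top_n=config.mia_top_n,
            p_adj_max=config.marker_alpha, min_log2fc=config.marker_min_log2fc,
        )
        mia.to_csv(out / "mia_scores.csv", out / "mia_overlaps.csv")
        results["mia"] = mia

        logger.info("stage deconv")
        signatures = build_signatures(profiles)
        deconv_rows = []
        for s in samples:
            scores = score_spots(s, signatures)
            scores.to_csv(out / f"deconv_{s.sample_id}.csv")
            for ct in signatures.celltypes:
                r = fraction_above(scores, ct, threshold=config.deconv_threshold)
                deconv_rows.append({"sample_id": s.sample_id, "celltype": ct, **r})
        deconv_table = pd.DataFrame(deconv_rows)
        deconv_table.to_csv(out / "deconv_fraction_above.csv", index=False)
        results["deconv"] = deconv_table

        logger.info("stage score")
        score_frames = {}
        isg = panels["isg"]
        score_frames["isg_per_gene_total"] = geneset_percent(samples, isg, annotation, "total", per_gene=True)
        score_frames["isg_any_total"] = geneset_percent(samples, isg, annotation, "total")
        for comp in ("epidermis", "dermis"):
            score_frames[f"isg_any_{comp}"] = geneset_percent(samples, isg, annotation, comp)
            score_frames[f"ifnb1_{comp}"] = geneset_percent(samples, panels["ifnb1"], annotation, comp)
            score_frames[f"zbp1_{comp}"] = geneset_percent(samples, panels["zbp1"], annotation, comp)
        score_frames["ifnb1_total"] = geneset_percent(samples, panels["ifnb1"], annotation, "total")
        score_frames["zbp1_total"] = geneset_percent(samples, panels["zbp1"], annotation, "total")
        score_frames["tgfb1_total"] = geneset_percent(samples, panels["tgfb1"], annotation, "total")
        if annotation is not None:
            cluster_ids = sorted(set(annotation.table["cluster_id"].astype(str)))
            score_frames["tgfb1_by_cluster"] = pd.concat(
                [
                    geneset_percent(samples, panels["tgfb1"], annotation, f"cluster:{cl}")
                    for cl in cluster_ids
                ],
                ignore_index=True,
            )
        apo = panels["apoptosis"]
        score_frames["apoptosis_k1_total"] = geneset_percent(samples, apo, annotation, "total")
        for k in (2, 5):
            pk = apo.with_k(k)
            score_frames[f"apoptosis_k{k}_total"] = geneset_percent(samples, pk, annotation, "total")
            for comp in ("epidermis", "dermis"):
                score_frames[f"apoptosis_k{k}_{comp}"] = geneset_percent(samples, pk, annotation, comp)
        nec = panels["necroptosis"]
        score_frames["necroptosis_k1_total"] = geneset_percent(samples, nec, annotation, "total")
        score_frames["necroptosis_per_gene_total"] = geneset_percent(samples, nec, annotation, "total", per_gene=True)

        anchor = panels["anchor_cd68"]
        pol_rows, cond_rows, co_rows = [], [], []
        for s in samples:
            pol = conditional_polarization(s, anchor, panels["m1_markers"], panels["m2_markers"])
            pol["group"] = samples.group_of(s.sample_id)
            pol_rows.append(pol)
            for pname in ("m1_cytokines", "m2_cytokines", "tgfb1"):
                r = conditional_percent(s, anchor, panels[pname])
                r["group"] = samples.group_of(s.sample_id)
                cond_rows.append(r)
            co = cooccurrence_percent(s, isg, apo)
            co["group"] = samples.group_of(s.sample_id)
            co_rows.append(co)
        score_frames["polarization_in_anchor"] = pd.DataFrame(pol_rows)
        score_frames["conditional_in_anchor"] = pd.DataFrame(cond_rows)
        score_frames["apoptosis_isg_cooccurrence"] = pd.DataFrame(co_rows)

        for name, frame in score_frames.items():
            frame.to_csv(out / f"score_{name}.csv", index=False)
        results["scores"] = score_frames

        logger.info("stage compare")
        comparisons = []
        group_names = sorted(set(samples.groups))
        if len(group_names) == 2 and all(samples.groups.count(g) >= 2 for g in group_names):
            ga, gb = group_names
            for name, frame in score_frames.items():
                if "percent" not in frame.columns:
                    continue
                ok = frame.loc[~frame["missing"]]
                keys = [c for c in ("panel", "scope") if c in ok.columns]
                for strat, sub in ok.groupby(keys) if keys else [((), ok)]:
                    a = sub.loc[sub["group"] == ga, "percent"].to_numpy()
                    b = sub.loc[sub["group"] == gb, "percent"].to_numpy()
                    if len(a) < 2 or len(b) < 2:
                        continue
                    cmp = compare_groups(a, b, method="student")
                    comparisons.append(
                        {
                            "report": name,
                            "stratum": "/".join(map(str, np.atleast_1d(strat))),
                            "group_a": ga,
                            "group_b": gb,
                            "t": cmp.statistic,
                            "df": cmp.df,
                            "p": cmp.p,
                            "label": cmp.significance_label(),
                        }
                    )
        comp_table = pd.DataFrame(comparisons)
        comp_table.to_csv(out / "comparisons.csv", index=False)
        results["comparisons"] = comp_table

        manifest = {
            "stscore_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
            "n_samples": len(samples),
            "report_kinds": sorted(score_frames),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        results["manifest"] = manifest
        logger.info("pipeline complete: %s", out)
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
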