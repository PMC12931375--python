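"""Gene-set panel definitions and symbol aliasing.

Figure legends and clinical shorthand use protein-style names (IL-1β,
TNFα, CD16); panels are matched case-insensitively through a small alias
table onto HGNC symbols before any lookup against the count matrix.

The bundled defaults cover the skin interferonopathy readouts this package
scores: the six-gene ISG panel, apoptosis and necroptosis marker panels,
the CD68 macrophage anchor, M1/M2 polarization marker and cytokine panels,
and single-gene panels for IFNB1, TGFB1 and ZBP1.  M1/M2 marker
orientation follows the immunohistochemistry convention (CD16/FCGR3A = M1,
CD163 = M2); the opposite orientation is shipped as ``m1_markers_alt`` /
``m2_markers_alt`` because the literature is not unanimous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["GeneSetPanel", "load_panels", "default_panels", "resolve_symbol", "ALIASES"]

ALIASES = {
    "IL-1B": "IL1B",
    "IL-1β": "IL1B",
    "IL1β": "IL1B",
    "TNFA": "TNF",
    "TNFα": "TNF",
    "TNF-α": "TNF",
    "IL-12": "IL12B",
    "IL12": "IL12B",
    "IL-18": "IL18",
    "IL-10": "IL10",
    "ARG": "ARG1",
    "TGFB": "TGFB1",
    "TGFβ": "TGFB1",
    "TGF-β": "TGFB1",
    "CD16": "FCGR3A",
    "CD64": "FCGR1A",
    "IFNB": "IFNB1",
}
_ALIASES_UPPER = {k.upper(): v for k, v in ALIASES.items()}


def resolve_symbol(name: str) -> str:
    """Map a protein-style or mixed-case gene name onto its HGNC symbol."""
    up = str(name).strip().upper()
    return _ALIASES_UPPER.get(up, up)


@dataclass
class GeneSetPanel:
    """A named gene panel with a k-of-n positivity rule.

    A spot is panel-positive when at least ``k_required`` of the panel's
    genes have raw UMI count ≥ ``min_count``.
    """

    name: str
    genes: list
    k_required: int = 1
    min_count: int = 1

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} has no genes")
        self.genes = [resolve_symbol(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name!r} has duplicate genes after aliasing")
        if not 1 <= self.k_required <= len(self.genes):
            raise ValueError(
                f"panel {self.name!r}: k_required={self.k_required} outside [1, {len(self.genes)}]"
            )
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    def with_k(self, k_required: int) -> "GeneSetPanel":
        return GeneSetPanel(self.name, list(self.genes), k_required, self.min_count)

    def single_gene_panels(self) -> list:
        """One single-gene panel per member, for per-gene reports."""
        return [GeneSetPanel(g, [g], 1, self.min_count) for g in self.genes]


def load_panels(path) -> dict:
    """Load panels from YAML: ``name: [genes]`` or
    ``name: {genes: [...], k_required: int, min_count: int}``."""
    payload = yaml.safe_load(Path(path).read_text())
    panels = {}
    for name, spec in payload.items():
        if isinstance(spec, dict):
            panels[name] = GeneSetPanel(
                name=name,
                genes=list(spec["genes"]),
                k_required=int(spec.get("k_required", 1)),
                min_count=int(spec.get("min_count", 1)),
            )
        else:
            panels[name] = GeneSetPanel(name=name, genes=list(spec))
    return panels


def default_panels() -> dict:
    """The bundled default panel set."""
    with resources.as_file(
        resources.files("stscore").joinpath("data/default_panels.yaml")
    ) as p:
        return load_panels(p)
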