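"""Marker-based cell-population scoring and immune-class clustering.

Population abundance is estimated MCP-counter style: the score of a
population in a sample is the arithmetic mean of the log2 expression of its
marker genes. Scores are in arbitrary units but comparable across samples
within a population. The immune cell infiltration (ICI) score sums the
scores of the immune (non-stromal) populations; samples are assigned to
low/intermediate/high infiltration groups by tertiles, and to immune
classes IC1..ICk by agglomerative clustering of the per-population z-scored
score matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .expression import ExpressionMatrix

log = logging.getLogger(__name__)

IMMUNE = "immune"
STROMAL = "stromal"


@dataclass(frozen=True)
class Population:
    genes: tuple
    compartment: str = IMMUNE

    def __post_init__(self):
        if not self.genes:
            raise ValueError("population marker list must be non-empty")
        if self.compartment not in (IMMUNE, STROMAL):
            raise ValueError(f"compartment must be immune/stromal, got {self.compartment!r}")


@dataclass
class MarkerSet:
    """Mapping population name -> marker genes with an immune/stromal flag."""

    populations: Dict[str, Population]

    def __post_init__(self):
        if not self.populations:
            raise ValueError("marker set is empty")

    @property
    def immune_populations(self) -> List[str]:
        return [n for n, p in self.populations.items() if p.compartment == IMMUNE]

    @property
    def stromal_populations(self) -> List[str]:
        return [n for n, p in self.populations.items() if p.compartment == STROMAL]

    def all_genes(self) -> List[str]:
        out: List[str] = []
        for p in self.populations.values():
            out.extend(p.genes)
        return sorted(set(out))

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarkerSet":
        pops = {
            name: Population(tuple(spec["genes"]), spec.get("compartment", IMMUNE))
            for name, spec in d.items()
        }
        return cls(pops)

    @classmethod
    def from_yaml(cls, path) -> "MarkerSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        d = {
            name: {"genes": list(p.genes), "compartment": p.compartment}
            for name, p in self.populations.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


#: Default eight-population panel: six immune and two stromal populations,
#: small curated marker lists. The estimator, not the exact catalogue, is
#: the contract; the panel is fully user-overridable via config.
DEFAULT_MARKERS = MarkerSet(
    {
        "T cells": Population(("CD3D", "CD3E", "CD3G", "CD2", "TRAT1")),
        "B lineage": Population(("MS4A1", "CD79A", "CD19", "BANK1", "FCRL2")),
        "NK cells": Population(("KLRD1", "NCR1", "GNLY", "KIR2DL3")),
        "Monocytic lineage": Population(("CD14", "CSF1R", "CD163", "LYZ")),
        "Myeloid dendritic cells": Population(("CD1A", "CD1E", "CLEC10A")),
        "Neutrophils": Population(("FCGR3B", "CEACAM3", "CSF3R")),
        "Endothelial cells": Population(("VWF", "PECAM1", "CDH5", "CLEC14A"), STROMAL),
        "Fibroblasts": Population(("COL1A1", "COL3A1", "PDGFRB", "DCN"), STROMAL),
    }
)


@dataclass
class ICIResult:
    score: pd.Series  # per-sample ICI score
    group: pd.Series  # per-sample label in {low, intermediate, high}


def score_populations(log_expr: ExpressionMatrix, markers: MarkerSet) -> pd.DataFrame:
    """Per-sample mean log2 expression over each population's marker genes.

    Returns a samples x populations DataFrame. Markers absent from the
    matrix are dropped with a log line; a population with no marker present
    is an error.
    """
    if log_expr.unit != "log2":
        raise ValueError(f"score_populations expects log2 expression, got {log_expr.unit!r}")
    cols = {}
    for name, pop in markers.populations.items():
        present = [g for g in pop.genes if g in log_expr.values.index]
        absent = [g for g in pop.genes if g not in log_expr.values.index]
        if absent:
            log.info("population %r: %d marker(s) absent from matrix: %s", name, len(absent), absent)
        if not present:
            raise ValueError(f"population {name!r} has no marker gene present in the matrix")
        cols[name] = log_expr.values.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


def tertile_groups(values: pd.Series) -> pd.Series:
    """Assign low/intermediate/high by the empirical 1/3 and 2/3 quantiles
    (linear-interpolation definition); values tied with a boundary go to the
    lower group (<= convention)."""
    q1, q2 = np.quantile(values.to_numpy(dtype=float), [1 / 3, 2 / 3])
    out = pd.Series("high", index=values.index, dtype=object)
    out[values <= q2] = "intermediate"
    out[values <= q1] = "low"
    return out


def compute_ici(scores: pd.DataFrame, markers: MarkerSet) -> ICIResult:
    """ICI score = sum of immune-population scores (stromal excluded),
    with tertile infiltration groups."""
    immune = [p for p in markers.immune_populations if p in scores.columns]
    if not immune:
        raise ValueError("no immune population among the scored columns")
    ici = scores[immune].sum(axis=1)
    return ICIResult(score=ici, group=tertile_groups(ici))


def _zscore_columns(df: pd.DataFrame) -> np.ndarray:
    arr = df.to_numpy(dtype=float)
    mean = arr.mean(axis=0, keepdims=True)
    sd = arr.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (arr - mean) / sd


def cluster_immune_classes(
    scores: pd.DataFrame,
    markers: MarkerSet = DEFAULT_MARKERS,
    k: int = 6,
    method: str = "ward",
) -> pd.Series:
    """Cluster samples into immune classes IC1..ICk.

    Per-population z-scored scores are clustered agglomeratively (Euclidean
    distance; Ward linkage by default, ``complete`` available), the tree is
    cut at k clusters, and clusters are relabelled by ascending mean ICI so
    IC1 is the least-infiltrated class.
    """
    n = scores.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return pd.Series("IC1", index=scores.index, dtype=object)
    z = _zscore_columns(scores)
    Z = linkage(pdist(z, metric="euclidean"), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    ici = compute_ici(scores, markers).score
    order = (
        pd.Series(ici.to_numpy(), index=raw).groupby(level=0).mean().sort_values().index
    )
    relabel = {old: f"IC{i + 1}" for i, old in enumerate(order)}
    return pd.Series([relabel[c] for c in raw], index=scores.index, dtype=object)
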