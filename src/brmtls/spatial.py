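"""Lymphoid-aggregate detection and TLS calling from phenotyped cell maps.

Input is a per-sample table of cell coordinates (µm) with phenotypes from a
fixed vocabulary (T, B, DC, macrophage, tumor, endothelial, other) plus a
vessel point set. T and B lymphocytes are clustered with DBSCAN; each
cluster becomes an aggregate annotated with lymphocyte composition, nearby
dendritic-cell and macrophage counts, and distance to the nearest vessel.
An aggregate is called TLS when it is perivascular, contains at least 500
cells and has a predominance of B cells (> 50% of lymphocytes); the
presence of at least one Lamp3+ dendritic cell upgrades the call to
"intermediate TLS". A sample is TLS-positive iff it holds at least one
TLS or intermediate-TLS call; sub-threshold aggregates and diffuse
infiltration leave it negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

log = logging.getLogger(__name__)

PHENOTYPES = ("T", "B", "DC", "macrophage", "tumor", "endothelial", "other")
LYMPHOCYTES = ("T", "B")

CALL_TLS = "TLS"
CALL_INTERMEDIATE = "intermediate_TLS"
CALL_AGGREGATE = "aggregate"


@dataclass
class CellMap:
    """Phenotyped cells and vessel points of one tissue sample (µm units)."""

    cells: pd.DataFrame  # columns: x_um, y_um, phenotype
    vessels: np.ndarray  # (n, 2) vessel point coordinates
    sample_id: str = ""

    def __post_init__(self) -> None:
        required = {"x_um", "y_um", "phenotype"}
        if not required.issubset(self.cells.columns):
            raise ValueError(f"cell table must have columns {sorted(required)}")
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError("cell coordinates must be finite")
        bad = set(self.cells["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotype label(s): {sorted(bad)}")
        self.vessels = np.asarray(self.vessels, dtype=float).reshape(-1, 2)


@dataclass
class Aggregate:
    """A detected lymphoid aggregate and its TLS annotation."""

    members: np.ndarray  # row positions in the cell table (lymphocytes)
    n_cells: int
    n_B: int
    n_T: int
    n_DC: int
    n_macrophage: int
    centroid: Tuple[float, float]
    b_fraction: float
    vessel_distance_um: float = float("nan")
    perivascular: bool = False
    call: str = CALL_AGGREGATE


@dataclass
class SampleTLSStatus:
    sample_id: str
    status: str  # "positive" / "negative"
    tls_score: int  # count of TLS + intermediate_TLS calls
    aggregates: List[Aggregate] = field(default_factory=list)


def detect_aggregates(
    cmap: CellMap,
    eps_um: float = 30.0,
    min_pts: int = 10,
    b_fraction_denominator: str = "lymphocytes",
) -> List[Aggregate]:
    """Density-based clustering of T and B cells into aggregates.

    DBSCAN semantics: a core cell has at least ``min_pts`` lymphocytes
    (counting itself) within ``eps_um``; clusters are connected core
    neighbourhoods plus border points. Dendritic cells and macrophages are
    not clustered but are counted as belonging to an aggregate when they lie
    within ``eps_um`` of any member lymphocyte.
    """
    if eps_um <= 0:
        raise ValueError("eps_um must be positive")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    if b_fraction_denominator not in ("lymphocytes", "all"):
        raise ValueError("b_fraction_denominator must be 'lymphocytes' or 'all'")
    cells = cmap.cells.reset_index(drop=True)
    lymph_mask = cells["phenotype"].isin(LYMPHOCYTES).to_numpy()
    lymph_idx = np.flatnonzero(lymph_mask)
    if lymph_idx.size == 0:
        return []
    xy = cells.loc[lymph_idx, ["x_um", "y_um"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=eps_um, min_samples=min_pts).fit_predict(xy)

    dc_xy = cells.loc[cells["phenotype"] == "DC", ["x_um", "y_um"]].to_numpy(dtype=float)
    mac_xy = cells.loc[cells["phenotype"] == "macrophage", ["x_um", "y_um"]].to_numpy(dtype=float)

    out: List[Aggregate] = []
    for lab in sorted(set(labels) - {-1}):
        sel = labels == lab
        members = lymph_idx[sel]
        member_xy = xy[sel]
        phen = cells.loc[members, "phenotype"]
        n_b = int((phen == "B").sum())
        n_t = int((phen == "T").sum())
        tree = cKDTree(member_xy)
        n_dc = int(np.sum(tree.query(dc_xy)[0] <= eps_um)) if dc_xy.size else 0
        n_mac = int(np.sum(tree.query(mac_xy)[0] <= eps_um)) if mac_xy.size else 0
        denom = (n_b + n_t) if b_fraction_denominator == "lymphocytes" else len(members)
        out.append(
            Aggregate(
                members=members,
                n_cells=int(len(members)),
                n_B=n_b,
                n_T=n_t,
                n_DC=n_dc,
                n_macrophage=n_mac,
                centroid=(float(member_xy[:, 0].mean()), float(member_xy[:, 1].mean())),
                b_fraction=(n_b / denom) if denom else 0.0,
            )
        )
    return out


def is_perivascular(
    agg: Aggregate, vessels: np.ndarray, d_max_um: float = 50.0
) -> bool:
    """True iff the aggregate centroid lies within d_max of a vessel point."""
    if d_max_um <= 0:
        raise ValueError("d_max_um must be positive")
    vessels = np.asarray(vessels, dtype=float).reshape(-1, 2)
    if vessels.shape[0] == 0:
        log.warning("no vessel points in sample; aggregate treated as non-perivascular")
        agg.vessel_distance_um = float("inf")
        agg.perivascular = False
        return False
    d = np.sqrt(((vessels - np.asarray(agg.centroid)) ** 2).sum(axis=1)).min()
    agg.vessel_distance_um = float(d)
    agg.perivascular = bool(d <= d_max_um)
    return agg.perivascular


def classify_aggregate(
    agg: Aggregate, min_cells: int = 500, min_b_fraction: float = 0.5
) -> str:
    """Apply the TLS calling rules.

    Perivascular, >= min_cells member cells and a strict B-cell predominance
    (B fraction > min_b_fraction) make a TLS; at least one dendritic cell in
    addition upgrades it to intermediate TLS; anything else stays a plain
    aggregate.
    """
    if agg.perivascular and agg.n_cells >= min_cells and agg.b_fraction > min_b_fraction:
        agg.call = CALL_INTERMEDIATE if agg.n_DC >= 1 else CALL_TLS
    else:
        agg.call = CALL_AGGREGATE
    return agg.call


def sample_status(aggregates: Sequence[Aggregate], sample_id: str = "") -> SampleTLSStatus:
    """Positive iff any aggregate is called TLS or intermediate TLS; the TLS
    score counts those calls."""
    n_tls = sum(1 for a in aggregates if a.call in (CALL_TLS, CALL_INTERMEDIATE))
    return SampleTLSStatus(
        sample_id=sample_id,
        status="positive" if n_tls > 0 else "negative",
        tls_score=n_tls,
        aggregates=list(aggregates),
    )


def analyze_cell_map(
    cmap: CellMap,
    eps_um: float = 30.0,
    min_pts: int = 10,
    min_cells: int = 500,
    min_b_fraction: float = 0.5,
    perivascular_dist_um: float = 50.0,
    b_fraction_denominator: str = "lymphocytes",
) -> SampleTLSStatus:
    """Full per-sample pipeline: detect, annotate, classify, summarise."""
    aggs = detect_aggregates(cmap, eps_um, min_pts, b_fraction_denominator)
    for a in aggs:
        is_perivascular(a, cmap.vessels, perivascular_dist_um)
        classify_aggregate(a, min_cells, min_b_fraction)
    return sample_status(aggs, cmap.sample_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cell_maps(cells_path, vessels_path) -> List[CellMap]:
    """Read a multi-sample cell CSV (sample,x_um,y_um,phenotype) and vessel
    CSV (sample,x_um,y_um) into per-sample CellMaps."""
    cells = pd.read_csv(cells_path)
    vessels = pd.read_csv(vessels_path)
    out = []
    for sid, grp in cells.groupby("sample", sort=True):
        v = vessels.loc[vessels["sample"] == sid, ["x_um", "y_um"]].to_numpy(dtype=float)
        out.append(
            CellMap(
                cells=grp[["x_um", "y_um", "phenotype"]].reset_index(drop=True),
                vessels=v,
                sample_id=str(sid),
            )
        )
    return out


def aggregates_table(statuses: Sequence[SampleTLSStatus]) -> pd.DataFrame:
    rows = []
    for st in statuses:
        for i, a in enumerate(st.aggregates):
            rows.append(
                {
                    "sample": st.sample_id,
                    "aggregate": i,
                    "n_cells": a.n_cells,
                    "n_B": a.n_B,
                    "n_T": a.n_T,
                    "n_DC": a.n_DC,
                    "n_macrophage": a.n_macrophage,
                    "b_fraction": a.b_fraction,
                    "centroid_x_um": a.centroid[0],
                    "centroid_y_um": a.centroid[1],
                    "vessel_distance_um": a.vessel_distance_um,
                    "perivascular": a.perivascular,
                    "call": a.call,
                }
            )
    cols = [
        "sample", "aggregate", "n_cells", "n_B", "n_T", "n_DC", "n_macrophage",
        "b_fraction", "centroid_x_um", "centroid_y_um", "vessel_distance_um",
        "perivascular", "call",
    ]
    return pd.DataFrame(rows, columns=cols)


def status_table(statuses: Sequence[SampleTLSStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [s.sample_id for s in statuses],
            "status": [s.status for s in statuses],
            "tls_score": [s.tls_score for s in statuses],
            "n_aggregates": [len(s.aggregates) for s in statuses],
        }
    )
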