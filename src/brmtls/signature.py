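"""TLS metagene construction, scoring, class assignment and cytolytic score.

The candidate compendium collects six published TLS-related gene lists
(12-chemokine signature, B-cell markers, activated dendritic-cell markers,
a melanoma-derived TLS list, TLS hallmark genes, and a Tfh signature). The
metagene for a cohort is built by correlating every candidate gene with the
seed score (geometric-mean score of the 12-chemokine genes) and discarding
genes with low expression or a correlation below the configured threshold
(by default, any negative correlation). Per-sample signature scores are
geometric means of TPM+1; classes TLS1 < TLS2 < TLS3 come from Ward
clustering of the z-scored signature genes, and the survival stratification
uses a median split of the score.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .expression import ExpressionMatrix, zscore_genes

log = logging.getLogger(__name__)

CHEMOKINE12 = (
    "CCL2", "CCL3", "CCL4", "CCL5", "CCL8", "CCL18",
    "CCL19", "CCL21", "CXCL9", "CXCL10", "CXCL11", "CXCL13",
)

#: Named source lists of the TLS candidate compendium.
DEFAULT_COMPENDIUM: Dict[str, Tuple[str, ...]] = {
    "chemokine12": CHEMOKINE12,
    "b_cell": (
        "BANK1", "CD19", "CD22", "CD79A", "CR2", "CR1",
        "FCRL2", "MS4A1", "PAX5", "FCER2", "MZB1",
    ),
    "dendritic": ("LAMP3", "CD80", "CD83", "CD86", "CCR7"),
    "melanoma_tls": (
        "CD79B", "RBP5", "EIF1AY", "CETP", "SKAP1",
        "LAT", "CCR6", "CD1D", "PTGDS",
    ),
    "hallmark": ("CCL19", "CCL21", "CXCL13", "CCR7", "CXCR5", "SELL", "LAMP3"),
    "tfh": ("CXCL13", "CD200", "FBLN7", "ICOS", "SGPP2", "SH2D1A", "TIGIT", "PDCD1"),
}

CYTOLYTIC_GENES = ("GZMA", "PRF1")


def candidate_union(compendium: Mapping[str, Iterable[str]] = DEFAULT_COMPENDIUM) -> pd.Series:
    """Union of the compendium lists, duplicates removed.

    Returns a Series indexed by sorted gene symbol whose values are the
    tuple of source-list names the gene appears in (its provenance).
    """
    prov: Dict[str, List[str]] = {}
    for source, genes in compendium.items():
        for g in genes:
            prov.setdefault(g, [])
            if source not in prov[g]:
                prov[g].append(source)
    genes_sorted = sorted(prov)
    return pd.Series({g: tuple(prov[g]) for g in genes_sorted}, name="sources")


def metagene_score(
    expr: ExpressionMatrix,
    genes: Iterable[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample geometric mean of (expression + pseudocount) over a gene set.

    score(s) = exp(mean_g ln(x_gs + 1)); the +1 convention is reported
    without back-subtraction. Genes absent from the matrix are dropped with
    a warning; no gene present is an error.
    """
    genes = list(genes)
    present = [g for g in genes if g in expr.values.index]
    absent = [g for g in genes if g not in expr.values.index]
    if absent:
        log.warning("metagene_score: %d gene(s) absent from matrix: %s", len(absent), absent[:10])
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    logs = np.log(expr.values.loc[present].to_numpy(dtype=float) + pseudocount)
    return pd.Series(np.exp(logs.mean(axis=0)), index=expr.values.columns, name="tls_score")


def build_signature(
    expr: ExpressionMatrix,
    compendium: Mapping[str, Iterable[str]] = DEFAULT_COMPENDIUM,
    min_mean_expr: float = 1.0,
    min_r: float = 0.0,
    seed_genes: Iterable[str] = CHEMOKINE12,
) -> pd.DataFrame:
    """Construct the cohort-specific TLS signature.

    The seed score is the geometric-mean score of the 12-chemokine genes.
    Every candidate gene present in the matrix is correlated (Pearson) with
    the seed score; genes with mean expression below ``min_mean_expr`` or a
    correlation below ``min_r`` are discarded. The remaining genes are
    returned ordered by descending correlation, with provenance, r and mean
    expression recorded per gene.
    """
    if expr.shape[1] < 3:
        raise ValueError("signature construction requires at least 3 samples")
    seed_genes = list(seed_genes)
    missing_seed = [g for g in seed_genes if g not in expr.values.index]
    if missing_seed:
        raise ValueError(f"seed genes absent from matrix: {missing_seed}")
    seed = metagene_score(expr, seed_genes).to_numpy()
    if np.std(seed) == 0:
        raise ValueError("seed score is constant; correlation undefined")
    union = candidate_union(compendium)
    rows = []
    for gene, sources in union.items():
        if gene not in expr.values.index:
            log.info("candidate %s absent from matrix; skipped", gene)
            continue
        x = expr.values.loc[gene].to_numpy(dtype=float)
        mean_expr = float(x.mean())
        if mean_expr < min_mean_expr:
            rows.append((gene, ";".join(sources), np.nan, mean_expr, False))
            continue
        if np.std(x) == 0:
            log.warning("candidate %s is constant; discarded", gene)
            rows.append((gene, ";".join(sources), np.nan, mean_expr, False))
            continue
        r = float(pearsonr(x, seed)[0])
        rows.append((gene, ";".join(sources), r, mean_expr, r >= min_r))
    df = pd.DataFrame(
        rows, columns=["gene", "sources", "r", "mean_expr", "keep"]
    ).set_index("gene")
    dropped = df.index[~df["keep"]].tolist()
    if dropped:
        log.info("build_signature: discarded %d candidate(s): %s", len(dropped), dropped)
    return df[df["keep"]].drop(columns="keep").sort_values("r", ascending=False)


def write_signature(signature: pd.DataFrame, path) -> None:
    signature.to_csv(path, sep="\t", index_label="gene")


def read_signature(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def assign_tls_classes(
    expr: ExpressionMatrix,
    signature_genes: Iterable[str],
    k: int = 3,
    method: str = "ward",
) -> pd.Series:
    """Cluster samples on z-scored signature genes into TLS1..TLSk.

    Signature-gene rows are log2(x+1)-transformed (unless already log2),
    z-scored, and clustered agglomeratively (Ward linkage on Euclidean
    distances by default); the tree is cut at k and clusters are relabelled
    by ascending mean TLS score so TLS1 is the lowest-expression class.
    """
    genes = [g for g in signature_genes if g in expr.values.index]
    if not genes:
        raise ValueError("no signature gene present in the expression matrix")
    n = expr.shape[1]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if k == 1:
        return pd.Series("TLS1", index=expr.values.columns, dtype=object)
    sub = expr.subset_genes(genes)
    if sub.unit != "log2":
        sub = ExpressionMatrix(np.log2(sub.values + 1.0), "log2")
    z = zscore_genes(sub)
    Z = linkage(pdist(z.to_numpy().T, metric="euclidean"), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    score = metagene_score(expr, genes)
    order = (
        pd.Series(score.to_numpy(), index=raw).groupby(level=0).mean().sort_values().index
    )
    relabel = {old: f"TLS{i + 1}" for i, old in enumerate(order)}
    return pd.Series([relabel[c] for c in raw], index=expr.values.columns, dtype=object)


def median_split(scores: pd.Series) -> pd.Series:
    """Stratify samples into high (> median) and low (<= median) score groups.

    The median is the standard interpolated median; samples exactly at the
    median go to the low group. An all-equal score vector yields all-low
    with a warning.
    """
    if len(scores) < 2:
        raise ValueError("median split requires at least 2 samples")
    med = float(np.median(scores.to_numpy(dtype=float)))
    out = pd.Series(np.where(scores > med, "high", "low"), index=scores.index, dtype=object)
    if (out == "low").all():
        log.warning("median_split: no sample above the median (constant scores?)")
    return out


def cytolytic_score(expr: ExpressionMatrix, mode: str = "log2_mean") -> pd.Series:
    """Cytolytic activity score from GZMA and PRF1.

    ``log2_mean`` (default): mean of log2(TPM+1) of the two genes.
    ``geometric``: log2 of the geometric mean of the raw values (classic
    Rooney-style definition, +1 inside the logs).
    """
    for g in CYTOLYTIC_GENES:
        if g not in expr.values.index:
            raise ValueError(f"cytolytic score requires gene {g} in the matrix")
    x = expr.values.loc[list(CYTOLYTIC_GENES)].to_numpy(dtype=float)
    if mode == "log2_mean":
        vals = np.log2(x + 1.0).mean(axis=0)
    elif mode == "geometric":
        vals = np.log2(np.sqrt((x[0] + 1.0) * (x[1] + 1.0)))
    else:
        raise ValueError(f"unknown cytolytic mode {mode!r}")
    return pd.Series(vals, index=expr.values.columns, name="cytolytic_score")
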