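"""Synthetic multi-site brain-metastasis cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
five-site cohort (lung, breast, melanoma, kidney, colon) with latent
per-population immune infiltration whose site means are ordered
lung > melanoma > breast; a TLS-positive subset in which all TLS-related
genes are elevated by a configurable fold; bulk counts drawn as Poisson
around lognormal rates with per-sample library factors; spatial tissue maps
with planted perivascular lymphoid aggregates carrying exact phenotype
counts; and exponential survival times whose hazard depends on TLS status.
Every generated dataset is emitted together with its ground truth, and one
master seed fixes bulk, spatial and survival outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .deconvolution import DEFAULT_MARKERS, MarkerSet
from .expression import ExpressionMatrix
from .signature import CHEMOKINE12, CYTOLYTIC_GENES, DEFAULT_COMPENDIUM, candidate_union
from .spatial import CellMap

log = logging.getLogger(__name__)

SITES = ("lung", "breast", "melanoma", "kidney", "colon")

#: Cohort composition modelled on a 95-patient multi-site series.
DEFAULT_SITE_N: Dict[str, int] = {"lung": 35, "breast": 29, "melanoma": 24, "kidney": 4, "colon": 3}

#: Site-level mean infiltration, ordered lung > melanoma > breast.
DEFAULT_INFILTRATION_MEAN: Dict[str, float] = {
    "lung": 1.0, "melanoma": 0.8, "kidney": 0.6, "colon": 0.5, "breast": 0.3,
}

#: TLS-positive fraction per site (lung/melanoma enriched, breast rare).
DEFAULT_TLS_FRACTION: Dict[str, float] = {
    "lung": 0.34, "melanoma": 0.29, "kidney": 0.5, "colon": 0.1, "breast": 0.05,
}


def _default_tls_genes() -> Tuple[str, ...]:
    return tuple(candidate_union(DEFAULT_COMPENDIUM).index)


@dataclass
class SimulationConfig:
    """Parameters of the bulk-cohort generator.

    Log-rate model per gene g and sample s::

        ln lambda(g,s) = base_g + marker_effect * infiltration(s, pop(g))
                         + ln(fold(g)) * TLS(s) + library_s + noise(g,s)

    with counts ~ Poisson(lambda). Marker genes load on their population's
    latent infiltration level; TLS-related genes carry fold
    ``tls_effect_size`` in TLS-positive samples (``anti_genes`` carry
    1/fold, emulating genes suppressed in TLS-positive tissue);
    ``low_genes`` sit far below the expression floor.
    """

    site_n: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SITE_N))
    infiltration_mean: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INFILTRATION_MEAN))
    infiltration_sd: float = 0.25
    tls_fraction: Dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_TLS_FRACTION))
    tls_effect_size: float = 8.0
    tls_genes: Tuple[str, ...] = field(default_factory=_default_tls_genes)
    anti_genes: Tuple[str, ...] = ()
    low_genes: Tuple[str, ...] = ()
    extra_genes: Tuple[str, ...] = ()
    cytolytic_coupling: bool = True  # GZMA/PRF1 elevated sqrt(fold) in TLS+ samples
    markers: MarkerSet = field(default_factory=lambda: DEFAULT_MARKERS)
    marker_effect: float = 1.0      # ln-scale loading per infiltration unit
    baseline_log_mean: float = 3.0  # ln-scale mean of per-gene baselines
    baseline_log_sd: float = 0.5
    low_gene_offset: float = -9.0   # ln-scale shift applied to low_genes
    library_log_sd: float = 0.2
    noise_sd: float = 0.3
    #: background genes keep the planted signal a small share of the
    #: library so configured folds survive TPM's compositional rescaling
    n_filler_genes: int = 2000
    length_range_bp: Tuple[int, int] = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.tls_fraction
        vals = fr.values() if isinstance(fr, Mapping) else [fr]
        if any(not (0.0 <= f <= 1.0) for f in vals):
            raise ValueError("TLS fractions must lie in [0, 1]")
        if self.tls_effect_size < 1:
            raise ValueError("TLS effect size must be >= 1")

    def tls_fraction_for(self, site: str) -> float:
        if isinstance(self.tls_fraction, Mapping):
            return float(self.tls_fraction[site])
        return float(self.tls_fraction)

    def gene_universe(self) -> List[str]:
        genes = set(self.markers.all_genes())
        genes.update(candidate_union(DEFAULT_COMPENDIUM).index)
        genes.update(CYTOLYTIC_GENES)
        genes.update(self.tls_genes)
        genes.update(self.anti_genes)
        genes.update(self.low_genes)
        genes.update(self.extra_genes)
        genes.update(f"FILLER{i:03d}" for i in range(1, self.n_filler_genes + 1))
        return sorted(genes)


@dataclass
class AggregateTruth:
    center: Tuple[float, float]
    n_cells: int
    b_fraction: float
    n_B: int
    n_T: int
    n_DC: int
    perivascular: bool
    radius_um: float


@dataclass
class CohortTruth:
    """Ground truth emitted alongside every generated dataset."""

    samples: pd.DataFrame  # index sample; site, tls_status, infil_<population>
    aggregates: Dict[str, List[AggregateTruth]] = field(default_factory=dict)
    beta_tls: Optional[float] = None

    def to_json(self, path) -> None:
        payload = {
            "samples": self.samples.reset_index().to_dict(orient="list"),
            "aggregates": {
                sid: [asdict(a) for a in aggs] for sid, aggs in self.aggregates.items()
            },
            "beta_tls": self.beta_tls,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        with open(path) as fh:
            payload = json.load(fh)
        samples = pd.DataFrame(payload["samples"]).set_index("sample")
        aggregates = {
            sid: [AggregateTruth(**{**a, "center": tuple(a["center"])}) for a in aggs]
            for sid, aggs in payload["aggregates"].items()
        }
        return cls(samples, aggregates, payload.get("beta_tls"))


def _draw_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for site in sorted(cfg.site_n):
        n = cfg.site_n[site]
        mu = cfg.infiltration_mean.get(site, 0.5)
        frac = cfg.tls_fraction_for(site)
        for i in range(n):
            infil = {
                f"infil_{pop}": max(0.0, rng.normal(mu, cfg.infiltration_sd))
                for pop in cfg.markers.populations
            }
            rows.append(
                {"sample": f"{site}_{i + 1:03d}", "site": site,
                 "tls_status": bool(rng.random() < frac), **infil}
            )
    return pd.DataFrame(rows).set_index("sample")


def expected_rates(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    base: pd.Series,
    library: pd.Series,
) -> pd.DataFrame:
    """Deterministic part of the Poisson rate matrix (genes x samples)."""
    genes = base.index
    samples = truth.index
    ln_rate = np.tile(base.to_numpy()[:, None], (1, len(samples))).astype(float)
    ln_rate += library.to_numpy()[None, :]
    gene_pos = {g: i for i, g in enumerate(genes)}
    for pop, spec in cfg.markers.populations.items():
        infil = truth[f"infil_{pop}"].to_numpy(dtype=float)
        for g in spec.genes:
            if g in gene_pos:
                ln_rate[gene_pos[g]] += cfg.marker_effect * infil
    tls = truth["tls_status"].to_numpy(dtype=bool)
    lf = np.log(cfg.tls_effect_size)
    for g in cfg.tls_genes:
        if g in gene_pos:
            ln_rate[gene_pos[g], tls] += lf
    for g in cfg.anti_genes:
        if g in gene_pos:
            ln_rate[gene_pos[g], tls] -= lf
    if cfg.cytolytic_coupling:
        for g in CYTOLYTIC_GENES:
            if g in gene_pos:
                ln_rate[gene_pos[g], tls] += lf / 2.0
    return pd.DataFrame(np.exp(ln_rate), index=genes, columns=samples)


def generate_bulk_cohort(
    cfg: SimulationConfig,
) -> Tuple[ExpressionMatrix, pd.Series, CohortTruth]:
    """Simulate a bulk count matrix with gene lengths and ground truth."""
    universe = cfg.gene_universe()
    missing = [g for g in cfg.markers.all_genes() if g not in universe]
    if missing:
        raise ValueError(f"marker gene(s) missing from the universe: {missing}")
    ss = np.random.SeedSequence(cfg.seed)
    rng_truth, rng_base, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    truth_df = _draw_truth(cfg, rng_truth)

    base = pd.Series(
        rng_base.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, len(universe)),
        index=universe,
    )
    base[list(cfg.low_genes)] += cfg.low_gene_offset
    lengths = pd.Series(
        rng_base.integers(cfg.length_range_bp[0], cfg.length_range_bp[1] + 1, len(universe)),
        index=universe,
        name="length_bp",
    )
    library = pd.Series(
        rng_base.normal(0.0, cfg.library_log_sd, len(truth_df)), index=truth_df.index
    )
    lam = expected_rates(cfg, truth_df, base, library)
    if cfg.noise_sd > 0:
        lam = lam * np.exp(rng_noise.normal(0.0, cfg.noise_sd, lam.shape))
    counts = pd.DataFrame(
        rng_noise.poisson(lam.to_numpy()).astype(float),
        index=lam.index, columns=lam.columns,
    )
    return ExpressionMatrix(counts, "counts"), lengths, CohortTruth(truth_df)


# ---------------------------------------------------------------------------
# Spatial maps
# ---------------------------------------------------------------------------

#: Background phenotype mixture of a tumor-dominated tissue section.
DEFAULT_BACKGROUND_PROBS: Dict[str, float] = {
    "tumor": 0.55, "other": 0.15, "macrophage": 0.12, "endothelial": 0.08,
    "T": 0.07, "B": 0.02, "DC": 0.01,
}


@dataclass
class AggregateSpec:
    """A planted lymphoid aggregate: exact cell counts, Gaussian scatter."""

    n_cells: int = 600
    b_fraction: float = 0.62
    n_dc: int = 0
    perivascular: bool = True
    radius_um: float = 40.0


@dataclass
class CellMapConfig:
    extent_um: Tuple[float, float] = (2000.0, 2000.0)
    background_intensity: float = 3e-4  # cells per µm²
    background_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_PROBS))
    n_vessels: int = 25
    aggregates: Tuple[AggregateSpec, ...] = (AggregateSpec(),)
    perivascular_offset_um: float = 20.0   # max center-to-vessel distance when planting
    distant_clearance_um: float = 150.0    # min vessel distance for non-perivascular centers
    min_center_separation_um: float = 300.0
    max_density: float = 0.2               # cells per µm² feasibility ceiling


def generate_cell_map(
    cfg: CellMapConfig, seed: int, sample_id: str = "S1"
) -> Tuple[CellMap, List[AggregateTruth]]:
    """Simulate one phenotyped tissue map with planted aggregates.

    Background cells are homogeneous Poisson over the rectangle; vessels are
    uniform random points; each planted aggregate scatters exactly
    ``n_cells`` lymphocytes (``round(b_fraction * n)`` B cells, remainder T)
    Gaussian with SD ``radius_um`` around a vessel-adjacent or vessel-distant
    center, plus ``n_dc`` dendritic cells.
    """
    if cfg.extent_um[0] <= 0 or cfg.extent_um[1] <= 0:
        raise ValueError("tissue extent must be positive")
    rng = np.random.default_rng(seed)
    W, H = cfg.extent_um
    for spec in cfg.aggregates:
        density = spec.n_cells / (np.pi * (2.0 * spec.radius_um) ** 2)
        if density > cfg.max_density:
            raise ValueError(
                f"aggregate of {spec.n_cells} cells within radius {spec.radius_um} µm "
                f"exceeds the feasible density ({density:.3f} > {cfg.max_density} cells/µm²)"
            )
        if spec.radius_um * 4 > min(W, H):
            raise ValueError("aggregate radius too large for the tissue extent")

    vessels = rng.uniform([0, 0], [W, H], size=(cfg.n_vessels, 2))

    rows: List[Tuple[float, float, str]] = []
    n_bg = rng.poisson(cfg.background_intensity * W * H)
    if n_bg > 0:
        bg_xy = rng.uniform([0, 0], [W, H], size=(n_bg, 2))
        phens = list(cfg.background_probs)
        probs = np.array([cfg.background_probs[p] for p in phens], dtype=float)
        probs /= probs.sum()
        bg_ph = rng.choice(phens, size=n_bg, p=probs)
        rows.extend(zip(bg_xy[:, 0], bg_xy[:, 1], bg_ph))

    centers: List[np.ndarray] = []
    truth: List[AggregateTruth] = []
    for spec in cfg.aggregates:
        center = _place_center(cfg, spec, vessels, centers, rng)
        centers.append(center)
        n_b = int(round(spec.b_fraction * spec.n_cells))
        n_t = spec.n_cells - n_b
        phens = ["B"] * n_b + ["T"] * n_t + ["DC"] * spec.n_dc
        xy = rng.normal(center, spec.radius_um, size=(len(phens), 2))
        xy = np.clip(xy, [0, 0], [W, H])
        rows.extend(zip(xy[:, 0], xy[:, 1], phens))
        truth.append(
            AggregateTruth(
                center=(float(center[0]), float(center[1])),
                n_cells=spec.n_cells, b_fraction=spec.b_fraction,
                n_B=n_b, n_T=n_t, n_DC=spec.n_dc,
                perivascular=spec.perivascular, radius_um=spec.radius_um,
            )
        )

    cells = pd.DataFrame(rows, columns=["x_um", "y_um", "phenotype"])
    cells["x_um"] = cells["x_um"].astype(float)
    cells["y_um"] = cells["y_um"].astype(float)
    return CellMap(cells=cells, vessels=vessels, sample_id=sample_id), truth


def _place_center(cfg, spec, vessels, existing, rng, max_tries: int = 500) -> np.ndarray:
    W, H = cfg.extent_um
    margin = 3.0 * spec.radius_um
    for _ in range(max_tries):
        if spec.perivascular:
            v = vessels[rng.integers(len(vessels))]
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0, cfg.perivascular_offset_um)
            cand = v + r * np.array([np.cos(ang), np.sin(ang)])
        else:
            cand = rng.uniform([margin, margin], [W - margin, H - margin])
            d = np.sqrt(((vessels - cand) ** 2).sum(axis=1)).min() if len(vessels) else np.inf
            if d < cfg.distant_clearance_um:
                continue
        if cand[0] < margin or cand[0] > W - margin or cand[1] < margin or cand[1] > H - margin:
            continue
        if all(np.linalg.norm(cand - c) >= cfg.min_center_separation_um for c in existing):
            return cand
    raise RuntimeError("could not place aggregate center; relax the map configuration")


def generate_spatial_cohort(
    truth: CohortTruth,
    seed: int,
    map_cfg: Optional[CellMapConfig] = None,
    samples: Optional[Sequence[str]] = None,
    subthreshold_prob: float = 0.3,
) -> List[CellMap]:
    """Tissue maps consistent with per-sample TLS status.

    TLS-positive samples receive 1-2 qualifying perivascular aggregates
    (n >= 600 cells, B fraction >= 0.6, 0-3 dendritic cells); TLS-negative
    samples receive either nothing (diffuse pattern) or one sub-threshold
    aggregate (too small or T-dominated). Truths are recorded into
    ``truth.aggregates``.
    """
    base = map_cfg or CellMapConfig()
    ss = np.random.SeedSequence(seed)
    sample_ids = list(samples) if samples is not None else list(truth.samples.index)
    maps: List[CellMap] = []
    for sid, child in zip(sample_ids, ss.spawn(len(sample_ids))):
        rng = np.random.default_rng(child)
        pos = bool(truth.samples.loc[sid, "tls_status"])
        if pos:
            specs = tuple(
                AggregateSpec(
                    n_cells=int(rng.integers(600, 901)),
                    b_fraction=float(rng.uniform(0.60, 0.72)),
                    n_dc=int(rng.integers(0, 4)),
                    perivascular=True,
                )
                for _ in range(int(rng.integers(1, 3)))
            )
        elif rng.random() < subthreshold_prob:
            if rng.random() < 0.5:  # too small
                specs = (AggregateSpec(n_cells=int(rng.integers(100, 301)),
                                       b_fraction=0.65, perivascular=True),)
            else:  # T-dominated
                specs = (AggregateSpec(n_cells=int(rng.integers(600, 801)),
                                       b_fraction=float(rng.uniform(0.2, 0.4)),
                                       perivascular=True),)
        else:
            specs = ()
        cfg = replace(base, aggregates=specs)
        cmap, agg_truth = generate_cell_map(
            cfg, seed=int(rng.integers(2**31 - 1)), sample_id=sid
        )
        truth.aggregates[sid] = agg_truth
        maps.append(cmap)
    return maps


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def generate_survival(
    truth: CohortTruth,
    beta_tls: float = -0.8,
    baseline_hazard: float = 0.04,  # events per month
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical table with exponential event times and uniform censoring.

    The hazard of a sample is ``baseline_hazard * exp(beta_tls * TLS_high)``
    where TLS_high is the sample's true TLS status; survival time is
    measured in months from BrM diagnosis. Censoring times are uniform on
    (0, b) with b calibrated so the expected censored fraction matches
    ``censoring_rate``.
    """
    if not np.isfinite(beta_tls):
        raise ValueError("beta_tls must be finite")
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if not (0.0 <= censoring_rate < 1.0):
        raise ValueError("censoring rate must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    tls = truth.samples["tls_status"].to_numpy(dtype=bool)
    hazard = baseline_hazard * np.exp(beta_tls * tls)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        h_mean = float(hazard.mean())

        def cens_frac(b):  # P(C < T), C ~ U(0,b), T ~ Exp(h)
            return (1.0 - np.exp(-h_mean * b)) / (h_mean * b) - censoring_rate

        b = brentq(cens_frac, 1e-9, 1e9)
        c = rng.uniform(0.0, b, size=len(tls))
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(len(tls), dtype=int)
    n = len(tls)
    sites = truth.samples["site"]
    histology = np.where(
        sites == "lung",
        np.where(rng.random(n) < 0.8, "NSCLC", "SCLC"),
        sites.str.capitalize(),
    )
    df = pd.DataFrame(
        {
            "sample": truth.samples.index,
            "time_months": np.maximum(time, 1e-3),
            "event": event,
            "age": np.round(rng.normal(62, 10, n), 1),
            "sex": rng.choice(["F", "M"], n),
            "histological_subtype": histology,
            "extracerebral_mets": rng.integers(0, 2, n),
            "treatment_naive": rng.integers(0, 2, n),
            "tls_level": np.where(tls, "high", "low"),
        }
    ).set_index("sample")
    truth.beta_tls = float(beta_tls)
    return df


# ---------------------------------------------------------------------------
# Scenario presets used by the calibration experiments
# ---------------------------------------------------------------------------

SIGNATURE_PLANTED = ("TLSCOV1", "TLSCOV2", "TLSCOV3", "TLSCOV4", "TLSCOV5")
SIGNATURE_ANTI = ("TLSANTI1", "TLSANTI2", "TLSANTI3")
SIGNATURE_LOW = ("TLSLOW1", "TLSLOW2")

#: Compendium of the signature-construction experiment: the 12-chemokine
#: seed list plus ten synthetic planted candidates (5 co-varying, 3
#: anti-correlated, 2 below the expression floor).
SIGNATURE_SCENARIO_COMPENDIUM: Dict[str, Tuple[str, ...]] = {
    "chemokine12": CHEMOKINE12,
    "planted": SIGNATURE_PLANTED + SIGNATURE_ANTI + SIGNATURE_LOW,
}


def signature_scenario_config(seed: int, n_samples: int = 60, fold: float = 8.0) -> SimulationConfig:
    """Single-pool cohort for the signature-construction experiment: the
    chemokine seed genes and 5 planted candidates co-vary with TLS status,
    3 candidates are suppressed in TLS-positive samples and 2 sit below the
    1-TPM expression floor."""
    return SimulationConfig(
        site_n={"lung": n_samples},
        tls_fraction=0.5,
        tls_effect_size=fold,
        tls_genes=tuple(CHEMOKINE12) + SIGNATURE_PLANTED,
        anti_genes=SIGNATURE_ANTI,
        low_genes=SIGNATURE_LOW,
        seed=seed,
    )


def recovery_config(seed: int, n_samples: int = 60, fold: float = 8.0) -> SimulationConfig:
    """Balanced-prevalence cohort for the median-split recovery experiment
    (a median split can only track truth when classes are balanced)."""
    return SimulationConfig(
        site_n={"lung": n_samples},
        tls_fraction=0.5,
        tls_effect_size=fold,
        seed=seed,
    )


def generate_three_tier_cohort(
    seed: int,
    n_per_tier: int = 20,
    folds: Tuple[float, float, float] = (1.0, 10.0, 100.0),
    n_filler_genes: int = 2000,
) -> Tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Counts matrix whose samples fall in three well-separated planted
    TLS-expression tiers (the given folds applied to every TLS-related
    gene); returns (counts, lengths, tier labels).

    A transcriptome-sized filler background keeps the TLS genes a small
    share of the library, so the planted folds survive TPM normalisation
    instead of saturating against the compositional ceiling.
    """
    cfg = SimulationConfig(
        site_n={"lung": len(folds) * n_per_tier},
        tls_fraction=0.0,
        n_filler_genes=n_filler_genes,
        seed=seed,
    )
    counts, lengths, _ = generate_bulk_cohort(cfg)
    genes = [g for g in cfg.tls_genes if g in counts.values.index]
    vals = counts.values.copy()
    labels = pd.Series(
        np.repeat([f"tier{i + 1}" for i in range(len(folds))], n_per_tier),
        index=vals.columns,
        name="tier",
    )
    for i, fold in enumerate(folds):
        cols = labels.index[labels == f"tier{i + 1}"]
        vals.loc[genes, cols] = np.round(vals.loc[genes, cols] * fold)
    return ExpressionMatrix(vals, "counts"), lengths, labels
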