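"""Synthetic district-panel generator.

Emulates the statistical structure the pipeline assumes about a megacity's
districts: a spatially autocorrelated aging field over a contiguity graph,
land areas spanning roughly two orders of magnitude (lognormal), a compact
small-area core with high older-population density, and a resource score
whose response to demand is controlled in sign and strength
(``mismatch_beta``). Defaults mirror the study conditions: 11 districts,
positive spatial autocorrelation of aging, and resources deployed away from
the high-demand core (negative demand-resource relationship).

The aging field follows a spatial autoregressive (SAR) process
x = mu + (I - rho * W_rs)^(-1) eps on the row-standardized adjacency, then is
affinely mapped into the observed coefficient range [5, 35] percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .concentration import classify_match, concentration_index, inconsistency_index
from .panel_io import DistrictPanel, DistrictRecord, SpatialWeights

__all__ = ["SimConfig", "SyntheticTruth", "make_adjacency", "simulate_aging_field", "simulate_panel"]

# Intercept of the resource response; with the default mismatch_beta the
# noiseless resource score stays inside (0, 1].
_RESOURCE_ALPHA = 0.7
_SCORE_FLOOR = 1e-4


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    rho is the SAR strength in (-1, 1) (admissible for row-standardized
    weights, spectral radius 1); area_log_mean/sd parameterize lognormal
    areas in km² (defaults give a median ~330 km² spanning about two orders
    of magnitude, as in the study region); mismatch_beta > 0 makes resources
    respond negatively to demand; core_fraction is the share of districts
    forming the small-area, high-density core.
    """

    n_districts: int = 11
    graph_kind: str = "random_geometric"
    rho: float = 0.5
    area_log_mean: float = 5.8
    area_log_sd: float = 1.3
    mismatch_beta: float = 0.5
    noise_sd: float = 0.05
    core_fraction: float = 0.3
    seed: int = 20150101
    year: int = 2023

    def __post_init__(self) -> None:
        if self.n_districts < 4:
            raise ValueError("need at least 4 districts")
        if self.graph_kind not in ("grid", "cycle", "random_geometric"):
            raise ValueError("graph_kind must be grid|cycle|random_geometric")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.core_fraction < 1:
            raise ValueError("core_fraction must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated panel."""

    config: SimConfig
    adjacency: SpatialWeights
    true_match_type: dict[str, str]
    noiseless_demand: dict[str, float] = field(default_factory=dict)
    noiseless_resource: dict[str, float] = field(default_factory=dict)


def _labels(n: int) -> list[str]:
    return [f"D{i:03d}" for i in range(n)]


def make_adjacency(cfg: SimConfig, rng: np.random.Generator | None = None) -> SpatialWeights:
    """Connected binary symmetric adjacency over n districts.

    grid: rook contiguity on the nearest-to-square lattice (row-major prefix
    when n is not a perfect rectangle); cycle: a ring; random_geometric: a
    threshold graph with mean degree ~5, regenerated until connected
    (bounded at 100 attempts).
    """
    n = cfg.n_districts
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.graph_kind == "grid":
        rows = int(round(np.sqrt(n)))
        cols = int(np.ceil(n / rows))
        G = nx.grid_2d_graph(rows, cols)
        keep = sorted(G.nodes)[:n]
        G = G.subgraph(keep)
        order = {node: i for i, node in enumerate(sorted(G.nodes))}
    elif cfg.graph_kind == "cycle":
        G = nx.cycle_graph(n)
        order = {node: node for node in G.nodes}
    else:
        radius = np.sqrt(5.0 / (np.pi * (n - 1)))
        for _ in range(100):
            seed_int = int(rng.integers(0, 2**31 - 1))
            G = nx.random_geometric_graph(n, radius, seed=seed_int)
            if nx.is_connected(G):
                break
        else:
            raise RuntimeError(
                "could not generate a connected random geometric graph in 100 tries"
            )
        order = {node: node for node in G.nodes}
    W = np.zeros((n, n))
    for a, b in G.edges:
        i, j = order[a], order[b]
        W[i, j] = W[j, i] = 1.0
    return SpatialWeights(labels=_labels(n), matrix=W)


def simulate_aging_field(
    cfg: SimConfig,
    W: SpatialWeights,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Spatially autocorrelated aging coefficients (%) in [5, 35].

    x = mu + (I - rho W_rs)^(-1) eps with eps ~ N(0, noise_sd^2 * scale);
    the innovation scale is fixed at 1 so noise_sd only governs measurement
    noise elsewhere — the field's spread is set by the affine map to [5, 35].
    A zero-spread draw (degenerate) returns a constant 20% field with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = W.n
    Wrs = W.row_standardized().matrix
    eps = rng.standard_normal(n)
    u = np.linalg.solve(np.eye(n) - cfg.rho * Wrs, eps)
    lo, hi = u.min(), u.max()
    if hi == lo:
        warnings.warn("degenerate aging field (zero spread)", RuntimeWarning)
        return np.full(n, 20.0)
    return 5.0 + 30.0 * (u - lo) / (hi - lo)


def simulate_panel(cfg: SimConfig) -> tuple[DistrictPanel, SyntheticTruth]:
    """One synthetic cross-section plus its ground truth.

    Construction: lognormal areas with the smallest areas assigned to a
    BFS-connected core around the highest-degree node; district populations
    are comparable across districts so older-population density scales like
    1/area and peaks in the core; demand_score is the min-max-normalized
    log density; resource_score = alpha - mismatch_beta * demand + noise,
    clipped to (0, 1]. Truth labels apply the concentration/RI pipeline to
    the noiseless fields. Fixed seed => bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    W = make_adjacency(cfg, rng)
    n = cfg.n_districts
    labels = W.labels

    areas = np.sort(rng.lognormal(cfg.area_log_mean, cfg.area_log_sd, n))
    # core: BFS ball around the best-connected node, smallest areas inside
    k = max(1, int(round(cfg.core_fraction * n)))
    G = nx.from_numpy_array(W.matrix)
    center = max(G.degree, key=lambda t: t[1])[0]
    core = [center]
    for node in nx.bfs_tree(G, center):
        if node not in core:
            core.append(node)
        if len(core) >= k:
            break
    core = set(core[:k])
    periphery = [i for i in range(n) if i not in core]
    area_by_node = np.empty(n)
    area_by_node[sorted(core)] = areas[:k][rng.permutation(k)]
    area_by_node[periphery] = areas[k:][rng.permutation(n - k)]

    aging_coef = simulate_aging_field(cfg, W, rng)
    # comparable district populations (lognormal around 1e6 residents)
    population = rng.lognormal(np.log(1e6), 0.3, n)
    aging_density = aging_coef / 100.0 * population / area_by_node
    income = 50_000 * np.where(
        [i in core for i in range(n)], 1.5, 1.0
    ) * rng.lognormal(0.0, 0.1, n)

    log_density = np.log1p(aging_density)
    lo, hi = log_density.min(), log_density.max()
    spread = hi - lo
    if spread == 0:
        demand = np.full(n, 0.5)
    else:
        demand = np.clip(
            _SCORE_FLOOR + (1 - _SCORE_FLOOR) * (log_density - lo) / spread,
            _SCORE_FLOOR,
            1.0,
        )

    resource_clean = np.clip(
        _RESOURCE_ALPHA - cfg.mismatch_beta * demand, _SCORE_FLOOR, 1.0
    )
    resource = np.clip(
        resource_clean + rng.normal(0.0, cfg.noise_sd, n), _SCORE_FLOOR, 1.0
    )

    # per-thousand resource indicators consistent with the resource score,
    # so the entropy module can be exercised on raw indicators
    indicator_scales = {"X3": 2.0, "X4": 40.0, "X5": 1.0, "X6": 5.0}
    indicators = {
        code: resource * scale * rng.lognormal(0.0, 0.15, n)
        for code, scale in indicator_scales.items()
    }

    records = [
        DistrictRecord(
            district=labels[i],
            year=cfg.year,
            area_km2=float(area_by_node[i]),
            aging_coefficient=float(aging_coef[i]),
            aging_density=float(aging_density[i]),
            income_per_capita=float(income[i]),
            resource_indicators={c: float(v[i]) for c, v in indicators.items()},
            demand_score=float(demand[i]),
            resource_score=float(resource[i]),
        )
        for i in range(n)
    ]
    panel = DistrictPanel(records=records, district_order=list(labels))

    d_conc = concentration_index(demand, area_by_node)
    r_conc = concentration_index(resource_clean, area_by_node)
    ri = inconsistency_index(d_conc, r_conc)
    truth = SyntheticTruth(
        config=cfg,
        adjacency=W,
        true_match_type={labels[i]: classify_match(ri[i]) for i in range(n)},
        noiseless_demand={labels[i]: float(demand[i]) for i in range(n)},
        noiseless_resource={labels[i]: float(resource_clean[i]) for i in range(n)},
    )
    return panel, truth
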