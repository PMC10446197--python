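"""Synthetic benchmark data: Gaussian graphical subnetworks embedded in noise.

Two phenotypes A and B share four "common" subnetworks (identical generating
distribution in both groups) and carry six "responsive" subnetworks whose
genes follow a different Gaussian graphical model per phenotype: phenotype A
uses the scenario's graph structure (random / cluster / scale-free / hub),
phenotype B always uses a width-1 band graph and additionally receives a
mean shift mu on every subnetwork gene. All remaining genes are i.i.d.
standard normal background.

Precision matrices are built from a binary graph structure: off-diagonal
entries 0.5 on edges, and a constant diagonal |lambda_min(0.5 A)| + 0.2 so
the matrix is positive definite with spectral margin exactly 0.2.

The sample-specific variant draws a scalar modulator m_alpha ~ U(-1, 1) per
cell line and interpolates each responsive precision matrix's edge strengths
between half and full intensity: with delta_alpha = (m_alpha + 1)/2, the
off-diagonal entries become (0.5 + 0.5 delta_alpha) * Omega_ij while the
diagonal is held fixed, so regulatory strength — and hence every conditional
regression coefficient — grows monotonically with the modulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
from scipy import linalg

from .data import ExpressionDataset, SubnetworkSpec

__all__ = [
    "PrecisionGraph",
    "ScenarioConfig",
    "ScenarioTruth",
    "generate_structure",
    "interpolate_precision",
    "generate_scenario",
    "generate_sample_specific_scenario",
    "SCENARIO_STRUCTURE",
]

StructureTag = Literal["random", "band", "cluster", "scale_free", "hub"]

#: Graph structure of the common and A-specific subnetworks per scenario id.
SCENARIO_STRUCTURE: dict[int, StructureTag] = {
    1: "random",
    2: "cluster",
    3: "scale_free",
    4: "hub",
}

#: Off-diagonal precision value placed on every edge.
EDGE_STRENGTH = 0.5
#: Extra positive number added to the diagonal (the generator's ``u``).
DIAG_BOOST = 0.2
#: Baseline the conventional graphical-model generator always adds before u.
GENERATOR_BASELINE = 0.1
#: Resulting positive-definiteness margin of every precision matrix.
PD_MARGIN = GENERATOR_BASELINE + DIAG_BOOST


@dataclass
class PrecisionGraph:
    """A binary graph structure together with its precision matrix."""

    adjacency: np.ndarray
    omega: np.ndarray
    structure_tag: str

    def __post_init__(self) -> None:
        a, w = self.adjacency, self.omega
        assert a.shape == w.shape and a.shape[0] == a.shape[1]
        assert np.array_equal(a, a.T) and np.allclose(w, w.T)

    @property
    def size(self) -> int:
        return self.omega.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.omega)[0])

    @property
    def sigma(self) -> np.ndarray:
        """Sampling covariance: omega^{-1} standardized to unit variances."""
        return covariance_from_precision(self.omega)


@dataclass
class ScenarioConfig:
    """Configuration of one Monte Carlo scenario.

    Defaults are the benchmark's study conditions: 10 subnetworks (4 common,
    6 responsive) of ``subnetwork_size`` genes inside ``p`` total genes,
    n_A = n_B = 50 cell lines, mean shift mu = 0.3 on phenotype-B responsive
    genes.
    """

    scenario_id: int = 1
    subnetwork_size: int = 10
    p: int = 1000
    n_a: int = 50
    n_b: int = 50
    mu: float = 0.3
    n_common: int = 4
    n_specific: int = 6
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_STRUCTURE:
            raise ValueError(f"scenario_id must be in 1..4, got {self.scenario_id}")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        need = (self.n_common + self.n_specific) * self.subnetwork_size
        if need > self.p:
            raise ValueError(
                f"subnetworks need {need} genes but p = {self.p}"
            )

    @property
    def structure(self) -> StructureTag:
        return SCENARIO_STRUCTURE[self.scenario_id]

    @property
    def n_subnetwork_genes(self) -> int:
        return (self.n_common + self.n_specific) * self.subnetwork_size


@dataclass
class ScenarioTruth:
    """Ground-truth subnetwork membership and responsiveness labels."""

    subnetworks: list[SubnetworkSpec]
    labels: list[str]  # "common" or "responsive", aligned with subnetworks
    graphs: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert len(self.subnetworks) == len(self.labels)
        seen: set[str] = set()
        for s in self.subnetworks:
            overlap = seen.intersection(s.genes)
            assert not overlap, f"overlapping truth gene sets: {sorted(overlap)[:3]}"
            seen.update(s.genes)

    @property
    def responsive(self) -> list[str]:
        return [s.name for s, l in zip(self.subnetworks, self.labels) if l == "responsive"]

    @property
    def common(self) -> list[str]:
        return [s.name for s, l in zip(self.subnetworks, self.labels) if l == "common"]


# ---------------------------------------------------------------------------
# Structure and precision-matrix construction
# ---------------------------------------------------------------------------

def generate_structure(
    structure_tag: StructureTag,
    size: int,
    rng: np.random.Generator | int | None = None,
    p_edge: float | None = None,
) -> PrecisionGraph:
    """Generate a binary graph and its edge-strength-0.5 precision matrix.

    Structures: ``random`` (Erdos–Renyi with edge probability `p_edge`,
    default 0.3 for size <= 25 else 0.1), ``band`` (|i - j| <= 1),
    ``cluster`` (two equal groups, within-group edge probability 0.6),
    ``scale_free`` (preferential-attachment tree, one edge per new node),
    ``hub`` (ceil(size/10) groups, first gene of each group connected to the
    rest of its group).
    """
    if size < 2:
        raise ValueError(f"subnetwork size must be >= 2, got {size}")
    rng = np.random.default_rng(rng)
    adj = np.zeros((size, size), dtype=int)
    if structure_tag == "random":
        pe = p_edge if p_edge is not None else (0.3 if size <= 25 else 0.1)
        upper = rng.random((size, size)) < pe
        iu = np.triu_indices(size, k=1)
        adj[iu] = upper[iu]
        adj = adj + adj.T
    elif structure_tag == "band":
        idx = np.arange(size - 1)
        adj[idx, idx + 1] = 1
        adj = adj + adj.T
    elif structure_tag == "cluster":
        half = size // 2
        groups = [np.arange(half), np.arange(half, size)]
        for g in groups:
            for a in range(len(g)):
                for b in range(a + 1, len(g)):
                    if rng.random() < 0.6:
                        adj[g[a], g[b]] = adj[g[b], g[a]] = 1
    elif structure_tag == "scale_free":
        g = nx.barabasi_albert_graph(size, 1, seed=int(rng.integers(2**31)))
        for a, b in g.edges:
            adj[a, b] = adj[b, a] = 1
    elif structure_tag == "hub":
        n_groups = int(np.ceil(size / 10))
        for block in np.array_split(np.arange(size), n_groups):
            hub = block[0]
            for other in block[1:]:
                adj[hub, other] = adj[other, hub] = 1
    else:
        raise ValueError(f"unknown structure tag {structure_tag!r}")
    omega = _precision_from_adjacency(adj)
    return PrecisionGraph(adjacency=adj, omega=omega, structure_tag=structure_tag)


def _precision_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """Off-diagonals 0.5 on edges; constant diagonal |lambda_min| + 0.1 + 0.2.

    This mirrors the standard Gaussian graphical model generator: the edge
    strength v goes on the off-diagonals and the diagonal is the absolute
    smallest eigenvalue plus a fixed 0.1 baseline plus the user's added
    positive number u (here 0.2), guaranteeing positive definiteness with
    spectral margin 0.1 + u.
    """
    m = EDGE_STRENGTH * adj.astype(float)
    lam_min = float(np.linalg.eigvalsh(m)[0])
    diag = abs(lam_min) + PD_MARGIN
    omega = m + diag * np.eye(adj.shape[0])
    # by construction lambda_min(omega) = lam_min + |lam_min| + margin >= margin
    assert np.linalg.eigvalsh(omega)[0] > 0
    return omega


def interpolate_precision(
    omega: np.ndarray,
    delta: float,
    mode: Literal["offdiag", "full"] = "offdiag",
) -> np.ndarray:
    """Interpolate a precision matrix between half and full edge intensity.

    ``offdiag`` (default): off-diagonal entries are scaled by
    (0.5 + 0.5*delta) while the diagonal is held fixed, so edge strengths —
    and conditional regression coefficients — vary with delta. ``full``
    scales the whole matrix, which rescales variances but leaves the
    conditional regression structure unchanged.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    c = 0.5 + 0.5 * delta
    if mode == "full":
        return c * omega
    out = c * omega
    np.fill_diagonal(out, np.diag(omega))
    return out


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

def _gene_ids(p: int) -> list[str]:
    return [f"g{i:04d}" for i in range(p)]


def covariance_from_precision(omega: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Invert a precision matrix; by default rescale to unit marginal variances.

    The standardization mirrors the conventional Gaussian graphical model
    generator behavior: the graph (pattern of conditional dependence) is
    defined by the precision matrix, while expression is sampled on a
    correlation scale so every gene has variance 1 and the mean shift mu is
    expressed in marginal-standard-deviation units.
    """
    sigma = linalg.inv(omega)
    if standardize:
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    return sigma


def _mvn_from_precision(
    omega: np.ndarray,
    n: int,
    rng: np.random.Generator,
    mean: float = 0.0,
    standardize: bool = True,
) -> np.ndarray:
    """Draw n samples from the graphical model defined by a precision matrix."""
    sigma = covariance_from_precision(omega, standardize)
    chol = linalg.cholesky(sigma, lower=True)
    z = rng.standard_normal((n, omega.shape[0]))
    return z @ chol.T + mean


def _build_truth(cfg: ScenarioConfig, rng: np.random.Generator):
    """Draw all precision graphs and lay out the subnetwork gene sets."""
    genes = _gene_ids(cfg.p)
    k = cfg.subnetwork_size
    subnetworks: list[SubnetworkSpec] = []
    labels: list[str] = []
    graphs: dict[str, object] = {}
    pos = 0
    for i in range(cfg.n_common):
        name = f"common_{i + 1}"
        subnetworks.append(
            SubnetworkSpec(name, genes[pos : pos + k], description="common")
        )
        labels.append("common")
        graphs[name] = generate_structure(cfg.structure, k, rng)
        pos += k
    for i in range(cfg.n_specific):
        name = f"responsive_{i + 1}"
        subnetworks.append(
            SubnetworkSpec(name, genes[pos : pos + k], description="responsive")
        )
        labels.append("responsive")
        graphs[name] = (
            generate_structure(cfg.structure, k, rng),  # phenotype A
            generate_structure("band", k, rng),  # phenotype B
        )
        pos += k
    truth = ScenarioTruth(subnetworks=subnetworks, labels=labels, graphs=graphs)
    return genes, truth


def _assemble_dataset(
    cfg: ScenarioConfig,
    genes: list[str],
    values: np.ndarray,
    modulator: np.ndarray | None,
) -> ExpressionDataset:
    import pandas as pd

    n = cfg.n_a + cfg.n_b
    cells = [f"c{i:03d}" for i in range(n)]
    phen = ["A"] * cfg.n_a + ["B"] * cfg.n_b
    df = pd.DataFrame(values, index=cells, columns=genes)
    return ExpressionDataset(df, phen, modulator)


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[ExpressionDataset, ScenarioTruth]:
    """Generate one bulk-phenotype benchmark dataset with ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes, truth = _build_truth(cfg, rng)
    n = cfg.n_a + cfg.n_b
    values = rng.standard_normal((n, cfg.p))  # background genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    a_rows = np.arange(cfg.n_a)
    b_rows = np.arange(cfg.n_a, n)
    for spec, label in zip(truth.subnetworks, truth.labels):
        cols = [gene_pos[g] for g in spec.genes]
        if label == "common":
            pg: PrecisionGraph = truth.graphs[spec.name]  # type: ignore[assignment]
            values[:, cols] = _mvn_from_precision(pg.omega, n, rng)
        else:
            pg_a, pg_b = truth.graphs[spec.name]  # type: ignore[misc]
            values[np.ix_(a_rows, cols)] = _mvn_from_precision(
                pg_a.omega, cfg.n_a, rng
            )
            values[np.ix_(b_rows, cols)] = _mvn_from_precision(
                pg_b.omega, cfg.n_b, rng, mean=cfg.mu
            )
    return _assemble_dataset(cfg, genes, values, None), truth


def generate_sample_specific_scenario(
    config: ScenarioConfig,
    interpolation: Literal["offdiag", "full"] = "offdiag",
) -> tuple[ExpressionDataset, ScenarioTruth]:
    """Generate a sample-specific benchmark dataset driven by a modulator.

    Each cell line draws m_alpha ~ U(-1, 1); responsive-subnetwork genes are
    sampled per cell line from the interpolated precision matrix
    ``interpolate_precision(omega, (m_alpha + 1)/2)`` of its phenotype.
    Common subnetworks and background genes are generated as in the bulk
    scenario.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes, truth = _build_truth(cfg, rng)
    n = cfg.n_a + cfg.n_b
    modulator = rng.uniform(-1.0, 1.0, size=n)
    delta = (modulator + 1.0) / 2.0
    values = rng.standard_normal((n, cfg.p))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for spec, label in zip(truth.subnetworks, truth.labels):
        cols = [gene_pos[g] for g in spec.genes]
        if label == "common":
            pg: PrecisionGraph = truth.graphs[spec.name]  # type: ignore[assignment]
            values[:, cols] = _mvn_from_precision(pg.omega, n, rng)
        else:
            pg_a, pg_b = truth.graphs[spec.name]  # type: ignore[misc]
            for alpha in range(n):
                if alpha < cfg.n_a:
                    omega = interpolate_precision(
                        pg_a.omega, delta[alpha], interpolation
                    )
                    mean = 0.0
                else:
                    omega = interpolate_precision(
                        pg_b.omega, delta[alpha], interpolation
                    )
                    mean = cfg.mu
                values[alpha, cols] = _mvn_from_precision(omega, 1, rng, mean)[0]
    return _assemble_dataset(cfg, genes, values, modulator), truth
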