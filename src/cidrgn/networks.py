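"""Gene regulatory network estimation by per-target sparse regression.

Bulk mode regresses each target gene's expression on all other genes of the
universe with an L1 penalty, per phenotype. Sample-specific mode fits, for
each cell line alpha, the same regressions with Gaussian kernel weights
K((m_i - m_alpha)/h) on a scalar modulator m — a varying-coefficient
estimator yielding one network per cell line.

Expression columns are standardized within the estimation subset before the
lasso (penalty fairness across genes); coefficients are reported on the
original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV

from ._solver import coefs_from_gram, standardized_gram
from .data import ExpressionDataset

__all__ = [
    "GeneNetwork",
    "SampleNetworkSet",
    "estimate_network",
    "estimate_sample_specific_networks",
    "neighborhoods",
    "resolve_alpha",
    "silverman_bandwidth",
    "write_edge_list",
    "read_edge_list",
]


@dataclass
class GeneNetwork:
    """Directed weighted network: coef[l, j] is the effect of gene j on target l."""

    genes: list[str]
    coef: np.ndarray
    phenotype_tag: str = ""

    def __post_init__(self) -> None:
        assert self.coef.shape == (len(self.genes), len(self.genes))
        assert np.all(np.isfinite(self.coef)), "non-finite network coefficients"
        assert np.all(np.diag(self.coef) == 0.0), "self-loops are not allowed"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coef, index=self.genes, columns=self.genes)


@dataclass
class SampleNetworkSet:
    """One network per cell line from a varying-coefficient fit.

    ``coef[a, l, j]`` is the effect of regulator j on target l in cell line
    a's network, evaluated at that cell line's modulator value.
    """

    genes: list[str]
    coef: np.ndarray  # (n_cell_lines, g, g)
    modulator: np.ndarray
    cell_lines: list[str]

    def __post_init__(self) -> None:
        n, g1, g2 = self.coef.shape
        assert g1 == g2 == len(self.genes)
        assert n == len(self.modulator) == len(self.cell_lines)

    def network(self, a: int) -> GeneNetwork:
        return GeneNetwork(self.genes, self.coef[a], phenotype_tag=self.cell_lines[a])


# ---------------------------------------------------------------------------
# Penalty selection
# ---------------------------------------------------------------------------

def resolve_alpha(rule, n: int, n_predictors: int) -> float | None:
    """Resolve a lambda rule to a fixed penalty, or None for per-target CV.

    Rules: a float (fixed penalty on the standardized scale); ``"universal"``
    for sqrt(2 log(p)/n); ``"cv1se"`` / ``"cvmin"`` for 5-fold
    cross-validation (1-SE or minimum-MSE rule) resolved per target.
    """
    if isinstance(rule, (int, float)):
        if rule < 0:
            raise ValueError("fixed penalty must be nonnegative")
        return float(rule)
    if rule == "universal":
        return float(np.sqrt(2.0 * np.log(max(n_predictors, 2)) / n))
    if rule in ("cv1se", "cvmin"):
        return None
    raise ValueError(f"unknown lambda rule {rule!r}")


def _cv_lasso_fit(xs: np.ndarray, ys: np.ndarray, rule: str, seed: int) -> np.ndarray:
    """Per-target LassoCV on standardized data; 1-SE rule optional."""
    cv = LassoCV(cv=5, random_state=seed, fit_intercept=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv.fit(xs, ys)
    alpha = float(cv.alpha_)
    if rule == "cv1se":
        mean_mse = cv.mse_path_.mean(axis=1)
        se = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
        best = int(np.argmin(mean_mse))
        limit = mean_mse[best] + se[best]
        # alphas_ is descending; the largest alpha within 1 SE of the best
        within = np.nonzero(mean_mse <= limit)[0]
        alpha = float(cv.alphas_[within[0]])
    m = Lasso(alpha=alpha, fit_intercept=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.fit(xs, ys)
    return m.coef_


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def _estimate_coef_matrix(
    X: np.ndarray,
    lambda_rule,
    weights: np.ndarray | None = None,
    cv_seed: int = 0,
) -> np.ndarray:
    """Per-target lasso over a gene block; coefficients on the original scale."""
    n, g = X.shape
    # for kernel-weighted fits the information content is the effective
    # sample size (sum w)^2 / sum w^2, not the raw row count
    n_eff = n if weights is None else float(weights.sum() ** 2 / (weights**2).sum())
    alpha = resolve_alpha(lambda_rule, n_eff, g - 1)
    G, mean, sd = standardized_gram(X, weights)
    if alpha is not None:
        return coefs_from_gram(G, sd, alpha)
    # CV path: per-target sklearn fits on standardized columns
    ok = sd > 0
    scale = np.where(ok, sd, 1.0)
    xs = (X - mean) / scale
    if weights is not None:
        xs = xs * np.sqrt(weights / weights.mean())[:, None]
    coef = np.zeros((g, g))
    for l in range(g):
        if not ok[l]:
            continue
        idx = [j for j in range(g) if j != l]
        b = _cv_lasso_fit(xs[:, idx], xs[:, l], lambda_rule, cv_seed)
        coef[l, idx] = b * sd[l] / scale[idx]
    coef[:, ~ok] = 0.0
    return coef


def estimate_network(
    dataset: ExpressionDataset | pd.DataFrame,
    phenotype: str | None = None,
    gene_universe: Sequence[str] | None = None,
    lambda_rule="cv1se",
    phenotype_tag: str | None = None,
    cv_seed: int = 0,
) -> GeneNetwork:
    """Estimate a weighted GRN from one phenotype's expression.

    Parameters
    ----------
    dataset : ExpressionDataset or DataFrame
        If an ExpressionDataset, `phenotype` selects the cell lines.
    gene_universe : sequence of str, optional
        Restrict estimation to these genes (default: all genes).
    lambda_rule : "cv1se" | "cvmin" | "universal" | float
        Penalty selection; the default is 5-fold cross-validation with the
        1-SE rule per target gene.
    """
    if isinstance(dataset, ExpressionDataset):
        frame = dataset.values
        if phenotype is not None:
            frame = frame.loc[dataset.mask(phenotype)]
    else:
        frame = dataset
    if gene_universe is not None:
        missing = [g for g in gene_universe if g not in frame.columns]
        if missing:
            raise ValueError(f"genes not in dataset: {missing[:5]}")
        frame = frame[list(gene_universe)]
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 cell lines for network estimation")
    X = frame.to_numpy(dtype=float)
    if (X.std(axis=0) == 0).any():
        const = frame.columns[X.std(axis=0) == 0].tolist()
        warnings.warn(
            f"constant gene column(s) {const[:5]}; their coefficients are zero"
        )
    coef = _estimate_coef_matrix(X, lambda_rule, cv_seed=cv_seed)
    tag = phenotype_tag if phenotype_tag is not None else (phenotype or "")
    return GeneNetwork(genes=frame.columns.tolist(), coef=coef, phenotype_tag=tag)


def select_bandwidth_cv(
    X: np.ndarray,
    m: np.ndarray,
    lambda_rule="universal",
    grid: Sequence[float] | None = None,
) -> float:
    """Leave-one-out bandwidth selection for the varying-coefficient fit.

    For each candidate h, every cell line is predicted from the others'
    kernel-weighted per-target lasso fit evaluated at its modulator value;
    the h minimizing the pooled squared prediction error wins. The default
    grid spans Silverman's rule up to half the modulator range, so the data
    decide between locality (coefficients vary fast in m) and stability
    (coefficients vary slowly, in which case heavy smoothing is better).
    """
    from ._solver import coefs_from_gram, standardized_gram

    n, g = X.shape
    if grid is None:
        sil = silverman_bandwidth(m)
        span = (m.max() - m.min()) / 2.0 or 1.0
        if sil <= 0:
            return 0.0
        grid = sorted({sil, 2 * sil, 4 * sil, span, 2 * span})
    best_h, best_err = float(grid[0]), np.inf
    for h in grid:
        err = 0.0
        for a in range(n):
            w = np.exp(-0.5 * ((m - m[a]) / h) ** 2)
            w[a] = 0.0
            n_eff = float(w.sum() ** 2 / (w**2).sum())
            alpha = resolve_alpha(lambda_rule, n_eff, g - 1)
            if alpha is None:
                raise ValueError("bandwidth CV needs a closed-form lambda rule")
            gram, mean, sd = standardized_gram(X, w)
            coef = coefs_from_gram(gram, sd, alpha)
            resid = (X[a] - mean) - coef @ (X[a] - mean)
            err += float(resid @ resid)
        if err < best_err:
            best_err, best_h = err, float(h)
    return best_h


def silverman_bandwidth(m: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for the modulator values."""
    m = np.asarray(m, dtype=float)
    n = len(m)
    sd = m.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(m, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def estimate_sample_specific_networks(
    dataset: ExpressionDataset,
    gene_universe: Sequence[str] | None = None,
    lambda_rule="universal",
    bandwidth: float | None = None,
    bandwidth_rule: str = "silverman",
) -> SampleNetworkSet:
    """Kernel-weighted varying-coefficient networks, one per cell line.

    Cell line i receives Gaussian kernel weight exp(-((m_i - m_a)/h)^2 / 2)
    when estimating cell line a's network; h defaults to Silverman's rule on
    the modulator. If all modulators coincide the kernel degenerates and the
    estimate falls back to unweighted (every network identical) with a
    warning.
    """
    if dataset.modulator is None:
        raise ValueError("sample-specific estimation requires a modulator")
    frame = dataset.values
    if gene_universe is not None:
        frame = frame[list(gene_universe)]
    X = frame.to_numpy(dtype=float)
    m = dataset.modulator.to_numpy()
    if bandwidth is not None:
        h = bandwidth
    elif bandwidth_rule == "cv":
        h = select_bandwidth_cv(X, m, lambda_rule)
    elif bandwidth_rule == "silverman":
        h = silverman_bandwidth(m)
    else:
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    n, g = X.shape
    coefs = np.empty((n, g, g))
    if h <= 0:
        warnings.warn("degenerate bandwidth (constant modulator); falling back "
                      "to unweighted estimation")
        shared = _estimate_coef_matrix(X, lambda_rule)
        coefs[:] = shared
    else:
        for a in range(n):
            w = np.exp(-0.5 * ((m - m[a]) / h) ** 2)
            coefs[a] = _estimate_coef_matrix(X, lambda_rule, weights=w)
    return SampleNetworkSet(
        genes=frame.columns.tolist(),
        coef=coefs,
        modulator=m,
        cell_lines=[str(c) for c in frame.index],
    )


# ---------------------------------------------------------------------------
# Neighborhoods and edge-list I/O
# ---------------------------------------------------------------------------

def neighborhoods(
    network: GeneNetwork | np.ndarray, edge_threshold: float = 0.0
) -> dict[str, set[str]] | np.ndarray:
    """Undirected neighborhoods: k in N_j iff |coef[j,k]| or |coef[k,j]| > thr.

    Given a GeneNetwork, returns {gene: set of neighbor genes}. Given a bare
    coefficient matrix, returns the symmetric boolean adjacency matrix.
    """
    if edge_threshold < 0:
        raise ValueError("edge_threshold must be nonnegative")
    coef = network.coef if isinstance(network, GeneNetwork) else network
    adj = (np.abs(coef) > edge_threshold) | (np.abs(coef.T) > edge_threshold)
    np.fill_diagonal(adj, False)
    if not isinstance(network, GeneNetwork):
        return adj
    return {
        g: {network.genes[k] for k in np.nonzero(adj[j])[0]}
        for j, g in enumerate(network.genes)
    }


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write nonzero coefficients as TSV: regulator, target, weight."""
    tgt, reg = np.nonzero(network.coef)
    df = pd.DataFrame(
        {
            "regulator": [network.genes[j] for j in reg],
            "target": [network.genes[l] for l in tgt],
            "weight": network.coef[tgt, reg],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(
    path: str | Path, genes: Sequence[str], phenotype_tag: str = ""
) -> GeneNetwork:
    """Read an edge-list TSV back into a GeneNetwork over `genes`."""
    df = pd.read_csv(path, sep="\t")
    pos = {g: i for i, g in enumerate(genes)}
    coef = np.zeros((len(genes), len(genes)))
    for reg, tgt, w in df.itertuples(index=False):
        coef[pos[tgt], pos[reg]] = w
    return GeneNetwork(list(genes), coef, phenotype_tag)
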