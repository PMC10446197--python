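"""Subnetwork dissimilarity statistics.

For a gene set V scored between phenotypes A and B the module computes:

* ``D_SAM-GS`` — sum over genes of squared mean differences standardized by
  the SAM gene-specific scatter plus a stabilizer s0;
* ``D_GSCA`` — mean over gene pairs of squared Pearson-correlation
  differences;
* ``Gamma`` — mean squared distance between per-gene regulatory-effect
  vectors (coefficient × phenotype-mean expression of the regulator);
* ``Lambda`` — mean Jaccard distance between per-gene network neighborhoods;
* ``Gamma_Lambda`` — mean of gamma_j (1 + lambda_j), the Jaccard-adjusted
  regulatory-effect dissimilarity;
* the combined scores CIdrgn.1 = Gamma_Lambda + D_SAM-GS and
  CIdrgn.2 = Gamma + Lambda + D_SAM-GS (on permutation-normalized scales,
  see :mod:`cidrgn.model`);
* sample-specific variants where per-gene effects are phenotype medians of
  per-cell-line effects and neighborhoods are phenotype-wise unions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubnetworkScore",
    "samgs_scatter",
    "samgs_statistic",
    "gsca_statistic",
    "regulatory_effects",
    "gamma_j",
    "gamma_subnetwork",
    "lambda_j",
    "lambda_subnetwork",
    "gamma_lambda_subnetwork",
    "combine",
    "gamma_profile",
    "lambda_profile",
    "ss_effect_tensor",
    "ss_regulatory_effects",
    "ss_gamma_profile",
    "ss_lambda_j",
    "ss_lambda_profile",
    "pearson_difference_matrix",
]


@dataclass
class SubnetworkScore:
    """All per-subnetwork statistics for one gene set."""

    name: str
    genes: list[str]
    gamma: float
    lam: float
    gamma_lambda: float
    samgs: float
    gsca: float
    cidrgn1: float | None = None  # combined scores exist only after
    cidrgn2: float | None = None  # cross-permutation normalization

    def __post_init__(self) -> None:
        assert self.gamma >= 0 and self.samgs >= 0 and self.gsca >= 0
        assert -1e-12 <= self.lam <= 1 + 1e-12
        assert self.gamma_lambda >= self.gamma - 1e-12


# ---------------------------------------------------------------------------
# Expression-level statistics (SAM-GS, GSCA)
# ---------------------------------------------------------------------------

def samgs_scatter(
    values: np.ndarray,
    in_a: np.ndarray,
    in_b: np.ndarray,
    scatter: str = "sqrt",
) -> np.ndarray:
    """Per-gene SAM scatter s_j over all columns of `values`.

    ``scatter="sqrt"`` (default) takes the square root of the pooled scaled
    sum of squared deviations, matching the SAM lineage where s_j is a
    standard-deviation-like quantity; ``"raw"`` keeps the literal pooled sum.
    """
    xa, xb = values[in_a], values[in_b]
    na, nb = xa.shape[0], xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each phenotype needs at least 2 cell lines")
    a = (1.0 / na + 1.0 / nb) / (na + nb - 2.0)
    ss = ((xa - xa.mean(axis=0)) ** 2).sum(axis=0) + (
        (xb - xb.mean(axis=0)) ** 2
    ).sum(axis=0)
    s = a * ss
    if scatter == "sqrt":
        s = np.sqrt(s)
    elif scatter != "raw":
        raise ValueError(f"unknown scatter form {scatter!r}")
    return s


def samgs_statistic(
    values: np.ndarray,
    in_a: np.ndarray,
    in_b: np.ndarray,
    gene_idx: np.ndarray,
    s0: float | str = "median",
    scatter: str = "sqrt",
) -> float:
    """SAM-GS statistic for the genes at `gene_idx` of `values`.

    ``s0="median"`` uses the median scatter over the full gene universe
    (all columns of `values`) as the stabilizer.
    """
    gene_idx = np.asarray(gene_idx)
    if gene_idx.size == 0:
        raise ValueError("empty gene set")
    s_all = samgs_scatter(values, in_a, in_b, scatter)
    if isinstance(s0, str):
        if s0 != "median":
            raise ValueError(f"unknown s0 rule {s0!r}")
        s0 = float(np.median(s_all))
    diff = values[in_a].mean(axis=0) - values[in_b].mean(axis=0)
    d = diff[gene_idx] ** 2 / (s_all[gene_idx] + s0)
    return float(d.sum())


def _safe_corr(x: np.ndarray) -> np.ndarray:
    """Correlation matrix with constant genes contributing correlation 0."""
    sd = x.std(axis=0)
    if (sd == 0).any():
        warnings.warn("constant gene within a phenotype; its correlations "
                      "are treated as 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.atleast_2d(c)
    return np.nan_to_num(c, nan=0.0)


def pearson_difference_matrix(
    values: np.ndarray, in_a: np.ndarray, in_b: np.ndarray, gene_idx: np.ndarray
) -> np.ndarray:
    """Difference of phenotype correlation matrices for a gene block."""
    xa = values[np.ix_(in_a.nonzero()[0], gene_idx)]
    xb = values[np.ix_(in_b.nonzero()[0], gene_idx)]
    return _safe_corr(xa) - _safe_corr(xb)


def gsca_statistic(
    values: np.ndarray, in_a: np.ndarray, in_b: np.ndarray, gene_idx: np.ndarray
) -> float:
    """GSCA dispersion: mean squared correlation difference over gene pairs."""
    gene_idx = np.asarray(gene_idx)
    k = gene_idx.size
    if k < 2:
        raise ValueError("GSCA needs at least 2 genes")
    diff = pearson_difference_matrix(values, in_a, in_b, gene_idx)
    iu = np.triu_indices(k, 1)
    return float((diff[iu] ** 2).sum() / (k * (k - 1) / 2.0))


# ---------------------------------------------------------------------------
# Regulatory-effect dissimilarity (bulk)
# ---------------------------------------------------------------------------

def regulatory_effects(
    coef: np.ndarray, means: np.ndarray, j: int, mean_of: str = "regulator"
) -> np.ndarray:
    """Regulatory-effect vector of gene j: coefficients scaled by mean expression.

    First block (length q = #targets): effect of j on each target l,
    coef[l, j] * mean_j. Second block (length p = #regulators): effect of
    each regulator k on j, coef[j, k] * mean_k. The default scales each
    coefficient by its regulator's phenotype-mean expression;
    ``mean_of="target"`` scales by the target's mean instead (an alternative
    reading of the effect definition).
    """
    if mean_of == "regulator":
        first = coef[:, j] * means[j]
        second = coef[j, :] * means
    elif mean_of == "target":
        first = coef[:, j] * means
        second = coef[j, :] * means[j]
    else:
        raise ValueError(f"unknown mean_of {mean_of!r}")
    return np.concatenate([first, second])


def gamma_j(ra: np.ndarray, rb: np.ndarray) -> float:
    """Squared Euclidean distance of two effect vectors over their length."""
    ra, rb = np.asarray(ra, float), np.asarray(rb, float)
    if ra.shape != rb.shape:
        raise ValueError("effect vectors must have equal length")
    d = ra - rb
    return float(d @ d / d.size)


def gamma_subnetwork(gammas) -> float:
    gammas = np.asarray(gammas, float)
    if gammas.size == 0:
        raise ValueError("empty subnetwork")
    return float(gammas.mean())


def lambda_j(na: set, nb: set) -> float:
    """Jaccard distance of two neighborhoods; two empty sets give 0."""
    union = len(na | nb)
    if union == 0:
        return 0.0
    return 1.0 - len(na & nb) / union


def lambda_subnetwork(lams) -> float:
    lams = np.asarray(lams, float)
    if lams.size == 0:
        raise ValueError("empty subnetwork")
    return float(lams.mean())


def gamma_lambda_subnetwork(gammas, lams) -> float:
    """Mean of gamma_j * (1 + lambda_j) over the subnetwork's genes."""
    gammas, lams = np.asarray(gammas, float), np.asarray(lams, float)
    if gammas.shape != lams.shape:
        raise ValueError("gamma and lambda profiles must align")
    if gammas.size == 0:
        raise ValueError("empty subnetwork")
    return float((gammas * (1.0 + lams)).mean())


def combine(variant: int, *, gamma=None, lam=None, gamma_lambda=None, samgs=None):
    """Combined score from (already normalized) components.

    Variant 1: Gamma_Lambda + D_SAM-GS. Variant 2: Gamma + Lambda + D_SAM-GS.
    Accepts scalars or aligned arrays.
    """
    if variant == 1:
        if gamma_lambda is None or samgs is None:
            raise ValueError("variant 1 needs gamma_lambda and samgs")
        return gamma_lambda + samgs
    if variant == 2:
        if gamma is None or lam is None or samgs is None:
            raise ValueError("variant 2 needs gamma, lam and samgs")
        return gamma + lam + samgs
    raise ValueError(f"unknown variant {variant!r}")


# -- vectorized per-subnetwork profiles -------------------------------------

def gamma_profile(
    coef_a: np.ndarray, coef_b: np.ndarray, mean_a: np.ndarray, mean_b: np.ndarray
) -> np.ndarray:
    """Per-gene gamma_j for a whole gene block (vectorized over j)."""
    ea_first = coef_a * mean_a[None, :]  # effect of j (col) on target l (row)
    eb_first = coef_b * mean_b[None, :]
    d_first = ((ea_first - eb_first) ** 2).sum(axis=0)  # per regulator j
    d_second = ((ea_first - eb_first) ** 2).sum(axis=1)  # per target j
    g = coef_a.shape[0]
    return (d_first + d_second) / (2.0 * g)


def lambda_profile(adj_a: np.ndarray, adj_b: np.ndarray) -> np.ndarray:
    """Per-gene Jaccard distances between two boolean adjacency matrices."""
    inter = (adj_a & adj_b).sum(axis=1)
    union = (adj_a | adj_b).sum(axis=1)
    with np.errstate(invalid="ignore"):
        lam = 1.0 - inter / union
    return np.where(union > 0, lam, 0.0)


# ---------------------------------------------------------------------------
# Sample-specific variants
# ---------------------------------------------------------------------------

def ss_effect_tensor(coef_stack: np.ndarray, values_block: np.ndarray) -> np.ndarray:
    """Per-cell-line effects E[a, l, j] = coef[a, l, j] * x[a, j].

    The same tensor serves both blocks of the effect vector: gene j's vector
    in cell line a is (E[a, :, j], E[a, j, :]).
    """
    return coef_stack * values_block[:, None, :]


def ss_regulatory_effects(
    effects: np.ndarray, member_mask: np.ndarray, j: int
) -> np.ndarray:
    """Phenotype-median effect vector of gene j from the per-cell-line tensor."""
    e = effects[member_mask]
    if e.shape[0] == 0:
        raise ValueError("empty phenotype")
    return np.concatenate(
        [np.median(e[:, :, j], axis=0), np.median(e[:, j, :], axis=0)]
    )


def ss_gamma_profile(
    effects: np.ndarray, in_a: np.ndarray, in_b: np.ndarray
) -> np.ndarray:
    """Per-gene gamma_j^ss between phenotype-median effect matrices."""
    ma = np.median(effects[in_a], axis=0)
    mb = np.median(effects[in_b], axis=0)
    d = (ma - mb) ** 2
    g = d.shape[0]
    return (d.sum(axis=0) + d.sum(axis=1)) / (2.0 * g)


def ss_lambda_j(neigh_by_cell: list[set], in_a: np.ndarray, in_b: np.ndarray) -> float:
    """Jaccard distance between the phenotype-wise unions of neighborhoods."""
    ua: set = set().union(*(neigh_by_cell[i] for i in np.nonzero(in_a)[0]))
    ub: set = set().union(*(neigh_by_cell[i] for i in np.nonzero(in_b)[0]))
    return lambda_j(ua, ub)


def ss_lambda_profile(
    adj_stack: np.ndarray, in_a: np.ndarray, in_b: np.ndarray
) -> np.ndarray:
    """Vectorized lambda_j^ss from a stack of boolean adjacency matrices."""
    ua = adj_stack[in_a].any(axis=0)
    ub = adj_stack[in_b].any(axis=0)
    return lambda_profile(ua, ub)
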