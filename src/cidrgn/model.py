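"""Permutation testing pipeline for differential regulatory network analysis.

:class:`CIdrgn` is the central model object, in the statsmodels mould: it is
built from an :class:`~cidrgn.data.ExpressionDataset` and a list of
subnetworks, and :meth:`CIdrgn.fit` runs the full procedure —

1. estimate phenotype networks per subnetwork (bulk: per-phenotype lasso;
   sample-specific: one kernel-weighted network per cell line);
2. compute the observed dissimilarity statistics Gamma, Lambda,
   Gamma_Lambda, D_SAM-GS (and D_GSCA for the comparator test);
3. draw T label permutations, re-estimate networks and statistics on each;
4. z-score each statistic across its (T+1)-vector per subnetwork so no
   addend dominates the combined scores;
5. form CIdrgn.1 / CIdrgn.2, compute permutation p-values, and flag
   subnetworks with p < kappa as responsive.

The comparator permutation tests (SAM-GS alone and GSCA alone) share the
same permutation draws, so all four methods are evaluated on identical
resamples. Results are returned as a :class:`CIdrgnResults` carrying
per-subnetwork scores, normalized vectors, p-values per method, decisions
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._solver import coefs_from_gram, standardized_gram
from .data import ExpressionDataset, SubnetworkSpec
from .networks import neighborhoods, resolve_alpha
from .statistics import (
    combine,
    gamma_lambda_subnetwork,
    gamma_profile,
    gsca_statistic,
    lambda_profile,
    samgs_scatter,
)

__all__ = [
    "CIdrgn",
    "CIdrgnResults",
    "TestDecision",
    "make_permutation_pair",
    "normalize_across_permutations",
    "permutation_pvalue",
    "run_cidrgn",
]

METHODS = ("samgs", "gsca", "cidrgn1", "cidrgn2")
_STATS = ("gamma", "lam", "gamma_lambda", "samgs")


@dataclass
class TestDecision:
    """Per-subnetwork outcome of the permutation test."""

    subnetwork: str
    p_value: float
    kappa: float
    responsive: bool

    def __post_init__(self) -> None:
        assert self.responsive == (self.p_value < self.kappa)


# ---------------------------------------------------------------------------
# Permutation primitives
# ---------------------------------------------------------------------------

def make_permutation_pair(
    n_total: int, n_a: int, n_b: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint random index sets of sizes n_a and n_b from the pooled cells."""
    if n_a + n_b > n_total:
        raise ValueError("permutation sizes exceed the pooled sample")
    perm = rng.permutation(n_total)
    return perm[:n_a], perm[n_a : n_a + n_b]


def normalize_across_permutations(raw: np.ndarray) -> np.ndarray:
    """Z-score a (T+1)-vector (observed first); constant vectors map to zero."""
    raw = np.asarray(raw, dtype=float)
    sd = raw.std()  # population SD over the T+1 entries
    # relative guard: a numerically constant vector normalizes to zeros
    if sd <= 1e-12 * max(1.0, float(np.abs(raw).max())):
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def permutation_pvalue(
    observed: float, permuted: np.ndarray, rule: str = "plain"
) -> float:
    """Fraction of permutation statistics >= observed (ties count).

    ``rule="plain"`` divides by T as in the defining estimator (p = 0 is
    possible); ``"add-one"`` uses (count+1)/(T+1) for strictly positive
    p-values.
    """
    permuted = np.asarray(permuted, dtype=float)
    t = permuted.size
    if t < 1:
        raise ValueError("need at least one permutation")
    count = int((observed <= permuted).sum())
    if rule == "plain":
        return count / t
    if rule == "add-one":
        return (count + 1) / (t + 1)
    raise ValueError(f"unknown p-value rule {rule!r}")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class CIdrgn:
    """Differential regulatory network permutation test.

    Parameters
    ----------
    dataset : ExpressionDataset
    subnetworks : sequence of SubnetworkSpec
        The gene sets to score.
    mode : "bulk" | "sample_specific"
        Sample-specific mode requires a modulator on the dataset and scores
        phenotype medians/unions over per-cell-line networks.
    variant : 1 | 2
        Which combined score drives the reported decisions (both p-values
        are always computed).
    n_permutations : int
        T, the number of label permutations.
    kappa : float
        Significance threshold on the permutation p-value.
    lambda_rule : "universal" | "cv1se" | "cvmin" | float
        Lasso penalty rule used for every network estimation, observed and
        permuted alike. The pipeline default is the closed-form universal
        penalty sqrt(2 log p / n); cross-validated rules are available but
        cost a CV per target per permutation.
    edge_threshold : float
        Coefficient magnitude above which an edge enters a neighborhood
        (0 means any nonzero coefficient).
    samgs_scatter : "sqrt" | "raw"
        Form of the SAM gene-specific scatter.
    s0_rule : "median" or float
        SAM-GS stabilizer rule.
    pvalue_rule : "plain" | "add-one"
    bandwidth : float, optional
        Kernel bandwidth for sample-specific estimation (default Silverman).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        subnetworks: Sequence[SubnetworkSpec],
        *,
        mode: str = "bulk",
        variant: int = 2,
        n_permutations: int = 100,
        kappa: float = 0.05,
        lambda_rule="universal",
        edge_threshold: float = 0.0,
        samgs_scatter: str = "sqrt",
        s0_rule="median",
        pvalue_rule: str = "plain",
        bandwidth: float | None = None,
        bandwidth_rule: str = "cv",
        compute_network_stats: bool = True,
    ) -> None:
        if mode not in ("bulk", "sample_specific"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "sample_specific" and dataset.modulator is None:
            raise ValueError("sample_specific mode requires a dataset modulator")
        if variant not in (1, 2):
            raise ValueError(f"variant must be 1 or 2, got {variant}")
        if n_permutations < 1:
            raise ValueError("need at least one permutation")
        if not 0.0 < kappa < 1.0:
            raise ValueError("kappa must lie in (0, 1)")
        if not subnetworks:
            raise ValueError("no subnetworks to test")
        gene_pos = {g: i for i, g in enumerate(dataset.genes)}
        for s in subnetworks:
            missing = [g for g in s.genes if g not in gene_pos]
            if missing:
                raise ValueError(f"{s.name}: genes not in dataset: {missing[:5]}")
        self.dataset = dataset
        self.subnetworks = list(subnetworks)
        self.mode = mode
        self.variant = variant
        self.n_permutations = int(n_permutations)
        self.kappa = float(kappa)
        self.lambda_rule = lambda_rule
        self.edge_threshold = float(edge_threshold)
        self.samgs_scatter = samgs_scatter
        self.s0_rule = s0_rule
        self.pvalue_rule = pvalue_rule
        self.bandwidth = bandwidth
        if bandwidth_rule not in ("cv", "silverman"):
            raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
        self.bandwidth_rule = bandwidth_rule
        # speed knob for comparator-only benchmark runs: skip the network
        # statistics entirely (their combined p-values are then meaningless)
        self.compute_network_stats = bool(compute_network_stats)
        self._gene_idx = [
            np.array([gene_pos[g] for g in s.genes]) for s in subnetworks
        ]

    # -- shared statistic machinery -----------------------------------------
    def _samgs_per_subnetwork(
        self, values: np.ndarray, in_a: np.ndarray, in_b: np.ndarray
    ) -> np.ndarray:
        s_all = samgs_scatter(values, in_a, in_b, self.samgs_scatter)
        s0 = (
            float(np.median(s_all))
            if isinstance(self.s0_rule, str)
            else float(self.s0_rule)
        )
        diff2 = (values[in_a].mean(axis=0) - values[in_b].mean(axis=0)) ** 2
        per_gene = diff2 / (s_all + s0)
        return np.array([per_gene[idx].sum() for idx in self._gene_idx])

    def _gsca_per_subnetwork(
        self, values: np.ndarray, in_a: np.ndarray, in_b: np.ndarray
    ) -> np.ndarray:
        return np.array(
            [gsca_statistic(values, in_a, in_b, idx) for idx in self._gene_idx]
        )

    def _bulk_network_stats(
        self, values: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Gamma, Lambda, Gamma_Lambda per subnetwork for one label split."""
        gam = np.empty(len(self._gene_idx))
        lam = np.empty(len(self._gene_idx))
        gl = np.empty(len(self._gene_idx))
        for s, idx in enumerate(self._gene_idx):
            xa = values[np.ix_(rows_a, idx)]
            xb = values[np.ix_(rows_b, idx)]
            alpha = resolve_alpha(self.lambda_rule, xa.shape[0], idx.size - 1)
            if alpha is None:
                from .networks import _estimate_coef_matrix

                ca = _estimate_coef_matrix(xa, self.lambda_rule)
                cb = _estimate_coef_matrix(xb, self.lambda_rule)
            else:
                ga_, _, sda = standardized_gram(xa)
                gb_, _, sdb = standardized_gram(xb)
                ca = coefs_from_gram(ga_, sda, alpha)
                cb = coefs_from_gram(gb_, sdb, alpha)
            gp = gamma_profile(ca, cb, xa.mean(axis=0), xb.mean(axis=0))
            lp = lambda_profile(
                neighborhoods(ca, self.edge_threshold),
                neighborhoods(cb, self.edge_threshold),
            )
            gam[s] = gp.mean()
            lam[s] = lp.mean()
            gl[s] = gamma_lambda_subnetwork(gp, lp)
        return gam, lam, gl

    # -- fitting -------------------------------------------------------------
    def fit(self, seed: int | np.random.SeedSequence | None = None) -> "CIdrgnResults":
        """Run the full permutation procedure; reproducible from `seed`."""
        rng = np.random.default_rng(seed)
        values = self.dataset.values.to_numpy(dtype=float)
        lev_a, lev_b = self.dataset.levels
        in_a = self.dataset.mask(lev_a)
        in_b = self.dataset.mask(lev_b)
        n_a, n_b = int(in_a.sum()), int(in_b.sum())
        n = values.shape[0]
        t = self.n_permutations
        n_sub = len(self.subnetworks)

        raw = {k: np.empty((n_sub, t + 1)) for k in _STATS}
        gsca = np.empty((n_sub, t + 1))

        splits = [(np.nonzero(in_a)[0], np.nonzero(in_b)[0])]
        for _ in range(t):
            splits.append(make_permutation_pair(n, n_a, n_b, rng))

        # the kernel bandwidth is chosen once, on the observed split, and
        # reused for every permutation replicate (same discipline as the
        # lasso penalty rule)
        self._fit_bandwidth: float | None = self.bandwidth
        if (
            self.mode == "sample_specific"
            and self.compute_network_stats
            and self.bandwidth is None
            and self.bandwidth_rule == "cv"
        ):
            self._fit_bandwidth = self._select_bandwidth(
                values, splits[0][0], splits[0][1]
            )

        for pm, (rows_a, rows_b) in enumerate(splits):
            ma = np.zeros(n, dtype=bool)
            mb = np.zeros(n, dtype=bool)
            ma[rows_a] = True
            mb[rows_b] = True
            raw["samgs"][:, pm] = self._samgs_per_subnetwork(values, ma, mb)
            gsca[:, pm] = self._gsca_per_subnetwork(values, ma, mb)
            if not self.compute_network_stats:
                g_ = l_ = gl_ = np.zeros(n_sub)
            elif self.mode == "bulk":
                g_, l_, gl_ = self._bulk_network_stats(values, rows_a, rows_b)
            else:
                g_, l_, gl_ = self._ss_network_stats(values, rows_a, rows_b)
            raw["gamma"][:, pm] = g_
            raw["lam"][:, pm] = l_
            raw["gamma_lambda"][:, pm] = gl_

        normalized = {
            k: np.apply_along_axis(normalize_across_permutations, 1, raw[k])
            for k in _STATS
        }
        c1 = combine(1, gamma_lambda=normalized["gamma_lambda"], samgs=normalized["samgs"])
        c2 = combine(
            2,
            gamma=normalized["gamma"],
            lam=normalized["lam"],
            samgs=normalized["samgs"],
        )
        pvals = pd.DataFrame(
            {
                "samgs": [
                    permutation_pvalue(raw["samgs"][s, 0], raw["samgs"][s, 1:], self.pvalue_rule)
                    for s in range(n_sub)
                ],
                "gsca": [
                    permutation_pvalue(gsca[s, 0], gsca[s, 1:], self.pvalue_rule)
                    for s in range(n_sub)
                ],
                "cidrgn1": [
                    permutation_pvalue(c1[s, 0], c1[s, 1:], self.pvalue_rule)
                    for s in range(n_sub)
                ],
                "cidrgn2": [
                    permutation_pvalue(c2[s, 0], c2[s, 1:], self.pvalue_rule)
                    for s in range(n_sub)
                ],
            },
            index=[s.name for s in self.subnetworks],
        )
        raw["gsca"] = gsca
        return CIdrgnResults(
            model=self,
            raw=raw,
            normalized=normalized,
            combined={"cidrgn1": c1, "cidrgn2": c2},
            p_values=pvals,
        )

    # -- sample-specific internals -------------------------------------------
    def _select_bandwidth(
        self, values: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray
    ) -> float:
        """Median of per-side, per-subnetwork leave-one-out CV bandwidths."""
        from .networks import select_bandwidth_cv

        mod = self.dataset.modulator.to_numpy()
        picks = []
        for idx in self._gene_idx:
            for rows in (rows_a, rows_b):
                picks.append(
                    select_bandwidth_cv(
                        values[np.ix_(rows, idx)], mod[rows], self.lambda_rule
                    )
                )
        return float(np.median(picks))

    def _ss_side(
        self, values: np.ndarray, rows: np.ndarray, idx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Median effect matrix and union adjacency for one phenotype side.

        Each cell line of the side gets its own kernel-weighted network,
        estimated from the side's cell lines only (the sample-specific
        analogue of per-phenotype bulk estimation), so permutation replicates
        re-estimate the networks on the permuted partition.
        """
        from .networks import silverman_bandwidth

        X = values[np.ix_(rows, idx)]
        m = self.dataset.modulator.to_numpy()[rows]
        h = (
            self._fit_bandwidth
            if self._fit_bandwidth is not None
            else silverman_bandwidth(m)
        )
        n_side, g = X.shape
        effects = np.empty((n_side, g, g))
        union_adj = np.zeros((g, g), dtype=bool)
        for a in range(n_side):
            w = (
                np.exp(-0.5 * ((m - m[a]) / h) ** 2)
                if h > 0
                else np.ones(n_side)
            )
            gram, _, sd = standardized_gram(X, w)
            alpha = resolve_alpha(
                self.lambda_rule,
                float(w.sum() ** 2 / (w**2).sum()),
                g - 1,
            )
            if alpha is None:
                raise ValueError(
                    "sample_specific mode needs a closed-form lambda rule"
                )
            coef = coefs_from_gram(gram, sd, alpha)
            effects[a] = coef * X[a][None, :]
            union_adj |= (np.abs(coef) > self.edge_threshold) | (
                np.abs(coef.T) > self.edge_threshold
            )
        np.fill_diagonal(union_adj, False)
        return np.median(effects, axis=0), union_adj

    def _ss_network_stats(
        self, values: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n_sub = len(self._gene_idx)
        gam = np.empty(n_sub)
        lam = np.empty(n_sub)
        gl = np.empty(n_sub)
        for s, idx in enumerate(self._gene_idx):
            med_a, adj_a = self._ss_side(values, rows_a, idx)
            med_b, adj_b = self._ss_side(values, rows_b, idx)
            d = (med_a - med_b) ** 2
            gp = (d.sum(axis=0) + d.sum(axis=1)) / (2.0 * idx.size)
            lp = lambda_profile(adj_a, adj_b)
            gam[s] = gp.mean()
            lam[s] = lp.mean()
            gl[s] = gamma_lambda_subnetwork(gp, lp)
        return gam, lam, gl


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class CIdrgnResults:
    """Fitted permutation ensemble: observed + permuted statistics, p-values."""

    model: CIdrgn
    raw: dict[str, np.ndarray]  # stat -> (n_subnetworks, T+1), observed first
    normalized: dict[str, np.ndarray]
    combined: dict[str, np.ndarray]
    p_values: pd.DataFrame  # columns = METHODS

    @property
    def T(self) -> int:
        return self.raw["samgs"].shape[1] - 1

    @property
    def observed(self) -> pd.DataFrame:
        """Observed (unnormalized) statistics per subnetwork."""
        names = [s.name for s in self.model.subnetworks]
        return pd.DataFrame(
            {
                "gamma": self.raw["gamma"][:, 0],
                "lambda": self.raw["lam"][:, 0],
                "gamma_lambda": self.raw["gamma_lambda"][:, 0],
                "samgs": self.raw["samgs"][:, 0],
                "gsca": self.raw["gsca"][:, 0],
            },
            index=names,
        )

    def decisions(
        self, method: str | None = None, correction: str | None = None
    ) -> pd.DataFrame:
        """Responsive calls at the model's kappa for one method.

        ``correction="bh"`` applies Benjamini–Hochberg across the tested
        subnetworks before thresholding (off by default: the benchmark design
        tests each subnetwork at raw kappa).
        """
        method = method or f"cidrgn{self.model.variant}"
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        p = self.p_values[method]
        if correction == "bh":
            from scipy.stats import false_discovery_control

            p = pd.Series(false_discovery_control(p, method="bh"), index=p.index)
        elif correction is not None:
            raise ValueError(f"unknown correction {correction!r}")
        return pd.DataFrame(
            {
                "p_value": p,
                "kappa": self.model.kappa,
                "responsive": p < self.model.kappa,
            }
        )

    def decision_objects(self, method: str | None = None) -> list[TestDecision]:
        df = self.decisions(method)
        return [
            TestDecision(str(i), float(r.p_value), float(r.kappa), bool(r.responsive))
            for i, r in df.iterrows()
        ]

    def summary(self) -> str:
        """Readable per-subnetwork table of statistics and p-values."""
        obs = self.observed.copy()
        for m in METHODS:
            obs[f"p_{m}"] = self.p_values[m]
        dec = self.decisions()
        obs["responsive"] = dec["responsive"]
        lines = [
            "Differential regulatory network permutation test",
            f"mode={self.model.mode}  variant={self.model.variant}  "
            f"T={self.T}  kappa={self.model.kappa}  "
            f"lambda_rule={self.model.lambda_rule}",
            "",
            obs.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def run_cidrgn(
    dataset: ExpressionDataset,
    subnetworks: Sequence[SubnetworkSpec],
    n_permutations: int = 100,
    kappa: float = 0.05,
    variant: int = 2,
    mode: str = "bulk",
    seed=None,
    **config,
) -> tuple[list[TestDecision], CIdrgnResults]:
    """Functional wrapper: run the full procedure and return decisions."""
    model = CIdrgn(
        dataset,
        subnetworks,
        mode=mode,
        variant=variant,
        n_permutations=n_permutations,
        kappa=kappa,
        **config,
    )
    res = model.fit(seed=seed)
    return res.decision_objects(), res
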