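"""Dietary Gaussian-graphical-model network, centrality weights, and scores.

The whole-diet intake score is built in three steps: (1) estimate a sparse
partial-correlation network over the 16 food groups by graphical lasso, with
the regularization penalty selected by the extended Bayesian information
criterion (EBIC, gamma = 0.5 by default); (2) weight each food group by its
max-normalized eigenvector centrality in that network; (3) score each subject
by the centrality-weighted sum of daily intakes (g/day) and cut the scores
into tertiles labelled light / normal / heavy eating behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

__all__ = [
    "PartialCorrelationNetwork",
    "CentralityWeights",
    "ebic",
    "estimate_ggm",
    "partial_correlations",
    "eigenvector_centrality",
    "dietary_score",
    "tertile_classes",
    "score_cohort",
]

EATING_BEHAVIOR_LEVELS = ("light", "normal", "heavy")

#: Entries of the estimated precision smaller than this (absolute) are
#: treated as shrunk to exactly zero by the lasso penalty.
_ZERO_TOL = 1e-8


@dataclass
class PartialCorrelationNetwork:
    """Symmetric regularized partial-correlation matrix over food groups.

    ``weights[i, j]`` is the partial correlation of groups i and j given all
    other groups; entries removed by the selected penalty are exactly 0.
    """

    labels: list[str]
    weights: np.ndarray
    selected_penalty: float = 0.0
    ebic_gamma: float = 0.5
    ebic_value: float = float("nan")
    n_samples: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        p = len(self.labels)
        if w.shape != (p, p):
            raise ValueError(f"weights must be {p}x{p}, got {w.shape}")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric (tol 1e-12)")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("weights must have a zero diagonal")
        if np.any(np.abs(w) >= 1.0):
            raise ValueError("partial correlations must satisfy |rho| < 1")
        self.weights = w

    @property
    def n_edges(self) -> int:
        """Number of nonzero edges (upper triangle)."""
        iu = np.triu_indices_from(self.weights, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)

    def edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices_from(self.weights, k=1)
        rows = [
            (self.labels[i], self.labels[j], self.weights[i, j])
            for i, j in zip(*iu)
            if self.weights[i, j] != 0.0
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def to_graph(self):
        """Weighted undirected :class:`networkx.Graph` of the nonzero edges."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        return g


@dataclass
class CentralityWeights:
    """Per-food-group eigenvector centrality, scaled so the maximum is 1."""

    labels: list[str]
    weight: np.ndarray
    convention: str = "positive"

    def __post_init__(self) -> None:
        w = np.asarray(self.weight, dtype=float)
        if w.shape != (len(self.labels),):
            raise ValueError("one weight per label required")
        if not np.isclose(w.max(), 1.0):
            raise ValueError("weights must be max-normalized (max == 1)")
        if self.convention != "signed" and np.any(w < -1e-12):
            raise ValueError("centrality weights must be nonnegative")
        self.weight = w

    def to_series(self) -> pd.Series:
        return pd.Series(self.weight, index=self.labels, name="centrality")


def ebic(loglik: float, n: int, p: int, n_edges: int, gamma: float) -> float:
    """Extended Bayesian information criterion for a Gaussian graphical model.

    ``-2 loglik + E log n + 4 E gamma log p`` with ``E`` the number of nonzero
    off-diagonal edges (upper triangle).  ``gamma = 0`` recovers ordinary BIC.
    """
    if n < 0 or p < 0 or n_edges < 0:
        raise ValueError("n, p and n_edges must be nonnegative")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)


def _gaussian_loglik(precision: np.ndarray, emp_cov: np.ndarray, n: int) -> float:
    p = precision.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(emp_cov @ precision) - p * np.log(2 * np.pi))


def partial_correlations(cov: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix implied by a covariance matrix.

    Inverts the covariance and rescales: ``rho_ij = -w_ij / sqrt(w_ii w_jj)``,
    with a zero diagonal.  Serves as the closed-form (penalty-free) oracle for
    the graphical-lasso estimate.
    """
    cov = np.asarray(cov, dtype=float)
    prec = np.linalg.inv(cov)
    d = np.sqrt(np.diag(prec))
    rho = -prec / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


def _precision_to_pcor(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    rho[np.abs(rho) < _ZERO_TOL] = 0.0
    return rho


def default_penalty_grid(emp_corr: np.ndarray, size: int = 100) -> np.ndarray:
    """Log-spaced penalty grid from 1% of the largest |off-diagonal| up to it."""
    iu = np.triu_indices_from(emp_corr, k=1)
    lam_max = float(np.max(np.abs(emp_corr[iu])))
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(np.log10(0.01 * lam_max), np.log10(lam_max), size)


def estimate_ggm(
    intakes: pd.DataFrame | np.ndarray,
    gamma: float = 0.5,
    penalty_grid: np.ndarray | None = None,
    grid_size: int = 100,
) -> PartialCorrelationNetwork:
    """Estimate the sparse food-group network by EBIC-selected graphical lasso.

    Columns are standardized (partial correlations are scale-free, so this is
    presentational), a sparse precision matrix is fit for every penalty on the
    grid, and the network minimizing the EBIC at the given ``gamma`` is
    returned as a partial-correlation matrix.

    Parameters
    ----------
    intakes
        n x p matrix of intakes (g/day), n > p, complete, positive variance.
    gamma
        EBIC edge-penalty weight; 0 gives ordinary BIC.
    penalty_grid
        Optional explicit grid of nonnegative lasso penalties.  A penalty of
        exactly 0 is solved by direct inversion of the sample covariance when
        it is nonsingular (and dropped, with a warning, when it is not).
    """
    if isinstance(intakes, pd.DataFrame):
        labels = [str(c) for c in intakes.columns]
        X = intakes.to_numpy(dtype=float)
    else:
        X = np.asarray(intakes, dtype=float)
        labels = [f"v{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples than variables (n={n}, p={p})")
    if np.isnan(X).any():
        raise ValueError("intakes contain missing values")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        bad = [labels[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"columns with zero variance: {bad}")

    Z = (X - X.mean(axis=0)) / sd
    S = (Z.T @ Z) / n

    if penalty_grid is None:
        penalty_grid = default_penalty_grid(S, size=grid_size)
    grid = np.sort(np.asarray(penalty_grid, dtype=float))
    if np.any(grid < 0):
        raise ValueError("penalties must be nonnegative")

    best: tuple[float, float, np.ndarray] | None = None  # (ebic, alpha, prec)
    for alpha in grid:
        if alpha == 0.0:
            if np.linalg.cond(S) > 1e12:
                warnings.warn(
                    "sample covariance is singular at penalty 0; "
                    "restricting the grid to positive penalties",
                    stacklevel=2,
                )
                continue
            prec = np.linalg.inv(S)
        else:
            try:
                with warnings.catch_warnings():
                    # near-zero penalties stop at tiny dual gaps; harmless here
                    warnings.simplefilter("ignore")
                    _, prec = graphical_lasso(S, alpha=float(alpha), max_iter=200)
            except FloatingPointError:  # pragma: no cover - degenerate grids
                continue
        off = prec.copy()
        np.fill_diagonal(off, 0.0)
        n_edges = int(np.count_nonzero(np.abs(np.triu(off, k=1)) > _ZERO_TOL))
        crit = ebic(_gaussian_loglik(prec, S, n), n, p, n_edges, gamma)
        if best is None or crit < best[0]:
            best = (crit, float(alpha), prec)

    if best is None:
        raise RuntimeError("no penalty on the grid produced a valid fit")
    crit, alpha, prec = best
    return PartialCorrelationNetwork(
        labels=labels,
        weights=_precision_to_pcor(prec),
        selected_penalty=alpha,
        ebic_gamma=gamma,
        ebic_value=crit,
        n_samples=n,
    )


def eigenvector_centrality(
    network: PartialCorrelationNetwork,
    convention: str = "positive",
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> CentralityWeights:
    """Eigenvector centrality of the food-group network, max-normalized.

    Power iteration on the edge-weight matrix until successive max-normalized
    iterates differ by less than ``tol`` in max-norm; the result is scaled so
    the most central node is exactly 1 and isolated nodes are 0.

    ``convention`` controls how the signed partial correlations enter the
    adjacency: ``"positive"`` (default) keeps only positive edges, the
    convention under which eigenvector centrality is well defined by
    Perron-Frobenius and which reproduces the published weights;
    ``"absolute"`` uses |rho|; ``"signed"`` uses rho as-is (entries of the
    resulting vector may then be negative).
    """
    if convention == "positive":
        M = np.where(network.weights > 0, network.weights, 0.0)
    elif convention == "absolute":
        M = np.abs(network.weights)
    elif convention == "signed":
        M = network.weights.copy()
    else:
        raise ValueError(f"unknown convention: {convention!r}")
    if not np.any(M):
        raise ValueError("network has no usable edges; centrality undefined")

    # spectral shift: bipartite-like graphs have +-lambda eigenvalue pairs on
    # which plain power iteration oscillates; M + sigma*I keeps the same
    # eigenvectors while making the leading eigenvalue strictly dominant
    sigma = 1.0 + float(np.abs(M).sum(axis=1).max())
    Ms = M + sigma * np.eye(M.shape[0])

    v = np.ones(M.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        w = Ms @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise RuntimeError("power iteration collapsed to the zero vector")
        w /= norm
        # sign-fix so the dominant component stays positive across iterations
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError(
            f"power iteration did not converge within {max_iter} iterations "
            f"(residual {np.max(np.abs(Ms @ v / np.linalg.norm(Ms @ v) - v)):.2e})"
        )
    centr = v / np.max(v)
    if convention != "signed":
        centr = np.clip(centr, 0.0, None)
    return CentralityWeights(labels=list(network.labels), weight=centr, convention=convention)


def dietary_score(
    intake: pd.Series | np.ndarray | pd.DataFrame, weights: CentralityWeights
) -> float | np.ndarray:
    """Centrality-weighted whole-diet intake, in g/day.

    ``score = sum_g weight_g * intake_g``.  Accepts a single 16-vector or an
    n x 16 table; labelled inputs must match the weight labels.
    """
    w = weights.weight
    if isinstance(intake, pd.DataFrame):
        if list(intake.columns) != list(weights.labels):
            raise ValueError("intake columns do not match weight labels")
        x = intake.to_numpy(dtype=float)
    elif isinstance(intake, pd.Series):
        if list(intake.index) != list(weights.labels):
            raise ValueError("intake index does not match weight labels")
        x = intake.to_numpy(dtype=float)
    else:
        x = np.asarray(intake, dtype=float)
        if x.shape[-1] != len(weights.labels):
            raise ValueError("intake length does not match weight labels")
    if np.any(x < 0):
        raise ValueError("intakes must be nonnegative")
    return x @ w


def tertile_classes(scores: np.ndarray | pd.Series) -> np.ndarray:
    """Cut dietary scores into light / normal / heavy tertiles.

    Cutpoints are the empirical 1/3 and 2/3 quantiles; ties on a cutpoint go
    to the lower class (``score <= q1/3`` is light).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 3:
        raise ValueError("at least 3 subjects are required for tertiles")
    if np.all(s == s[0]):
        raise ValueError("all scores identical; tertiles undefined")
    q1, q2 = np.quantile(s, [1 / 3, 2 / 3])
    out = np.where(s <= q1, "light", np.where(s <= q2, "normal", "heavy"))
    return out.astype(object)


def score_cohort(
    intakes: pd.DataFrame, weights: CentralityWeights, assign_tertiles: bool = True
) -> pd.DataFrame:
    """Per-subject dietary score (and eating-behavior tertile) table."""
    scores = dietary_score(intakes, weights)
    out = pd.DataFrame({"dietary_score": scores}, index=intakes.index)
    if assign_tertiles:
        out["eating_behavior"] = tertile_classes(out["dietary_score"].to_numpy())
    return out
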