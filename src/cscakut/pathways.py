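"""Gene-set (pathway) burden enrichment via logistic regression.

For each gene set, every individual's gene burdens over the member genes
are summed into a per-person total score, which enters a logistic model

    logit P(case) = b0 + b1 * score.

The enrichment odds ratio is exp(b1) per unit of total score, with a Wald
95% CI and p-value from the maximum-likelihood fit.  With few cases and
rare scores the MLE can diverge (quasi-complete separation); such fits fall
back to Firth's bias-reduced logistic regression, reporting a penalized
likelihood-ratio p and carrying a separation flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

from .burden import BurdenMatrix
from .io_formats import GeneSet, GeneSetCollection, SampleTable


@dataclass
class PathwayScoreVector:
    set_name: str
    scores: np.ndarray  # per-sample total burden over member genes


@dataclass
class PathwayResult:
    set_name: str
    source: str
    odds_ratio: float | None
    ci95_low: float | None
    ci95_high: float | None
    p_value: float | None
    n_case_nonzero: int
    n_control_nonzero: int
    separation_flag: bool = False
    converged: bool = True
    untestable: bool = False


def aggregate_set_score(burden_matrix: BurdenMatrix, gene_set: GeneSet,
                        set_name: str = "") -> PathwayScoreVector:
    """Per-person total score: sum of gene burdens over member genes.

    Genes absent from the burden matrix contribute 0; linear in the matrix.
    """
    cols = [burden_matrix.gene_index[g] for g in gene_set.genes if g in burden_matrix.gene_index]
    if cols:
        scores = burden_matrix.values[:, cols].sum(axis=1)
    else:
        scores = np.zeros(burden_matrix.values.shape[0])
    return PathwayScoreVector(set_name=set_name, scores=scores)


# ---------------------------------------------------------------------------
# Firth bias-reduced logistic regression (used on separation)
# ---------------------------------------------------------------------------


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Newton iterations on Jeffreys-penalized logistic likelihood.

    Returns (beta, covariance, penalized log-likelihood, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)

    def penalized_ll(b):
        eta = X @ b
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        W = mu * (1 - mu)
        info = (X * W[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        return ll + 0.5 * logdet if sign > 0 else -np.inf

    ll_old = penalized_ll(beta)
    cov = None
    converged = False
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = np.clip(mu * (1 - mu), 1e-12, None)
        info = (X * W[:, None]).T @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = W * np.einsum("ij,jk,ik->i", X, cov, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cov @ score
        # step-halving to ensure the penalized likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            ll_new = penalized_ll(beta + factor * step)
            if ll_new >= ll_old - 1e-12:
                break
            factor /= 2
        beta = beta + factor * step
        if ll_new > -np.inf:
            ll_old = ll_new
        if np.max(np.abs(factor * step)) < tol:
            converged = True
            break
    mu = expit(X @ beta)
    W = np.clip(mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    return beta, cov, ll_old, converged


def logistic_enrichment(
    score_vector: PathwayScoreVector | np.ndarray,
    sample_table: SampleTable,
    source: str = "custom",
) -> PathwayResult:
    """Fit logit P(case) = b0 + b1*score; OR = exp(b1) per unit score.

    Standard IRLS fit with Wald CI/p; Firth bias-reduction with a penalized
    likelihood-ratio p on detected separation or non-convergence (flagged).
    """
    if isinstance(score_vector, PathwayScoreVector):
        name, x = score_vector.set_name, score_vector.scores
    else:
        name, x = "", np.asarray(score_vector, dtype=float)
    y = sample_table.case_mask.astype(float)
    case = sample_table.case_mask
    n_case_nz = int((x[case] != 0).sum())
    n_ctrl_nz = int((x[~case] != 0).sum())

    if np.all(x == x[0]):
        return PathwayResult(name, source, None, None, None, None,
                             n_case_nz, n_ctrl_nz, untestable=True)

    X = np.column_stack([np.ones_like(x), x])
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, warn_convergence=False)
        beta1 = float(fit.params[1])
        se1 = float(fit.bse[1])
        if (not fit.mle_retvals.get("converged", False)) or abs(beta1) > 15 or se1 > 50:
            separation = True
    except Exception:
        separation = True

    if not separation:
        or_ = float(np.exp(beta1))
        return PathwayResult(
            name, source,
            odds_ratio=or_,
            ci95_low=float(np.exp(beta1 - 1.96 * se1)),
            ci95_high=float(np.exp(beta1 + 1.96 * se1)),
            p_value=float(fit.pvalues[1]),
            n_case_nonzero=n_case_nz,
            n_control_nonzero=n_ctrl_nz,
        )

    # Firth path
    beta, cov, ll_full, conv_full = _firth_fit(X, y)
    beta0_null, _, ll_null, _ = _firth_fit(X[:, :1], y)
    lr = max(0.0, 2 * (ll_full - ll_null))
    p = float(chi2_dist.sf(lr, 1))
    se1 = float(np.sqrt(cov[1, 1]))
    b1 = float(beta[1])
    return PathwayResult(
        name, source,
        odds_ratio=float(np.exp(b1)),
        ci95_low=float(np.exp(b1 - 1.96 * se1)),
        ci95_high=float(np.exp(b1 + 1.96 * se1)),
        p_value=min(max(p, 1e-300), 1.0),
        n_case_nonzero=n_case_nz,
        n_control_nonzero=n_ctrl_nz,
        separation_flag=True,
        converged=conv_full,
    )


def run_pathway_scan(
    burden_matrix: BurdenMatrix,
    collection: GeneSetCollection,
    sample_table: SampleTable,
    top_k: int = 15,
) -> tuple[list[PathwayResult], list[PathwayResult]]:
    """One logistic enrichment result per testable set, ranked by p.

    Returns (all results sorted ascending by p, the top-``top_k`` forest
    table). Untestable (constant-score) sets sort last with p = None.
    Output is invariant to the ordering of the collection.
    """
    results = []
    for name in sorted(collection.sets):
        gs = collection.sets[name]
        sv = aggregate_set_score(burden_matrix, gs, set_name=name)
        results.append(logistic_enrichment(sv, sample_table, source=gs.source))
    results.sort(key=lambda r: (r.p_value if r.p_value is not None else 2.0, r.set_name))
    testable = [r for r in results if not r.untestable]
    return results, testable[:top_k]
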