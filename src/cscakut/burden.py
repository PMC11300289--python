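"""Weighted gene-based burden testing with Cauchy p-value combination.

The per-individual burden of a gene is the *maximum* mask weight among the
burden-eligible ultra-rare variants that individual carries (0 if none).
Each gene's association p-value is an omnibus:

* for every mask level present in the gene, a score test of the
  level-restricted max-weight burden against case status;
* when a gene harbours >= 2 levels, an additional score test of the overall
  max-weight burden;
* the component p-values are combined with the Cauchy (ACAT) combination,
  weighted by the mask weights (the overall component by the largest one).

Sparse-carrier handling.  With tens of cases against thousands of controls
almost every gene has only a handful of carriers, where the asymptotic
score test is anti-conservative and the exact permutation tail is heavily
discrete (hence conservative).  Below ``min_carriers_asymptotic`` carriers
the test therefore enumerates the complete label-permutation distribution
and by default reports the *fuzzy* (randomized) p-value

    p = P(T > t_obs) + U * P(T = t_obs),   U ~ Uniform(0, 1),

which is exactly Uniform(0,1) under the null and keeps the genome-wide scan
calibrated.  The conservative tail ``P(T >= t_obs)`` and mid-p variants are
always computed alongside for inspection.

A nominal two-sided Fisher's exact test on carrier counts, with
Haldane-Anscombe-corrected odds ratio and Woolf confidence interval,
accompanies every gene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .io_formats import SampleTable
from .masks import MaskedVariant

# ---------------------------------------------------------------------------
# Burden matrix
# ---------------------------------------------------------------------------


@dataclass
class BurdenMatrix:
    """Samples x genes matrix of max-weight burden values in [0, 1]."""

    values: np.ndarray
    sample_ids: list[str]
    genes: list[str]
    gene_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.gene_index = {g: j for j, g in enumerate(self.genes)}

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index[gene]]


def compute_burden_matrix(
    eligible: Sequence[MaskedVariant], sample_table: SampleTable
) -> BurdenMatrix:
    """Max mask weight carried per sample per gene; carrier semantics (het == hom)."""
    genes = sorted({mv.gene_symbol for mv in eligible})
    gene_index = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(sample_table), len(genes)))
    for mv in eligible:
        j = gene_index[mv.gene_symbol]
        idx = mv.carriers()
        np.maximum.at(values[:, j], idx, mv.weight)
    return BurdenMatrix(values=values, sample_ids=list(sample_table.sample_ids), genes=genes)


# ---------------------------------------------------------------------------
# Score / permutation burden test
# ---------------------------------------------------------------------------


@dataclass
class ScoreTestResult:
    p: float | None
    statistic: float | None
    method: str  # "score", "permutation", "permutation_mc", "untestable"
    p_conservative: float | None = None
    p_midp: float | None = None
    p_gt: float | None = None
    p_eq: float | None = None
    untestable: bool = False


def _log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def burden_score_test(
    burden_column: np.ndarray,
    case_mask: np.ndarray,
    mode: str = "randomized",
    rng: np.random.Generator | None = None,
    min_carriers_asymptotic: int = 10,
    n_permutations: int | None = None,
) -> ScoreTestResult:
    """Two-sided test of association between a burden column and case status.

    Uses the logistic-regression score statistic ``T = U^2 / V`` with
    ``U = sum_i x_i (y_i - ybar)`` and ``V = ybar (1 - ybar) sum_i (x_i - xbar)^2``.
    Below ``min_carriers_asymptotic`` nonzero entries the permutation
    distribution of T is enumerated exactly; ``mode`` selects which p-value
    is reported ("randomized" fuzzy p, "conservative" P(T>=t), or "midp").
    ``n_permutations`` forces a Monte-Carlo permutation p for larger carrier
    counts (validation use).
    """
    x = np.asarray(burden_column, dtype=float)
    y = np.asarray(case_mask, dtype=bool)
    n = x.size
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both phenotype classes must be present")
    if np.all(x == x[0]):  # constant column (including all-zero)
        return ScoreTestResult(p=None, statistic=None, method="untestable", untestable=True)

    ybar = n1 / n
    xbar = x.mean()
    u_obs = float(x @ (y - ybar))
    v = ybar * (1 - ybar) * float(((x - xbar) ** 2).sum())
    t_obs = u_obs**2 / v

    carriers = np.flatnonzero(x != 0)
    k = carriers.size

    if k < min_carriers_asymptotic:
        # exact enumeration over which carriers are assigned case labels
        xc = x[carriers]
        sx = float(xc.sum())
        log_denom = _log_choose(n, n1)
        t_vals = np.empty(2**k)
        log_p = np.empty(2**k)
        for s in range(2**k):
            bits = [(s >> i) & 1 for i in range(k)]
            j = sum(bits)
            u = float(sum(b * w for b, w in zip(bits, xc))) - ybar * sx
            t_vals[s] = u**2 / v
            log_p[s] = _log_choose(n - k, n1 - j) - log_denom if n1 - j >= 0 else -np.inf
        probs = np.exp(log_p)
        probs /= probs.sum()  # guards lgamma rounding; sums to 1 analytically
        eps = 1e-9 * max(t_obs, 1.0)
        p_gt = float(probs[t_vals > t_obs + eps].sum())
        p_eq = float(probs[np.abs(t_vals - t_obs) <= eps].sum())
        p_cons = p_gt + p_eq
        p_mid = p_gt + 0.5 * p_eq
        if mode == "randomized":
            u_rand = (rng or np.random.default_rng()).random()
            p = p_gt + u_rand * p_eq
        elif mode == "conservative":
            p = p_cons
        elif mode == "midp":
            p = p_mid
        else:
            raise ValueError(f"unknown mode {mode!r}")
        p = min(max(p, 1e-300), 1.0)
        return ScoreTestResult(
            p=p, statistic=t_obs, method="permutation",
            p_conservative=p_cons, p_midp=p_mid, p_gt=p_gt, p_eq=p_eq,
        )

    if n_permutations is not None:
        rng = rng or np.random.default_rng()
        exceed = 0
        for _ in range(n_permutations):
            case_idx = rng.choice(n, size=n1, replace=False)
            u = float(x[case_idx].sum()) - n1 * xbar
            if u**2 / v >= t_obs * (1 - 1e-12):
                exceed += 1
        p = (exceed + 1) / (n_permutations + 1)
        return ScoreTestResult(p=p, statistic=t_obs, method="permutation_mc",
                               p_conservative=p, p_gt=p, p_eq=0.0)

    p = float(chi2_dist.sf(t_obs, 1))
    p = min(max(p, 1e-300), 1.0)
    return ScoreTestResult(p=p, statistic=t_obs, method="score",
                           p_conservative=p, p_midp=p, p_gt=p, p_eq=0.0)


# ---------------------------------------------------------------------------
# Cauchy (ACAT) combination
# ---------------------------------------------------------------------------


def cauchy_combine(p_values: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Combine p-values with the Cauchy combination T = sum w_i tan((0.5-p_i)pi) / sum w_i.

    Numerically stable for very small p (tan replaced by 1/(pi p) below
    1e-16, and p_combined by 1/(pi T) for very large T). Inputs at 0 or 1
    are clamped into (0, 1) with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights and p-values differ in length")
    if np.any(w <= 0):
        raise ValueError("combination weights must be positive")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values at 0 or 1 clamped into (0, 1)", stacklevel=2)
        p = np.clip(p, 1e-300, 1 - 1e-16)
    w = w / w.sum()
    t = np.where(p < 1e-16, 1.0 / (p * np.pi), np.tan((0.5 - p) * np.pi))
    t_stat = float((w * t).sum())
    if t_stat > 1e15:
        return 1.0 / (t_stat * np.pi)
    return min(max(0.5 - math.atan(t_stat) / math.pi, 1e-300), 1 - 1e-16)


# ---------------------------------------------------------------------------
# Nominal Fisher's exact test with OR / CI
# ---------------------------------------------------------------------------


@dataclass
class FisherResult:
    p: float | None
    odds_ratio: float | None
    ci95_low: float | None
    ci95_high: float | None
    untestable: bool = False


def _fisher_two_sided_p(a: int, r1: int, c1: int, n: int) -> float:
    """Exact two-sided p: sum of hypergeometric probabilities <= P(observed).

    Computed with exact integer combinatorics so ties are resolved exactly.
    ``a`` successes in the first row with margins (r1, n-r1) x (c1, n-c1).
    """
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    numerators = [math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)]
    obs = numerators[a - lo]
    tail = sum(num for num in numerators if num <= obs)
    return float(Fraction(tail, math.comb(n, c1)))


def fisher_nominal_test(
    case_carriers: int, n_cases: int, control_carriers: int, n_controls: int
) -> FisherResult:
    """Two-sided Fisher's exact p with Haldane-Anscombe OR and Woolf 95% CI.

    The 0.5 continuity correction is applied to all cells when any cell is
    zero; otherwise the OR is the plain cross-product ratio.
    """
    a, b = case_carriers, n_cases - case_carriers
    c, d = control_carriers, n_controls - control_carriers
    if min(a, b, c, d) < 0:
        raise ValueError("carrier counts exceed cohort sizes")
    n = n_cases + n_controls
    c1 = a + c
    if c1 == 0 or c1 == n:
        return FisherResult(None, None, None, None, untestable=True)
    p = _fisher_two_sided_p(a, n_cases, c1, n)
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = float(a), float(b), float(c), float(d)
    odds_ratio = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    ci_low = math.exp(math.log(odds_ratio) - 1.96 * se)
    ci_high = math.exp(math.log(odds_ratio) + 1.96 * se)
    return FisherResult(p=p, odds_ratio=odds_ratio, ci95_low=ci_low, ci95_high=ci_high)


# ---------------------------------------------------------------------------
# Gene scan
# ---------------------------------------------------------------------------


@dataclass
class GeneAssociationResult:
    gene_symbol: str
    p_burden: float | None
    p_nominal: float | None
    odds_ratio: float | None
    ci95_low: float | None
    ci95_high: float | None
    case_tally: tuple[int, int, dict[str, int]]
    control_tally: tuple[int, int, dict[str, int]]
    n_eligible_variants: int
    p_bonferroni: float | None = None
    p_bh: float | None = None


def _level_burden(
    variants: Sequence[MaskedVariant], n_samples: int, level_key: tuple[int, bool] | None
) -> np.ndarray:
    """Max-weight burden column restricted to one mask level (or all if None)."""
    x = np.zeros(n_samples)
    for mv in variants:
        if level_key is None or (mv.mask_level, mv.missense_flag) == level_key:
            np.maximum.at(x, mv.carriers(), mv.weight)
    return x


def gene_burden_p(
    variants: Sequence[MaskedVariant],
    case_mask: np.ndarray,
    mode: str = "randomized",
    rng: np.random.Generator | None = None,
    min_carriers_asymptotic: int = 10,
) -> float | None:
    """Omnibus burden p for one gene's eligible variants.

    The combined statistic is the Cauchy (ACAT) combination of score-test
    components — one per mask level present, on the level-restricted
    max-weight burden, plus an overall max-weight component for genes with
    two or more levels — weighted by the mask weights.

    Because the components share carriers, the asymptotic null of the
    combination is unreliable for the sparse-carrier genes that dominate a
    rare-variant scan.  Genes with fewer than ``min_carriers_asymptotic``
    carriers are therefore calibrated by *exact label permutation of the
    combined statistic*: the Cauchy statistic is recomputed for every
    assignment of case labels to the gene's carriers, and the fuzzy
    permutation p (exactly Uniform(0,1) under the null) is reported.
    Larger genes combine per-component p-values directly.
    """
    n = case_mask.size
    y = np.asarray(case_mask, dtype=bool)
    n1 = int(y.sum())
    ybar = n1 / n

    levels = sorted({(mv.mask_level, mv.missense_flag) for mv in variants})
    level_weight = {(mv.mask_level, mv.missense_flag): mv.weight for mv in variants}
    keys: list[tuple[int, bool] | None] = list(levels)
    comb_weights = [level_weight[k] for k in levels]
    if len(levels) >= 2:
        keys.append(None)  # overall max-weight burden
        comb_weights.append(max(level_weight.values()))

    columns, weights = [], []
    for key, w in zip(keys, comb_weights):
        x = _level_burden(variants, n, key)
        if not np.all(x == x[0]):
            columns.append(x)
            weights.append(w)
    if not columns:
        return None

    carrier_set: set[int] = set()
    for x in columns:
        carrier_set.update(np.flatnonzero(x != 0).tolist())
    carriers = np.array(sorted(carrier_set))
    k = carriers.size

    if k >= min_carriers_asymptotic:
        ps = []
        for x in columns:
            res = burden_score_test(
                x, y, mode=mode, rng=rng, min_carriers_asymptotic=min_carriers_asymptotic
            )
            ps.append(min(res.p, 1 - 1e-16))  # fuzzy p can hit 1.0 exactly
        return cauchy_combine(ps, weights)

    # exact permutation of the Cauchy-combined statistic over carrier labels
    n_comp = len(columns)
    xc = np.stack([x[carriers] for x in columns], axis=1)  # (k, n_comp)
    col_sums = np.array([x.sum() for x in columns])
    v = np.array(
        [ybar * (1 - ybar) * float(((x - x.mean()) ** 2).sum()) for x in columns]
    )
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    n_sub = 2**k
    subsets = ((np.arange(n_sub)[:, None] >> np.arange(k)) & 1).astype(float)  # (n_sub, k)
    sizes = subsets.sum(axis=1).astype(int)
    u = subsets @ xc - ybar * col_sums  # (n_sub, n_comp)
    t = u**2 / v
    p_comp = np.clip(chi2_dist.sf(t, 1), 1e-300, 1 - 1e-16)
    tan_terms = np.where(p_comp < 1e-16, 1.0 / (p_comp * np.pi), np.tan((0.5 - p_comp) * np.pi))
    t_comb = tan_terms @ w  # larger = more significant

    log_denom = _log_choose(n, n1)
    with np.errstate(divide="ignore"):
        log_probs = np.array(
            [
                _log_choose(n - k, n1 - j) - log_denom if n1 - j >= 0 else -np.inf
                for j in range(k + 1)
            ]
        )
    probs = np.exp(log_probs[sizes])
    probs /= probs.sum()

    obs_bits = np.isin(carriers, np.flatnonzero(y)).astype(float)
    obs_idx = int((obs_bits * (1 << np.arange(k))).sum())
    t_obs = t_comb[obs_idx]
    eps = 1e-9 * max(abs(t_obs), 1.0)
    p_gt = float(probs[t_comb > t_obs + eps].sum())
    p_eq = float(probs[np.abs(t_comb - t_obs) <= eps].sum())
    if mode == "randomized":
        p = p_gt + (rng or np.random.default_rng()).random() * p_eq
    elif mode == "conservative":
        p = p_gt + p_eq
    elif mode == "midp":
        p = p_gt + 0.5 * p_eq
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return min(max(p, 1e-300), 1.0)


def _tally(
    variants: Sequence[MaskedVariant], sample_idx: np.ndarray, denominator: int
) -> tuple[int, int, dict[str, int]]:
    """Carrier count and per-mask carried-variant counts for one cohort arm."""
    arm = set(sample_idx.tolist())
    carrier_samples: set[int] = set()
    counts: dict[str, int] = {}
    for mv in variants:
        hits = [i for i in mv.carriers().tolist() if i in arm]
        if hits:
            carrier_samples.update(hits)
            counts[mv.mask_label] = counts.get(mv.mask_label, 0) + len(hits)
    return len(carrier_samples), denominator, counts


def run_gene_scan(
    eligible: Sequence[MaskedVariant],
    sample_table: SampleTable,
    mode: str = "randomized",
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[GeneAssociationResult]:
    """Per-gene burden + nominal Fisher scan, sorted ascending by burden p.

    One result per gene with >= 1 eligible variant; ties broken by nominal p
    then gene symbol. Deterministic given ``seed`` (which drives the fuzzy
    permutation p-values).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    case_mask = sample_table.case_mask
    case_idx = np.flatnonzero(case_mask)
    ctrl_idx = np.flatnonzero(~case_mask)
    by_gene: dict[str, list[MaskedVariant]] = {}
    for mv in eligible:
        by_gene.setdefault(mv.gene_symbol, []).append(mv)

    results: list[GeneAssociationResult] = []
    for gene in sorted(by_gene):
        variants = by_gene[gene]
        p_burden = gene_burden_p(variants, case_mask, mode=mode, rng=rng)
        case_tally = _tally(variants, case_idx, sample_table.n_cases)
        ctrl_tally = _tally(variants, ctrl_idx, sample_table.n_controls)
        fr = fisher_nominal_test(
            case_tally[0], sample_table.n_cases, ctrl_tally[0], sample_table.n_controls
        )
        results.append(
            GeneAssociationResult(
                gene_symbol=gene,
                p_burden=p_burden,
                p_nominal=fr.p,
                odds_ratio=fr.odds_ratio,
                ci95_low=fr.ci95_low,
                ci95_high=fr.ci95_high,
                case_tally=case_tally,
                control_tally=ctrl_tally,
                n_eligible_variants=len(variants),
            )
        )

    # multiple-testing extras on the burden p-values (raw p remains primary)
    tested = [r for r in results if r.p_burden is not None]
    m = len(tested)
    if m:
        order = np.argsort([r.p_burden for r in tested])
        bh = np.empty(m)
        prev = 1.0
        for rank, i in enumerate(reversed(order), start=0):
            r = tested[i]
            q = r.p_burden * m / (m - rank)
            prev = min(prev, q)
            bh[i] = prev
        for i, r in enumerate(tested):
            r.p_bonferroni = min(1.0, r.p_burden * m)
            r.p_bh = min(1.0, bh[i])

    results.sort(
        key=lambda r: (
            r.p_burden if r.p_burden is not None else 2.0,
            r.p_nominal if r.p_nominal is not None else 2.0,
            r.gene_symbol,
        )
    )
    return results


# ---------------------------------------------------------------------------
# QQ diagnostics
# ---------------------------------------------------------------------------


def qq_points(p_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray, float]:
    """Expected/observed -log10 p pairs and the genomic inflation lambda.

    lambda is the median 1-df chi-square quantile of the p-values divided by
    the theoretical null median (chi2.ppf(0.5, 1) ~ 0.4549).
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("need at least one p-value")
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)  # descending in rank
    observed = -np.log10(np.clip(p, 1e-300, None))  # p ascending -> -log10 descending
    lam = float(np.median(chi2_dist.isf(p, 1)) / chi2_dist.ppf(0.5, 1))
    return expected, observed, lam
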