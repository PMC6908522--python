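"""Significance Analysis of Microarrays (SAM).

Per feature i the moderated statistic is

    d_i = (mean_case - mean_ctrl) / (s_i + s0)

with s_i the pooled two-group standard error and s0 a "fudge factor" chosen
to minimize the coefficient of variation of d across the range of s. The
null distribution is built by permuting group labels and pooling the
permuted d values across features; Storey q-values convert permutation
p-values into false-discovery-rate estimates. Genes are called at q below a
hard threshold and the called set carries a study-level estimated FDR that
is checked against a ceiling (non-conforming call sets are kept but
flagged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy
from .errors import StatisticsError

logger = logging.getLogger(__name__)

S0_ALPHA_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 2)


@dataclass
class SamResult:
    """Per-feature SAM statistics plus study-level summaries.

    ``table`` is indexed by feature with columns ``d``, ``s``, ``delta_mean``,
    ``direction``, ``p_perm``, ``q`` and (after :func:`call_degs`)
    ``called``.
    """

    study_id: str
    table: pd.DataFrame
    s0: float
    s0_alpha: float | None
    pi0: float
    n_permutations: int
    fdr_at_call: float | None = None
    fdr_flagged: bool = False
    q_threshold: float | None = None
    null_abs_d: np.ndarray | None = field(default=None, repr=False)

    @property
    def called_up(self) -> set[str]:
        t = self.table
        return set(t.index[t["called"] & (t["direction"] > 0)])

    @property
    def called_down(self) -> set[str]:
        t = self.table
        return set(t.index[t["called"] & (t["direction"] < 0)])


def _group_counts(case_mask: np.ndarray) -> tuple[int, int]:
    n_case = int(case_mask.sum())
    n_ctrl = int((~case_mask).sum())
    if n_case < 2 or n_ctrl < 2:
        raise StatisticsError("each group needs >= 2 samples")
    return n_case, n_ctrl


def pooled_se(matrix: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Pooled two-group standard error per feature.

    s_i = sqrt( a * (SS_case + SS_ctrl) ), a = (1/n1 + 1/n2) / (n1 + n2 - 2).
    """
    matrix = np.asarray(matrix, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    n1, n2 = _group_counts(case_mask)
    xc = matrix[:, case_mask]
    xu = matrix[:, ~case_mask]
    ss = ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xu - xu.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    return np.sqrt(a * ss)


def _moderated_d(delta: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    denom = s + s0
    zero = denom == 0
    if np.any(zero & (delta != 0)):
        raise StatisticsError(
            "zero denominator with non-zero mean difference for feature "
            f"indices {np.nonzero(zero & (delta != 0))[0][:5].tolist()}"
        )
    d = np.zeros_like(delta)
    np.divide(delta, denom, out=d, where=~zero)
    return d


def estimate_s0(delta: np.ndarray, s: np.ndarray,
                n_windows: int = 100) -> tuple[float, float]:
    """SAM fudge factor: the s-quantile minimizing the CV of scaled MADs.

    For each candidate alpha in {0, 0.05, ..., 1.0}, d(alpha) is computed
    with s0 = quantile(s, alpha); the features are split into equal-count
    windows by s and the coefficient of variation of the window-wise scaled
    MADs of d(alpha) is minimized. Returns ``(s0, alpha)``; ties break to
    the smallest alpha. When every s is equal the choice is vacuous and
    s0 = 0 is returned with a warning.
    """
    delta = np.asarray(delta, dtype=float)
    s = np.asarray(s, dtype=float)
    m = s.size
    if m < 100:
        logger.warning("estimate_s0: only %d features (>=100 recommended)", m)
    if np.ptp(s) == 0:
        logger.warning("estimate_s0: all s identical; returning s0 = 0")
        return 0.0, 0.0

    order = np.argsort(s, kind="stable")
    k = min(n_windows, max(2, m // 5))
    bins = np.array_split(order, k)
    best_alpha, best_cv = None, np.inf
    for alpha in S0_ALPHA_GRID:
        s0 = float(np.quantile(s, alpha))
        d = _moderated_d(delta, s, s0)
        mads = np.array([
            1.4826 * np.median(np.abs(d[b] - np.median(d[b]))) for b in bins
        ])
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std(ddof=1) / mean
        if cv < best_cv - 1e-15:
            best_cv, best_alpha = cv, float(alpha)
    if best_alpha is None:
        logger.warning("estimate_s0: degenerate spread; returning s0 = 0")
        return 0.0, 0.0
    return float(np.quantile(s, best_alpha)), best_alpha


def sam_statistics(study: ExpressionStudy, s0: float) -> pd.DataFrame:
    """Moderated d, mean difference and direction per feature."""
    matrix = study.matrix()
    case_mask = study.case_mask()
    _group_counts(case_mask)
    s = pooled_se(matrix, case_mask)
    delta = matrix[:, case_mask].mean(axis=1) - matrix[:, ~case_mask].mean(axis=1)
    d = _moderated_d(delta, s, s0)
    return pd.DataFrame(
        {
            "d": d,
            "s": s,
            "delta_mean": delta,
            "direction": np.sign(delta).astype(int),
        },
        index=study.values.index,
    )


def _distinct_case_masks(n: int, n_case: int, B: int, rng: np.random.Generator,
                         identity: tuple[int, ...]) -> np.ndarray:
    """B distinct case-assignments (identity excluded when possible)."""
    total = math.comb(n, n_case)
    if total - 1 <= B:
        # exhaustive enumeration, identity excluded
        from itertools import combinations

        combos = [c for c in combinations(range(n), n_case) if c != identity]
        logger.info("permutations: exhaustive enumeration, B reduced to %d",
                    len(combos))
    else:
        seen: set[tuple[int, ...]] = {identity}
        combos = []
        while len(combos) < B:
            c = tuple(sorted(rng.choice(n, size=n_case, replace=False).tolist()))
            if c not in seen:
                seen.add(c)
                combos.append(c)
    masks = np.zeros((len(combos), n), dtype=bool)
    for b, c in enumerate(combos):
        masks[b, list(c)] = True
    return masks


def permutation_pvalues(
    study: ExpressionStudy, s0: float, B: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled permutation p-values.

    Group labels are permuted over ``B`` distinct assignments; the null d
    values of all features and permutations are pooled and

        p_i = (1 + #{(b, j): |d_jb| >= |d_i|}) / (1 + m * B).

    Returns ``(p, null_abs_d, B_effective)``; the "+1" smoothing avoids
    zero p-values.
    """
    if B < 50:
        raise StatisticsError("B must be >= 50")
    if B < 200:
        logger.warning("permutation_pvalues: B=%d is low (>=200 recommended)", B)
    matrix = study.matrix()
    case_mask = study.case_mask()
    n1, n2 = _group_counts(case_mask)
    n = n1 + n2
    rng = np.random.default_rng(seed)
    identity = tuple(sorted(np.nonzero(case_mask)[0].tolist()))
    masks = _distinct_case_masks(n, n1, B, rng, identity)
    b_eff = masks.shape[0]

    # vectorized null d: group means and sums of squares via matrix products
    x = matrix
    x2 = x ** 2
    mask_f = masks.T.astype(float)            # n x B
    sum_case = x @ mask_f                     # m x B
    sum_ctrl = x.sum(axis=1, keepdims=True) - sum_case
    mean_case = sum_case / n1
    mean_ctrl = sum_ctrl / n2
    ss_case = x2 @ mask_f - n1 * mean_case ** 2
    ss_ctrl = x2.sum(axis=1, keepdims=True) - x2 @ mask_f - n2 * mean_ctrl ** 2
    a = (1.0 / n1 + 1.0 / n2) / (n - 2)
    s_null = np.sqrt(a * np.maximum(ss_case + ss_ctrl, 0.0))
    delta_null = mean_case - mean_ctrl
    denom = s_null + s0
    d_null = np.zeros_like(delta_null)
    np.divide(delta_null, denom, out=d_null, where=denom != 0)
    null_abs = np.abs(d_null)

    obs = sam_statistics(study, s0)
    abs_d = np.abs(obs["d"].to_numpy())
    # round before comparing so exact ties (e.g. the complement of the
    # identity assignment) are counted consistently across float paths
    pool = np.sort(np.round(null_abs.ravel(), 12))
    m_b = pool.size
    n_ge = m_b - np.searchsorted(pool, np.round(abs_d, 12), side="left")
    p = (1.0 + n_ge) / (1.0 + m_b)
    return p, null_abs, b_eff


def storey_q(p: np.ndarray, lam: float = 0.5) -> tuple[np.ndarray, float]:
    """Storey q-values with a single-lambda pi0 estimate.

    pi0 = min(1, #{p > lambda} / (m (1 - lambda))); q-values are the
    pi0-weighted step-up (BH-like) quantities with monotonicity enforced
    from the largest p downwards. pi0 is not floored.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise StatisticsError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = min(1.0, float((p > lam).sum()) / (m * (1.0 - lam)))
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def call_degs(result: SamResult, q_threshold: float = 0.01,
              fdr_ceiling: float = 0.15) -> SamResult:
    """Call DEGs at q < q_threshold and attach the study-level FDR estimate.

    fdr_at_call = pi0 * median over permutations of the number of null |d|
    values at or beyond the call cutoff, divided by the number of calls.
    Call sets whose estimated FDR exceeds ``fdr_ceiling`` are kept but
    flagged non-conforming.
    """
    table = result.table.copy()
    called = table["q"] < q_threshold
    table["called"] = called
    n_called = int(called.sum())
    if n_called == 0:
        fdr = 0.0
    else:
        if result.null_abs_d is None:
            raise StatisticsError("call_degs requires the permutation null")
        cutoff = float(np.abs(table.loc[called, "d"]).min())
        exceed = (result.null_abs_d >= cutoff).sum(axis=0)
        fdr = float(result.pi0 * np.median(exceed) / n_called)
    flagged = fdr > fdr_ceiling
    if flagged:
        logger.warning("study %s: call set FDR %.3f exceeds ceiling %.2f",
                       result.study_id, fdr, fdr_ceiling)
    return SamResult(
        study_id=result.study_id,
        table=table,
        s0=result.s0,
        s0_alpha=result.s0_alpha,
        pi0=result.pi0,
        n_permutations=result.n_permutations,
        fdr_at_call=fdr,
        fdr_flagged=flagged,
        q_threshold=q_threshold,
        null_abs_d=result.null_abs_d,
    )


def sam_analyze(
    study: ExpressionStudy,
    q_threshold: float = 0.01,
    fdr_ceiling: float = 0.15,
    B: int = 1000,
    seed: int = 0,
    s0: float | None = None,
    lam: float = 0.5,
    keep_null: bool = False,
) -> SamResult:
    """Full per-study SAM analysis: s0, d, permutation p, q, DEG calls."""
    matrix = study.matrix()
    case_mask = study.case_mask()
    s = pooled_se(matrix, case_mask)
    delta = matrix[:, case_mask].mean(axis=1) - matrix[:, ~case_mask].mean(axis=1)
    if s0 is None:
        s0_val, alpha = estimate_s0(delta, s)
    else:
        s0_val, alpha = float(s0), None
        logger.info("study %s: using supplied s0=%g", study.study_id, s0_val)
    table = sam_statistics(study, s0_val)
    p, null_abs, b_eff = permutation_pvalues(study, s0_val, B=B, seed=seed)
    q, pi0 = storey_q(p, lam=lam)
    table["p_perm"] = p
    table["q"] = q
    result = SamResult(
        study_id=study.study_id,
        table=table,
        s0=s0_val,
        s0_alpha=alpha,
        pi0=pi0,
        n_permutations=b_eff,
        null_abs_d=null_abs,
    )
    result = call_degs(result, q_threshold=q_threshold, fdr_ceiling=fdr_ceiling)
    if not keep_null:
        result.null_abs_d = None
    return result
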