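"""Shared statistical routines.

Standard tests are delegated to scipy/statsmodels; the G-test and Dunn's
rank-based post-hoc test are written out here because no pre-installed
package exposes them directly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import StatResult


def g_test(observed: np.ndarray, expected_proportions: np.ndarray) -> StatResult:
    """Log-likelihood-ratio goodness-of-fit test.

    ``G = 2 * sum O * ln(O / E)`` over classes with O > 0, where
    ``E = expected_proportion * total``.  Degrees of freedom are the number of
    classes minus one; p comes from the chi-square distribution.  G is
    asymptotically equivalent to the Pearson chi-square statistic but remains
    well behaved at very large counts.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes differ")
    if np.any(obs < 0):
        raise ValueError("negative observed count")
    if np.any((props <= 0) & (obs > 0)):
        raise ValueError("expected proportion is zero where observed count is positive")
    total = obs.sum()
    if total == 0:
        raise ValueError("empty observed counts")
    exp = props * total
    nz = obs > 0
    g = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    df = obs.size - 1
    p = float(sps.chi2.sf(g, df)) if df > 0 else 1.0
    return StatResult("G-test", g, p, df=df, n=int(total))


def cramers_v(table: np.ndarray, drop_empty: bool = True) -> StatResult:
    """Cramér's V (phi_c) for a contingency table of counts.

    ``V = sqrt(chi2 / (N * (min(rows, cols) - 1)))``.  Classes (columns) empty
    in every row are dropped before testing; a warning note records how many.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    note = None
    if drop_empty:
        keep = t.sum(axis=0) > 0
        dropped = int((~keep).sum())
        if dropped:
            note = f"dropped {dropped} empty class(es)"
            t = t[:, keep]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 rows and columns")
    n = t.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    # identical rows => no association; chi2_contingency handles this but we
    # avoid its warning path for exact zeros
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    v = float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))
    return StatResult(
        "chi2-contingency", float(chi2), float(p), df=float(df),
        effect=v, effect_name="cramers_v", n=int(n), note=note,
    )


def holm_bonferroni(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def dunn_posthoc(
    groups: dict[str, np.ndarray]
) -> list[tuple[str, str, StatResult]]:
    """Dunn's pairwise z-tests on pooled ranks, Holm–Bonferroni adjusted.

    For groups i, j with mean pooled ranks Rbar_i, Rbar_j:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))

    with tie correction ``T = sum(t^3 - t) / (12 (N - 1))`` over tied-value
    multiplicities t.  Two-sided p from the standard normal.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("Dunn's test needs >= 2 groups")
    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    sizes = {k: len(groups[k]) for k in names}
    if min(sizes.values()) == 0:
        raise ValueError("empty group in Dunn's test")
    n_total = len(values)
    ranks = sps.rankdata(values)
    mean_rank = {}
    i = 0
    for k in names:
        mean_rank[k] = float(np.mean(ranks[i : i + sizes[k]]))
        i += sizes[k]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs: list[tuple[str, str]] = []
    raw: list[tuple[float, float]] = []
    for a_i, a in enumerate(names):
        for b in names[a_i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2.0 * float(sps.norm.sf(abs(z)))
            pairs.append((a, b))
            raw.append((z, min(p, 1.0)))
    adjusted = holm_bonferroni([p for _, p in raw])
    out = []
    for (a, b), (z, p), p_adj in zip(pairs, raw, adjusted):
        res = StatResult(
            "dunn", float(z), float(p), n=sizes[a] + sizes[b],
            extras={"p_adjusted": float(p_adj)},
        )
        out.append((a, b, res))
    return out


def point_biserial(indicator: np.ndarray, values: np.ndarray) -> StatResult:
    """Point-biserial correlation: Pearson r of a 0/1 indicator with values."""
    ind = np.asarray(indicator, dtype=float)
    vals = np.asarray(values, dtype=float)
    if ind.shape != vals.shape:
        raise ValueError("shape mismatch")
    if len(np.unique(ind)) < 2 or np.std(vals) == 0:
        return StatResult("point-biserial", float("nan"), float("nan"),
                          n=len(vals), note="degenerate input")
    r, p = sps.pointbiserialr(ind, vals)
    return StatResult("point-biserial", float(r), float(p),
                      effect=float(r), effect_name="r_pb", n=len(vals))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return float("nan")
    return float((np.mean(a) - np.mean(b)) / pooled)


def welch_t(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-sided Welch's unequal-variance t-test with Cohen's d effect size."""
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return StatResult(
        "welch-t", float(t), float(p),
        effect=cohens_d(a, b), effect_name="cohens_d", n=len(a) + len(b),
    )
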