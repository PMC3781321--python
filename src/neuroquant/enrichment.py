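"""Disease-association enrichment statistics for an interactome gene list.

Given per-gene association p-values for the genes of a protein interactome
(e.g. genes encoding the binding partners of a synaptic protein, tested
against a psychiatric-disorder GWAS), this module answers:

* how many genes are expected to reach nominal significance under the null
  (``n_tests * alpha`` — e.g. 1.8 of 36 genes at alpha = 0.05);
* whether the observed count exceeds that expectation (exact binomial tail;
  or a one-sided Fisher exact test when a genome-wide background table
  supplies an empirical null rate);
* which genes survive Bonferroni correction for the family of tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "expected_nominal_count",
    "binomial_tail",
    "fisher_one_sided",
    "bonferroni",
    "enrichment_report",
    "disease_category_percentages",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Summary of an interactome nominal-significance enrichment analysis."""

    n_tests: int
    alpha: float
    k_observed: int
    expected: float
    p_binomial: float
    p_fisher: float | None = None
    background_rate: float | None = None
    adjusted: pd.DataFrame | None = None


def expected_nominal_count(n_tests: int, alpha: float = 0.05) -> float:
    """Expected number of nominally significant genes under a uniform null."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    return n_tests * alpha


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binom.sf(k - 1, n, p0))


def fisher_one_sided(table: np.ndarray) -> float:
    """One-sided (enrichment direction) Fisher exact test on a 2x2 table.

    Rows are groups (e.g. interactome vs background genes), columns outcomes
    (nominally significant vs not); the alternative is that the first row is
    enriched for the first column.  Degenerate margins (an all-zero row or
    column) carry no information and return p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_int = t.astype(int)
        if np.any(t_int != t) or np.any(t_int < 0):
            raise ValueError("table must hold non-negative integers")
        t = t_int
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn(
            "degenerate margin in 2x2 table; Fisher test uninformative (p = 1)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    _, p = stats.fisher_exact(t, alternative="greater")
    return float(p)


def bonferroni(
    p_values: np.ndarray | list[float], m: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Bonferroni adjustment: ``p_adj = min(1, p * m)``.

    ``m`` defaults to the number of p-values; a larger family size may be
    supplied when only a subset of the tested family is listed.  Returns a
    frame with ``p``, ``p_adjusted`` and a family-wise ``significant`` flag.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise ValueError("family size m cannot be smaller than the number of p-values")
    adj = np.minimum(1.0, p * m_eff)
    return pd.DataFrame(
        {"p": p, "p_adjusted": adj, "significant": adj < alpha}
    )


def enrichment_report(
    genes: pd.DataFrame,
    alpha: float = 0.05,
    background: pd.DataFrame | None = None,
) -> EnrichmentResult:
    """Full enrichment analysis of a gene table (columns ``gene, p_value``).

    Without a background table the null nominal-significance rate is
    ``alpha`` itself and the exact binomial tail is the enrichment p-value.
    With a genome-wide background (same columns), a 2x2 Fisher exact test of
    interactome vs background genes against nominal significance is added,
    using the background's empirical rate.
    """
    if not {"gene", "p_value"}.issubset(genes.columns):
        raise ValueError("gene table needs columns 'gene' and 'p_value'")
    p = genes["p_value"].to_numpy(dtype=float)
    n = len(p)
    if n == 0:
        raise ValueError("empty gene table")
    k = int((p < alpha).sum())
    res_fisher = None
    bg_rate = None
    if background is not None:
        bg_p = background["p_value"].to_numpy(dtype=float)
        bg_k = int((bg_p < alpha).sum())
        bg_n = len(bg_p)
        bg_rate = bg_k / bg_n if bg_n else float("nan")
        table = np.array([[k, n - k], [bg_k, bg_n - bg_k]])
        res_fisher = fisher_one_sided(table)
    return EnrichmentResult(
        n_tests=n,
        alpha=alpha,
        k_observed=k,
        expected=expected_nominal_count(n, alpha),
        p_binomial=binomial_tail(k, n, alpha),
        p_fisher=res_fisher,
        background_rate=bg_rate,
        adjusted=pd.concat(
            [genes.reset_index(drop=True), bonferroni(p, alpha=alpha).drop(columns="p")],
            axis=1,
        ),
    )


def disease_category_percentages(
    annotations: pd.DataFrame, n_total: int | None = None
) -> pd.Series:
    """Percentage of genes annotated to each disease category.

    ``annotations`` has columns ``gene, disease``; a gene annotated to several
    diseases counts once in each category.  ``n_total`` is the size of the
    full gene list (default: number of distinct annotated genes).
    """
    if not {"gene", "disease"}.issubset(annotations.columns):
        raise ValueError("annotation table needs columns 'gene' and 'disease'")
    denom = n_total if n_total is not None else annotations["gene"].nunique()
    if denom <= 0:
        raise ValueError("n_total must be positive")
    counts = annotations.drop_duplicates().groupby("disease")["gene"].nunique()
    return 100.0 * counts / denom
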