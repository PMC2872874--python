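"""Differential-expression calling between two count libraries.

Implements the exact Poisson test: conditional on the total s = y1 + y2, the
first library's count is Binomial(s, M1/(M1+M2)) under the null of equal
(library-size-scaled) rates.  Two-sidedness follows the minimum-likelihood
rule — sum the probabilities of all outcomes no more likely than the one
observed — which makes the test equivalent to a conditional Fisher-style
exact test.  Gene-wise p-values are corrected by Benjamini-Hochberg and
flagged at an FDR threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from lenrich.errors import ValidationError
from lenrich.io_annotation import GeneTable

# Relative slack when comparing pmf values, as in R's binom.test: outcomes with
# pmf(j) <= pmf(obs) * (1 + 1e-7) are counted, guarding against float ties.
_REL_TOL = 1.0 + 1e-7


def poisson_exact_pvalue(y1: int, y2: int, M1: float, M2: float) -> float:
    """Two-sided exact p-value for equal scaled Poisson rates.

    Conditional on s = y1 + y2, computes the minimum-likelihood two-sided
    binomial sum with success probability M1 / (M1 + M2).  Returns 1.0 when
    s == 0 (the conditional support is a single point).
    """
    if y1 < 0 or y2 < 0:
        raise ValidationError("counts must be non-negative")
    if M1 <= 0 or M2 <= 0:
        raise ValidationError("library sizes must be positive")
    s = int(y1) + int(y2)
    if s == 0:
        return 1.0
    p0 = M1 / (M1 + M2)
    j = np.arange(s + 1)
    # Work in logs throughout; for large s the raw pmf underflows.
    logpmf = stats.binom.logpmf(j, s, p0)
    cut = logpmf[int(y1)] + np.log(_REL_TOL)
    keep = logpmf <= cut
    logp = _logsumexp(logpmf[keep])
    return float(min(1.0, np.exp(logp)))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be a 1-d vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # cumulative minimum from the largest p downward
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def call_de(
    table: GeneTable,
    fdr_threshold: float = 1e-4,
    external_flags=None,
) -> GeneTable:
    """Annotate a GeneTable with DE p-values, BH q-values and flags.

    ``external_flags`` bypasses the Poisson test entirely: the supplied
    binary flags (array or mapping by gene_id) are stored as-is and no p/q
    columns are written — any upstream DE-calling procedure can be used.
    """
    if external_flags is not None:
        flags = _coerce_flags(external_flags, table)
        table.frame["de_flag"] = flags
        return table
    if not (0 < fdr_threshold < 1):
        raise ValidationError("fdr_threshold must lie in (0, 1)")
    counts = table.counts
    M1, M2 = table.lib_sizes
    pvals = _poisson_exact_vector(counts[:, 0], counts[:, 1], M1, M2)
    qvals = bh_adjust(pvals)
    table.frame["de_pvalue"] = pvals
    table.frame["de_qvalue"] = qvals
    table.frame["de_flag"] = qvals <= fdr_threshold
    return table


def _poisson_exact_vector(y1, y2, M1, M2) -> np.ndarray:
    """Vectorized per-gene exact test; identical genes share one computation."""
    y1 = np.asarray(y1, dtype=np.int64)
    y2 = np.asarray(y2, dtype=np.int64)
    if M1 == M2:
        # Symmetric binomial: the minimum-likelihood region is exactly the two
        # symmetric tails, so both tails can be summed in closed form.
        s = y1 + y2
        lo = np.minimum(y1, y2)
        hi = s - lo
        with np.errstate(divide="ignore", invalid="ignore"):
            p = stats.binom.cdf(lo, s, 0.5) + stats.binom.sf(hi - 1, s, 0.5)
        p = np.where(s == 0, 1.0, np.minimum(p, 1.0))
        return p
    out = np.empty(y1.size)
    cache: dict[tuple[int, int], float] = {}
    for i in range(y1.size):
        key = (int(y1[i]), int(y2[i]))
        if key not in cache:
            cache[key] = poisson_exact_pvalue(key[0], key[1], M1, M2)
        out[i] = cache[key]
    return out


def _coerce_flags(flags, table: GeneTable) -> np.ndarray:
    if isinstance(flags, dict):
        missing = [g for g in table.gene_ids if g not in flags]
        if missing:
            raise ValidationError(f"external flags missing gene {missing[0]!r}")
        arr = np.array([bool(flags[g]) for g in table.gene_ids])
    else:
        arr = np.asarray(flags).astype(bool)
        if arr.shape != (table.n_genes,):
            raise ValidationError(
                f"external flags length {arr.size} != {table.n_genes} genes"
            )
    return arr
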