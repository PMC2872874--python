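"""Per-category over/under-representation tests under three nulls.

``hypergeometric``  — the classical urn: every gene equally likely to be DE.
``sampling``        — weighted resampling: each replicate redraws the DE set
                      without replacement with per-draw probability
                      proportional to each gene's remaining PWF weight (the
                      finite-population scheme whose exact law is Wallenius'
                      non-central hypergeometric distribution).
``wallenius``       — closed-form approximation: genes inside a category are
                      given their mean PWF weight, genes outside theirs, and
                      the tail of Wallenius' distribution with odds equal to
                      the ratio of the two means is evaluated.

Both tails always include the observed count, so p_over + p_under >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from lenrich.de_testing import bh_adjust
from lenrich.errors import ConfigurationError, ValidationError
from lenrich.io_annotation import CategoryMap, GeneTable

logger = logging.getLogger(__name__)

METHODS = ("hypergeometric", "sampling", "wallenius")


@dataclass(frozen=True)
class ContingencyCounts:
    """Enrichment contingency: N genes, K in category, n DE, k DE-in-category."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValidationError(f"inconsistent contingency counts {self}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValidationError(f"inconsistent contingency counts {self}")
        # k cannot be smaller than the forced overlap
        if self.k < self.K + self.n - self.N:
            raise ValidationError(f"inconsistent contingency counts {self}")


@dataclass
class EnrichmentResult:
    """One category's test outcome."""

    category_id: str
    counts: ContingencyCounts
    odds: float
    p_over: float
    p_under: float
    method: str
    fdr_over: float = np.nan
    rank: int = 0
    sampling_reps: int | None = None
    seed: int | None = None
    null_counts: np.ndarray | None = field(default=None, repr=False)


def hypergeometric_pvalues(c: ContingencyCounts) -> tuple[float, float]:
    """Upper and lower tail of Hypergeometric(N, K, n) at the observed k.

    Both tails include the observed value: p_over = P(X >= k),
    p_under = P(X <= k).
    """
    p_over = float(stats.hypergeom.sf(c.k - 1, c.N, c.K, c.n))
    p_under = float(stats.hypergeom.cdf(c.k, c.N, c.K, c.n))
    return min(p_over, 1.0), min(p_under, 1.0)


def category_odds(weights_in, weights_out) -> float:
    """Mean in-category PWF weight over mean out-of-category PWF weight."""
    win = np.asarray(weights_in, dtype=float)
    wout = np.asarray(weights_out, dtype=float)
    if win.size == 0 or wout.size == 0:
        raise ValidationError("category and complement must both be non-empty")
    if np.any(win <= 0) or np.any(wout <= 0) or np.any(win > 1) or np.any(wout > 1):
        raise ValidationError("weights must lie in (0, 1]")
    return float(win.mean() / wout.mean())


def wallenius_pvalues(c: ContingencyCounts, odds: float) -> tuple[float, float]:
    """Tails of Wallenius' non-central hypergeometric distribution.

    The urn holds c.K items with weight ``odds`` and c.N - c.K with weight 1;
    c.n items are drawn sequentially without replacement with probability
    proportional to remaining weight.  At odds = 1 this is exactly the
    hypergeometric, and that central case is dispatched to the hypergeometric
    tails so the reduction holds to machine precision.
    """
    if not np.isfinite(odds) or odds <= 0:
        raise ValidationError("odds must be a positive finite number")
    if odds == 1.0:
        return hypergeometric_pvalues(c)
    k_min = max(0, c.K + c.n - c.N)
    k_max = min(c.K, c.n)
    if k_min == k_max:  # degenerate support
        return 1.0, 1.0
    dist = stats.nchypergeom_wallenius(c.N, c.K, c.n, odds)
    p_over = float(dist.sf(c.k - 1))
    p_under = float(dist.cdf(c.k))
    if not (np.isfinite(p_over) and np.isfinite(p_under)):
        raise ValidationError(
            f"Wallenius tail evaluation failed for {c} at odds={odds}; "
            "consider the sampling method"
        )
    return float(np.clip(p_over, 0.0, 1.0)), float(np.clip(p_under, 0.0, 1.0))


def weighted_sample_counts(
    weights: np.ndarray,
    membership: np.ndarray,
    n_de: int,
    reps: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """Replicate in-category counts under the weighted resampling null.

    Each replicate draws ``n_de`` of N genes without replacement with
    per-draw probability proportional to remaining weight.  The draw is
    realised with exponential race keys (arrival time Exp(w_g); the n_de
    earliest arrivals form the sample), which is distributed identically to
    the sequential scheme.  ``membership`` is (N, n_categories) boolean;
    returns an (reps, n_categories) count matrix — one shared ensemble of
    draws scored against every category.
    """
    N = weights.size
    out = np.empty((reps, membership.shape[1]), dtype=np.int32)
    memb_f = membership.astype(np.float32)
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        keys = rng.exponential(size=(b, N)) / weights
        sel = np.argpartition(keys, n_de - 1, axis=1)[:, :n_de]
        rows = np.zeros((b, N), dtype=np.float32)
        np.put_along_axis(rows, sel, 1.0, axis=1)
        out[done : done + b] = np.rint(rows @ memb_f).astype(np.int32)
        done += b
    return out


def sampling_pvalues(
    weights,
    category_members,
    n_de: int,
    k_observed: int,
    reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Monte-Carlo tail probabilities for one category.

    Uses the (b + 1) / (reps + 1) estimator so a p-value of exactly 0 is
    impossible; identical seeds give identical output.  Returns
    (p_over, p_under, histogram of replicate in-category counts).
    """
    w = np.asarray(weights, dtype=float)
    members = np.asarray(category_members, dtype=bool)
    if w.shape != members.shape or w.ndim != 1:
        raise ValidationError("weights and membership must be equal-length vectors")
    if np.any(w <= 0):
        raise ValidationError("all weights must be positive")
    if not (0 < n_de < w.size):
        raise ValidationError("n_de must satisfy 0 < n_de < N")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = weighted_sample_counts(
        w, members[:, None], n_de, reps, rng
    )[:, 0]
    p_over = (np.count_nonzero(counts >= k_observed) + 1) / (reps + 1)
    p_under = (np.count_nonzero(counts <= k_observed) + 1) / (reps + 1)
    hist = np.bincount(counts, minlength=int(members.sum()) + 1)
    return float(p_over), float(p_under), hist


def test_categories(
    table: GeneTable,
    categories: CategoryMap,
    method: str = "wallenius",
    reps: int = 2000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Test every category for over/under-representation of DE genes.

    Requires DE flags on the table and, for the bias-corrected methods, PWF
    weights.  For ``sampling``, one shared stream of ``reps`` replicate draws
    is scored against all categories, so category p-values share a common
    null ensemble.  Results carry BH-adjusted p_over across categories and
    1-based ranks by (p_over, category_id).
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if "de_flag" not in table.frame:
        raise ConfigurationError("DE flags missing; run the DE stage first")
    flags = table.frame["de_flag"].to_numpy(dtype=bool)
    n_de = int(flags.sum())
    if n_de == 0:
        raise ValidationError("no DE genes; nothing to test")
    needs_weights = method in ("sampling", "wallenius")
    if needs_weights and "pwf_weight" not in table.frame:
        raise ConfigurationError(f"method {method!r} requires fitted PWF weights")
    weights = (
        table.frame["pwf_weight"].to_numpy(dtype=float) if needs_weights else None
    )

    gene_order = table.gene_ids
    membership, cat_ids = categories.membership_matrix(gene_order)
    N = len(gene_order)
    logger.info(
        "testing %d categories: N=%d, n_DE=%d, method=%s",
        len(cat_ids), N, n_de, method,
    )

    K_vec = membership.sum(axis=0)
    k_vec = membership[flags].sum(axis=0)

    if method == "sampling":
        if not (0 < n_de < N):
            raise ValidationError("sampling requires 0 < n_DE < N")
        rng = np.random.default_rng(seed)
        null_counts = weighted_sample_counts(weights, membership, n_de, reps, rng)

    results = []
    for j, cat in enumerate(cat_ids):
        c = ContingencyCounts(N=N, K=int(K_vec[j]), n=n_de, k=int(k_vec[j]))
        if needs_weights:
            odds = category_odds(weights[membership[:, j]], weights[~membership[:, j]])
        else:
            odds = 1.0
        if method == "hypergeometric":
            p_over, p_under = hypergeometric_pvalues(c)
        elif method == "wallenius":
            p_over, p_under = wallenius_pvalues(c, odds)
        else:
            col = null_counts[:, j]
            p_over = (np.count_nonzero(col >= c.k) + 1) / (reps + 1)
            p_under = (np.count_nonzero(col <= c.k) + 1) / (reps + 1)
        results.append(
            EnrichmentResult(
                category_id=cat,
                counts=c,
                odds=odds,
                p_over=float(p_over),
                p_under=float(p_under),
                method=method,
                sampling_reps=reps if method == "sampling" else None,
                seed=seed if method == "sampling" else None,
            )
        )

    fdr = bh_adjust([r.p_over for r in results])
    for r, q in zip(results, fdr):
        r.fdr_over = float(q)
    results.sort(key=lambda r: (r.p_over, r.category_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results
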