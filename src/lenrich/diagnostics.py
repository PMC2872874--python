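"""Evaluation machinery: category length-bias testing and ranked-list
comparison between enrichment methods."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lenrich.errors import ValidationError
from lenrich.io_annotation import CategoryMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedList:
    """Category ids ordered by ascending p-value (ties broken by id)."""

    category_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.category_ids)) != len(self.category_ids):
            raise ValidationError("ranked list contains duplicate categories")

    @classmethod
    def from_results(cls, results) -> "RankedList":
        ordered = sorted(results, key=lambda r: (r.p_over, r.category_id))
        return cls(tuple(r.category_id for r in ordered))

    def top(self, k: int) -> set[str]:
        if k > len(self.category_ids):
            raise ValidationError(
                f"k={k} exceeds list length {len(self.category_ids)}"
            )
        return set(self.category_ids[:k])

    def ranks(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.category_ids, start=1)}

    def __len__(self) -> int:
        return len(self.category_ids)


def category_length_bias_test(
    lengths: dict[str, float] | pd.Series,
    categories: CategoryMap,
    min_size: int = 2,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test of in-category vs out-of-category lengths.

    Returns a frame with per-category median length and MWU p-value.
    Categories with fewer than ``min_size`` genes on either side are skipped
    with a warning.
    """
    lengths = pd.Series(lengths, dtype=float)
    if lengths.empty:
        raise ValidationError("empty gene universe")
    rows = []
    all_genes = set(lengths.index)
    for cat in categories.categories:
        in_genes = categories.genes_in(cat) & all_genes
        out_genes = all_genes - in_genes
        if len(in_genes) < min_size or len(out_genes) < min_size:
            logger.warning("skipping category %s: too few genes", cat)
            continue
        lin = lengths.loc[sorted(in_genes)].to_numpy()
        lout = lengths.loc[sorted(out_genes)].to_numpy()
        if np.ptp(np.concatenate([lin, lout])) == 0:
            p = 1.0  # no rank separation possible
        else:
            p = float(stats.mannwhitneyu(lin, lout, alternative="two-sided").pvalue)
        rows.append((cat, float(np.median(lin)), p))
    return pd.DataFrame(rows, columns=["category_id", "median_length", "mwu_pvalue"])


def rank_discrepancy(a: RankedList, b: RankedList, k: int) -> int:
    """Number of categories in a's top k that are absent from b's top k.

    Symmetric in (a, b) because both top-k sets have size k.
    """
    return len(a.top(k) - b.top(k))


def rank_change_table(
    a: RankedList, b: RankedList, category_stats: dict[str, float] | pd.Series
) -> pd.DataFrame:
    """Per-category 1-based ranks in each list and their change (a -> b)."""
    if set(a.category_ids) != set(b.category_ids):
        raise ValidationError("ranked lists cover different category universes")
    stats_s = pd.Series(category_stats, dtype=float)
    ra, rb = a.ranks(), b.ranks()
    rows = [
        (c, ra[c], rb[c], ra[c] - rb[c], float(stats_s.get(c, np.nan)))
        for c in sorted(ra)
    ]
    return pd.DataFrame(
        rows, columns=["category_id", "rank_a", "rank_b", "delta_rank", "stat"]
    )


def overlap_fraction_curve(reference: RankedList, test: RankedList, ks) -> list[float]:
    """Fraction of the reference top k recovered by the test list's top k."""
    ks = list(ks)
    if any(k2 < k1 for k1, k2 in zip(ks, ks[1:])):
        raise ValidationError("ks must be sorted ascending")
    return [len(test.top(k) & reference.top(k)) / k for k in ks]


def method_comparison_binomial(recovered_a, recovered_b) -> float:
    """One-sided binomial test that method a recovers more categories than b.

    Among discordant categories (recovered by exactly one method), tests the
    a-only count against Binomial(n_discordant, 1/2).  Returns 1.0 when no
    category is discordant.
    """
    ra = np.asarray(recovered_a, dtype=bool)
    rb = np.asarray(recovered_b, dtype=bool)
    if ra.shape != rb.shape or ra.ndim != 1:
        raise ValidationError("recovery vectors must be equal-length")
    discordant = ra ^ rb
    n_disc = int(discordant.sum())
    if n_disc == 0:
        return 1.0
    a_only = int((ra & ~rb).sum())
    return float(stats.binom.sf(a_only - 1, n_disc, 0.5))
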