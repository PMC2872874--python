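"""Fully specified synthetic data generator.

Produces gene lengths (log-normal), expression levels (gamma), two-condition
Poisson counts in which a gene's expected count is proportional to
length x expression (the mechanism that creates length bias in DE calling),
category maps with optional length-biased membership, and planted category
enrichment with known truth labels.  Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lenrich.errors import ValidationError
from lenrich.io_annotation import CategoryMap, GeneTable


@dataclass
class SimulationConfig:
    """Knobs for one synthetic dataset."""

    n_genes: int = 10_000
    length_meanlog: float = 7.8       # natural-log scale; median length e^meanlog bp
    length_sdlog: float = 0.7
    expression_shape: float = 1.2     # gamma expression-level distribution
    expression_scale: float = 1.0
    lib_sizes: tuple[int, int] = (2_000_000, 2_000_000)
    de_fraction: float = 0.1
    fold_change: float = 5.0
    # fraction of truly DE genes that go DOWN (at 1/fold_change) in condition
    # 2; the 0.5 default keeps the two conditions' total intensity balanced so
    # non-DE genes stay null under per-condition normalisation
    de_down_fraction: float = 0.5
    n_categories: int = 200
    category_size_range: tuple[int, int] = (20, 200)
    length_bias_strength: float = 0.0  # exponent on length rank when sampling members
    enriched_categories: dict[str, float] = field(default_factory=dict)
    overdispersion: float = 0.0        # negative-binomial knob; 0 = pure Poisson
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if self.length_sdlog < 0 or self.expression_shape <= 0 or self.expression_scale <= 0:
            raise ValidationError("distribution parameters must be positive")
        if any(m <= 0 for m in self.lib_sizes) or len(self.lib_sizes) != 2:
            raise ValidationError("two positive library sizes required")
        if not (0 <= self.de_fraction <= 1):
            raise ValidationError("de_fraction must lie in [0, 1]")
        if not (0 <= self.de_down_fraction <= 1):
            raise ValidationError("de_down_fraction must lie in [0, 1]")
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be positive")
        lo, hi = self.category_size_range
        if not (1 <= lo <= hi):
            raise ValidationError("invalid category size range")
        if hi > self.n_genes:
            raise ValidationError("category size exceeds n_genes")
        if self.length_bias_strength < 0 or self.overdispersion < 0:
            raise ValidationError("strengths must be non-negative")


def generate_genes(config: SimulationConfig):
    """Draw lengths, expression levels and true DE labels.

    Returns (lengths, expressions, true_de_flags); reproducible per seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = rng.lognormal(config.length_meanlog, config.length_sdlog, config.n_genes)
    expressions = rng.gamma(
        config.expression_shape, config.expression_scale, config.n_genes
    )
    n_de = int(round(config.de_fraction * config.n_genes))
    true_de = np.zeros(config.n_genes, dtype=bool)
    if n_de:
        true_de[rng.choice(config.n_genes, size=n_de, replace=False)] = True
    return lengths, expressions, true_de


def generate_counts(lengths, expressions, true_de_flags, config: SimulationConfig):
    """Draw the two-condition count matrix.

    Expected count is lib_size x length x expression / sum(length x expression)
    per condition; truly DE genes have expression multiplied by fold_change in
    condition 2.  Counts are Poisson, or negative binomial when the
    overdispersion knob is on.
    """
    lengths = np.asarray(lengths, dtype=float)
    expressions = np.asarray(expressions, dtype=float)
    true_de = np.asarray(true_de_flags, dtype=bool)
    if not (lengths.shape == expressions.shape == true_de.shape):
        raise ValidationError("inputs must have equal length")
    rng = np.random.default_rng(config.seed + 1)
    down = true_de & (rng.random(true_de.size) < config.de_down_fraction)
    factor = np.where(down, 1.0 / config.fold_change, config.fold_change)
    expr2 = np.where(true_de, expressions * factor, expressions)
    counts = np.empty((lengths.size, 2), dtype=np.int64)
    for cond, expr in enumerate((expressions, expr2)):
        intensity = lengths * expr
        total = intensity.sum()
        if total <= 0:
            raise ValidationError("all-zero expected counts")
        mu = config.lib_sizes[cond] * intensity / total
        if config.overdispersion > 0:
            # NB with variance mu + overdispersion * mu^2
            shape = 1.0 / config.overdispersion
            lam = rng.gamma(shape, mu / shape)
            counts[:, cond] = rng.poisson(lam)
        else:
            counts[:, cond] = rng.poisson(mu)
    return counts


def generate_category_map(lengths, config: SimulationConfig, true_de_flags=None):
    """Build a category map, optionally length-biased and/or DE-enriched.

    Each category draws its members either uniformly or with probability
    proportional to (length rank)^strength — interpolated per category by
    ``length_bias_strength`` acting as the probability a category is built
    rank-weighted.  Categories named in ``enriched_categories`` additionally
    over-sample truly-DE genes at the configured odds.  Returns
    (CategoryMap, truth frame) where the truth frame labels each category
    length_biased / enriched.
    """
    config.validate()
    lengths = np.asarray(lengths, dtype=float)
    n = lengths.size
    rng = np.random.default_rng(config.seed + 2)
    ranks = stats_rankdata(lengths)
    gene_ids = [f"g{i:06d}" for i in range(n)]
    lo, hi = config.category_size_range
    c2g: dict[str, frozenset[str]] = {}
    truth_rows = []
    true_de = (
        np.asarray(true_de_flags, dtype=bool)
        if true_de_flags is not None
        else np.zeros(n, dtype=bool)
    )
    for j in range(config.n_categories):
        cat = f"C{j:05d}"
        size = int(rng.integers(lo, hi + 1))
        biased = bool(rng.random() < config.length_bias_strength)
        if biased:
            w = ranks ** 3.0  # rank-weighted: strongly favours long genes
        else:
            w = np.ones(n)
        odds = config.enriched_categories.get(cat, 1.0)
        if odds != 1.0:
            w = w * np.where(true_de, odds, 1.0)
        members = rng.choice(n, size=size, replace=False, p=w / w.sum())
        c2g[cat] = frozenset(gene_ids[i] for i in members)
        truth_rows.append((cat, biased, odds != 1.0, odds))
    truth = pd.DataFrame(
        truth_rows, columns=["category_id", "length_biased", "enriched", "odds"]
    )
    return CategoryMap(c2g), truth


def stats_rankdata(x: np.ndarray) -> np.ndarray:
    order = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return (order + 1).astype(float)


def generate_dataset(config: SimulationConfig):
    """One-call generator: GeneTable + CategoryMap + truth tables.

    Returns (table, cmap, truth) with gene ids g000000..; the gene table's
    library sizes are the realised column sums (self-consistent with the
    counts).
    """
    lengths, expressions, true_de = generate_genes(config)
    counts = generate_counts(lengths, expressions, true_de, config)
    cmap, cat_truth = generate_category_map(lengths, config, true_de)
    gene_ids = [f"g{i:06d}" for i in range(config.n_genes)]
    frame = pd.DataFrame(
        {
            "length_bp": lengths,
            "count_1": counts[:, 0],
            "count_2": counts[:, 1],
            "true_de": true_de,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    lib_sizes = (max(1, int(counts[:, 0].sum())), max(1, int(counts[:, 1].sum())))
    table = GeneTable(frame, lib_sizes)
    return table, cmap, cat_truth


def write_dataset(table: GeneTable, cmap: CategoryMap, truth, out_prefix: str) -> dict:
    """Write counts/lengths/categories/truth TSVs; returns the path map."""
    paths = {
        "counts": f"{out_prefix}counts.tsv",
        "lengths": f"{out_prefix}lengths.tsv",
        "categories": f"{out_prefix}categories.tsv",
        "truth": f"{out_prefix}truth.tsv",
    }
    counts = table.frame[["count_1", "count_2"]].reset_index()
    counts.columns = ["gene_id", "count_cond1", "count_cond2"]
    counts.to_csv(paths["counts"], sep="\t", index=False)
    lengths = table.frame[["length_bp"]].reset_index()
    lengths.columns = ["gene_id", "length_bp"]
    lengths.to_csv(paths["lengths"], sep="\t", index=False, float_format="%.6f")
    with open(paths["categories"], "w", encoding="utf-8") as fh:
        for cat in cmap.categories:
            for g in sorted(cmap.genes_in(cat)):
                fh.write(f"{g}\t{cat}\n")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
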