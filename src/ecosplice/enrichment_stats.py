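"""Randomization enrichment tests, two-proportion Z, and multiplicity control.

The enrichment framework compares the count of feature-positive items in a
test set against its distribution over ``n_iter`` equal-sized random draws
(without replacement) from a reference pool. The empirical Z

    z = (observed - null_mean) / null_sd

with a two-sided normal p is the primary statistic; because the draws are
without replacement the exact null is hypergeometric, and the exact
hypergeometric two-sided p is reported alongside as a closed-form
cross-check, together with the empirical tail proportion.

Two-sided p values throughout; the direction (enriched vs. depleted) is
reported separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 10_000
#: smallest per-term background annotation count kept as its own GO category;
#: smaller terms are pooled into one composite category before testing
DEFAULT_MIN_TERM = 100


@dataclass
class EnrichmentResult:
    feature_id: str
    observed: int
    null_mean: float
    null_sd: float
    z: float  # nan when null_sd == 0
    p_raw: float
    p_emp: float
    p_hyper: float
    direction: str  # enriched | depleted
    n_iter: int
    seed: int
    p_adj: float = math.nan

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adj < alpha


@dataclass(frozen=True)
class TwoPropResult:
    z: float
    p: float
    p1_hat: float
    p2_hat: float
    pooled_p: float


def _sample_counts(
    pool_feature: np.ndarray, k: int, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Feature-positive counts over n_iter uniform size-k draws without replacement.

    Each row of uniform keys is argpartitioned so its k smallest keys pick a
    uniformly random k-subset of the pool.
    """
    n = pool_feature.shape[0]
    counts = np.empty(n_iter, dtype=np.int64)
    batch = max(1, min(n_iter, int(4e6) // max(n, 1)))
    done = 0
    while done < n_iter:
        m = min(batch, n_iter - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        counts[done:done + m] = pool_feature[idx].sum(axis=1)
        done += m
    return counts


def randomization_enrichment(
    test_set: Iterable[Hashable],
    pool: Sequence[Hashable],
    feature: Callable[[Hashable], bool],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    feature_id: str = "feature",
) -> EnrichmentResult:
    """Empirical-Z enrichment of a boolean feature in ``test_set`` vs. ``pool``.

    ``test_set`` must be a subset of ``pool``. Each draw samples
    ``len(test_set)`` items from the pool without replacement and counts
    feature-positive items; reproducible from ``seed``.
    """
    test_set = list(test_set)
    pool = list(pool)
    try:
        is_subset = set(test_set) <= set(pool)
    except TypeError:  # unhashable items: fall back to object identity
        pool_ids = set(map(id, pool))
        is_subset = all(id(x) in pool_ids for x in test_set)
    if not is_subset:
        raise ValueError("test_set must be a subset of pool")
    if len(test_set) < 1:
        raise ValueError("test_set must be non-empty")
    pool_feature = np.fromiter((bool(feature(x)) for x in pool), dtype=np.int64, count=len(pool))
    n_pos = int(pool_feature.sum())
    if n_pos == 0 or n_pos == len(pool):
        raise ValueError("pool must contain both feature-positive and feature-negative items")

    observed = sum(1 for x in test_set if feature(x))
    k = len(test_set)
    rng = np.random.default_rng(seed)
    counts = _sample_counts(pool_feature, k, n_iter, rng)
    null_mean = float(counts.mean())
    null_sd = float(counts.std(ddof=0))

    # empirical two-sided tail: how often a random draw deviates from the
    # null mean at least as far as the observation did (add-one smoothed)
    dev = abs(observed - null_mean)
    p_emp = float((np.sum(np.abs(counts - null_mean) >= dev) + 1) / (n_iter + 1))

    if null_sd == 0.0:
        logger.warning("%s: null sd is zero; z undefined, p taken from empirical tail", feature_id)
        z = math.nan
        p_raw = p_emp
    else:
        z = (observed - null_mean) / null_sd
        p_raw = 2.0 * stats.norm.sf(abs(z))

    p_hyper = _hypergeom_two_sided(observed, len(pool), n_pos, k)
    direction = "enriched" if observed > null_mean else "depleted"
    return EnrichmentResult(
        feature_id=feature_id, observed=observed, null_mean=null_mean, null_sd=null_sd,
        z=z, p_raw=min(1.0, p_raw), p_emp=p_emp, p_hyper=p_hyper,
        direction=direction, n_iter=n_iter, seed=seed,
    )


def _hypergeom_two_sided(observed: int, pool_size: int, n_pos: int, k: int) -> float:
    """Exact two-sided hypergeometric p by minimum-likelihood summation."""
    rv = stats.hypergeom(pool_size, n_pos, k)
    support = np.arange(max(0, k - (pool_size - n_pos)), min(k, n_pos) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(observed)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))


def adjust_pvalues(p: Sequence[float], method: str = "bh", m: int | None = None) -> list[float]:
    """Bonferroni or Benjamini–Hochberg adjusted p values.

    ``m`` overrides the family size (Bonferroni only; BH uses the list
    itself as the family). Backed by statsmodels' multipletests.
    """
    p = list(p)
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise ValueError("p values must lie in [0, 1]")
    if not p:
        return []
    if method == "bonferroni":
        fam = m if m is not None else len(p)
        if fam < len(p):
            raise ValueError("family size m cannot be smaller than the number of tests")
        return [min(1.0, x * fam) for x in p]
    if method == "bh":
        return list(multipletests(p, method="fdr_bh")[1])
    raise ValueError(f"unknown method {method!r}")


def two_prop_z(x1: int, n1: int, x2: int, n2: int) -> TwoPropResult:
    """Pooled two-proportion Z test with two-sided normal p."""
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("counts must satisfy 0 <= x <= n with n >= 1")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.warning("two_prop_z: pooled proportion is %s, no variance", pooled)
        return TwoPropResult(z=0.0, p=1.0, p1_hat=p1, p2_hat=p2, pooled_p=pooled)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return TwoPropResult(z=z, p=min(1.0, 2.0 * stats.norm.sf(abs(z))), p1_hat=p1, p2_hat=p2, pooled_p=pooled)


def event_type_enrichment(
    specific_events: dict[str, list],
    all_confirmed_events: list,
    event_types: Sequence[str] = ("ES", "5S", "3S", "3S5S", "IR"),
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    bonferroni_family: int | None = None,
) -> dict[tuple[str, str], EnrichmentResult]:
    """Per-(ecotype, event type) enrichment of ecotype-specific events.

    For each ecotype's specific events, each of the five types is tested
    against equal-sized draws from the pool of all confirmed events;
    Bonferroni correction over the full family (default: ecotypes x types).
    """
    family = bonferroni_family if bonferroni_family is not None else len(specific_events) * len(event_types)
    results: dict[tuple[str, str], EnrichmentResult] = {}
    for i, (ecotype, events) in enumerate(sorted(specific_events.items())):
        for j, etype in enumerate(event_types):
            res = randomization_enrichment(
                test_set=events, pool=all_confirmed_events,
                feature=lambda ev, t=etype: ev.event_type == t,
                n_iter=n_iter, seed=seed + 1000 * i + j,
                feature_id=f"{ecotype}:{etype}",
            )
            res.p_adj = min(1.0, res.p_raw * family)
            results[(ecotype, etype)] = res
    return results


def group_small_terms(
    term_to_genes: dict[str, set[str]],
    background: set[str],
    min_term: int = DEFAULT_MIN_TERM,
    composite_name: str = "small_terms_grouped",
) -> dict[str, set[str]]:
    """Pool GO terms annotating fewer than ``min_term`` background genes.

    Terms are sized by their intersection with the background; all
    undersized terms merge into one composite category.
    """
    grouped: dict[str, set[str]] = {}
    composite: set[str] = set()
    for term, genes in term_to_genes.items():
        bg_genes = genes & background
        if not bg_genes:
            continue
        if len(bg_genes) < min_term:
            composite |= bg_genes
        else:
            grouped[term] = bg_genes
    if composite:
        grouped[composite_name] = composite
    return grouped


def gene_set_enrichment(
    test_genes: set[str],
    background_genes: set[str],
    gene_sets: dict[str, set[str]],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    min_term: int | None = None,
) -> dict[str, EnrichmentResult]:
    """Randomization enrichment of each gene set in ``test_genes``, BH-adjusted.

    ``background_genes`` is the pool (typically all alternatively spliced
    genes). When ``min_term`` is given, undersized sets are pooled first.
    """
    if not background_genes:
        raise ValueError("background gene set is empty")
    if not test_genes <= background_genes:
        raise ValueError("test_genes must be a subset of background_genes")
    if min_term is not None:
        gene_sets = group_small_terms(gene_sets, background_genes, min_term)
    pool = sorted(background_genes)
    results: dict[str, EnrichmentResult] = {}
    for i, name in enumerate(sorted(gene_sets)):
        members = gene_sets[name] & background_genes
        if not members or members == background_genes:
            logger.warning("gene set %s degenerate within background; skipped", name)
            continue
        results[name] = randomization_enrichment(
            test_set=sorted(test_genes), pool=pool,
            feature=lambda g, s=members: g in s,
            n_iter=n_iter, seed=seed + i, feature_id=name,
        )
    adj = adjust_pvalues([results[n].p_raw for n in sorted(results)], method="bh")
    for name, a in zip(sorted(results), adj):
        results[name].p_adj = a
    return results
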