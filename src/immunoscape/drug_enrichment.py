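"""Permutation test of candidate-gene overlap with drug-target genes.

The observed overlap between the candidate list and the drug-target list is
compared with the overlaps of random candidate-sized draws from a gene
universe (without replacement). Fold enrichment = observed / mean null
overlap; the one-sided p is the fraction of null draws at least as large as
the observed overlap. The analytic hypergeometric expectation and tail
provide a closed-form cross-check.

A count-only mode reproduces published statistics when only the list sizes
(universe, candidates, targets) and the observed overlap are known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "DrugEnrichmentResult",
    "overlap_permutation_test",
    "overlap_permutation_counts",
    "hypergeometric_check",
]


@dataclass
class DrugEnrichmentResult:
    n_candidates: int
    n_targets: int
    n_universe: int
    observed_overlap: int
    null_mean: float
    fold_enrichment: float
    p_one_sided: float
    p_is_upper_bound: bool  # True when no null draw reached the observed overlap
    n_permutations: int
    seed: int
    overlapping_genes: list[str] = field(default_factory=list)


def _null_overlaps(
    n_universe: int, target_mask: np.ndarray, n_candidates: int, n_perm: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        draw = rng.choice(n_universe, size=n_candidates, replace=False)
        out[i] = int(target_mask[draw].sum())
    return out


def _finalize(
    observed: int,
    nulls: np.ndarray,
    n_candidates: int,
    n_targets: int,
    n_universe: int,
    seed: int,
    overlapping: list[str],
) -> DrugEnrichmentResult:
    null_mean = float(nulls.mean())
    if null_mean == 0:
        raise ValueError("null mean overlap is 0 (no target gene in the universe)")
    n_perm = len(nulls)
    count = int((nulls >= observed).sum())
    if count == 0:
        p, bound = 1.0 / n_perm, True
    else:
        p, bound = count / n_perm, False
    return DrugEnrichmentResult(
        n_candidates=n_candidates,
        n_targets=n_targets,
        n_universe=n_universe,
        observed_overlap=observed,
        null_mean=null_mean,
        fold_enrichment=observed / null_mean,
        p_one_sided=p,
        p_is_upper_bound=bound,
        n_permutations=n_perm,
        seed=seed,
        overlapping_genes=overlapping,
    )


def overlap_permutation_test(
    candidates: list[str],
    targets: list[str],
    universe: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> DrugEnrichmentResult:
    """Fold-enrichment permutation test on explicit gene lists.

    Candidates/targets outside the universe are dropped with a warning. The
    null draws |candidates| genes uniformly without replacement from the
    universe for each of ``n_perm`` permutations.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    cand = [g for g in dict.fromkeys(candidates) if g in uni_set]
    targ = [g for g in dict.fromkeys(targets) if g in uni_set]
    dropped_c = len(set(candidates)) - len(cand)
    dropped_t = len(set(targets)) - len(targ)
    if dropped_c or dropped_t:
        logger.warning(
            "dropped %d candidates and %d targets outside the universe", dropped_c, dropped_t
        )
    if not cand:
        raise ValueError("candidate list empty (after universe restriction)")

    overlapping = sorted(set(cand) & set(targ))
    target_mask = np.isin(np.asarray(uni), np.asarray(targ))
    nulls = _null_overlaps(len(uni), target_mask, len(cand), n_perm, seed)
    return _finalize(len(overlapping), nulls, len(cand), len(targ), len(uni), seed, overlapping)


def overlap_permutation_counts(
    n_candidates: int,
    n_targets: int,
    n_universe: int,
    observed: int,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DrugEnrichmentResult:
    """Count-only mode: run the same null with only the list sizes and the
    observed overlap (for reproducing published statistics)."""
    if not (0 <= observed <= min(n_candidates, n_targets)):
        raise ValueError("observed overlap inconsistent with list sizes")
    if n_targets > n_universe or n_candidates > n_universe:
        raise ValueError("list sizes exceed the universe")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    target_mask = np.zeros(n_universe, dtype=bool)
    target_mask[:n_targets] = True
    nulls = _null_overlaps(n_universe, target_mask, n_candidates, n_perm, seed)
    return _finalize(observed, nulls, n_candidates, n_targets, n_universe, seed, [])


def hypergeometric_check(
    n_candidates: int, n_targets: int, n_universe: int, observed: int
) -> tuple[float, float]:
    """Closed-form null: expected overlap n·K/N and exact tail P(X >= obs)."""
    if n_targets > n_universe or n_candidates > n_universe:
        raise ValueError("list sizes exceed the universe")
    if not (0 <= observed <= min(n_candidates, n_targets)):
        raise ValueError("observed overlap inconsistent with list sizes")
    expected = n_candidates * n_targets / n_universe
    tail = float(hypergeom.sf(observed - 1, n_universe, n_targets, n_candidates))
    return float(expected), tail
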