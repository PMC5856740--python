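"""Trophic-overlap randomization test and combined significance.

Tests whether species of two insect taxa (orders or families) visit
different assemblages of plant species at a site. The statistic is the
mean Bray-Curtis dissimilarity over all between-taxa species pairs,
D_obs; the null shuffles taxon labels over the species while holding
every species' visitation profile and the two group sizes fixed. D_obs
exceeding 97.5% of the null values is evidence of trophic partitioning.
Site-level p-values are pooled over the elevational gradient with the
Jost generalization of Fisher's combined probability test,

    P = K * sum_{i=0}^{N-1} (-ln K)^i / i!,   K = p_1 * ... * p_N,

which equals the upper tail of a chi-square with 2N df at -2 ln K.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .network import INCLUSION_THRESHOLDS, TaxonLevel, VisitationNetwork, \
    build_network, inclusion_filter
from .records import VisitRecord

#: Default number of label permutations.
DEFAULT_B = 1000

#: One-sided criterion: D_obs must exceed this percentile of the null.
CRITERION_PERCENTILE = 97.5


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x_i - y_i| / sum(x_i + y_i).

    0 means identical visit profiles, 1 disjoint plant sets. A
    semimetric: symmetric and bounded but the triangle inequality may
    fail. Undefined (error) when both vectors are all zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def _pairwise_bray_curtis(profiles: np.ndarray) -> np.ndarray:
    """Full n x n Bray-Curtis matrix of row profiles (vectorized)."""
    totals = profiles.sum(axis=1)
    num = np.abs(profiles[:, None, :] - profiles[None, :, :]).sum(axis=2)
    den = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    return d


def _cross_mean(d: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    return float(d[np.ix_(idx1, idx2)].mean())


def _profiles(network: VisitationNetwork, species: Sequence[str]) -> np.ndarray:
    m = network.counts.loc[list(species)].to_numpy(dtype=float)
    if (m.sum(axis=1) == 0).any():
        raise ValueError("every species profile must have at least one visit")
    return m


def mean_cross_dissimilarity(
    network: VisitationNetwork,
    taxon1: str,
    taxon2: str,
    level: TaxonLevel = "order",
) -> float:
    """D_obs: unweighted mean Bray-Curtis over between-taxa species pairs."""
    s1 = network.species_of(taxon1, level)
    s2 = network.species_of(taxon2, level)
    if not s1 or not s2:
        raise ValueError(
            f"both taxa need >= 1 species at site {network.site_id!r}: "
            f"{taxon1}={len(s1)}, {taxon2}={len(s2)}")
    profiles = _profiles(network, list(s1) + list(s2))
    d = _pairwise_bray_curtis(profiles)
    n1 = len(s1)
    return _cross_mean(d, np.arange(n1), np.arange(n1, n1 + len(s2)))


def permutation_null(
    network: VisitationNetwork,
    taxon1: str,
    taxon2: str,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    level: TaxonLevel = "order",
    universe: str = "pair",
) -> np.ndarray:
    """Null sample of D_0 by shuffling species' taxon labels.

    Each replicate reassigns the labels uniformly at random while
    keeping every species' plant-visit profile and the group sizes
    |T1|, |T2| fixed, then recomputes the mean cross-taxa dissimilarity.

    ``universe`` selects the label pool: ``"pair"`` (default) permutes
    over the species of T1 and T2 only; ``"all"`` draws the two groups
    from every species at the site.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s1 = network.species_of(taxon1, level)
    s2 = network.species_of(taxon2, level)
    if not s1 or not s2:
        raise ValueError("both taxa need >= 1 species")
    n1, n2 = len(s1), len(s2)
    if universe == "pair":
        pool = list(s1) + list(s2)
    elif universe == "all":
        pool = list(network.counts.index)
    else:
        raise ValueError(f"unknown universe {universe!r}")
    profiles = _profiles(network, pool)
    # The statistic depends on species only through their pairwise
    # dissimilarities, so the matrix is computed once and each replicate
    # averages a shuffled cross block.
    d = _pairwise_bray_curtis(profiles)
    n = len(pool)
    out = np.empty(B)
    for b in range(B):
        perm = rng.permutation(n)
        out[b] = _cross_mean(d, perm[:n1], perm[n1:n1 + n2])
    return out


def exhaustive_null(
    network: VisitationNetwork,
    taxon1: str,
    taxon2: str,
    level: TaxonLevel = "order",
) -> np.ndarray:
    """Exact null: D_0 for every distinct taxon-label assignment.

    Enumerates all C(n1+n2, n1) ways of labelling the pooled species,
    feasible only for small networks; used to validate the Monte-Carlo
    null.
    """
    s1 = network.species_of(taxon1, level)
    s2 = network.species_of(taxon2, level)
    pool = list(s1) + list(s2)
    d = _pairwise_bray_curtis(_profiles(network, pool))
    n, n1 = len(pool), len(s1)
    values = []
    all_idx = frozenset(range(n))
    for combo in itertools.combinations(range(n), n1):
        idx1 = np.fromiter(combo, dtype=int)
        idx2 = np.fromiter(sorted(all_idx - set(combo)), dtype=int)
        values.append(_cross_mean(d, idx1, idx2))
    return np.asarray(values)


@dataclass
class OverlapResult:
    """Outcome of the site-level overlap randomization test."""

    site_id: str
    taxon1: str
    taxon2: str
    level: TaxonLevel
    d_obs: float
    null: np.ndarray
    p_value: float
    significant: bool
    B: int
    seed: int | None
    n_visits: tuple[int, int] = (0, 0)
    n_species: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        assert 0.0 <= self.d_obs <= 1.0 + 1e-12
        assert 1.0 / (self.B + 1) <= self.p_value <= 1.0


def overlap_test(
    network: VisitationNetwork,
    taxon1: str,
    taxon2: str,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    level: TaxonLevel = "order",
    universe: str = "pair",
) -> OverlapResult:
    """Three-step randomization test of foraging-preference overlap.

    (1) compute D_obs; (2) build the permutation null of D_0; (3) call
    the partitioning significant when D_obs strictly exceeds the
    empirical 97.5th percentile of the null. The p-value uses the
    add-one estimator (1 + #{D_0 >= D_obs}) / (B + 1), so it is never 0
    and downstream combination is well defined.
    """
    d_obs = mean_cross_dissimilarity(network, taxon1, taxon2, level)
    null = permutation_null(network, taxon1, taxon2, B=B, seed=seed,
                            level=level, universe=universe)
    p = (1.0 + float((null >= d_obs).sum())) / (B + 1.0)
    threshold = float(np.percentile(null, CRITERION_PERCENTILE))
    return OverlapResult(
        site_id=network.site_id,
        taxon1=taxon1,
        taxon2=taxon2,
        level=level,
        d_obs=d_obs,
        null=null,
        p_value=p,
        significant=bool(d_obs > threshold),
        B=B,
        seed=seed if isinstance(seed, int) else None,
        n_visits=(network.taxon_stats(taxon1, level)[0],
                  network.taxon_stats(taxon2, level)[0]),
        n_species=(network.taxon_stats(taxon1, level)[1],
                   network.taxon_stats(taxon2, level)[1]),
    )


@dataclass
class CombinedResult:
    """Jost combined significance over N independent site-level tests."""

    N: int
    K: float
    P: float

    def __post_init__(self) -> None:
        assert 0.0 < self.K <= 1.0
        assert 0.0 < self.P <= 1.0 + 1e-12
        self.P = min(self.P, 1.0)


def jost_combine(p_values: Sequence[float]) -> CombinedResult:
    """Combine independent p-values: P = K * sum_{i<N} (-ln K)^i / i!.

    K is the product of the N p-values. The series is evaluated in log
    space so tiny K (strong combined evidence) stays accurate; it is
    mathematically the chi-square(2N) survival function at -2 ln K.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    log_k = float(np.log(p).sum())
    if log_k == 0.0:
        return CombinedResult(N=n, K=1.0, P=1.0)
    # log P = log K + logsumexp_i [ i*log(-log K) - log i! ]
    i = np.arange(n)
    log_terms = i * np.log(-log_k) - gammaln(i + 1)
    log_p = log_k + logsumexp(log_terms)
    return CombinedResult(N=n, K=float(np.exp(log_k)), P=float(np.exp(min(log_p, 0.0))))


@dataclass
class OverlapSuiteResult:
    """Per-site tests, per-pair combined significance, and exclusions."""

    level: TaxonLevel
    site_results: list[OverlapResult]
    combined: dict[tuple[str, str], CombinedResult]
    excluded: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (site, taxon1, taxon2, reason)

    def site_table(self) -> pd.DataFrame:
        rows = [
            {
                "site_id": r.site_id,
                "taxon1": r.taxon1,
                "taxon2": r.taxon2,
                "d_obs": r.d_obs,
                "p_value": r.p_value,
                "significant": r.significant,
                "n_visits_1": r.n_visits[0],
                "n_visits_2": r.n_visits[1],
                "n_species_1": r.n_species[0],
                "n_species_2": r.n_species[1],
            }
            for r in self.site_results
        ]
        return pd.DataFrame(rows, columns=[
            "site_id", "taxon1", "taxon2", "d_obs", "p_value", "significant",
            "n_visits_1", "n_visits_2", "n_species_1", "n_species_2"])


#: Orders with enough visits for the order-level analysis; butterflies
#: are too scarce per site to qualify.
DEFAULT_ORDER_TAXA = ("Diptera", "Hymenoptera", "Coleoptera")


def _pair_seed(root: int | None, site: str, t1: str, t2: str) -> np.random.Generator:
    """Deterministic per-(site, pair) stream; independent of site order."""
    entropy = [zlib.crc32(s.encode()) for s in (site, t1, t2)]
    if root is not None:
        entropy.insert(0, int(root) % (2**31))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_overlap_suite(
    records: Sequence[VisitRecord],
    level: TaxonLevel = "order",
    pairs: Sequence[tuple[str, str]] | None = None,
    B: int = DEFAULT_B,
    seed: int | None = None,
    min_visits: int | None = None,
    min_species: int | None = None,
    universe: str = "pair",
) -> OverlapSuiteResult:
    """Overlap tests at every qualifying site, combined per taxon pair.

    Default pairs are all pairs of {Diptera, Hymenoptera, Coleoptera} at
    order level, and all pairs of the focal Diptera families (those
    jointly holding >= 75% of Diptera visits) at family level — the only
    families dense enough per site to pass the inclusion thresholds.
    Sites failing the thresholds for a pair are logged, not tested.
    """
    if pairs is None:
        if level == "order":
            taxa: Sequence[str] = DEFAULT_ORDER_TAXA
        else:
            from .phenology import select_focal_families
            taxa = select_focal_families(records, "Diptera")
        pairs = list(itertools.combinations(sorted(taxa), 2))

    site_ids = sorted({r.site_id for r in records})
    networks = {s: build_network(records, s, taxon_level=level) for s in site_ids}

    site_results: list[OverlapResult] = []
    excluded: list[tuple[str, str, str, str]] = []
    p_by_pair: dict[tuple[str, str], list[float]] = {tuple(p): [] for p in pairs}
    for t1, t2 in pairs:
        for site in site_ids:
            net = networks[site]
            ok, reason = inclusion_filter(net, t1, t2, level=level,
                                          min_visits=min_visits,
                                          min_species=min_species)
            if not ok:
                excluded.append((site, t1, t2, reason))
                continue
            rng = _pair_seed(seed, site, t1, t2)
            res = overlap_test(net, t1, t2, B=B, seed=rng, level=level,
                               universe=universe)
            res.seed = seed
            site_results.append(res)
            p_by_pair[(t1, t2)].append(res.p_value)

    combined = {
        pair: jost_combine(ps) for pair, ps in p_by_pair.items() if ps
    }
    return OverlapSuiteResult(level=level, site_results=site_results,
                              combined=combined, excluded=excluded)
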