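"""Seed-gene correlation expansion and binomial over-representation testing.

A small set of canonical HIF-target "seed" genes (default BNIP3, DDIT4,
P4HA1, P4HA2, PLAUR) anchors the search: for each seed, every other gene in
the matrix is ranked by Spearman correlation against the seed's expression
vector and the top-k (default 200) retained. Genes from a catalogue of
experimentally validated HIF targets found among those rankings form the
candidate "core"; the hit count is tested against a binomial null in which
validated targets make up a fixed fraction of the transcriptome (default
2%), using an exact log-space tail sum rather than a normal approximation.

Pooling semantics: under ``per_seed_union`` (default), the hit count is the
number of distinct catalogue genes across all per-seed rankings and the
binomial sample size is the number of distinct genes pooled across those
rankings — when the seeds are one tightly co-regulated block the per-seed
lists coincide and this reduces to a single top-k list, while for unrelated
seeds it keeps the null calibrated instead of multiply counting the same
200-gene budget once per seed. ``per_seed_each`` tests each seed's own top-k
separately with sample size k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .containers import ExpressionMatrix
from .exceptions import InputError, UndefinedCorrelationError
from .synthgen import DEFAULT_SEEDS


@dataclass
class SeedSet:
    """Unique seed gene symbols anchoring the expansion."""

    symbols: tuple[str, ...] = DEFAULT_SEEDS

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)
        if not self.symbols:
            raise InputError("seed set must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise InputError("seed symbols must be unique")


@dataclass
class TargetCatalogue:
    """Experimentally validated HIF targets and their assumed genome fraction."""

    symbols: tuple[str, ...]
    assumed_genome_fraction: float = 0.02

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)
        if not self.symbols:
            raise InputError("target catalogue must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise InputError("catalogue symbols must be unique")
        if not 0.0 < self.assumed_genome_fraction < 1.0:
            raise InputError(
                "assumed_genome_fraction must lie in (0, 1), "
                f"got {self.assumed_genome_fraction}"
            )


@dataclass
class ExpansionConfig:
    top_k: int = 200
    hit_threshold: int = 7
    alpha_enrich: float = 0.049
    pooling: str = "per_seed_union"

    def __post_init__(self) -> None:
        if not self.top_k >= self.hit_threshold >= 1:
            raise InputError(
                f"need top_k >= hit_threshold >= 1, got {self.top_k}, {self.hit_threshold}"
            )
        if not 0.0 < self.alpha_enrich < 1.0:
            raise InputError(f"alpha_enrich must be in (0, 1), got {self.alpha_enrich}")
        if self.pooling not in ("per_seed_union", "per_seed_each"):
            raise InputError(f"unknown pooling mode {self.pooling!r}")


@dataclass
class ExpansionResult:
    """Outcome of one expansion: per-seed rankings, core set, enrichment test."""

    per_seed_rankings: dict[str, list[tuple[str, float, float]]]
    core_genes: tuple[str, ...]
    hits: int
    n_trials: int
    binomial_p: float
    enriched: bool
    per_seed: dict[str, dict] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "hits": self.hits,
            "n_trials": self.n_trials,
            "binomial_p": self.binomial_p,
            "enriched": self.enriched,
            "core_genes": list(self.core_genes),
        }


def spearman(x, y, method: str = "approx") -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    ``method='approx'`` uses the large-sample t approximation with n - 2
    degrees of freedom (adequate for the cohort sizes this pipeline targets);
    ``method='exact'`` enumerates all rank permutations (only for n <= 8) and
    is intended for very small samples where the t approximation is poor.

    Raises
    ------
    InputError
        on length mismatch or n < 4.
    UndefinedCorrelationError
        if either vector has zero variance — the correlation is undefined
        and is never silently reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 4:
        raise InputError(f"need at least 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "Spearman correlation undefined for a zero-variance vector"
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if method == "exact":
        if n > 8:
            raise InputError("exact permutation p-value limited to n <= 8")
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=1)


def _spearman_against(seed_ranks: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Spearman rho of one ranked vector against every ranked row (vectorized)."""
    s = seed_ranks - seed_ranks.mean()
    r = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((s * s).sum()) * np.sqrt((r * r).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (r @ s) / denom
    return np.clip(rho, -1.0, 1.0)


def rank_by_seed(
    mat: ExpressionMatrix, seed: str, top_k: int = 200
) -> list[tuple[str, float, float]]:
    """Rank all non-seed genes by descending Spearman rho against the seed.

    Ties in rho are broken by ascending gene symbol so results are identical
    across platforms and row orderings. Exactly ``top_k`` entries returned.
    """
    vec = mat.vector(seed)
    if np.ptp(vec) == 0:
        raise UndefinedCorrelationError(f"seed {seed!r} has zero variance")
    if top_k > mat.n_genes - 1:
        raise InputError(
            f"top_k={top_k} exceeds available genes ({mat.n_genes - 1} non-seed)"
        )
    genes = np.asarray(mat.genes)
    keep = genes != seed
    ranks = _rank_rows(mat.values[keep])
    const = np.ptp(mat.values[keep], axis=1) == 0
    rho = _spearman_against(stats.rankdata(vec), ranks)
    rho[const] = np.nan  # undefined; sorted last, never into a top list
    n = mat.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho * rho, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    order = np.lexsort((genes[keep], -np.nan_to_num(rho, nan=-np.inf)))[:top_k]
    sub_genes = genes[keep]
    return [(str(sub_genes[i]), float(rho[i]), float(p[i])) for i in order]


def binom_tail(k: int, n: int, p: float) -> float:
    """Exact upper binomial tail P(X >= k) by direct log-space summation.

    Sums the n - k + 1 tail terms of Binomial(n, p) with log binomial
    coefficients and ``logsumexp``; no normal approximation at any size.
    Monotone non-increasing in k; returns exactly 1.0 for k <= 0.
    """
    if not 0 <= k <= n or n < 0:
        raise InputError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise InputError(f"p must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    i = np.arange(k, n + 1)
    log_terms = (
        special.gammaln(n + 1)
        - special.gammaln(i + 1)
        - special.gammaln(n - i + 1)
        + i * np.log(p)
        + (n - i) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(special.logsumexp(log_terms))))


def expand(
    mat: ExpressionMatrix,
    seeds: SeedSet,
    catalogue: TargetCatalogue,
    cfg: ExpansionConfig | None = None,
) -> ExpansionResult:
    """Run the full expansion: per-seed rankings, core set, enrichment test.

    Seeds are excluded from hit counting (a seed trivially correlates with
    itself; counting it would inflate enrichment).
    """
    cfg = cfg or ExpansionConfig()
    missing = [s for s in seeds.symbols if s not in mat]
    if missing:
        from .exceptions import MissingGeneError

        raise MissingGeneError(missing)
    rankings = {s: rank_by_seed(mat, s, cfg.top_k) for s in seeds.symbols}
    cat = set(catalogue.symbols) - set(seeds.symbols)
    p0 = catalogue.assumed_genome_fraction

    per_seed: dict[str, dict] = {}
    for s, ranked in rankings.items():
        top = {g for g, _, _ in ranked} - set(seeds.symbols)
        hits_s = sorted(top & cat)
        p_s = binom_tail(len(hits_s), cfg.top_k, p0)
        per_seed[s] = {
            "hits": len(hits_s),
            "n_trials": cfg.top_k,
            "binomial_p": p_s,
            "enriched": p_s < cfg.alpha_enrich,
            "core_genes": hits_s,
        }

    if cfg.pooling == "per_seed_each":
        hits = max(v["hits"] for v in per_seed.values())
        worst = min(per_seed.values(), key=lambda v: v["binomial_p"])
        core = tuple(sorted(set().union(*(v["core_genes"] for v in per_seed.values()))))
        result_p = worst["binomial_p"]
        n_trials = cfg.top_k
    else:
        union = set()
        for ranked in rankings.values():
            union |= {g for g, _, _ in ranked}
        union -= set(seeds.symbols)
        core = tuple(sorted(union & cat))
        hits = len(core)
        n_trials = len(union)
        result_p = binom_tail(hits, n_trials, p0)
    return ExpansionResult(
        per_seed_rankings=rankings,
        core_genes=core,
        hits=hits,
        n_trials=n_trials,
        binomial_p=result_p,
        enriched=result_p < cfg.alpha_enrich,
        per_seed=per_seed,
    )
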