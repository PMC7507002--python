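"""Correlation-matrix construction and Cox-based signature compaction.

The candidate core set is first summarized as a Bonferroni-masked Spearman
correlation matrix (family alpha split over all unordered gene pairs), then
compacted by stepwise selection operating directly on the Cox proportional-
hazards partial likelihood with overall survival as the dependent variable.
The Cox fitter is a Newton–Raphson maximizer of the Efron-tie-corrected
partial likelihood, written here because the stepwise search needs full
control of convergence diagnostics (score tolerance, step-halving, iteration
caps) and refits hundreds of small models per run.

The compact signature is scored per sample either as the unweighted mean of
per-gene z-scores (``zmean``, the default: portable to external cohorts
where refit Cox weights would not transfer) or as the Cox linear predictor
over z-scored genes; scores are z-standardized and dichotomized at the
median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SurvivalTable
from .exceptions import (
    DegenerateScoreError,
    InputError,
    UndefinedCorrelationError,
    UnfitError,
)

# ---------------------------------------------------------------------------
# Bonferroni-masked Spearman correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """All pairwise Spearman correlations over a gene set with Bonferroni mask."""

    genes: list[str]
    rho: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    family_alpha: float
    per_pair_alpha: float
    n_pairs: int
    fraction_significant: float

    def to_long_tsv(self, path) -> None:
        rows = []
        g = self.genes
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                rows.append(
                    (g[i], g[j], self.rho[i, j], self.p[i, j], bool(self.significant[i, j]))
                )
        pd.DataFrame(
            rows, columns=["geneA", "geneB", "rho", "p", "significant"]
        ).to_csv(path, sep="\t", index=False)


def corr_matrix(
    mat: ExpressionMatrix, genes, family_alpha: float = 0.01
) -> CorrelationMatrix:
    """Pairwise Spearman matrix with a Bonferroni significance mask.

    The family alpha (default 0.01) is split over the g(g-1)/2 unordered
    pairs; the diagonal is excluded from significance counting. Also reports
    the fraction of significant pairs.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise InputError("need at least 2 genes for a correlation matrix")
    sub = mat.subset(genes)
    values = sub.values
    flat = np.ptp(values, axis=1) == 0
    if flat.any():
        bad = [g for g, f in zip(genes, flat) if f]
        raise UndefinedCorrelationError(f"zero-variance gene(s): {bad}")
    rho, p = stats.spearmanr(values, axis=1)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    g = len(genes)
    n_pairs = g * (g - 1) // 2
    per_pair_alpha = family_alpha / n_pairs
    significant = p < per_pair_alpha
    np.fill_diagonal(significant, False)
    iu = np.triu_indices(g, k=1)
    frac = float(significant[iu].mean())
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        genes=genes,
        rho=rho,
        p=p,
        significant=significant,
        family_alpha=family_alpha,
        per_pair_alpha=per_pair_alpha,
        n_pairs=n_pairs,
        fraction_significant=frac,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton-Raphson)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    Coefficients are log hazard ratios; when ``standardized`` is True they
    are on the per-SD scale of internally z-scored covariates.
    """

    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    log_likelihood_null: float
    n: int
    n_events: int
    converged: bool
    iterations: int
    max_score: float
    standardized: bool

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci_95(self) -> np.ndarray:
        """95% CI for the hazard ratios, shape (p, 2)."""
        z = 1.959963984540054
        lo = np.exp(self.coefficients - z * self.standard_errors)
        hi = np.exp(self.coefficients + z * self.standard_errors)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        z = self.coefficients / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * len(self.coefficients)

    def summary_frame(self) -> pd.DataFrame:
        ci = self.ci_95
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "HR": self.hazard_ratios,
                "HR 95% lo": ci[:, 0],
                "HR 95% hi": ci[:, 1],
                "p": self.p_values,
            },
            index=self.names,
        )


def _efron_ll_grad_hess(beta, X, time, event):
    """Efron-approximated partial log-likelihood with gradient and Hessian.

    Rows must be sorted by ascending time. Vectorized over tied-event blocks.
    """
    eta = X @ beta
    eta = eta - eta.max()  # numerical shift; cancels in every phi ratio
    w = np.exp(eta)
    n, p = X.shape
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]
    # reverse cumulative sums -> risk-set sums at each index
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum(wX[::-1], axis=0)[::-1]
    c2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    uniq, starts = np.unique(time, return_index=True)
    starts = np.sort(starts)
    bounds = np.append(starts, n)
    for s, e in zip(bounds[:-1], bounds[1:]):
        ev = np.flatnonzero(event[s:e]) + s
        d = ev.size
        if d == 0:
            continue
        s0_r = c0[s]
        s1_r = c1[s]
        s2_r = c2[s]
        if d == 1:
            j = ev[0]
            phi = s0_r
            m = s1_r / phi
            ll += eta[j] - np.log(phi)
            grad += X[j] - m
            hess -= s2_r / phi - np.outer(m, m)
        else:
            s0_t = w[ev].sum()
            s1_t = wX[ev].sum(axis=0)
            s2_t = wXX[ev].sum(axis=0)
            frac = np.arange(d) / d
            phi = s0_r - frac * s0_t  # (d,)
            M = (s1_r[None, :] - frac[:, None] * s1_t[None, :]) / phi[:, None]
            S2 = (s2_r[None, :, :] - frac[:, None, None] * s2_t[None, :, :]) / phi[
                :, None, None
            ]
            ll += eta[ev].sum() - np.log(phi).sum()
            grad += X[ev].sum(axis=0) - M.sum(axis=0)
            hess -= (S2 - M[:, :, None] * M[:, None, :]).sum(axis=0)
    return ll, grad, hess


def cox_fit(
    X,
    surv: SurvivalTable,
    names=None,
    standardize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton iteration.

    Ties in event times are handled with the Efron approximation. Covariates
    are z-standardized internally by default (coefficients then on the
    per-SD scale); pass ``standardize=False`` for raw-scale coefficients,
    e.g. for a binary group indicator where exp(coef) is the group hazard
    ratio. Convergence requires max |score| < ``tol``; diverging steps are
    halved up to 30 times.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(surv):
        X = X.T
    n, p = X.shape
    if n != len(surv):
        raise InputError(f"covariate rows ({n}) != survival rows ({len(surv)})")
    if not np.isfinite(X).all():
        raise InputError("covariates must be finite")
    if surv.n_events == 0:
        raise UnfitError("cannot fit a Cox model with zero observed events")
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        idx = np.flatnonzero(sd == 0)
        raise InputError(f"zero-variance covariate(s) at column(s) {idx.tolist()}")
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]

    order = np.argsort(surv.time, kind="stable")
    Xs = X[order]
    ts = surv.time[order]
    es = surv.event[order]

    beta = np.zeros(p)
    ll, grad, hess = _efron_ll_grad_hess(beta, Xs, ts, es)
    ll_null = _efron_ll_grad_hess(np.zeros(p), Xs, ts, es)[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new = _efron_ll_grad_hess(new_beta, Xs, ts, es)
        halves = 0
        while (not np.isfinite(new[0]) or new[0] < ll - 1e-12) and halves < 30:
            step *= 0.5
            new_beta = beta + step
            new = _efron_ll_grad_hess(new_beta, Xs, ts, es)
            halves += 1
        if not np.isfinite(new[0]):
            break
        beta, (ll, grad, hess) = new_beta, new
    else:
        it = max_iter
    if np.abs(grad).max() < tol:
        converged = True
    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return CoxFit(
        names=names,
        coefficients=beta,
        standard_errors=se,
        log_likelihood=float(ll),
        log_likelihood_null=float(ll_null),
        n=n,
        n_events=surv.n_events,
        converged=converged,
        iterations=it,
        max_score=float(np.abs(grad).max()),
        standardized=standardize,
    )


# ---------------------------------------------------------------------------
# Stepwise signature selection
# ---------------------------------------------------------------------------


@dataclass
class Signature:
    """A compact gene signature: ordered symbols, Cox weights, selection trace."""

    genes: list[str]
    weights: np.ndarray
    selection_trace: list[tuple[int, str, str, float]]
    fit: CoxFit | None
    criterion: str = "aic"
    direction: str = "both"
    warning: str | None = None

    def to_tsv(self, path) -> None:
        pd.DataFrame({"gene": self.genes, "weight": self.weights}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_gene_list(cls, genes) -> "Signature":
        """Weight-free signature (e.g. transferred to an external cohort)."""
        genes = list(genes)
        return cls(
            genes=genes,
            weights=np.ones(len(genes)),
            selection_trace=[],
            fit=None,
        )


def _zmatrix(mat: ExpressionMatrix, genes) -> np.ndarray:
    """Samples x genes array of z-scored expression."""
    sub = mat.subset(genes).values  # genes x samples
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise UndefinedCorrelationError(f"zero-variance gene(s): {bad}")
    return ((sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]).T


def stepwise_cox(
    mat: ExpressionMatrix,
    candidates,
    surv: SurvivalTable,
    criterion: str = "pval",
    direction: str = "both",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int | None = None,
) -> Signature:
    """Stepwise Cox selection over candidate genes on the partial likelihood.

    ``criterion='aic'`` adds/drops the move that most lowers the partial-
    likelihood AIC; ``criterion='pval'`` enters the smallest Wald p below
    ``p_enter`` and removes the largest above ``p_remove``. Ties are broken
    by ascending gene symbol. ``direction`` is forward, backward, or both
    (forward steps interleaved with drop scans; the default). Selection
    starts from the empty model (full model for backward). The returned
    signature carries the full trace and a final refit.

    If no candidate improves the criterion at the first step, an empty
    signature with a warning record is returned, not an exception.
    """
    if criterion not in ("aic", "pval"):
        raise InputError(f"unknown criterion {criterion!r}")
    if direction not in ("forward", "backward", "both"):
        raise InputError(f"unknown direction {direction!r}")
    candidates = sorted(set(candidates))
    if not candidates:
        raise InputError("stepwise selection needs at least one candidate gene")
    mat.require(candidates)
    surv = surv.align(mat.samples)
    Z = _zmatrix(mat, candidates)
    col = {g: i for i, g in enumerate(candidates)}

    def fit_genes(genes) -> CoxFit:
        idx = [col[g] for g in genes]
        return cox_fit(Z[:, idx], surv, names=list(genes), standardize=False)

    # AIC of the empty model: -2 * null partial log-likelihood, 0 parameters;
    # taken from the stored null likelihood of a probe fit.
    probe = cox_fit(Z[:, [0]], surv, standardize=False)
    current_aic = -2.0 * probe.log_likelihood_null
    selected: list[str] = list(candidates) if direction == "backward" else []
    if direction == "backward":
        f = fit_genes(selected)
        current_aic = f.aic
    trace: list[tuple[int, str, str, float]] = []
    step_no = 0
    warning = None
    max_steps = max_steps if max_steps is not None else 4 * len(candidates)

    def try_add():
        nonlocal current_aic, step_no
        best = None
        remaining = [g for g in candidates if g not in selected]
        for g in remaining:  # candidates pre-sorted => symbol tie-break
            f = fit_genes(selected + [g])
            if criterion == "aic":
                val = f.aic
                ok = val < current_aic - 1e-10
            else:
                val = float(f.p_values[-1])
                ok = val < p_enter
            if ok and (best is None or val < best[1] - 1e-12):
                best = (g, val)
        if best is None:
            return False
        selected.append(best[0])
        step_no += 1
        trace.append((step_no, "add", best[0], best[1]))
        if criterion == "aic":
            current_aic = best[1]
        else:
            current_aic = fit_genes(selected).aic
        return True

    def try_drop():
        nonlocal current_aic, step_no
        if not selected:
            return False
        best = None
        if criterion == "aic":
            for g in sorted(selected):
                rest = [x for x in selected if x != g]
                val = fit_genes(rest).aic if rest else -2.0 * probe.log_likelihood_null
                if val < current_aic - 1e-10 and (best is None or val < best[1] - 1e-12):
                    best = (g, val)
        else:
            f = fit_genes(selected)
            pv = dict(zip(selected, f.p_values))
            worst = max(sorted(selected), key=lambda g: pv[g])
            if pv[worst] > p_remove:
                rest = [x for x in selected if x != worst]
                val = fit_genes(rest).aic if rest else -2.0 * probe.log_likelihood_null
                best = (worst, pv[worst] if criterion == "pval" else val)
        if best is None:
            return False
        selected.remove(best[0])
        step_no += 1
        trace.append((step_no, "drop", best[0], best[1]))
        current_aic = (
            fit_genes(selected).aic if selected else -2.0 * probe.log_likelihood_null
        )
        return True

    while step_no < max_steps:
        moved = False
        if direction in ("forward", "both"):
            moved = try_add()
            if direction == "both":
                while step_no < max_steps and try_drop():
                    moved = True
        elif direction == "backward":
            moved = try_drop()
        if not moved:
            break

    if not selected:
        warning = "no candidate improved the selection criterion; empty signature"
        return Signature(
            genes=[],
            weights=np.array([]),
            selection_trace=trace,
            fit=None,
            criterion=criterion,
            direction=direction,
            warning=warning,
        )
    final = fit_genes(selected)
    return Signature(
        genes=list(selected),
        weights=final.coefficients.copy(),
        selection_trace=trace,
        fit=final,
        criterion=criterion,
        direction=direction,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Per-sample scoring and median dichotomization
# ---------------------------------------------------------------------------


@dataclass
class ScoreVector:
    """Z-standardized per-sample signature score with low/high median split."""

    sample_ids: list[str]
    score: np.ndarray
    group: np.ndarray  # array of "low"/"high"

    @property
    def high(self) -> np.ndarray:
        return self.group == "high"

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": self.sample_ids, "score": self.score, "group": self.group}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScoreVector":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str})
        return cls(
            sample_ids=df["sample"].tolist(),
            score=df["score"].to_numpy(dtype=float),
            group=df["group"].to_numpy(dtype=object),
        )


def compute_score(
    mat: ExpressionMatrix, sig: Signature, mode: str = "zmean"
) -> ScoreVector:
    """Per-sample signature score, z-standardized and split at the median.

    ``zmean`` (default) averages per-gene z-scores with equal weight; it
    transfers unchanged to external cohorts. ``linear_predictor`` weights
    each z-scored gene by its Cox coefficient. Samples exactly at the median
    are assigned to the low group (deterministic, conservative for the
    high-score risk claim).
    """
    if mode not in ("zmean", "linear_predictor"):
        raise InputError(f"unknown score mode {mode!r}")
    if not sig.genes:
        raise InputError("cannot score an empty signature")
    Z = _zmatrix(mat, sig.genes)
    if mode == "zmean":
        raw = Z.mean(axis=1)
    else:
        raw = Z @ np.asarray(sig.weights, dtype=float)
    sd = raw.std(ddof=0)
    if sd == 0:
        raise DegenerateScoreError("all samples share one score value")
    score = (raw - raw.mean()) / sd
    med = np.median(score)
    group = np.where(score > med, "high", "low").astype(object)
    if (group == "low").all() or (group == "high").all():
        raise DegenerateScoreError("median split produced a single group")
    return ScoreVector(sample_ids=mat.samples, score=score, group=group)
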