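"""Model-style front end tying discovery and validation together.

:class:`HifSignatureModel` is built from an expression matrix and a survival
table (plus seed genes and a validated-target catalogue); ``fit()`` runs the
full discovery chain — seed expansion, Bonferroni-masked correlation matrix,
stepwise Cox compaction, per-sample scoring — and returns a
:class:`HifSignatureResults` carrying the estimates, their uncertainties and
a ``summary()`` table. Validation statistics (Kaplan–Meier, log-rank,
dichotomized hazard ratio, Welch association, fold-change table) and the KM
plot hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seedx, sigbuild, survstats
from .containers import ClinicalTable, ExpressionMatrix, SurvivalTable
from .exceptions import InputError


class HifSignatureModel:
    """Signature discovery model over one expression/survival cohort.

    Parameters
    ----------
    expression : ExpressionMatrix
    survival : SurvivalTable
        Joined to the expression samples at fit time; unmatched IDs raise.
    seeds : SeedSet, optional
        Defaults to the five canonical HIF-target seeds.
    catalogue : TargetCatalogue
        Experimentally validated HIF targets with an assumed genome fraction.
    expansion : ExpansionConfig, optional
    family_alpha : float
        Bonferroni family alpha for the core correlation matrix.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        survival: SurvivalTable,
        catalogue: seedx.TargetCatalogue,
        seeds: seedx.SeedSet | None = None,
        expansion: seedx.ExpansionConfig | None = None,
        family_alpha: float = 0.01,
    ):
        self.expression = expression
        self.survival = survival.align(expression.samples)
        self.seeds = seeds or seedx.SeedSet()
        self.catalogue = catalogue
        self.expansion_config = expansion or seedx.ExpansionConfig()
        self.family_alpha = family_alpha

    @classmethod
    def from_tsv(
        cls, expression_path, survival_path, catalogue_symbols, seeds=None, **kw
    ) -> "HifSignatureModel":
        return cls(
            ExpressionMatrix.from_tsv(expression_path),
            SurvivalTable.from_tsv(survival_path),
            seedx.TargetCatalogue(tuple(catalogue_symbols)),
            seeds=seedx.SeedSet(tuple(seeds)) if seeds else None,
            **kw,
        )

    def fit(
        self,
        criterion: str = "pval",
        direction: str = "both",
        score_mode: str = "zmean",
    ) -> "HifSignatureResults":
        """Run expansion, correlation masking, stepwise Cox, and scoring."""
        expansion = seedx.expand(
            self.expression, self.seeds, self.catalogue, self.expansion_config
        )
        if not expansion.core_genes:
            raise InputError(
                "expansion found no catalogue genes among the seed rankings; "
                "nothing to compact"
            )
        core = list(expansion.core_genes)
        correlation = (
            sigbuild.corr_matrix(self.expression, core, self.family_alpha)
            if len(core) >= 2
            else None
        )
        signature = sigbuild.stepwise_cox(
            self.expression, core, self.survival, criterion=criterion, direction=direction
        )
        scores = (
            sigbuild.compute_score(self.expression, signature, mode=score_mode)
            if signature.genes
            else None
        )
        return HifSignatureResults(
            model=self,
            expansion=expansion,
            correlation=correlation,
            signature=signature,
            scores=scores,
            score_mode=score_mode,
        )


@dataclass
class HifSignatureResults:
    """Fitted signature with expansion/correlation context and validation API."""

    model: HifSignatureModel
    expansion: seedx.ExpansionResult
    correlation: sigbuild.CorrelationMatrix | None
    signature: sigbuild.Signature
    scores: sigbuild.ScoreVector | None
    score_mode: str

    def validate(
        self,
        clinical: ClinicalTable | None = None,
        expression: ExpressionMatrix | None = None,
        survival: SurvivalTable | None = None,
    ) -> "ValidationResult":
        """Survival validation of the score, optionally on an external cohort.

        With ``expression``/``survival`` given, the signature's gene list is
        transferred and rescored (zmean) on the external matrix; otherwise
        the discovery cohort is used.
        """
        if self.scores is None:
            raise InputError("empty signature; nothing to validate")
        if expression is not None:
            if survival is None:
                raise InputError("external validation needs a survival table")
            sig = sigbuild.Signature.from_gene_list(self.signature.genes)
            scores = sigbuild.compute_score(expression, sig, mode="zmean")
            surv = survival.align(expression.samples)
            mat = expression
        else:
            scores = self.scores
            surv = self.model.survival
            mat = self.model.expression
        labels = scores.group
        km = survstats.km_estimate(surv, labels)
        lr = survstats.logrank(surv, labels)
        hr = survstats.dichotomized_hr(surv, scores)
        welch = None
        if clinical is not None:
            cl = clinical.align(scores.sample_ids)
            welch = survstats.assoc_welch(scores, cl.covariate)
        fc = survstats.foldchange_table(mat, scores, list(self.expansion.core_genes))
        return ValidationResult(
            scores=scores, km=km, logrank=lr, hr=hr, welch=welch, foldchange=fc
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        e = self.expansion
        lines = [
            "HIF-inducible signature fit",
            "===========================",
            f"Samples: {self.model.expression.n_samples}   "
            f"Genes: {self.model.expression.n_genes}   "
            f"Events: {self.model.survival.n_events}",
            f"Seeds: {', '.join(self.model.seeds.symbols)}",
            f"Expansion: {e.hits} catalogue hits among {e.n_trials} pooled genes; "
            f"binomial P = {e.binomial_p:.3g}; enriched = {e.enriched}",
        ]
        if self.correlation is not None:
            c = self.correlation
            lines.append(
                f"Core correlation: {c.n_pairs} pairs, per-pair alpha = "
                f"{c.per_pair_alpha:.3g}, significant fraction = "
                f"{c.fraction_significant:.2f}"
            )
        if self.signature.genes and self.signature.fit is not None:
            lines.append(
                f"Signature ({len(self.signature.genes)} genes, criterion="
                f"{self.signature.criterion}, direction={self.signature.direction}):"
            )
            frame = self.signature.fit.summary_frame()
            lines.append(frame.to_string(float_format=lambda v: f"{v:.4f}"))
        else:
            lines.append("Signature: EMPTY (no candidate improved the criterion)")
        return "\n".join(lines)

    def plot_km(self, validation: "ValidationResult | None" = None, ax=None):
        """Kaplan–Meier curves for the low/high score groups."""
        import matplotlib.pyplot as plt

        v = validation or self.validate()
        if ax is None:
            _, ax = plt.subplots()
        for label, curve in sorted(v.km.items()):
            t = np.concatenate([[0.0], np.repeat(curve.event_times, 2)])
            s = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]])
            ax.plot(t, s, label=f"{label} (n={curve.n})")
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


@dataclass
class ValidationResult:
    scores: sigbuild.ScoreVector
    km: dict[str, survstats.KMCurve]
    logrank: survstats.LogRankResult
    hr: sigbuild.CoxFit
    welch: tuple[float, float, float] | None
    foldchange: pd.DataFrame

    def summary(self) -> str:
        hr_ci = self.hr.ci_95[0]
        lines = [
            "Score validation",
            "================",
            "KM median survival: "
            + ", ".join(
                f"{k} = {v.median_survival:.3g}" if v.median_defined else f"{k} = n.r."
                for k, v in sorted(self.km.items())
            ),
            f"Log-rank: chi2 = {self.logrank.statistic:.3f} "
            f"(df={self.logrank.df}), P = {self.logrank.p:.3g}",
            f"HR (high vs low) = {self.hr.hazard_ratios[0]:.3f} "
            f"[{hr_ci[0]:.3f}, {hr_ci[1]:.3f}]",
        ]
        if self.welch is not None:
            t, df, p = self.welch
            lines.append(f"Welch t = {t:.3f} (df = {df:.1f}), P = {p:.3g}")
        n_up = int((self.foldchange["flag"] == "up").sum())
        n_dn = int((self.foldchange["flag"] == "down").sum())
        lines.append(
            f"Fold change (|1.5x|): {n_up} up, {n_dn} down of "
            f"{len(self.foldchange)} core genes"
        )
        return "\n".join(lines)
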