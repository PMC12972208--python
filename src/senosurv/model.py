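"""Model/Results interface tying scoring and survival together.

:class:`SignatureSurvivalModel` is built from a gene-level expression
matrix, a clinical table and a gene signature; :meth:`fit` derives the
hazard-ratio weights, computes per-sample scores, runs the IQR-restricted
minimum-p cutoff scan, and returns a :class:`SignatureSurvivalResults`
carrying estimates, intervals, diagnostics and a ``summary()`` table.
Covariate-adjusted (two-variable) models and Kaplan–Meier plotting hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .scoring import SignatureWeights, compute_score, derive_weights, univariate_gene_hrs
from .signatures import GeneSignature, match_signature
from .survival import CutoffScanResult, SurvivalFit, scan_cutoffs, two_variable_cox

__all__ = ["SignatureSurvivalModel", "SignatureSurvivalResults"]


class SignatureSurvivalModel:
    """Prognostic evaluation of one gene signature on one cohort.

    Parameters
    ----------
    expression
        Gene-level expression (:class:`ExpressionMatrix` or a genes x
        samples DataFrame of positive linear intensities).
    clinical
        DataFrame indexed by sample id with ``time`` and ``event`` columns
        (column names configurable) plus any clinical covariates.
    signature
        :class:`GeneSignature` to evaluate.
    weight_mode
        ``"log_hr"`` (w = -ln HR, default) or ``"sign_only"``.
    expression_mode
        ``"zscore"`` (default) or ``"raw"`` expression entering the score.
    """

    def __init__(
        self,
        expression,
        clinical: pd.DataFrame,
        signature: GeneSignature,
        *,
        time_col: str = "time",
        event_col: str = "event",
        weight_mode: str = "log_hr",
        expression_mode: str = "zscore",
        cutoff_window: tuple[float, float] = (0.25, 0.75),
        min_group: int = 5,
        pseudocount: float = 0.0,
    ) -> None:
        data = expression.data if isinstance(expression, ExpressionMatrix) else expression
        common = [s for s in data.columns if s in clinical.index]
        orphans_x = [s for s in data.columns if s not in clinical.index]
        orphans_c = [s for s in clinical.index if s not in set(data.columns)]
        if not common:
            raise ValueError(
                f"no shared samples between expression and clinical tables "
                f"(expression-only: {orphans_x[:3]}, clinical-only: {orphans_c[:3]})"
            )
        self.expression = data.loc[:, common]
        self.clinical = clinical.loc[common]
        self.signature = signature
        self.time = self.clinical[time_col].to_numpy(dtype=float)
        self.event = self.clinical[event_col].to_numpy(dtype=int)
        self.weight_mode = weight_mode
        self.expression_mode = expression_mode
        self.cutoff_window = cutoff_window
        self.min_group = min_group
        self.pseudocount = pseudocount
        self.matched, self.missing = match_signature(signature, self.expression.index)

    @classmethod
    def from_files(
        cls, expression_path, clinical_path, signature: GeneSignature, **kwargs
    ) -> "SignatureSurvivalModel":
        expr = ExpressionMatrix.from_tsv(expression_path)
        clin = pd.read_csv(clinical_path, sep="\t", index_col=0)
        clin.index = clin.index.astype(str)
        return cls(expr, clin, signature, **kwargs)

    def fit(self, n_permutations: int = 0, seed: int | None = None) -> "SignatureSurvivalResults":
        """Derive weights, score samples, scan cutoffs; return results."""
        sub = self.expression.loc[self.matched]
        records = univariate_gene_hrs(sub, self.time, self.event, self.pseudocount)
        weights = derive_weights(records, self.weight_mode)
        scores = compute_score(sub, weights, self.expression_mode, self.pseudocount)
        scan = scan_cutoffs(
            scores,
            self.time,
            self.event,
            window=self.cutoff_window,
            min_group=self.min_group,
            n_permutations=n_permutations,
            seed=seed,
        )
        return SignatureSurvivalResults(model=self, weights=weights, scores=scores, scan=scan)


@dataclass
class SignatureSurvivalResults:
    """Fitted signature-prognosis results.

    Key attributes: ``weights`` (per-gene HR records + weights), ``scores``
    (per-sample signature score), ``scan`` (cutoff scan with the selected
    split, its Cox HR/CI and KM curves).
    """

    model: SignatureSurvivalModel
    weights: SignatureWeights
    scores: pd.Series
    scan: CutoffScanResult
    adjusted: dict[str, SurvivalFit] = field(default_factory=dict)

    # -- headline quantities -------------------------------------------
    @property
    def hazard_ratio(self) -> float:
        """HR of the high-score group at the selected cutoff."""
        return self.scan.hazard_ratio

    @property
    def conf_int(self) -> tuple[float, float]:
        return self.scan.conf_int

    @property
    def logrank_p(self) -> float:
        return self.scan.p_selected

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def n_events(self) -> int:
        return int(self.model.event.sum())

    # -- adjusted models -----------------------------------------------
    def adjust_for(self, covariate: str, use_indicator: bool = True) -> SurvivalFit:
        """Two-variable Cox model: signature term + one clinical covariate.

        ``use_indicator`` enters the selected high/low split; otherwise
        the continuous score is used.  Complete cases for the covariate
        only, maximizing n per comparison.
        """
        term = (
            self.scan.high_group.astype(float)
            if use_indicator
            else self.scores
        )
        fit = two_variable_cox(
            term.to_numpy(),
            self.model.clinical[covariate],
            self.model.time,
            self.model.event,
            score_name="signature",
            covariate_name=covariate,
        )
        self.adjusted[covariate] = fit
        return fit

    # -- presentation ---------------------------------------------------
    def gene_table(self) -> pd.DataFrame:
        return self.weights.to_frame()

    def summary(self) -> str:
        sig = self.model.signature
        lo, hi = self.conf_int
        lines = [
            "Signature survival analysis",
            "=" * 60,
            f"signature:        {sig.name} ({len(sig)} genes, "
            f"{len(self.model.matched)} matched, {len(self.model.missing)} missing)",
            f"samples / events: {self.n} / {self.n_events}",
            f"weight mode:      {self.weights.mode}; expression: {self.model.expression_mode}",
            f"cutoff window:    quantiles {self.model.cutoff_window}, "
            f"{self.scan.n_candidates} candidates",
            f"selected cutoff:  {self.scan.cutoff:.4f} "
            f"(high n={self.scan.n_high}, low n={self.scan.n_low})",
            f"high-vs-low HR:   {self.hazard_ratio:.3f} (95% CI {lo:.3f}-{hi:.3f})",
            f"log-rank p:       {self.logrank_p:.3g} (minimum over candidates, unadjusted)",
        ]
        if self.scan.p_permutation is not None:
            lines.append(f"permutation-adjusted p: {self.scan.p_permutation:.3g}")
        for cov, fit in self.adjusted.items():
            row = fit.table.iloc[0]
            lines.append(
                f"adjusted for {cov}: signature HR {row['hr']:.3f} "
                f"(95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}, p {row['p']:.3g}, "
                f"n={fit.n})"
            )
        return "\n".join(lines)

    def km_frames(self) -> pd.DataFrame:
        """Both KM curves stacked, with a ``group`` column (high/low)."""
        hi = self.scan.km_high.assign(group="high")
        lo = self.scan.km_low.assign(group="low")
        return pd.concat([hi, lo], ignore_index=True)

    def plot_km(self, ax=None):
        """Step plot of the two survival curves (matplotlib axis returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for km, label, color in (
            (self.scan.km_high, f"high (n={self.scan.n_high})", "tab:red"),
            (self.scan.km_low, f"low (n={self.scan.n_low})", "black"),
        ):
            ax.step(km["time"], km["survival"], where="post", label=label, color=color)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        lo, hi = self.conf_int
        ax.set_title(
            f"{self.model.signature.name}: HR {self.hazard_ratio:.2f} "
            f"({lo:.2f}-{hi:.2f}), log-rank p {self.logrank_p:.2g}"
        )
        ax.legend()
        return ax
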