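"""Hazard-ratio-weighted signature scores.

Per-gene univariate Cox hazard ratios (per 1 SD of log2 expression) are
turned into signed weights — risk genes (HR > 1) get negative weights,
protective genes (HR < 1) positive weights — and the per-sample score is
the weighted average of gene expression under those weights.  A high
score therefore always points towards the protective transcriptional
state, regardless of the mix of risk and protective genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .survival import fit_cox

__all__ = [
    "univariate_gene_hrs",
    "derive_weights",
    "compute_score",
    "SignatureWeights",
    "log2_zscore",
]


def _as_frame(X) -> pd.DataFrame:
    return X.data if isinstance(X, ExpressionMatrix) else X


def log2_zscore(X, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-gene z-score of log2 intensities (genes x samples).

    With ``pseudocount=0`` (default) intensities must be strictly
    positive, which makes the z-scores — and hence scores — exactly
    invariant to any positive rescaling of the raw matrix.  Matrices
    containing zeros need an explicit pseudocount, at the cost of that
    exact invariance.
    """
    values = _as_frame(X)
    arr = values.to_numpy(dtype=float) + pseudocount
    if (arr <= 0).any():
        raise ValueError(
            "zscore mode needs strictly positive intensities; "
            "pass a pseudocount for matrices containing zeros"
        )
    logged = np.log2(arr)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=0, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (logged - mean) / sd_safe
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def univariate_gene_hrs(
    Xg,
    times,
    events,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Single-covariate Cox fit per gene on z-scored log2 expression.

    Returns a derivation-record table indexed by gene: ``hr`` (per 1 SD),
    ``ci_low``/``ci_high`` (Wald 95%), ``p``, ``zero_variance``.  Genes
    with zero expression variance cannot be fitted and are recorded with
    HR = 1 and flagged.
    """
    values = _as_frame(Xg)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) != values.shape[1]:
        raise ValueError("clinical length does not match number of samples")
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite values")
    if events.sum() < 10:
        raise ValueError(f"need >= 10 events to derive weights, got {int(events.sum())}")

    z = log2_zscore(values, pseudocount)
    records = []
    for gene in values.index:
        zg = z.loc[gene].to_numpy()
        if np.ptp(values.loc[gene].to_numpy()) == 0:
            records.append((gene, 1.0, np.nan, np.nan, np.nan, True))
            continue
        fit = fit_cox(zg, times, events)
        row = fit.table.iloc[0]
        records.append(
            (gene, float(row["hr"]), float(row["ci_low"]), float(row["ci_high"]),
             float(row["p"]), False)
        )
    out = pd.DataFrame(
        records, columns=["gene", "hr", "ci_low", "ci_high", "p", "zero_variance"]
    ).set_index("gene")
    return out


@dataclass
class SignatureWeights:
    """Per-gene signed weights plus the HR records they derive from."""

    weights: pd.Series  # gene -> w_g
    records: pd.DataFrame  # univariate_gene_hrs output
    mode: str

    def __post_init__(self) -> None:
        hr = self.records["hr"]
        w = self.weights
        mismatch = np.sign(w.to_numpy()) != -np.sign(np.log(hr.to_numpy()))
        if "zero_variance" in self.records:
            # flagged genes carry weight 0 regardless of their recorded HR
            mismatch &= ~self.records["zero_variance"].to_numpy(bool)
        if mismatch.any():
            bad = w.index[mismatch].tolist()
            raise ValueError(f"weight sign inconsistent with HR for genes: {bad[:5]}")

    def to_frame(self) -> pd.DataFrame:
        out = self.records.copy()
        out["weight"] = self.weights
        return out


def derive_weights(records: pd.DataFrame, mode: str = "log_hr") -> SignatureWeights:
    """Turn per-gene HR records into signed weights.

    ``log_hr`` (default): w_g = -ln(HR_g), so risk genes (HR > 1) weigh
    negatively and protective genes positively, proportionally to effect
    size.  ``sign_only``: w_g in {-1, 0, +1}, the pure sign rule.
    Zero-variance-flagged genes keep weight 0 so the weight vector always
    aligns with the matched gene list.
    """
    hr = records["hr"].to_numpy(dtype=float)
    if not np.isfinite(hr).all() or (hr <= 0).any():
        raise ValueError("every HR must be finite and > 0")
    log_hr = np.log(hr)
    if mode == "log_hr":
        w = -log_hr
    elif mode == "sign_only":
        w = -np.sign(log_hr)
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    if "zero_variance" in records:
        w = np.where(records["zero_variance"].to_numpy(bool), 0.0, w)
    return SignatureWeights(pd.Series(w, index=records.index, name="weight"), records, mode)


def compute_score(
    Xg,
    weights: SignatureWeights | pd.Series,
    expression_mode: str = "zscore",
    pseudocount: float = 0.0,
) -> pd.Series:
    """Weighted-average signature score per sample.

    S_i = sum_g w_g * e_ig / sum_g |w_g|, with e_ig the per-gene z-scored
    log2 expression (``zscore``, default) or the normalized intensity
    (``raw``).  Genes with w_g = 0 contribute nothing; every gene with a
    nonzero weight must be present in the matrix.
    """
    values = _as_frame(Xg)
    w = weights.weights if isinstance(weights, SignatureWeights) else pd.Series(weights)
    active = w[w != 0]
    if np.abs(w.to_numpy()).sum() == 0:
        raise ValueError("all weights are zero; score is undefined")
    missing = active.index.difference(values.index)
    if len(missing):
        raise ValueError(f"weighted genes absent from matrix: {list(missing)[:5]}")

    sub = values.loc[active.index]
    if expression_mode == "zscore":
        e = log2_zscore(sub, pseudocount)
    elif expression_mode == "raw":
        e = sub
    else:
        raise ValueError(f"unknown expression_mode {expression_mode!r}")
    num = active.to_numpy() @ e.to_numpy()
    score = num / np.abs(w.to_numpy()).sum()
    if not np.isfinite(score).all():
        raise ValueError("non-finite score encountered")
    return pd.Series(score, index=values.columns, name="score")
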