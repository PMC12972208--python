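"""Secondary normalization and QC chain for multi-cohort microarray data.

Mirrors the harmonization applied to integrated Affymetrix cohorts:

1. scale every array so its mean intensity over the shared probe universe
   hits a uniform target (default 1000);
2. restrict to the probes shared across platforms;
3. drop technical replicates (identical expression profiles), keeping the
   first occurrence;
4. exclude samples whose QC metrics fall outside the central 95% interval
   of any metric;
5. collapse probes to genes by picking one best probe per gene.

Expression stays on the linear intensity scale throughout; any log
transform happens downstream in scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "scale_normalize",
    "restrict_to_shared_probes",
    "remove_duplicate_samples",
    "filter_samples_by_qc",
    "collapse_probes_to_genes",
    "read_probe_gene_map",
    "harmonize_pipeline",
    "HarmonizationLog",
]

QC_METRIC_COLUMNS = (
    "background",
    "noise",
    "present_rate",
    "ratio_gapdh_3p5p",
    "ratio_actb_3p5p",
)


def scale_normalize(X: ExpressionMatrix, target: float = 1000.0) -> ExpressionMatrix:
    """Scale each sample so its mean intensity equals ``target``.

    Idempotent; preserves feature and sample order.  A sample with zero
    mean intensity cannot be scaled and raises, naming the sample.
    """
    if target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    means = X.data.mean(axis=0)
    zero = means[means <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with nonpositive mean intensity: {list(zero.index)[:5]}")
    scaled = X.data * (target / means)
    return ExpressionMatrix(scaled, X.batch_of)


def restrict_to_shared_probes(X: ExpressionMatrix, shared) -> ExpressionMatrix:
    """Keep only features present in ``shared``, preserving X's order."""
    shared = set(shared)
    if not shared:
        raise ValueError("shared probe list is empty")
    keep = [f for f in X.feature_ids if f in shared]
    if not keep:
        raise ValueError("no overlap between matrix features and shared probe list")
    return X.subset_features(keep)


def remove_duplicate_samples(
    X: ExpressionMatrix, decimals: int = 4
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples whose expression profile duplicates an earlier sample.

    Profiles are compared exactly after rounding to ``decimals`` decimals,
    so float round-off from upstream scaling cannot defeat the rule.  The
    first occurrence is kept; column order is otherwise preserved.
    """
    rounded = np.round(X.data.to_numpy(), decimals)
    seen: dict[bytes, str] = {}
    keep: list[str] = []
    removed: list[str] = []
    for j, sid in enumerate(X.sample_ids):
        key = rounded[:, j].tobytes()
        if key in seen:
            removed.append(sid)
        else:
            seen[key] = sid
            keep.append(sid)
    return X.subset_samples(keep), removed


def filter_samples_by_qc(
    metrics: pd.DataFrame,
    keep_interval: float = 0.95,
    method: str = "percentile",
) -> list[str]:
    """Return sample ids passing the central-interval rule on every metric.

    A sample is kept iff, for every metric column, its value lies within
    the central ``keep_interval`` interval of that metric computed across
    all input samples.  ``method='percentile'`` (default) uses the
    [(1-q)/2, 1-(1-q)/2] percentile interval; ``method='normal'`` uses the
    parametric mean +/- z*SD alternative.  Intervals are computed once on
    the full input and applied once (no iteration).
    """
    if not 0 < keep_interval < 1:
        raise ValueError("keep_interval must be in (0, 1)")
    if len(metrics) < 20:
        raise ValueError(f"QC filtering needs >= 20 samples, got {len(metrics)}")
    values = metrics.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite value in QC metric {metrics.columns[j]!r} "
            f"for sample {metrics.index[i]!r}"
        )
    tail = (1.0 - keep_interval) / 2.0
    if method == "percentile":
        lo = np.percentile(values, 100 * tail, axis=0)
        hi = np.percentile(values, 100 * (1 - tail), axis=0)
    elif method == "normal":
        from scipy.stats import norm

        z = norm.ppf(1 - tail)
        mean, sd = values.mean(axis=0), values.std(axis=0, ddof=1)
        lo, hi = mean - z * sd, mean + z * sd
    else:
        raise ValueError(f"unknown method {method!r}")
    ok = ((values >= lo) & (values <= hi)).all(axis=1)
    return [sid for sid, keep in zip(metrics.index, ok) if keep]


def read_probe_gene_map(path) -> dict[str, str]:
    """Read a 2-column TSV (probe_id, gene_symbol); probes must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe-gene map needs two columns (probe_id, gene_symbol)")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        raise ValueError(f"duplicate probe ids in map: {probes[probes.duplicated()].tolist()[:5]}")
    return dict(zip(probes, genes))


def collapse_probes_to_genes(
    X: ExpressionMatrix, probe_gene_map: dict[str, str]
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse a probe-level matrix to one row per gene.

    For each gene the probe with the largest interquartile range across
    samples is chosen (a deterministic stand-in for annotation-based best
    probe selection); ties break to the lexicographically smallest probe
    id.  Unmapped probes are dropped.  Returns the gene-level matrix and a
    selection report (gene, chosen_probe, n_candidates).
    """
    mapped = [p for p in X.feature_ids if p in probe_gene_map]
    if not mapped:
        raise ValueError("no probe of the matrix appears in the probe-gene map")
    values = X.data.loc[mapped]
    q75, q25 = np.percentile(values.to_numpy(), [75, 25], axis=1)
    iqr = pd.Series(q75 - q25, index=mapped)

    by_gene: dict[str, list[str]] = {}
    for p in mapped:
        by_gene.setdefault(probe_gene_map[p], []).append(p)

    chosen: list[tuple[str, str, int]] = []
    for gene, probes in by_gene.items():
        best = min(probes, key=lambda p: (-iqr[p], p))
        chosen.append((gene, best, len(probes)))
    report = pd.DataFrame(chosen, columns=["gene", "chosen_probe", "n_candidates"])

    out = X.data.loc[report["chosen_probe"]].copy()
    out.index = pd.Index(report["gene"], name=None)
    return ExpressionMatrix(out, X.batch_of), report


@dataclass
class HarmonizationLog:
    """Per-stage bookkeeping of the harmonization chain."""

    stages: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def harmonize_pipeline(
    X: ExpressionMatrix,
    shared_probes=None,
    qc_metrics: pd.DataFrame | None = None,
    probe_gene_map: dict[str, str] | None = None,
    target: float = 1000.0,
    keep_interval: float = 0.95,
    qc_method: str = "percentile",
) -> tuple[ExpressionMatrix, HarmonizationLog]:
    """Run normalize -> restrict -> dedupe -> QC -> collapse in order.

    The restrict, QC and collapse stages run only when their inputs are
    supplied.  The log records samples/features in and out of every stage.
    """
    stages: list[dict] = []

    def log(stage: str, before: ExpressionMatrix, after: ExpressionMatrix, **extra):
        stages.append(
            {
                "stage": stage,
                "samples_in": before.n_samples,
                "samples_out": after.n_samples,
                "features_in": before.n_features,
                "features_out": after.n_features,
                **extra,
            }
        )

    cur = scale_normalize(X, target)
    log("scale_normalize", X, cur, target=target)

    if shared_probes is not None:
        nxt = restrict_to_shared_probes(cur, shared_probes)
        log("restrict_to_shared_probes", cur, nxt)
        cur = nxt

    nxt, removed = remove_duplicate_samples(cur)
    log("remove_duplicate_samples", cur, nxt, removed=",".join(removed))
    cur = nxt

    if qc_metrics is not None:
        metrics = qc_metrics.loc[cur.sample_ids]
        kept = filter_samples_by_qc(metrics, keep_interval, qc_method)
        nxt = cur.subset_samples(kept)
        log("filter_samples_by_qc", cur, nxt)
        cur = nxt

    if probe_gene_map is not None:
        nxt, report = collapse_probes_to_genes(cur, probe_gene_map)
        log("collapse_probes_to_genes", cur, nxt)
        cur = nxt

    return cur, HarmonizationLog(stages)
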