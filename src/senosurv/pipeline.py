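"""Orchestration: dataset registry, cohort summaries, end-to-end analysis.

``run_analysis`` drives harmonize -> match -> weight -> score -> cutoff
scan -> BH correction -> two-variable adjusted models over endpoints and
histology strata, writing a machine-readable report bundle with a manifest
that logs every filtering step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .harmonize import harmonize_pipeline, read_probe_gene_map
from .matrix import ExpressionMatrix
from .model import SignatureSurvivalModel
from .signatures import GeneSignature, load_signature, read_gmt
from .survival import bh_adjust

__all__ = [
    "load_registry",
    "total_samples",
    "bundled_registry",
    "bundled_cohort_counts",
    "expand_counts",
    "summarize_cohort",
    "CohortSummary",
    "AnalysisConfig",
    "run_analysis",
]

logger = logging.getLogger("senosurv")

SUMMARY_COVARIATES = ("histology", "stage_T", "stage_N", "stage_M", "sex", "smoking")


# ----------------------------------------------------------------------
# Dataset registry
# ----------------------------------------------------------------------
def load_registry(path) -> pd.DataFrame:
    """Read a dataset registry TSV (accession, platform, n)."""
    reg = pd.read_csv(path, sep="\t", dtype={"accession": str, "platform": str})
    for col in ("accession", "platform", "n"):
        if col not in reg.columns:
            raise ValueError(f"registry is missing column {col!r}")
    if reg["accession"].duplicated().any():
        dups = reg.loc[reg["accession"].duplicated(), "accession"].tolist()
        raise ValueError(f"duplicate accessions in registry: {dups}")
    n_float = pd.to_numeric(reg["n"], errors="raise")
    if not (n_float == n_float.astype(int)).all():
        raise ValueError("registry sample sizes must be integers")
    if (n_float <= 0).any():
        raise ValueError("registry sample sizes must be positive")
    reg["n"] = n_float.astype(int)
    return reg


def total_samples(registry: pd.DataFrame) -> int:
    """Total sample count across all registered datasets."""
    return int(registry["n"].sum()) if len(registry) else 0


def bundled_registry() -> pd.DataFrame:
    """The 17-dataset lung cancer registry shipped with the package."""
    with resources.files("senosurv.data").joinpath("registry_lung17.tsv").open() as fh:
        return load_registry(fh)


def bundled_cohort_counts() -> pd.DataFrame:
    """Published per-category patient counts of the OS and FP cohorts."""
    with resources.files("senosurv.data").joinpath("cohort_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def expand_counts(counts: pd.DataFrame, cohort: str) -> pd.DataFrame:
    """Expand a count table into a per-patient clinical frame.

    Categories not annotated for a patient are filled with ``missing`` so
    that full-cohort and annotated-only denominators can both be formed.
    """
    sub = counts[counts["cohort"] == cohort]
    if not len(sub):
        raise ValueError(f"cohort {cohort!r} not present in count table")
    total = int(sub.loc[sub["covariate"] == "total", "count"].iloc[0])
    clin = pd.DataFrame(index=pd.RangeIndex(total))
    for cov in sub["covariate"].unique():
        if cov == "total":
            continue
        col = pd.Series(["missing"] * total, index=clin.index, dtype=object)
        pos = 0
        for _, row in sub[sub["covariate"] == cov].iterrows():
            c = int(row["count"])
            col.iloc[pos : pos + c] = str(row["category"])
            pos += c
        if pos > total:
            raise ValueError(f"counts for {cov!r} exceed the cohort total {total}")
        clin[cov] = col
    return clin


# ----------------------------------------------------------------------
# Cohort summarization
# ----------------------------------------------------------------------
def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Counts and percentages per clinical category."""

    total_n: int
    denominator: str  # 'full' or 'annotated'
    tables: dict[str, pd.DataFrame]  # covariate -> (category, count, percent)

    def to_frame(self) -> pd.DataFrame:
        frames = [
            tab.assign(covariate=cov)[["covariate", "category", "count", "percent"]]
            for cov, tab in self.tables.items()
        ]
        return pd.concat(frames, ignore_index=True)


def summarize_cohort(
    clinical: pd.DataFrame,
    denominator: str = "full",
    covariates=None,
) -> CohortSummary:
    """Count patients per category with percentages.

    ``denominator='full'`` divides by the whole cohort (the main-text
    convention); ``'annotated'`` divides by patients with a non-missing
    value for that covariate.  Percentages are rounded half-up to one
    decimal.  Missing values are counted as their own category but never
    reported as a percentage row.
    """
    if not len(clinical):
        raise ValueError("clinical table is empty")
    if denominator not in ("full", "annotated"):
        raise ValueError("denominator must be 'full' or 'annotated'")
    if covariates is None:
        covariates = [c for c in SUMMARY_COVARIATES if c in clinical.columns]
    total = len(clinical)
    tables: dict[str, pd.DataFrame] = {}
    for cov in covariates:
        col = clinical[cov].astype(str)
        is_missing = col.isin(("missing", "nan", "None", ""))
        counts = col[~is_missing].value_counts()
        denom = total if denominator == "full" else int((~is_missing).sum())
        rows = [
            {
                "category": cat,
                "count": int(cnt),
                "percent": round_half_up(100.0 * cnt / denom, 1) if denom else 0.0,
            }
            for cat, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        tables[cov] = pd.DataFrame(rows, columns=["category", "count", "percent"])
    return CohortSummary(total_n=total, denominator=denominator, tables=tables)


# ----------------------------------------------------------------------
# End-to-end analysis
# ----------------------------------------------------------------------
@dataclass
class AnalysisConfig:
    """Configuration of one end-to-end run (loadable from YAML)."""

    expression: str
    clinical: str
    signatures: list[str]
    out_dir: str
    probe_gene_map: str | None = None
    shared_probes: str | None = None
    qc_metrics: str | None = None
    registry: str | None = None
    endpoints: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {"OS": ("time", "event")}
    )
    strata: list[str] = field(default_factory=lambda: ["all"])
    stratum_column: str = "histology"
    weight_mode: str = "log_hr"
    expression_mode: str = "zscore"
    cutoff_window: tuple[float, float] = (0.25, 0.75)
    min_group: int = 5
    fdr: float = 0.10
    adjust_covariates: list[str] = field(default_factory=list)
    n_permutations: int = 0
    scale_target: float = 1000.0
    min_stratum_n: int = 30  # below this a stratum is flagged underpowered
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        lo, hi = self.cutoff_window
        if not (0 < lo < hi < 1):
            raise ValueError("cutoff_window must satisfy 0 < low < high < 1")
        self.endpoints = {k: tuple(v) for k, v in self.endpoints.items()}

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)


def _float_fmt(x: float) -> float:
    return float(f"{x:.10g}")


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Outputs under ``config.out_dir``: ``results.tsv`` (one row per
    signature x endpoint x stratum with cutoff, HR, CI, log-rank p and BH
    q), per-test KM curves as CSV, ``weights_*.tsv``, ``scores_*.tsv``,
    ``adjusted_models.tsv``, and ``manifest.json`` recording per-stage
    sample counts.  Deterministic given the config (and seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"config": {k: str(v) for k, v in vars(config).items()}, "stages": []}
    try:
        expr = ExpressionMatrix.from_tsv(config.expression)
        clinical = pd.read_csv(config.clinical, sep="\t", index_col=0)
        clinical.index = clinical.index.astype(str)
        logger.info("loaded expression %dx%d, clinical %d", expr.n_features,
                    expr.n_samples, len(clinical))

        shared = None
        if config.shared_probes:
            shared = [
                line.strip()
                for line in Path(config.shared_probes).read_text().splitlines()
                if line.strip()
            ]
        qc = None
        if config.qc_metrics:
            qc = pd.read_csv(config.qc_metrics, sep="\t", index_col=0)
            qc.index = qc.index.astype(str)
        pg_map = read_probe_gene_map(config.probe_gene_map) if config.probe_gene_map else None

        harmonized, hlog = harmonize_pipeline(
            expr, shared, qc, pg_map, target=config.scale_target
        )
        manifest["stages"] = hlog.stages
        for s in hlog.stages:
            logger.info(
                "%s: samples %d -> %d, features %d -> %d",
                s["stage"], s["samples_in"], s["samples_out"],
                s["features_in"], s["features_out"],
            )

        orphans = [s for s in harmonized.sample_ids if s not in clinical.index]
        if orphans:
            raise ValueError(f"samples without clinical rows: {orphans[:5]}")
        clinical = clinical.loc[harmonized.sample_ids]

        signatures: list[GeneSignature] = []
        for sp in config.signatures:
            p = Path(sp)
            if p.suffix.lower() == ".gmt":
                signatures.extend(read_gmt(p))
            else:
                signatures.append(load_signature(p))

        results_rows = []
        adjusted_rows = []
        files: list[str] = []
        for sig in signatures:
            for ep_name, (tcol, ecol) in config.endpoints.items():
                for stratum in config.strata:
                    if stratum == "all":
                        clin_s = clinical
                    else:
                        clin_s = clinical[
                            clinical[config.stratum_column].astype(str) == stratum
                        ]
                    if len(clin_s) < 2 * config.min_group:
                        logger.warning(
                            "skipping %s/%s/%s: only %d samples",
                            sig.name, ep_name, stratum, len(clin_s),
                        )
                        continue
                    expr_s = harmonized.subset_samples(clin_s.index)
                    model = SignatureSurvivalModel(
                        expr_s,
                        clin_s,
                        sig,
                        time_col=tcol,
                        event_col=ecol,
                        weight_mode=config.weight_mode,
                        expression_mode=config.expression_mode,
                        cutoff_window=config.cutoff_window,
                        min_group=config.min_group,
                    )
                    res = model.fit(
                        n_permutations=config.n_permutations, seed=config.seed
                    )
                    tag = f"{sig.name}_{ep_name}_{stratum}".replace("/", "-")
                    lo, hi = res.conf_int
                    results_rows.append(
                        {
                            "signature": sig.name,
                            "endpoint": ep_name,
                            "stratum": stratum,
                            "n": res.n,
                            "events": res.n_events,
                            "genes_matched": len(model.matched),
                            "genes_missing": len(model.missing),
                            "cutoff": _float_fmt(res.scan.cutoff),
                            "n_high": res.scan.n_high,
                            "n_low": res.scan.n_low,
                            "hr": _float_fmt(res.hazard_ratio),
                            "ci_low": _float_fmt(lo),
                            "ci_high": _float_fmt(hi),
                            "logrank_p": _float_fmt(res.logrank_p),
                            "n_candidates": res.scan.n_candidates,
                            "p_permutation": (
                                _float_fmt(res.scan.p_permutation)
                                if res.scan.p_permutation is not None
                                else ""
                            ),
                            "underpowered": len(clin_s) < config.min_stratum_n,
                        }
                    )
                    km = res.km_frames()
                    km_file = f"km_{tag}.csv"
                    km.to_csv(out / km_file, index=False, float_format="%.10g")
                    files.append(km_file)
                    w_file = f"weights_{tag}.tsv"
                    res.gene_table().to_csv(out / w_file, sep="\t", float_format="%.10g")
                    files.append(w_file)
                    s_file = f"scores_{tag}.tsv"
                    res.scores.rename("score").to_frame().to_csv(
                        out / s_file, sep="\t", float_format="%.10g"
                    )
                    files.append(s_file)

                    if stratum == "all":
                        for cov in config.adjust_covariates:
                            if cov not in clin_s.columns:
                                continue
                            fit = res.adjust_for(cov)
                            row = fit.table.iloc[0]
                            adjusted_rows.append(
                                {
                                    "signature": sig.name,
                                    "endpoint": ep_name,
                                    "covariate": cov,
                                    "n": fit.n,
                                    "events": fit.n_events,
                                    "hr": _float_fmt(row["hr"]),
                                    "ci_low": _float_fmt(row["ci_low"]),
                                    "ci_high": _float_fmt(row["ci_high"]),
                                    "p": _float_fmt(row["p"]),
                                }
                            )

        results = pd.DataFrame(results_rows)
        if len(results):
            bh = bh_adjust(results["logrank_p"].to_numpy(), config.fdr)
            results["q"] = [_float_fmt(q) for q in bh.qvalues]
            results["significant"] = bh.significant
        results.to_csv(out / "results.tsv", sep="\t", index=False)
        files.append("results.tsv")
        if adjusted_rows:
            pd.DataFrame(adjusted_rows).to_csv(
                out / "adjusted_models.tsv", sep="\t", index=False
            )
            files.append("adjusted_models.tsv")

        if config.registry:
            reg = load_registry(config.registry)
            manifest["registry_total_samples"] = total_samples(reg)
            manifest["registry_datasets"] = len(reg)

        manifest["files"] = sorted(files)
        manifest["n_tests"] = len(results_rows)
        manifest["fdr"] = config.fdr
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
        logger.info("wrote %d result files", len(files) + 1)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest
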