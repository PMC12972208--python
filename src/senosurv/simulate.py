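"""Synthetic multi-batch expression + survival cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-gene log-normal intensities on a MAS5-like scale, a subset of
"signature" genes whose latent z-scores drive an exponential
proportional-hazards event process, independent exponential censoring with
an administrative horizon, per-batch multiplicative intensity shifts,
categorical clinical covariates with their own log-hazards, and injected
exact-duplicate samples and QC-outlier samples for the harmonization chain
to find.

Everything is deterministic given ``SimConfig.seed``; expression, survival,
batch, covariate and injection randomness come from separate named
substreams so perturbing one component leaves the others reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "CovariateSpec",
    "SimConfig",
    "SimTruth",
    "SimulatedCohort",
    "generate_cohort",
    "default_covariate_spec",
]

_SUBSTREAMS = ("expression", "survival", "batch", "covariates", "injection")


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical clinical covariate.

    ``frequencies`` must sum to 1; ``log_hazards`` gives the additive
    contribution of each category to the log hazard (reference coding is
    up to the caller — a zero entry is a reference category).
    """

    categories: tuple[str, ...]
    frequencies: tuple[float, ...]
    log_hazards: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.categories)
        if len(self.frequencies) != k or len(self.log_hazards) != k:
            raise ValueError("categories, frequencies and log_hazards must have equal length")
        if any(f < 0 for f in self.frequencies):
            raise ValueError("frequencies must be nonnegative")
        if abs(sum(self.frequencies) - 1.0) > 1e-8:
            raise ValueError(f"frequencies must sum to 1, got {sum(self.frequencies)}")


def default_covariate_spec() -> dict[str, CovariateSpec]:
    """Covariate mix loosely matching a large mixed NSCLC cohort.

    Category frequencies follow the published composition of integrated
    lung-cancer microarray cohorts (roughly half adenocarcinoma, male
    predominance, a minority of never-smokers, substantial missingness in
    smoking annotation); all log-hazards default to 0 so the covariates
    are pure nuisance unless a test plants an effect.
    """
    return {
        "histology": CovariateSpec(
            ("LUAD", "LUSC", "large-cell", "LCNEC", "missing"),
            (0.48, 0.37, 0.04, 0.04, 0.07),
            (0.0, 0.0, 0.0, 0.0, 0.0),
        ),
        "sex": CovariateSpec(("male", "female"), (0.58, 0.42), (0.0, 0.0)),
        "smoking": CovariateSpec(
            ("smoker", "never", "missing"), (0.24, 0.10, 0.66), (0.0, 0.0, 0.0)
        ),
    }


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the reference study conditions used throughout the
    test-suite: 800 tumours in 4 batches, 500 genes of which 40 form the
    signature (half protective, half risk, |log-hazard| 0.5 per latent SD),
    an exponential baseline of 0.02 events/month, exponential censoring at
    0.005/month with a 240-month administrative horizon (≈30% censoring),
    and moderate batch intensity shifts.
    """

    n_samples: int = 800
    n_genes: int = 500
    n_signature_genes: int = 40
    beta: tuple[float, ...] | None = None  # per-signature-gene log-hazard per latent SD
    baseline_rate: float = 0.02  # events per month
    censor_rate: float = 0.005  # exponential censoring, events per month
    admin_time: float = 240.0  # administrative horizon, months
    n_batches: int = 4
    batch_log_shift_sd: float = 0.3  # SD of per-batch shift on natural-log scale
    n_duplicates: int = 0
    n_qc_outliers: int = 0
    covariate_spec: dict[str, CovariateSpec] = field(default_factory=default_covariate_spec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_signature_genes", "n_batches",
                     "n_duplicates", "n_qc_outliers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples < 1 or self.n_genes < 1 or self.n_batches < 1:
            raise ValueError("n_samples, n_genes and n_batches must be >= 1")
        if self.n_signature_genes > self.n_genes:
            raise ValueError(
                f"n_signature_genes ({self.n_signature_genes}) exceeds n_genes ({self.n_genes})"
            )
        if self.baseline_rate <= 0:
            raise ValueError(f"baseline_rate must be positive, got {self.baseline_rate}")
        if self.censor_rate <= 0:
            raise ValueError(f"censor_rate must be positive, got {self.censor_rate}")
        if self.admin_time <= 0:
            raise ValueError(f"admin_time must be positive, got {self.admin_time}")
        if self.batch_log_shift_sd < 0:
            raise ValueError("batch_log_shift_sd must be >= 0")
        if self.beta is None:
            # default: alternating protective/risk effects of magnitude 0.5
            self.beta = tuple(
                0.5 if i % 2 else -0.5 for i in range(self.n_signature_genes)
            )
        self.beta = tuple(float(b) for b in self.beta)
        if len(self.beta) != self.n_signature_genes:
            raise ValueError(
                f"beta has length {len(self.beta)}, expected n_signature_genes="
                f"{self.n_signature_genes}"
            )


@dataclass
class SimTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    signature_gene_ids: list[str]
    beta_per_gene: dict[str, float]
    covariate_log_hazards: dict[str, dict[str, float]]
    batch_factors: dict[str, float]
    duplicate_pairs: list[tuple[str, str]]  # (original, copy)
    qc_outlier_ids: list[str]
    baseline_rate: float
    censor_rate: float
    admin_time: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signature_gene_ids": self.signature_gene_ids,
            "beta_per_gene": self.beta_per_gene,
            "covariate_log_hazards": self.covariate_log_hazards,
            "batch_factors": self.batch_factors,
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "qc_outlier_ids": self.qc_outlier_ids,
            "baseline_rate": self.baseline_rate,
            "censor_rate": self.censor_rate,
            "admin_time": self.admin_time,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["duplicate_pairs"] = [tuple(p) for p in d["duplicate_pairs"]]
        return cls(**d)


@dataclass
class SimulatedCohort:
    """Bundle emitted by :func:`generate_cohort`."""

    expression: ExpressionMatrix
    clinical: pd.DataFrame  # indexed by sample id: time, event, covariates, batch
    qc: pd.DataFrame  # indexed by sample id: background, noise, present_rate, ratios
    truth: SimTruth

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write the four components as TSV/JSON; returns file name map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "expression": "expression.tsv",
            "clinical": "clinical.tsv",
            "qc": "qc.tsv",
            "truth": "truth.json",
        }
        self.expression.to_tsv(out / files["expression"])
        clin = self.clinical.copy()
        clin.index.name = "sample_id"
        clin.to_csv(out / files["clinical"], sep="\t", float_format="%.6f")
        qc = self.qc.copy()
        qc.index.name = "sample_id"
        qc.to_csv(out / files["qc"], sep="\t", float_format="%.6f")
        self.truth.to_json(out / files["truth"])
        return files


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one cohort under ``config``.

    The hazard of sample *i* is ``λ0 · exp(Σ_g β_g z_ig + Σ_c γ_c)`` where
    ``z_ig`` is the latent (pre-batch-shift) per-gene z-score of the log2
    expression of signature gene *g*.  Event times are exponential with that
    rate; the observed time is ``min(event, exp-censor, admin_time)``.
    Duplicates and QC outliers are appended after the base samples and
    flagged in the returned :class:`SimTruth`.
    """
    rng = _rngs(config.seed)
    n, g = config.n_samples, config.n_genes
    k = config.n_signature_genes

    gene_ids = [f"G{i:05d}" for i in range(g)]
    sample_ids = [f"S{i:05d}" for i in range(n)]
    sig_ids = gene_ids[:k]

    # --- expression: per-gene log-normal baseline on log2 scale ----------
    r = rng["expression"]
    mu = r.uniform(6.0, 10.0, size=g)  # per-gene mean, log2 scale
    log2_x = mu[:, None] + r.standard_normal((g, n))  # per-gene SD 1
    z = log2_x[:k, :] - mu[:k, None]  # latent z-scores of signature genes

    # --- covariates ------------------------------------------------------
    r = rng["covariates"]
    cov_cols: dict[str, np.ndarray] = {}
    cov_lp = np.zeros(n)
    for name, spec in config.covariate_spec.items():
        idx = r.choice(len(spec.categories), size=n, p=spec.frequencies)
        cov_cols[name] = np.asarray(spec.categories, dtype=object)[idx]
        cov_lp += np.asarray(spec.log_hazards)[idx]

    # --- survival --------------------------------------------------------
    r = rng["survival"]
    beta = np.asarray(config.beta)
    lp = beta @ z if k else np.zeros(n)
    hazard = config.baseline_rate * np.exp(lp + cov_lp)
    event_time = r.exponential(1.0 / hazard)
    censor_time = np.minimum(r.exponential(1.0 / config.censor_rate, size=n),
                             config.admin_time)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    # --- batches ---------------------------------------------------------
    r = rng["batch"]
    batch_labels = [f"B{j}" for j in range(config.n_batches)]
    factors = np.exp(r.normal(0.0, config.batch_log_shift_sd, size=config.n_batches))
    batch_idx = np.arange(n) % config.n_batches
    intensity = np.power(2.0, log2_x) * factors[batch_idx][None, :]

    # --- QC metrics ------------------------------------------------------
    r = rng["injection"]
    qc = pd.DataFrame(
        {
            "background": r.normal(100.0, 10.0, size=n),
            "noise": r.normal(4.0, 0.5, size=n),
            "present_rate": np.clip(r.beta(40.0, 40.0, size=n), 0.0, 1.0),
            "ratio_gapdh_3p5p": np.exp(r.normal(0.0, 0.15, size=n)),
            "ratio_actb_3p5p": np.exp(r.normal(0.0, 0.15, size=n)),
        },
        index=sample_ids,
    )

    clinical = pd.DataFrame(
        {"time": time, "event": event, **cov_cols,
         "batch": np.asarray(batch_labels, dtype=object)[batch_idx]},
        index=sample_ids,
    )
    expr = pd.DataFrame(intensity, index=gene_ids, columns=sample_ids)

    # --- injected duplicates --------------------------------------------
    duplicate_pairs: list[tuple[str, str]] = []
    if config.n_duplicates:
        if config.n_duplicates > n:
            raise ValueError("n_duplicates exceeds n_samples")
        originals = r.choice(n, size=config.n_duplicates, replace=False)
        for j, oi in enumerate(sorted(originals)):
            orig = sample_ids[oi]
            copy = f"D{j:03d}_{orig}"
            expr[copy] = expr[orig].to_numpy()  # exact value copy
            clinical.loc[copy] = clinical.loc[orig]
            qc.loc[copy] = qc.loc[orig]
            duplicate_pairs.append((orig, copy))

    # --- injected QC outliers -------------------------------------------
    qc_outlier_ids: list[str] = []
    if config.n_qc_outliers:
        base_mu = mu[:, None]
        for j in range(config.n_qc_outliers):
            sid = f"Q{j:03d}"
            x = (base_mu + r.standard_normal((g, 1))).ravel()
            expr[sid] = np.power(2.0, x)
            t = min(float(r.exponential(1.0 / config.baseline_rate)), config.admin_time)
            clinical.loc[sid] = {
                "time": t, "event": 1,
                **{name: spec.categories[0] for name, spec in config.covariate_spec.items()},
                "batch": batch_labels[0],
            }
            # metrics far outside the range of every regular sample
            qc.loc[sid] = {
                "background": float(qc["background"].iloc[:n].max()) * 3.0,
                "noise": float(qc["noise"].iloc[:n].max()) * 4.0,
                "present_rate": 0.01,
                "ratio_gapdh_3p5p": 10.0,
                "ratio_actb_3p5p": 10.0,
            }
            qc_outlier_ids.append(sid)

    clinical["event"] = clinical["event"].astype(int)
    batch_of = clinical["batch"].copy()

    truth = SimTruth(
        signature_gene_ids=sig_ids,
        beta_per_gene={gid: float(b) for gid, b in zip(sig_ids, beta)},
        covariate_log_hazards={
            name: dict(zip(spec.categories, map(float, spec.log_hazards)))
            for name, spec in config.covariate_spec.items()
        },
        batch_factors=dict(zip(batch_labels, map(float, factors))),
        duplicate_pairs=duplicate_pairs,
        qc_outlier_ids=qc_outlier_ids,
        baseline_rate=config.baseline_rate,
        censor_rate=config.censor_rate,
        admin_time=config.admin_time,
    )
    return SimulatedCohort(ExpressionMatrix(expr, batch_of), clinical, qc, truth)
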