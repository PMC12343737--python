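"""Fully synthetic metastasis-like cohorts with known ground truth.

Every pipeline stage gets a recovery oracle from here: planted 96-channel
signatures mixed through Dirichlet exposures, negative-binomial mutation
loads, exponential survival whose hazard depends on planted gene / CNV /
signature status, gene pairs with planted co-occurrence odds ratios, and an
ICI arm with a planted response logit. Same config + seed => byte-identical
output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog96 import CHANNELS
from .errors import ParameterError
from .io_cohort import ClinicalRecord, CnvRecord, IciRecord, MutationRecord, write_maf

#: Driver-like gene names used for planted effects in fixtures.
DRIVER_GENES = (
    "TP53",
    "KRAS",
    "EGFR",
    "PTPRT",
    "PTPRD",
    "APC",
    "PTEN",
    "DUSP4",
    "RB1",
    "ARID1A",
    "FAT1",
    "ATM",
    "NOTCH3",
    "SPEN",
    "TET2",
    "PIK3CG",
)


def default_signatures(k: int = 4, seed: int = 7) -> np.ndarray:
    """Deterministic, well-separated k x 96 row-stochastic planted signatures.

    Each signature concentrates ~95% of its mass on its own block of channels
    (sparse Dirichlet within the block) plus a uniform floor, so distinct
    signatures have near-zero cosine overlap.
    """
    if not (1 <= k <= 8):
        raise ParameterError("default signatures support k in [1, 8]")
    rng = np.random.default_rng(seed)
    n_ch = len(CHANNELS)
    W = np.full((k, n_ch), 0.05 / n_ch)
    block = n_ch // k
    for s in range(k):
        lo = s * block
        hi = n_ch if s == k - 1 else (s + 1) * block
        mass = rng.dirichlet(np.full(hi - lo, 0.5))
        W[s, lo:hi] += 0.95 * mass
    return W / W.sum(axis=1, keepdims=True)


@dataclass
class SimConfig:
    n_samples: int = 300
    planted_signatures: Optional[np.ndarray] = None  # k x 96; default_signatures(4)
    exposure_alpha: Optional[Sequence[float]] = None  # Dirichlet conc.; default 0.25 per sig
    load_mean: float = 300.0
    load_dispersion: float = 5.0
    # survival model
    base_rate: float = np.log(2) / 21.0  # exponential baseline, median ~21 months
    censor_window: float = 120.0
    gene_hazard: dict = field(default_factory=lambda: {"PTPRT": 0.5, "RB1": 2.0})
    cnv_hazard: dict = field(default_factory=lambda: {"PTEN": 1.7, "DUSP4": 0.31})
    signature_hazard: dict = field(default_factory=dict)  # sig index (0-based) -> HR
    tumor_type_hazard: dict = field(default_factory=dict)  # level -> HR
    # gene / CNV models
    gene_background: dict = field(
        default_factory=lambda: {g: 0.15 for g in DRIVER_GENES} | {"TP53": 0.5}
    )
    planted_pairs: list = field(default_factory=list)  # (gene_a, gene_b, odds_ratio)
    cnv_deletion_prob: dict = field(default_factory=lambda: {"PTEN": 0.10, "DUSP4": 0.06})
    n_passenger_genes: int = 120
    panel_mb: float = 1.14
    # ICI arm
    ici_n: int = 0
    ici_gene: str = "PTPRT"
    ici_mut_prob: float = 0.2
    ici_response_logit: float = -1.0  # baseline log-odds of CR/PR
    ici_mut_logit: float = 1.2  # additive log-odds for mutants
    ici_mut_hr: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ParameterError("n_samples must be >= 10")
        if self.planted_signatures is None:
            self.planted_signatures = default_signatures(4)
        self.planted_signatures = np.asarray(self.planted_signatures, dtype=float)
        if not np.allclose(self.planted_signatures.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError("planted signature rows must sum to 1")
        k = self.planted_signatures.shape[0]
        if self.exposure_alpha is None:
            self.exposure_alpha = tuple(0.25 for _ in range(k))
        if len(self.exposure_alpha) != k:
            raise ParameterError("exposure_alpha length must equal number of signatures")
        for prob_map in (self.gene_background, self.cnv_deletion_prob):
            for g, p in prob_map.items():
                if not (0.0 <= p <= 1.0):
                    raise ParameterError(f"probability for {g} outside [0, 1]: {p}")

    @property
    def k(self) -> int:
        return self.planted_signatures.shape[0]


def _nb_loads(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def simulate_catalog_counts(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Vectorized core: (samples x 96 counts, samples x k true exposures)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    exposures = rng.dirichlet(np.asarray(cfg.exposure_alpha, float), size=cfg.n_samples)
    loads = _nb_loads(rng, cfg.n_samples, cfg.load_mean, cfg.load_dispersion)
    probs = exposures @ cfg.planted_signatures  # samples x 96 mixture
    counts = np.zeros((cfg.n_samples, 96), dtype=np.int64)
    for i in range(cfg.n_samples):
        if loads[i] > 0:
            counts[i] = rng.multinomial(loads[i], probs[i])
    return counts, exposures


def _channel_alleles(channel_idx: int) -> tuple[str, str, str]:
    """(ref, alt, context3) for a channel label."""
    label = CHANNELS[channel_idx]
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    return ref, alt, five + ref + three


def sample_ids(n: int) -> list[str]:
    return [f"BM{i + 1:04d}" for i in range(n)]


def simulate_catalog(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """(MutationRecord list with context3, true exposure matrix).

    Records carry synthetic genes/positions; channel draws follow the planted
    Dirichlet-mixture model. Use :func:`simulate_catalog_counts` when only the
    96-matrix is needed (much faster at high loads).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    counts, exposures = simulate_catalog_counts(cfg, rng)
    ids = sample_ids(cfg.n_samples)
    passengers = [f"PSG{i + 1:03d}" for i in range(cfg.n_passenger_genes)]
    records: list[MutationRecord] = []
    pos_counter = 1000
    for i, sid in enumerate(ids):
        ch_indices = np.repeat(np.arange(96), counts[i])
        genes = rng.choice(passengers, size=ch_indices.size)
        for ch, gene in zip(ch_indices, genes):
            ref, alt, ctx = _channel_alleles(int(ch))
            pos_counter += 7
            records.append(
                MutationRecord(
                    sample_id=sid,
                    gene=str(gene),
                    chrom=str(1 + (zlib.crc32(str(gene).encode()) % 22)),
                    pos=pos_counter,
                    ref=ref,
                    alt=alt,
                    variant_classification="Missense_Mutation",
                    variant_type="SNP",
                    context3=ctx,
                )
            )
    return records, exposures


def _pair_joint(p_a: float, p_b: float, odds_ratio: float) -> np.ndarray:
    """Cell probabilities (both, a-only, b-only, neither) for given margins and OR."""
    if odds_ratio <= 0:
        raise ParameterError("odds_ratio must be positive")
    if abs(odds_ratio - 1.0) < 1e-12:
        p11 = p_a * p_b
    else:
        w = odds_ratio - 1.0
        b = 1.0 + w * (p_a + p_b)
        disc = b * b - 4.0 * w * odds_ratio * p_a * p_b
        p11 = (b - np.sqrt(disc)) / (2.0 * w)
    p11 = float(np.clip(p11, max(0.0, p_a + p_b - 1.0), min(p_a, p_b)))
    return np.array([p11, p_a - p11, p_b - p11, 1.0 - p_a - p_b + p11])


def simulate_gene_matrix(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """(gene mutation matrix, CnvRecord list, IciRecord list).

    Independent genes are Bernoulli with their background probability; each
    planted pair is drawn jointly from the 2x2 with the requested odds ratio
    and the genes' marginal probabilities.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    ids = sample_ids(cfg.n_samples)
    n = cfg.n_samples
    paired = {g for a, b, _ in cfg.planted_pairs for g in (a, b)}
    M = pd.DataFrame(False, index=pd.Index(ids, name="sample_id"), columns=sorted(cfg.gene_background), dtype=bool)
    for gene, p in sorted(cfg.gene_background.items()):
        if gene in paired:
            continue
        M[gene] = rng.random(n) < p
    for a, b, orr in cfg.planted_pairs:
        cells = _pair_joint(cfg.gene_background.get(a, 0.2), cfg.gene_background.get(b, 0.2), orr)
        draw = rng.choice(4, size=n, p=cells)
        M[a] = np.isin(draw, (0, 1))
        M[b] = np.isin(draw, (0, 2))

    cnv_records = []
    for gene, p in sorted(cfg.cnv_deletion_prob.items()):
        deleted = rng.random(n) < p
        for sid, d in zip(ids, deleted):
            cnv_records.append(CnvRecord(sample_id=sid, gene=gene, call="deletion" if d else "neutral"))

    ici_records = []
    if cfg.ici_n > 0:
        mut = rng.random(cfg.ici_n) < cfg.ici_mut_prob
        logit = cfg.ici_response_logit + cfg.ici_mut_logit * mut
        responder = rng.random(cfg.ici_n) < 1.0 / (1.0 + np.exp(-logit))
        rate = cfg.base_rate * np.where(mut, cfg.ici_mut_hr, 1.0)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.uniform(0, cfg.censor_window, size=cfg.ici_n)
        for i in range(cfg.ici_n):
            ici_records.append(
                IciRecord(
                    sample_id=f"ICI{i + 1:04d}" + ("_MUT" if mut[i] else "_WT"),
                    response="PR" if responder[i] else "PD",
                    os_months=float(round(min(t_event[i], t_cens[i]), 4)),
                    os_event=int(t_event[i] <= t_cens[i]),
                    cohort="ICI1",
                )
            )
    return M, cnv_records, ici_records


def simulate_survival(
    cfg: SimConfig,
    covariates: pd.DataFrame,
    betas: dict[str, float],
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Exponential survival with hazard rate * exp(sum beta_c x_c), uniform censoring.

    ``betas`` maps covariate column names to log hazard ratios. Returns a
    DataFrame indexed like ``covariates`` with os_months and os_event.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    xb = np.zeros(len(covariates))
    for col, beta in betas.items():
        xb += beta * covariates[col].to_numpy(dtype=float)
    rate = cfg.base_rate * np.exp(xb)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0, cfg.censor_window, size=len(covariates))
    return pd.DataFrame(
        {
            "os_months": np.round(np.minimum(t_event, t_cens), 4),
            "os_event": (t_event <= t_cens).astype(int),
        },
        index=covariates.index,
    )


@dataclass
class SyntheticCohort:
    records: list  # MutationRecord
    clinical: list  # ClinicalRecord
    cnv: list  # CnvRecord
    ici: list  # IciRecord
    gene_matrix: pd.DataFrame
    exposures: np.ndarray
    truth: dict


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate a coherent MAF + clinical + CNV + ICI cohort.

    The MAF's gene content is made consistent with the simulated gene matrix:
    every mutated driver gene contributes one record (channel drawn from the
    sample's signature mixture); remaining load goes to passenger genes, so
    the matrix derived from the MAF reproduces the planted driver matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    counts, exposures = simulate_catalog_counts(cfg, rng)
    M, cnv_records, ici_records = simulate_gene_matrix(cfg, rng)
    ids = sample_ids(cfg.n_samples)
    mix = exposures @ cfg.planted_signatures
    passengers = [f"PSG{i + 1:03d}" for i in range(cfg.n_passenger_genes)]

    records: list[MutationRecord] = []
    pos_counter = 1000
    for i, sid in enumerate(ids):
        ch_indices = list(np.repeat(np.arange(96), counts[i]))
        drivers = [g for g in M.columns if M.iloc[i][g]]
        while len(ch_indices) < len(drivers):  # guarantee one record per mutated driver
            ch_indices.append(int(rng.choice(96, p=mix[i])))
        genes = drivers + list(rng.choice(passengers, size=len(ch_indices) - len(drivers)))
        for ch, gene in zip(ch_indices, genes):
            ref, alt, ctx = _channel_alleles(int(ch))
            pos_counter += 7
            records.append(
                MutationRecord(
                    sample_id=sid,
                    gene=str(gene),
                    chrom=str(1 + (zlib.crc32(str(gene).encode()) % 22)),
                    pos=pos_counter,
                    ref=ref,
                    alt=alt,
                    variant_classification="Missense_Mutation",
                    variant_type="SNP",
                    context3=ctx,
                )
            )

    # covariates feeding the survival model
    cov = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    betas: dict[str, float] = {}
    for gene, hr in sorted(cfg.gene_hazard.items()):
        col = f"gene_{gene}"
        cov[col] = M[gene].astype(float) if gene in M.columns else 0.0
        betas[col] = float(np.log(hr))
    del_status = {}
    for rec in cnv_records:
        if rec.call == "deletion":
            del_status.setdefault(rec.gene, set()).add(rec.sample_id)
    for gene, hr in sorted(cfg.cnv_hazard.items()):
        col = f"del_{gene}"
        carriers = del_status.get(gene, set())
        cov[col] = [float(s in carriers) for s in ids]
        betas[col] = float(np.log(hr))
    sig_present = exposures > 0.25
    for sig_idx, hr in sorted(cfg.signature_hazard.items()):
        col = f"sig_{sig_idx}"
        cov[col] = sig_present[:, int(sig_idx)].astype(float)
        betas[col] = float(np.log(hr))

    age = np.round(np.clip(rng.normal(62, 11, cfg.n_samples), 22, 92), 1)
    sex = rng.choice(["F", "M"], size=cfg.n_samples)
    tumor_type = rng.choice(
        ["NSCLC", "SKCM", "BRCA", "OTHER"], size=cfg.n_samples, p=[0.47, 0.15, 0.10, 0.28]
    )
    for level, hr in sorted(cfg.tumor_type_hazard.items()):
        col = f"tt_{level}"
        cov[col] = (tumor_type == level).astype(float)
        betas[col] = float(np.log(hr))

    surv = simulate_survival(cfg, cov, betas, rng)
    per_sample_load = counts.sum(axis=1)
    clinical = [
        ClinicalRecord(
            sample_id=ids[i],
            os_months=float(surv["os_months"].iloc[i]),
            os_event=int(surv["os_event"].iloc[i]),
            age=float(age[i]),
            sex=str(sex[i]),
            tumor_type=str(tumor_type[i]),
            tmb=float(round(per_sample_load[i] / cfg.panel_mb, 4)),
            fga=float(round(rng.beta(2, 8), 4)),
            msi=float(round(rng.exponential(1.0), 4)),
        )
        for i in range(cfg.n_samples)
    ]
    truth = {
        "seed": cfg.seed,
        "k": cfg.k,
        "planted_signatures": cfg.planted_signatures.tolist(),
        "exposure_alpha": list(map(float, cfg.exposure_alpha)),
        "gene_hazard": cfg.gene_hazard,
        "cnv_hazard": cfg.cnv_hazard,
        "signature_hazard": {str(k): v for k, v in cfg.signature_hazard.items()},
        "planted_pairs": [[a, b, float(o)] for a, b, o in cfg.planted_pairs],
        "ici": {
            "gene": cfg.ici_gene,
            "mut_prob": cfg.ici_mut_prob,
            "response_logit": cfg.ici_response_logit,
            "mut_logit": cfg.ici_mut_logit,
            "mut_hr": cfg.ici_mut_hr,
        },
    }
    return SyntheticCohort(
        records=records,
        clinical=clinical,
        cnv=cnv_records,
        ici=ici_records,
        gene_matrix=M,
        exposures=exposures,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write maf.tsv / clinical.tsv / cnv.tsv / ici.tsv / truth.json; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_maf(cohort.records, out / "maf.tsv")
    paths["maf"] = str(out / "maf.tsv")
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "os_months": r.os_months,
                "os_event": r.os_event,
                "age": r.age,
                "sex": r.sex,
                "tumor_type": r.tumor_type,
                "tmb": r.tmb,
                "fga": r.fga,
                "msi": r.msi,
            }
            for r in cohort.clinical
        ]
    ).to_csv(out / "clinical.tsv", sep="\t", index=False)
    paths["clinical"] = str(out / "clinical.tsv")
    pd.DataFrame(
        [{"sample_id": r.sample_id, "gene": r.gene, "call": r.call} for r in cohort.cnv]
    ).to_csv(out / "cnv.tsv", sep="\t", index=False)
    paths["cnv"] = str(out / "cnv.tsv")
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "response": r.response,
                "os_months": r.os_months,
                "os_event": r.os_event,
                "cohort": r.cohort,
            }
            for r in cohort.ici
        ]
    ).to_csv(out / "ici.tsv", sep="\t", index=False)
    paths["ici"] = str(out / "ici.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
    paths["truth"] = str(out / "truth.json")
    return paths
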