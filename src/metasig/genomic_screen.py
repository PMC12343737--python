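"""Cohort-level screens over gene mutations and copy-number calls.

Recurrent-gene selection, per-gene prognostic Cox models, the pairwise
co-occurrence / mutual-exclusivity network (Fisher + BH), CNV survival
screens, grouped burden comparisons, and the ICI response association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MetasigError, ParameterError
from .io_cohort import CnvRecord, IciRecord, MutationRecord
from .survstats import TestResult, bh_adjust, coxph_fit, fisher_exact, kruskal_wallis, wilcoxon_rank_sum

DEFAULT_MIN_CARRIERS = 5  # below this many carriers a per-gene fit is skipped


def gene_mutation_matrix(
    records: Iterable[MutationRecord], samples: Sequence[str]
) -> pd.DataFrame:
    """Samples x genes boolean matrix: sample carries >= 1 mutation in gene."""
    idx = pd.Index(samples, name="sample_id")
    genes = sorted({r.gene for r in records})
    M = pd.DataFrame(False, index=idx, columns=genes, dtype=bool)
    for r in records:
        if r.sample_id in M.index:
            M.loc[r.sample_id, r.gene] = True
    return M


def recurrent_genes(M: pd.DataFrame, min_frac: float = 0.05) -> list[str]:
    """Genes mutated in >= ceil(min_frac * n) samples, sorted by frequency then name."""
    if not (0.0 <= min_frac <= 1.0):
        raise ParameterError(f"min_frac must lie in [0, 1], got {min_frac}")
    n = len(M)
    threshold = ceil(min_frac * n)
    counts = M.sum(axis=0)
    kept = counts[counts >= threshold]
    return sorted(kept.index, key=lambda g: (-kept[g], g))


def prognostic_gene_screen(
    M: pd.DataFrame,
    clinical: pd.DataFrame,
    adjust: Sequence[str] = (),
    alpha: float = 0.05,
    genes: Optional[Sequence[str]] = None,
    min_carriers: int = DEFAULT_MIN_CARRIERS,
) -> pd.DataFrame:
    """Per-gene Cox screen of mutation status against overall survival.

    ``clinical`` must carry os_months/os_event plus any adjustment columns,
    indexed by sample_id. Reported flags use unadjusted p < alpha (matching
    the original screening convention) but BH q-values are always co-emitted.
    """
    genes = list(genes) if genes is not None else list(M.columns)
    rows = []
    for gene in genes:
        status = M[gene].astype(float)
        n_mut = int(status.sum())
        if n_mut < min_carriers or (len(status) - n_mut) < min_carriers:
            warnings.warn(f"{gene}: only {n_mut} carriers; skipped", stacklevel=2)
            continue
        df = clinical.join(status.rename("mutant"), how="inner")
        try:
            fit = coxph_fit(df, "os_months", "os_event", ["mutant", *adjust])
        except MetasigError as exc:
            warnings.warn(f"{gene}: fit failed ({exc})", stacklevel=2)
            continue
        s = fit.summary.loc["mutant"]
        rows.append(
            {
                "gene": gene,
                "n_mut": n_mut,
                "beta": s["beta"],
                "hr": s["hr"],
                "ci_low": s["ci_low"],
                "ci_high": s["ci_high"],
                "p": s["p"],
                "n_used": fit.n_used,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "n_mut", "beta", "hr", "ci_low", "ci_high", "p", "n_used"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p"] < alpha
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out


@dataclass(frozen=True)
class PairAssociation:
    gene_a: str
    gene_b: str
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    odds_ratio: float
    p: float
    q: float
    direction: str  # "co-occurrence" | "mutual-exclusivity"

    def __post_init__(self):
        if self.direction not in ("co-occurrence", "mutual-exclusivity"):
            raise ParameterError(f"bad direction {self.direction!r}")


def cooccurrence_network(
    M: pd.DataFrame,
    genes: Optional[Sequence[str]] = None,
    fdr: float = 0.1,
) -> tuple[list[PairAssociation], pd.Series]:
    """All-pairs Fisher co-occurrence / mutual-exclusivity screen with BH FDR.

    Returns the pair table (q-values computed across all tested pairs) and a
    per-gene significant-interaction degree series. Direction is
    co-occurrence when the sample odds ratio exceeds 1.
    """
    genes = list(genes) if genes is not None else list(M.columns)
    pairs = [(genes[i], genes[j]) for i in range(len(genes)) for j in range(i + 1, len(genes))]
    raw = []
    for a, b in pairs:
        va = M[a].to_numpy(dtype=bool)
        vb = M[b].to_numpy(dtype=bool)
        both = int((va & vb).sum())
        a_only = int((va & ~vb).sum())
        b_only = int((~va & vb).sum())
        neither = int((~va & ~vb).sum())
        res = fisher_exact([[both, a_only], [b_only, neither]])
        raw.append((a, b, both, a_only, b_only, neither, res.effect, res.p))
    qvals = bh_adjust([r[7] for r in raw]) if raw else np.array([])
    assocs = []
    degree = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    for (a, b, both, a_only, b_only, neither, orr, p), q in zip(raw, qvals):
        direction = "co-occurrence" if orr > 1 else "mutual-exclusivity"
        assocs.append(
            PairAssociation(
                gene_a=a,
                gene_b=b,
                n_both=both,
                n_a_only=a_only,
                n_b_only=b_only,
                n_neither=neither,
                odds_ratio=float(orr),
                p=float(p),
                q=float(q),
                direction=direction,
            )
        )
        if q < fdr:
            degree[a] += 1
            degree[b] += 1
    return assocs, degree


def pair_table(assocs: Sequence[PairAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": a.gene_a,
                "gene_b": a.gene_b,
                "n_both": a.n_both,
                "n_a_only": a.n_a_only,
                "n_b_only": a.n_b_only,
                "n_neither": a.n_neither,
                "odds_ratio": a.odds_ratio,
                "p": a.p,
                "q": a.q,
                "direction": a.direction,
            }
            for a in assocs
        ]
    )


def hotspot_counts(records: Iterable[MutationRecord], gene: str) -> pd.Series:
    """Per-protein-change mutation counts for one gene, most frequent first."""
    changes = [r.protein_change for r in records if r.gene == gene and r.protein_change]
    if not changes:
        return pd.Series(dtype=int, name="count")
    s = pd.Series(changes).value_counts()
    s.name = "count"
    s.index.name = "protein_change"
    return s


def cnv_matrix(records: Iterable[CnvRecord], samples: Sequence[str], call: str = "deletion") -> pd.DataFrame:
    """Samples x genes boolean matrix of one CNV call type."""
    idx = pd.Index(samples, name="sample_id")
    genes = sorted({r.gene for r in records})
    M = pd.DataFrame(False, index=idx, columns=genes, dtype=bool)
    for r in records:
        if r.call == call and r.sample_id in M.index:
            M.loc[r.sample_id, r.gene] = True
    return M


def cnv_survival_screen(
    cnv: Sequence[CnvRecord],
    clinical: pd.DataFrame,
    call: str = "deletion",
    adjust: Sequence[str] = ("age", "sex", "tumor_type"),
    min_carriers: int = DEFAULT_MIN_CARRIERS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Cox screen of a CNV call indicator against survival."""
    M = cnv_matrix(cnv, list(clinical.index), call=call)
    return prognostic_gene_screen(M, clinical, adjust=adjust, alpha=alpha, min_carriers=min_carriers)


def group_burden_compare(values: Sequence[float], grouping: Sequence) -> TestResult:
    """Rank-test dispatch: Wilcoxon for 2 groups, Kruskal-Wallis for >= 3."""
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    groups = [values[grouping == g] for g in pd.unique(grouping)]
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    if len(groups) == 2:
        return wilcoxon_rank_sum(groups[0], groups[1])
    return kruskal_wallis(groups)


def ici_response_assoc(
    ici: Sequence[IciRecord], mutant_samples: set[str]
) -> tuple[TestResult, dict[str, float]]:
    """Fisher association of objective response (CR/PR) with mutation status.

    NE records are excluded. Returns the test plus per-arm response rates (as
    percentages) and arm sizes.
    """
    rows = [(r.sample_id in mutant_samples, r.response in ("CR", "PR")) for r in ici if r.response != "NE"]
    n_mut = sum(1 for m, _ in rows if m)
    n_wt = len(rows) - n_mut
    if n_mut == 0 or n_wt == 0:
        raise DegenerateInputError("both mutant and wild-type arms required")
    resp_mut = sum(1 for m, rsp in rows if m and rsp)
    resp_wt = sum(1 for m, rsp in rows if not m and rsp)
    test = fisher_exact([[resp_mut, n_mut - resp_mut], [resp_wt, n_wt - resp_wt]])
    rates = {
        "mutant_rate_pct": 100.0 * resp_mut / n_mut,
        "wildtype_rate_pct": 100.0 * resp_wt / n_wt,
        "n_mutant": float(n_mut),
        "n_wildtype": float(n_wt),
    }
    return test, rates
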