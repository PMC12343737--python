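import numpy as np
import pandas as pd
import pytest

from metasig.io_cohort import MutationRecord

TOY_MAF = """#version 2.4
Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\tVariant_Classification\tVariant_Type\tTumor_Sample_Barcode
TP53\t17\t7577120\tC\tT\tMissense_Mutation\tSNP\tS1
KRAS\t12\t25398284\tC\tA\tSilent\tSNP\tS1
EGFR\t7\t55242465\tG\tA\tSplice_Site\tSNP\tS2
"""


@pytest.fixture
def toy_maf(tmp_path):
    p = tmp_path / "toy.maf"
    p.write_text(TOY_MAF)
    return p


@pytest.fixture
def clinical_tsv(tmp_path):
    p = tmp_path / "clinical.tsv"
    p.write_text(
        "sample_id\tos_months\tos_event\tage\tsex\ttumor_type\ttmb\tfga\tmsi\n"
        "S1\t12.5\t1\t63\tF\tNSCLC\t8.2\t0.3\t0.5\n"
        "S2\t30.0\t0\t55\tM\tSKCM\t15.1\t0.1\t1.2\n"
    )
    return p


def snv(sample="S1", gene="TP53", ref="C", alt="T", ctx="ACA", pos=100, cls="Missense_Mutation", germ=False):
    return MutationRecord(
        sample_id=sample,
        gene=gene,
        chrom="1",
        pos=pos,
        ref=ref,
        alt=alt,
        variant_classification=cls,
        variant_type="SNP",
        context3=ctx,
        germline_flag=germ,
    )


@pytest.fixture
def make_snv():
    return snv


@pytest.fixture
def surv_frame():
    """Deterministic single-binary-covariate survival data, no ties."""

    def _make(n=200, hr=2.0, seed=0, rate=0.05, window=40.0):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        t_event = rng.exponential(1.0 / (rate * np.exp(np.log(hr) * x)))
        t_cens = rng.uniform(0, window, n)
        return pd.DataFrame(
            {
                "time": np.minimum(t_event, t_cens),
                "event": (t_event <= t_cens).astype(int),
                "x": x,
            }
        )

    return _make
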