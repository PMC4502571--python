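import numpy as np
import pytest

from lgtscan import PipelineConfig
from lgtscan.composition import KmerClassModel


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def k1_model():
    """Order-0 model with P(A)=0.7 and 0.1 for the other bases."""
    return KmerClassModel(
        class_label="X", k=1,
        log_probs=np.log(np.array([[0.7, 0.1, 0.1, 0.1]])))


@pytest.fixture
def uniform_model():
    return KmerClassModel(
        class_label="U", k=1,
        log_probs=np.log(np.full((1, 4), 0.25)))


def make_hit(query_id="q", subject_id="s", pct_identity=90.0, aln_len=100,
             evalue=1e-20, bitscore=100.0, subject_class=None,
             q_len=None, s_len=None, q_start=1, q_end=None,
             s_start=1, s_end=None):
    from lgtscan import AlignmentHit
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id,
        pct_identity=pct_identity, aln_len=aln_len,
        q_start=q_start, q_end=q_end or aln_len,
        s_start=s_start, s_end=s_end or aln_len,
        evalue=evalue, bitscore=bitscore, subject_class=subject_class,
        q_len=q_len, s_len=s_len)
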