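import numpy as np
import pytest

from svcohort.sv_model import Genotype, SVRecord, SVType, sv_length
from svcohort.synthetic_data import SimConfig, simulate_cohort


def make_record(record_id="r1", sample_id="S1", chrom="chr1", start=1000,
                svtype=SVType.DEL, svlen=100, qual=60.0,
                genotype=Genotype.het, seq=None, rng=None):
    """Construct a consistent SVRecord without needing a reference genome."""
    rng = rng or np.random.default_rng(0)
    if seq is None:
        seq = "".join(rng.choice(list("ACGT"), size=svlen))
    if svtype == SVType.DEL:
        ref, alt = "A" + seq, "A"
    elif svtype == SVType.INS:
        ref, alt = "A", "A" + seq
    else:
        comp = str.maketrans("ACGT", "TGCA")
        ref, alt = seq, seq.translate(comp)[::-1]
    return SVRecord(record_id=record_id, sample_id=sample_id, chrom=chrom,
                    start=start, end=start + len(ref), ref_allele=ref,
                    alt_allele=alt, svtype=svtype,
                    svlen=sv_length(ref, alt, svtype), qual=qual,
                    genotype=genotype)


def dp_edit_distance(a: str, b: str) -> int:
    """Quadratic dynamic-programming Levenshtein oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[len(b)]


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-population cohort with replicates, shared across tests."""
    cfg = SimConfig(seed=11, n_per_pop=60, n_sites=80,
                    replicate_individuals=8, causal_effects=((5, 2.0),))
    return simulate_cohort(cfg)
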