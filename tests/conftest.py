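import numpy as np
import pytest

from seqddg.data_io import Mutation, MutationDataset, MutationRecord


def make_record(
    complex_id="CPLX1",
    ab_seq="ACDEFGHIKLMN",
    ag_seq="PQRSTVWY",
    mutations=None,
    ddg=1.0,
):
    if mutations is None:
        mutations = [Mutation("H", ab_seq[2], 3, "W" if ab_seq[2] != "W" else "Y")]
    return MutationRecord(
        complex_id=complex_id,
        antibody_chains=[("H", ab_seq)],
        antigen_chains=[("A", ag_seq)],
        mutations=mutations,
        ddg=ddg,
    )


def random_record(rng, complex_id="CPLX1", len_ab=12, len_ag=9, n_mut=1, ddg=None):
    from seqddg.alphabet import ALPHABET

    letters = list(ALPHABET)
    ab = "".join(rng.choice(letters, size=len_ab))
    ag = "".join(rng.choice(letters, size=len_ag))
    sites = rng.choice(np.arange(1, len_ab + 1), size=n_mut, replace=False)
    muts = []
    for pos in sites:
        wt = ab[pos - 1]
        mt = str(rng.choice([aa for aa in letters if aa != wt]))
        muts.append(Mutation("H", wt, int(pos), mt))
    return MutationRecord(
        complex_id=complex_id,
        antibody_chains=[("H", ab)],
        antigen_chains=[("A", ag)],
        mutations=muts,
        ddg=float(rng.normal()) if ddg is None else ddg,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_dataset(rng):
    """12 records over 2 complexes with varied mutation counts and labels."""
    records = []
    for c, (la, lg) in enumerate([(14, 10), (11, 13)]):
        crng = np.random.default_rng(100 + c)
        for _ in range(6):
            records.append(
                random_record(
                    crng, complex_id=f"CPLX{c + 1}", len_ab=la, len_ag=lg, n_mut=int(crng.integers(1, 3))
                )
            )
    return MutationDataset(records=records, name="tiny", provenance="synthetic")
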