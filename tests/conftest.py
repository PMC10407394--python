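import pytest

from ighclone import (
    DEFAULT_POLICY,
    Junction,
    MutationProfile,
    Rearrangement,
    SegmentAlignment,
    synthetic_germline_set,
)

GERMLINE_SEED = 3


@pytest.fixture(scope="session")
def germlines():
    """One synthetic IGHV/IGHD/IGHJ reference shared across the suite."""
    return synthetic_germline_set(seed=GERMLINE_SEED)


@pytest.fixture(scope="session")
def policy():
    return DEFAULT_POLICY


def make_rearrangement(
    cell_id: str,
    v_gene: str,
    cdr3: str,
    sample_id: str = "sample1",
    mutated: bool = False,
    positions: tuple = (),
    productive: str = "productive",
) -> Rearrangement:
    """A minimal hand-built record for clone-calling tests."""
    nt = "TGT" + cdr3 + "TGG"
    seq = "A" * 30 + nt + "C" * 10
    v = SegmentAlignment(
        gene=f"{v_gene}*01",
        score=100.0,
        identity_pct=100.0,
        q_start=0,
        q_end=30,
        g_start=0,
        g_end=30,
        n_mismatches=0,
        n_insertions=0,
        n_deletions=0,
        blocks=(((0, 30), (0, 30)),),
    )
    junction = Junction(
        nt=nt,
        cdr3_nt=cdr3,
        frame_offset=len(nt) % 3,
        contains_stop=False,
        q_start=30,
        q_end=30 + len(nt),
    )
    n_diff = len(positions) if positions else (5 if mutated else 0)
    mutation = MutationProfile(
        n_diff=n_diff,
        aligned_len=200,
        freq_pct=100.0 * n_diff / 200,
        status="mutated" if n_diff > 1 else "unmutated",
        positions=tuple(positions) or tuple((i, "A", "G") for i in range(n_diff)),
    )
    return Rearrangement(
        cell_id=cell_id,
        sequence=seq,
        sample_id=sample_id,
        v=v,
        junction=junction,
        productive=productive,
        mutation=mutation,
    )
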