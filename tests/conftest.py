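import random

import numpy as np
import pytest

from teforge.core_io import GenomeSet, Interval, Match


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate_seq(rng, seq, p_sub):
    out = []
    for c in seq:
        if rng.random() < p_sub:
            out.append(rng.choice("ACGT".replace(c, "")))
        else:
            out.append(c)
    return "".join(out)


def make_match(mid, qid, qs, qe, sid, ss, se, strand="+", identity=99.0, score=None):
    if score is None:
        score = float(qe - qs)
    return Match(
        id=mid,
        query=Interval(qid, qs, qe, "+"),
        subject=Interval(sid, ss, se, strand),
        identity=identity,
        score=score,
    )


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def np_rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_pair_genome(rng):
    """A 6 kb genome with two exact 500 bp copies of one repeat."""
    bg = random_seq(rng, 5000)
    rep = random_seq(rng, 500)
    seq = bg[:1500] + rep + bg[1500:3500] + rep + bg[3500:]
    genome = GenomeSet({"chr": seq})
    return genome, rep, (1500, 2000), (4000, 4500)


@pytest.fixture(scope="session")
def default_truth():
    """The default synthetic scenario, seed 1 (shared across tests)."""
    from teforge.synthgenome import simulate

    return simulate(seed=1)
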