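import numpy as np
import pytest

from mosatwin.io_formats import SitePileup


def make_pileup(
    bases: str,
    ref: str = "A",
    bq: int | list = 30,
    mq: int | list = 60,
    starts: list | None = None,
    contig: str = "chr1",
    pos: int = 100,
) -> SitePileup:
    """Build a small pileup from a base string, e.g. make_pileup('AAAC')."""
    n = len(bases)
    bq_arr = np.full(n, bq) if np.isscalar(bq) else np.asarray(bq)
    mq_arr = np.full(n, mq) if np.isscalar(mq) else np.asarray(mq)
    starts_arr = np.asarray(starts) if starts is not None else np.arange(1, n + 1)
    return SitePileup(
        contig, pos, ref, np.array(list(bases), dtype="U1"),
        bq_arr, mq_arr, starts_arr, np.array(["+"] * n, dtype="U1"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140705)


def random_pileup(rng, depth, ref="A", p_alt=0.0, alt="G", bq_range=(10, 41)):
    bases = np.where(rng.random(depth) < p_alt, alt, ref)
    return SitePileup(
        "chr1", 50, ref, bases.astype("U1"),
        rng.integers(*bq_range, size=depth), np.full(depth, 60),
        rng.integers(1, 50, size=depth),
        np.where(rng.random(depth) < 0.5, "+", "-").astype("U1"),
    )
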