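from __future__ import annotations

import numpy as np
import pytest

from varconcord import Callset, GenotypeCall, GenotypeClass, IntervalSet, Variant
from varconcord.variants import FilterStatus


@pytest.fixture
def chr1_universe() -> IntervalSet:
    return IntervalSet([("chr1", 0, 1_000_000)])


def make_call(
    pos: int,
    gclass: GenotypeClass = GenotypeClass.HET,
    ref: str = "A",
    alt: str = "G",
    chrom: str = "chr1",
    filtered: bool = False,
    **annotations,
) -> GenotypeCall:
    return GenotypeCall(
        Variant(chrom, pos, ref, alt),
        gclass,
        FilterStatus.FILTERED if filtered else FilterStatus.PASS,
        dict(annotations),
    )


def make_callset(calls, replicate_id="X", sample="S", **kwargs) -> Callset:
    return Callset(replicate_id, sample, calls, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140423)
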