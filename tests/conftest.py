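import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable

from dstile import (
    PlantSpec,
    ScanParams,
    Sequence,
    make_transcriptome,
    plant_offtarget,
    tile_target,
)


@pytest.fixture
def default_params():
    return ScanParams()


@pytest.fixture
def random_target():
    def _make(length=120, seed=0):
        rng = np.random.default_rng(seed)
        return Sequence("target", "".join(rng.choice(list("ACGT"), size=length)))

    return _make


@pytest.fixture
def planted_instance(random_target):
    """A small transcriptome with one mutated target block planted in it."""

    def _make(
        seed=0,
        target_len=100,
        n_tx=4,
        tx_len=(250, 350),
        block_len=40,
        source_start=30,
        sub_rate=0.0,
        indel_rate=0.0,
        host_position=None,
    ):
        target = random_target(target_len, seed=seed + 1000)
        tx = make_transcriptome(n_tx, tx_len, seed=seed)
        spec = PlantSpec(
            block_len=block_len,
            source_start=source_start,
            substitution_rate=sub_rate,
            indel_rate=indel_rate,
            host_transcript_id="tx1",
            host_position=host_position,
            seed=seed,
        )
        planted, truth = plant_offtarget(tx, target, spec)
        return target, planted, truth

    return _make
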