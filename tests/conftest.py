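import numpy as np
import pytest

import ribometh as rm


@pytest.fixture
def small_scene():
    """A 2-kb RNA with 30 planted, canonically guided, fully methylated sites."""
    config = rm.SimulationConfig(seed=7, rna_length=2000, n_sites=30)
    return rm.make_scene(config)


@pytest.fixture
def flat_track():
    """End-count track with a perfectly uniform combined count of 100."""
    L = 120
    track = rm.EndCountTrack.empty("flat", L)
    track.five_ends[1:L + 1] = 50
    track.three_ends[1:L + 1] = 50
    track.n_fragments = 50 * L
    return track


def make_track(combined, rna_id="t"):
    """Build a track whose combined counts equal ``combined`` (1-based list).

    All counts are planted on the 3'-end vector, so combined[i] == three[i].
    """
    L = len(combined) + 1
    track = rm.EndCountTrack.empty(rna_id, L)
    track.three_ends[1:L] = np.asarray(combined)
    track.n_fragments = int(np.sum(combined))
    return track


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="refs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path
    return _write
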