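import numpy as np
import pandas as pd
import pytest

from mrnafate.core_io import Transcript
from mrnafate.synthetic import SimulationSpec, simulate_transcriptome

PAPER_TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


@pytest.fixture
def toy_transcript() -> Transcript:
    # ATG GCC GCA AAA TAA -> peptide MAAK + stop
    return Transcript(id="toy", cds_seq="ATGGCCGCAAAATAA")


@pytest.fixture
def timecourse_arrays():
    """Pooled 7-timepoint x 3-replicate grid (t, replicate labels)."""
    t = np.tile(PAPER_TIMEPOINTS, 3)
    reps = np.repeat(["r1", "r2", "r3"], len(PAPER_TIMEPOINTS))
    return t, reps


@pytest.fixture(scope="session")
def small_transcriptome():
    spec = SimulationSpec(n_transcripts=60, seed=101)
    transcripts, truth = simulate_transcriptome(spec)
    return spec, transcripts, truth


def make_count_table_tsv(tmp_path, values: dict, index=("tx1", "tx2", "tx3")):
    df = pd.DataFrame(values, index=pd.Index(index, name="transcript_id"))
    path = tmp_path / "counts.tsv"
    df.to_csv(path, sep="\t")
    return path
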