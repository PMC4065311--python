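import numpy as np
import pandas as pd
import pytest

import immunosig as ims


@pytest.fixture(scope="session")
def small_library() -> ims.PeptideLibrary:
    return ims.generate_library(n=60, length=20, linker="GSC", seed=7)


@pytest.fixture(scope="session")
def tiny_library() -> ims.PeptideLibrary:
    return ims.PeptideLibrary.from_records(
        [
            ("p1", "ARNDKWYFHILMNGSC", 1, 1, 1),
            ("p2", "GGGGGGGGGGGGGGSC", 1, 1, 2),
        ]
    )


def make_matrix(values: np.ndarray, n_mice: int, reps: int = 1,
                strain: str = "MRL/lpr", scale: str = "raw",
                study: int = 1, peptide_ids=None) -> ims.IntensityMatrix:
    """Ad-hoc matrix builder: columns are mouse-major, replicate-minor."""
    records = []
    for m in range(n_mice):
        for r in range(1, reps + 1):
            records.append(
                ims.SampleRecord(
                    sample_id=f"m{m + 1}_r{r}", mouse_id=f"m{m + 1}",
                    strain=strain, age_months=4.0, replicate=r, study=study,
                )
            )
    samples = ims.array_io.samples_frame(records)
    if peptide_ids is None:
        peptide_ids = [f"pep_{i + 1}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(peptide_ids, name="peptide_id"),
                      columns=samples.index)
    return ims.IntensityMatrix(df, samples, scale=scale)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
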