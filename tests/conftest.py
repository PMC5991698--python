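import numpy as np
import pytest

from peakalign import PeakDataset, RetentionMatrix, SimConfig, generate


def make_matrix(rows, sample_ids=None, measures=None):
    """Build a RetentionMatrix from a list of row lists (0 = absent)."""
    rt = np.asarray(rows, dtype=float)
    if rt.ndim == 1:
        rt = rt.reshape(1, -1)
    ids = sample_ids or [f"s{j + 1}" for j in range(rt.shape[1])]
    meas = {k: np.asarray(v, dtype=float) for k, v in (measures or {}).items()}
    return RetentionMatrix(rt=rt, measures=meas, sample_ids=ids)


def make_dataset(times, areas=None, blanks=(), rt_variable="time"):
    """Build a PeakDataset from {sample: [rts]} (+ optional areas)."""
    sample_ids = list(times)
    peaks = {}
    for s in sample_ids:
        entry = {"time": [float(x) for x in times[s]]}
        if areas is not None:
            entry["area"] = [float(x) for x in areas[s]]
        peaks[s] = entry
    variables = ["time"] + (["area"] if areas is not None else [])
    return PeakDataset(sample_ids=sample_ids, variable_names=variables,
                       peaks=peaks, rt_variable=rt_variable,
                       blanks=list(blanks))


@pytest.fixture(scope="session")
def clean_sim():
    """One simulated dataset under the default study conditions."""
    return generate(SimConfig(seed=20_240_101))


@pytest.fixture(scope="session")
def blank_sim():
    """Simulated dataset with two blanks carrying contaminant substances."""
    cfg = SimConfig(n_samples=10, n_substances=25, n_blanks=2,
                    blank_contaminants=4, seed=77)
    return generate(cfg)
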