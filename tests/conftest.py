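import numpy as np
import pandas as pd
import pytest

from geneshift.gem import ExpressionMatrix, SampleMeta

TIME_GRID = (0.0, 12.0, 24.0, 48.0, 72.0)


def make_gem(values_by_profile, time_grid=TIME_GRID, scale="fpkm"):
    """Build an ExpressionMatrix from {gene: {(cond, rep): [v per time]}}."""
    profiles = sorted({key for prof in values_by_profile.values()
                       for key in prof})
    samples = [SampleMeta(f"{cond}_{int(t)}h_r{rep}", cond, float(t), rep)
               for cond, rep in profiles for t in time_grid]
    genes = sorted(values_by_profile)
    data = np.zeros((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        for (cond, rep), vals in values_by_profile[g].items():
            for ti, t in enumerate(time_grid):
                j = samples.index(SampleMeta(f"{cond}_{int(t)}h_r{rep}",
                                             cond, float(t), rep))
                data[gi, j] = vals[ti]
    df = pd.DataFrame(data, index=genes, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(df, samples, scale=scale)


@pytest.fixture
def tiny_gem():
    """3 genes x 2 conditions x 3 replicates x 5 time points, FPKM scale."""
    ramp = [0.0, 1.0, 2.0, 4.0, 8.0]
    prof = {}
    for g, base in (("gA", 1.0), ("gB", 2.0), ("gC", 0.5)):
        prof[g] = {}
        for cond in ("control", "treated"):
            for rep in (1, 2, 3):
                prof[g][(cond, rep)] = [base * v + rep * 0.1 for v in ramp]
    return make_gem(prof)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
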