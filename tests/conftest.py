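import numpy as np
import pandas as pd
import pytest

from starchnet import ExpressionMatrix, ScreenParams, SimulationConfig, simulate_expression


def make_matrix(ck_rows, rs_rows, gene_ids=None):
    """Build a small ExpressionMatrix from per-gene CK and RS value lists."""
    ck = np.atleast_2d(np.asarray(ck_rows, dtype=float))
    rs = np.atleast_2d(np.asarray(rs_rows, dtype=float))
    n = ck.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    samples = [f"CK{i+1}" for i in range(ck.shape[1])] + \
              [f"RS{i+1}" for i in range(rs.shape[1])]
    groups = pd.Series(["CK"] * ck.shape[1] + ["RS"] * rs.shape[1], index=samples)
    values = pd.DataFrame(np.hstack([ck, rs]), index=gene_ids, columns=samples)
    return ExpressionMatrix(values, groups)


@pytest.fixture
def small_sim():
    cfg = SimulationConfig(n_genes=200, n_per_group=3, frac_up=0.1, frac_down=0.1,
                           fc_up=3.0, fc_down=0.3, noise_sd_log2=0.2, seed=42)
    matrix, truth = simulate_expression(cfg)
    return cfg, matrix, truth


@pytest.fixture
def default_params():
    return ScreenParams(seed=0)
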