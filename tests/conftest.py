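import numpy as np
import pandas as pd
import pytest

from slopehunter import preset_scenario, simulate_individual


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def harmonised_table(rng):
    """A small harmonised table with a clear two-cluster structure."""
    n1, n2 = 120, 80
    x = np.concatenate([rng.normal(0, 0.03, n1), rng.normal(0, 0.03, n2)])
    y = np.empty(n1 + n2)
    y[:n1] = -0.4 * x[:n1] + rng.normal(0, 0.004, n1)
    y[n1:] = 0.2 * x[n1:] + rng.normal(0, 0.012, n2)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n1 + n2)],
        "ea": "A", "oa": "G",
        "beta_I": x, "se_I": 0.004,
        "beta_P": y, "se_P": 0.004,
    })


@pytest.fixture(scope="session")
def fig5a_study():
    """One full-size individual-level replicate of the balanced,
    uncorrelated-effects configuration (10,000 SNPs x 20,000 individuals)."""
    return simulate_individual(preset_scenario("fig5a", seed=20_220_202))


def write_sumstat_file(path, rows, header="SNP EA OA EAF BETA SE P N",
                       sep=" "):
    lines = [sep.join(header.split())]
    for row in rows:
        lines.append(sep.join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
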