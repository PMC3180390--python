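import numpy as np
import pytest

from dtwshift.trajectory import InterpSeries, RawSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20210818)


def make_interp(values, times=None, gene="g", group="grp"):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(1.0, values.size + 1)
    return InterpSeries(gene, group, np.asarray(times, dtype=float), values)


def make_raw(ages, values, gene="g", group="grp"):
    return RawSeries(gene, group, np.asarray(ages, float), np.asarray(values, float))


@pytest.fixture
def noisy_cubic_series(rng):
    t = np.sort(rng.uniform(0.5, 10.0, 39))
    y = 0.05 * t**3 - 0.6 * t**2 + t + 2 + rng.normal(0, 0.3, t.size)
    return make_raw(t, y)


@pytest.fixture
def tiny_dataset_files(tmp_path, rng):
    """A 3-gene, two-group expression matrix + metadata on disk."""
    ages_h = np.linspace(1, 20, 12)
    ages_c = np.linspace(1, 16, 8)
    samples = [f"h{i}" for i in range(12)] + [f"c{i}" for i in range(8)]
    groups = ["human"] * 12 + ["chimp"] * 8
    ages = np.concatenate([ages_h, ages_c])
    rows = {}
    for g in range(3):
        f = lambda t: 0.2 * t + 0.05 * (g + 1) * np.sin(t / 3.0)
        vals = np.concatenate([f(ages_h), f(ages_c + 1.5)])
        rows[f"gene{g}"] = vals + rng.normal(0, 0.05, vals.size)
    import pandas as pd

    expr = pd.DataFrame(rows, index=samples).T
    expr.index.name = "gene_id"
    meta = pd.DataFrame({"sample": samples, "group": groups, "age": ages})
    expr_path = tmp_path / "expr.tsv"
    meta_path = tmp_path / "meta.tsv"
    expr.to_csv(expr_path, sep="\t")
    meta.to_csv(meta_path, sep="\t", index=False)
    return expr_path, meta_path
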