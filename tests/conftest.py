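import numpy as np
import pandas as pd
import pytest

from dustdab import CountTable, SampleFrame


def make_table(counts, sample_ids=None, taxon_ids=None, lineages=None):
    counts = np.asarray(counts)
    n, p = counts.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    taxon_ids = taxon_ids or [f"G{j}" for j in range(p)]
    if lineages is None:
        lineages = [
            f"k__Bacteria;p__Phylum{j % 3};c__C;o__O;f__Family{j % 2};g__{t}"
            for j, t in enumerate(taxon_ids)
        ]
    return CountTable(counts=counts, taxon_ids=taxon_ids,
                      lineages=lineages, sample_ids=sample_ids)


def make_metadata(n, seed=0, with_outcomes=True):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "age": rng.normal(62, 11, n).round(1),
        "sex": rng.choice(["male", "female"], n),
        "height": rng.normal(171, 10, n).round(1),
        "weight": rng.normal(90, 21, n).clip(40).round(1),
        "smoking": rng.choice(["never", "former", "current"], n),
        "pack_years": rng.exponential(10, n).round(1),
        "asthma": rng.choice(["yes", "no"], n),
        "state": rng.choice(["NC", "IA"], n),
        "ancestry": rng.choice(["european", "not"], n, p=[0.95, 0.05]),
        "season": rng.choice(["winter", "not_winter"], n),
    })
    if with_outcomes:
        fvc = rng.normal(3600, 900, n).clip(1200)
        ratio = rng.uniform(0.5, 0.9, n)
        df["fvc"] = fvc.round()
        df["fev1"] = (fvc * ratio).round()
        df["fev1_fvc"] = (df["fev1"] / df["fvc"]).round(4)
        df["feno"] = rng.lognormal(2.8, 0.7, n).round(1)
        df["feno_below_lod"] = df["feno"] < 5
    return SampleFrame(df)


@pytest.fixture
def toy_table():
    return make_table([[10, 0, 5], [20, 3, 0], [1, 1, 1]])


@pytest.fixture
def meta50():
    return make_metadata(50, seed=1)
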