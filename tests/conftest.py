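import numpy as np
import pandas as pd
import pytest

from thermotol.expression import CountMatrix, SharedDEGSet
from thermotol.simulate import SimulationParams, simulate_counts


@pytest.fixture(scope="session")
def default_dataset():
    """A mid-size synthetic experiment reused by several test modules."""
    params = SimulationParams(
        n_genes=2000,
        frac_de=0.1,
        dup_fraction=0.4,
        discord_rate=0.08,
        seed=42,
    )
    cm, meta, truth = simulate_counts(params)
    return params, cm, meta, truth


@pytest.fixture
def deg_table_factory():
    """Build a minimal DEG table from {gene: log2fc} of significant genes."""

    def make(sig, comparison="HvL", strain="s", extra=()):
        genes = sorted(set(sig) | set(extra))
        tab = pd.DataFrame(
            {
                "log2fc": [sig.get(g, 0.0) for g in genes],
                "p": [0.001 if g in sig else 0.9 for g in genes],
                "q": [0.001 if g in sig else 0.95 for g in genes],
                "passed_filter": True,
                "significant": [g in sig for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )
        tab.attrs["comparison"] = comparison
        tab.attrs["strain"] = strain
        return tab

    return make


@pytest.fixture
def shared_set_factory():
    """Build a SharedDEGSet directly from per-strain log2FC dicts."""

    def make(lfc1, lfc2, comparison="HvL", strains=("s1", "s2")):
        genes = sorted(set(lfc1) & set(lfc2))
        s1, s2 = strains
        tab = pd.DataFrame(
            {
                f"log2fc_{s1}": [lfc1[g] for g in genes],
                f"log2fc_{s2}": [lfc2[g] for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )
        tab["avg_log2fc"] = (tab[f"log2fc_{s1}"] + tab[f"log2fc_{s2}"]) / 2.0
        tab["concordant"] = np.sign(tab[f"log2fc_{s1}"]) == np.sign(tab[f"log2fc_{s2}"])
        return SharedDEGSet(
            comparison=comparison, strains=strains, sig_sets={}, table=tab
        )

    return make


@pytest.fixture
def truth_shared_set(shared_set_factory):
    """SharedDEGSet built from a GroundTruth's true H-vs-L log2 fold changes."""

    def make(params, truth):
        s1, s2 = params.strains
        lfc1 = {g: truth.hvl_lfc[s1][g] for g in truth.shared_hvl}
        lfc2 = {g: truth.hvl_lfc[s2][g] for g in truth.shared_hvl}
        return shared_set_factory(lfc1, lfc2, strains=(s1, s2))

    return make


@pytest.fixture
def tiny_counts():
    counts = pd.DataFrame(
        {"s1": [10, 90], "s2": [20, 180]},
        index=pd.Index(["gA", "gB"], name="gene"),
    )
    lengths = pd.Series([1000, 1000], index=counts.index, name="length")
    return CountMatrix(counts, lengths)
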