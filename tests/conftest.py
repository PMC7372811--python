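import numpy as np
import pandas as pd
import pytest

from mucosanet import AbundanceTable, TaxonomyMap


def make_table(values, kind="counts", samples=None, species=None) -> AbundanceTable:
    values = np.asarray(values)
    samples = samples or [f"s{i + 1}" for i in range(values.shape[0])]
    species = species or [f"sp{j + 1}" for j in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=samples, columns=species), kind=kind)


def random_counts(rng: np.random.Generator, n_samples=8, n_species=6, depth=200) -> AbundanceTable:
    comp = rng.dirichlet(np.full(n_species, 0.7), size=n_samples)
    counts = np.vstack([rng.multinomial(depth, comp[i]) for i in range(n_samples)])
    return make_table(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def taxmap():
    species = [f"sp{j + 1}" for j in range(6)]
    frame = pd.DataFrame(
        {
            "phylum": ["Firmicutes"] * 3 + ["Proteobacteria"] * 3,
            "class": ["Bacilli"] * 3 + ["Gamma"] * 3,
            "order": ["Lactobacillales"] * 3 + ["Enterobacterales"] * 3,
            "family": ["Lactobacillaceae", "Lactobacillaceae", "Streptococcaceae",
                       "Enterobacteriaceae", "Enterobacteriaceae", "Moraxellaceae"],
            "genus": ["Lactobacillus", "Lactobacillus", "Streptococcus",
                      "Escherichia", "Shigella", "Moraxella"],
            "species": species,
        },
        index=pd.Index(species, name="species_id"),
    )
    return TaxonomyMap(frame)
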