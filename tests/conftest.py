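import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from invadiv.io import GenotypeDataset, Locus


def make_dataset(pop_genotypes: dict[str, list[dict]], loci: list[Locus] | None = None):
    """Build a GenotypeDataset from {pop: [ {locus: (a, b) | None}, ... ]}."""
    locus_names: list[str] = []
    for inds in pop_genotypes.values():
        for ind in inds:
            for loc in ind:
                if loc not in locus_names:
                    locus_names.append(loc)
    if loci is None:
        loci = [Locus(n) for n in locus_names]
    calls = {
        pop: {f"ind{i + 1}": dict(ind) for i, ind in enumerate(inds)}
        for pop, inds in pop_genotypes.items()
    }
    return GenotypeDataset(list(pop_genotypes), loci, calls)


def random_dataset(rng, n_pops=3, n_inds=4, n_loci=2, n_alleles=3, missing_rate=0.0):
    """Small random dataset for oracle comparisons."""
    sizes = [100 + 2 * i for i in range(n_alleles)]
    pops = {}
    for p in range(n_pops):
        inds = []
        for _ in range(n_inds):
            ind = {}
            for l in range(n_loci):
                if missing_rate and rng.random() < missing_rate:
                    ind[f"loc{l}"] = None
                else:
                    a, b = rng.choice(sizes, 2, replace=True)
                    ind[f"loc{l}"] = (int(a), int(b))
            inds.append(ind)
        pops[f"pop{p}"] = inds
    return make_dataset(pops)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
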