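"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (explicit enumeration, triple
loops) and independent of the vectorized implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from glrelate.core import STATE_PARTITIONS


def oracle_pair_prior(f: float) -> np.ndarray:
    """Brute-force genotype-pair prior by enumerating allele configurations.

    Enumerates all 2^4 assignments of alleles to the four gene copies
    (a1, a2, b1, b2); a configuration is consistent with a condensed state
    iff copies in the same IBD block carry equal alleles, and then has
    probability = product over blocks of the block allele's frequency.
    """
    out = np.zeros((9, 3, 3))
    for m, partition in enumerate(STATE_PARTITIONS):
        for config in np.ndindex(2, 2, 2, 2):
            weight = 1.0
            for block in partition:
                alleles = {config[c] for c in block}
                if len(alleles) != 1:
                    weight = 0.0
                    break
                weight *= f if alleles.pop() == 1 else 1.0 - f
            g = config[0] + config[1]
            h = config[2] + config[3]
            out[m, g, h] += weight
    return out


def oracle_site_emissions(gl_a: np.ndarray, gl_b: np.ndarray, f: float) -> np.ndarray:
    """Naive triple-loop emission computation for a single site."""
    prior = oracle_pair_prior(f)
    e = np.zeros(9)
    for m in range(9):
        for g in range(3):
            for h in range(3):
                e[m] += gl_a[g] * gl_b[h] * prior[m, g, h]
    return e


def one_hot_gl(genotype: int) -> np.ndarray:
    gl = np.zeros(3)
    gl[genotype] = 1.0
    return gl


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_117)


@pytest.fixture(scope="session")
def cousin_dataset():
    """One Scenario-1 replicate at moderate size, reused across tests."""
    from glrelate import SimParams, simulate_scenario
    from glrelate.core import site_emissions

    gls, freqs, pair, genomes = simulate_scenario(
        1, SimParams(n_sites=20_000, depth=8, error=0.001, maf=0.1, seed=11)
    )
    emissions = site_emissions(gls[pair[0]], gls[pair[1]], freqs)
    return {"gls": gls, "freqs": freqs, "pair": pair,
            "genomes": genomes, "emissions": emissions}
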