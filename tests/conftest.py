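import numpy as np
import pytest

from cgtherm import fixtures, md_engine, system_builder
from cgtherm.forcefield.parameters import PairParams
from cgtherm.system_builder import ChainTopology, ParticleSystem


@pytest.fixture(scope="session")
def neutral_ff():
    return fixtures.make_param_set(seed=3, style="neutral")


@pytest.fixture(scope="session")
def attractive_ff():
    return fixtures.make_param_set(seed=11, style="attractive", charges=False, yukawa_cutoff=20.0)


@pytest.fixture(scope="session")
def repulsive_ff():
    return fixtures.make_param_set(seed=11, style="repulsive_at_high_T", charges=False, yukawa_cutoff=20.0)


@pytest.fixture(scope="session")
def soft_ff():
    """Neutral set with mu = nu = 1 everywhere (soft walls for NVE checks)."""
    ff = fixtures.make_param_set(seed=3, style="neutral")
    ff.pairs = {
        k: PairParams(sigma_ij=p.sigma_ij, epsilon_ij_ref=p.epsilon_ij_ref,
                      mu_ij=1.0, nu_ij=1.0)
        for k, p in ff.pairs.items()
    }
    return ff


def make_two_chain_system(ff, seq="ACDEFGHIKL", seed=1):
    s1 = system_builder.build_single_chain(seq, ff, seed=seed)
    pos2 = s1.positions + np.array([12.0, 5.0, 3.0])
    n = len(seq)
    chains = [
        ChainTopology(seq, 0, ff.bond.r0, ff.bond.k),
        ChainTopology(seq, n, ff.bond.r0, ff.bond.k),
    ]
    system = ParticleSystem(
        np.vstack([s1.positions, pos2]), np.zeros((2 * n, 3)), chains, s1.box
    )
    system.wrap()
    md_engine.minimize(system, 300.0, ff, n_steps=200)
    return system


@pytest.fixture()
def two_chain_system(neutral_ff):
    return make_two_chain_system(neutral_ff)


def make_multichain_gas(ff, n_chains=8, seq="ACDEFGHIKLMNPQRSTVWY", box_edge=160.0, seed=0):
    """Dilute gas of chains in a box that admits a >= 3x3x3 cell grid."""
    rng = np.random.default_rng(seed)
    chains, blocks = [], []
    n = len(seq)
    for k in range(n_chains):
        s = system_builder.build_single_chain(seq, ff, seed=seed + k)
        blocks.append(
            s.positions - s.positions.mean(axis=0)
            + rng.uniform(0.15 * box_edge, 0.85 * box_edge, 3)
        )
        chains.append(ChainTopology(seq, k * n, ff.bond.r0, ff.bond.k))
    system = ParticleSystem(
        np.vstack(blocks), np.zeros((n_chains * n, 3)), chains,
        np.array([box_edge] * 3),
    )
    system.wrap()
    return system
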