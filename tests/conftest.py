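import numpy as np
import pytest

from pepbinder.structures import Chain, ComplexPair, Residue, Structure

ATOM_NAMES = ("N", "CA", "C", "O", "CB")


def random_residue(rng, index, center=None, spread=3.0, plddt=None):
    center = rng.uniform(-10, 10, 3) if center is None else np.asarray(center, float)
    atoms = {name: center + rng.uniform(-spread, spread, 3) for name in ATOM_NAMES}
    return Residue(
        index=index,
        aa=str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))),
        atoms=atoms,
        plddt=float(rng.uniform(30, 99)) if plddt is None else plddt,
    )


def random_chain(rng, chain_id, length, origin=(0, 0, 0), step=4.0):
    origin = np.asarray(origin, float)
    residues = [
        random_residue(rng, i + 1, center=origin + np.array([0, 0, step * i]))
        for i in range(length)
    ]
    return Chain(id=chain_id, residues=residues)


def random_complex(rng, receptor_len=8, binder_len=5, separation=6.0):
    receptor = random_chain(rng, "A", receptor_len)
    binder = random_chain(rng, "B", binder_len, origin=(separation, 0, 0))
    return ComplexPair(Structure([receptor, binder]), "A", "B")


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    return rot, rng.uniform(-20, 20, 3)


def transform_complex(pair, rot, trans):
    chains = []
    for chain in pair.structure.chains:
        residues = [
            Residue(
                index=r.index,
                aa=r.aa,
                atoms={n: rot @ xyz + trans for n, xyz in r.atoms.items()},
                plddt=r.plddt,
            )
            for r in chain.residues
        ]
        chains.append(Chain(id=chain.id, residues=residues))
    return ComplexPair(Structure(chains), pair.receptor_chain, pair.binder_chain)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ideal_pair():
    from pepbinder.synthetic import FixtureSpec, make_ideal_complex

    return make_ideal_complex(
        FixtureSpec(receptor_length=15, binder_length=8, n_contacts=5,
                    displacement=(3.0, 4.0, 0.0), rotation_deg=30.0, rng_seed=7)
    )
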