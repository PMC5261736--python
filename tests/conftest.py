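import numpy as np
import pytest

import dockpot as dp


@pytest.fixture(scope="session")
def bead_table4():
    return dp.pseudo_bead_table(4)


@pytest.fixture(scope="session")
def small_spec():
    return dp.FixtureSpec(n_complexes=2, atoms_per_partner=24,
                          decoys_per_complex=60, seed=11)


@pytest.fixture(scope="session")
def native(small_spec):
    return dp.make_toy_complex(small_spec, np.random.default_rng(11))


@pytest.fixture(scope="session")
def decoy_set(native, small_spec):
    decoys, tiers = dp.make_decoy_set(native, small_spec,
                                      np.random.default_rng(12))
    return decoys, tiers


def bead_structure(rec_coords, lig_coords, rec_types=None, lig_types=None,
                   n_types=4):
    """Hand-built bead complex: one single-atom residue per bead."""
    table = dp.pseudo_bead_table(n_types)
    rec_coords = np.asarray(rec_coords, dtype=float).reshape(-1, 3)
    lig_coords = np.asarray(lig_coords, dtype=float).reshape(-1, 3)
    if rec_types is None:
        rec_types = np.zeros(len(rec_coords), dtype=int)
    if lig_types is None:
        lig_types = np.zeros(len(lig_coords), dtype=int)

    def part(coords, types, chain):
        n = len(coords)
        return dp.AtomSet(
            coords=coords,
            atom_names=np.full(n, "CA"),
            res_names=np.array([f"P{t:02d}" for t in types]),
            chain_ids=np.full(n, chain),
            res_seq=np.arange(1, n + 1),
            icodes=np.full(n, ""),
            elements=np.full(n, "P"),
            heavy=np.ones(n, dtype=bool),
            types=np.asarray(types, dtype=int),
        )

    return dp.TypedStructure(receptor=part(rec_coords, rec_types, "A"),
                             ligand=part(lig_coords, lig_types, "B"),
                             table=table)
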