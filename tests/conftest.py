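import numpy as np
import pytest

from rnpmd import synthetic as syn
from rnpmd.io import AtomRecord, Ensemble, Frame


@pytest.fixture
def toy_ensemble():
    """5-atom, 2-chain, 2-frame ensemble with hand-placed coordinates."""
    topology = [
        AtomRecord(0, "N", "N", 1, "ALA", "A"),
        AtomRecord(1, "CA", "C", 1, "ALA", "A"),
        AtomRecord(2, "C", "C", 1, "ALA", "A"),
        AtomRecord(3, "P", "P", 28, "U", "R"),
        AtomRecord(4, "N3", "N", 28, "U", "R"),
    ]
    c0 = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.15, 0.0, 0.0],
            [0.25, 0.1, 0.0],
            [0.0, 0.0, 0.3],
            [0.1, 0.0, 0.3],
        ]
    )
    c1 = c0 + np.array([0.05, 0.0, 0.0])
    return Ensemble(
        topology=topology,
        frames=[Frame(c0, 0), Frame(c1, 1)],
        label="toy",
    )


@pytest.fixture
def planted_complex():
    plan = syn.InteractionPlan(
        hbonds=[syn.PlannedHBond("hb1", 0.70), syn.PlannedHBond("hb2", 0.40)],
        stacks=[syn.PlannedStack("s1", 0.35, 10.0)],
    )
    ens, truth = syn.make_complex_ensemble(100, plan, seed=11)
    return ens, truth


def two_conformer_noe_fixture(seed=0):
    """100 frames: 10 good frames around 2 planted conformers satisfy every
    restraint; 90 inflated frames violate at least 3 of the 4 restraints."""
    from rnpmd.noe import NOERestraint

    noise = 0.01
    mix, truth = syn.make_cluster_mixture(2, 10, separation=1.0, noise=noise, seed=seed)
    good = mix.coordinate_array()
    topology = mix.topology
    frames = [Frame(good[f], f) for f in range(10)]
    for f in range(10, 100):
        frames.append(Frame(good[f % 10] * 2.5, f))
    ens = Ensemble(topology=topology, frames=frames, label="noe-mixture")
    restraints = []
    for a, b in [(0, 5), (3, 11), (7, 17), (2, 20)]:
        ra, rb = topology[a], topology[b]
        d_good = max(np.linalg.norm(good[f, a] - good[f, b]) for f in range(10))
        restraints.append(
            NOERestraint(
                group1=((ra.chain_id, ra.residue_index, ra.atom_name),),
                group2=((rb.chain_id, rb.residue_index, rb.atom_name),),
                r_noe=d_good + 5 * noise,
            )
        )
    return ens, restraints, truth, noise


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
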