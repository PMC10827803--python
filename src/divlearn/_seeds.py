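"""Named, independent random streams derived from one master seed.

Every stochastic component of a run (each class landscape, the class
assignment, the node shuffle, the initial solutions, the dynamics, the
network) draws from its own stream so that, e.g., changing the number of
skill classes does not perturb the network realization.  Streams are keyed
by small integer tags appended to the master seed's entropy.
"""

from __future__ import annotations

import numpy as np

# stream tags (stable; part of the reproducibility contract)
LANDSCAPE = 0  # + class index
CLASS_ASSIGN = 1
NODE_SHUFFLE = 2
INIT_SOLUTIONS = 3
DYNAMICS = 4
NETWORK = 5
POPULATION = 6
TARGET = 7  # acceptance-script sub-experiments


def seed_sequence(master: int, *key: int) -> np.random.SeedSequence:
    entropy = (int(master),) + tuple(int(k) for k in key)
    return np.random.SeedSequence(entropy)


def rng(master: int, *key: int) -> np.random.Generator:
    """A Generator on the stream (master, *key)."""
    return np.random.default_rng(seed_sequence(master, *key))


def child_seed(master: int, *key: int) -> int:
    """A plain integer sub-seed (< 2**31) for APIs that take an int seed."""
    return int(seed_sequence(master, *key).generate_state(1)[0] % (2**31))
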