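"""Deterministic seed derivation.

Every stream in the package is a pure function of a user-supplied master seed
plus a structural coordinate (tree index, iteration number, target gene id).
Tree seeds in particular depend only on (master_seed, tree_index), never on
how trees are partitioned over workers: that is the contract that makes a
forest reproducible for any worker count.
"""

import hashlib

import numpy as np

# stream tags keep the (master_seed, k) spaces of different consumers disjoint
_TREE, _ITERATION, _TARGET, _GENERIC = 0, 1, 2, 3


def _derive(master_seed: int, tag: int, *coords: int, dtype=np.uint64) -> int:
    ss = np.random.SeedSequence([int(master_seed), tag, *[int(c) for c in coords]])
    return int(ss.generate_state(1, dtype)[0])


def tree_seed(master_seed: int, tree_index: int) -> int:
    """64-bit seed for one tree; pure function of (master_seed, tree_index)."""
    return _derive(master_seed, _TREE, tree_index)


def iteration_seed(master_seed: int, iteration: int) -> int:
    """Per-iteration forest master seed (31-bit, hash-combined)."""
    return _derive(master_seed, _ITERATION, iteration, dtype=np.uint32) % (2**31)


def target_seed(master_seed: int, target_id: str) -> int:
    """Per-target master seed keyed by a stable hash of the gene id.

    Keying by id (not column position) makes leave-one-out runs invariant
    under any reordering of the input genes.
    """
    digest = hashlib.md5(str(target_id).encode("utf-8")).digest()
    fingerprint = int.from_bytes(digest[:8], "little")
    return _derive(master_seed, _TARGET, fingerprint, dtype=np.uint32) % (2**31)


def generic_seed(master_seed: int, label: int) -> int:
    return _derive(master_seed, _GENERIC, label, dtype=np.uint32) % (2**31)
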