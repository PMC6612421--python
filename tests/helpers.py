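"""Shared helpers for the test suite (independent of the package's aligners)."""

import numpy as np


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mutate_nt(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute exactly round(divergence * len) positions to a different base."""
    s = list(seq)
    idx = rng.choice(len(s), size=int(round(divergence * len(s))), replace=False)
    for i in idx:
        s[i] = "ACGT"[("ACGT".index(s[i]) + 1 + int(rng.integers(3))) % 4]
    return "".join(s)


def mutate_aa(rng: np.random.Generator, seq: str, divergence: float) -> str:
    aa20 = "ACDEFGHIKLMNPQRSTVWY"
    s = list(seq)
    idx = rng.choice(len(s), size=int(round(divergence * len(s))), replace=False)
    for i in idx:
        s[i] = aa20[(aa20.index(s[i]) + 1 + int(rng.integers(19))) % 20]
    return "".join(s)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
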