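"""Low-level nucleotide sequence helpers shared across modules.

Sequences are stored as uppercase DNA strings (U is normalized to T on
input; display layers may relabel T as U for RNA-derived reads).
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID = set("ACGTN")

# Byte codes chosen so that an N in a read (0) never equals an N in a
# reference (1): ambiguous bases must not count as matches.
_READ_N_CODE = 0
_REF_N_CODE = 1


def normalize(seq: str) -> str:
    """Uppercase and map U->T. Raises ValueError on non-ACGTUN symbols."""
    s = seq.upper().replace("U", "T")
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        raise ValueError(f"non-ACGTUN symbols {bad!r} in sequence")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode_ref(seq: str) -> np.ndarray:
    """Encode a reference contig as uint8, with N remapped so it never matches."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = _REF_N_CODE
    return arr


def encode_read(seq: str) -> np.ndarray:
    """Encode a read as uint8, with N remapped so it never matches."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = _READ_N_CODE
    return arr


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform-random DNA sequence of the given length."""
    if length <= 0:
        raise ValueError(f"sequence length must be positive, got {length}")
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(seq: str, p_sub: float, rng: np.random.Generator,
           protected: list[tuple[int, int]] | None = None) -> str:
    """Substitute each site with probability ``p_sub`` to a different base.

    ``protected`` intervals (0-based half-open) are left untouched; indels
    are never introduced (independent-sites, uncorrected-divergence model).
    """
    if not 0.0 <= p_sub <= 1.0:
        raise ValueError(f"substitution probability {p_sub} outside [0, 1]")
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < p_sub
    if protected:
        for start, end in protected:
            hit[start:end] = False
    idx = np.flatnonzero(hit)
    if idx.size:
        bases = np.array(list("ACGT"))
        # draw an offset 1-3 from the current base, guaranteeing a change
        current = np.searchsorted(bases, chars[idx])
        new = (current + rng.integers(1, 4, size=idx.size)) % 4
        chars[idx] = bases[new]
    return "".join(chars)
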