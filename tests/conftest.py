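"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive per-position algorithms, distinct
from the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

_VALID = set("ACGT")
_STOPS = {"TAA", "TAG", "TGA"}
_RC = str.maketrans("ACGTN", "TGCAN")


def oracle_is_primitive(unit: str) -> bool:
    """Doubling trick: u is non-primitive iff u occurs inside (u+u)[1:-1]."""
    return unit not in (unit + unit)[1:-1]


def brute_force_ssrs(
    seq: str,
    min_units: int = 5,
    unit_lengths=range(2, 7),
    partial_extension: bool = True,
):
    """Try every (start, primitive unit) pair and extend maximally."""
    found = {}
    n = len(seq)
    for k in unit_lengths:
        for start in range(0, n - k):
            unit = seq[start : start + k]
            if any(b not in _VALID for b in unit):
                continue
            if not oracle_is_primitive(unit):
                continue
            e = start + k
            while e < n and seq[e] in _VALID and seq[e] == seq[e - k]:
                e += 1
            s = start
            while s > 0 and seq[s - 1] in _VALID and seq[s - 1] == seq[s - 1 + k]:
                s -= 1
            span = e - s
            count = span // k
            if count < min_units:
                continue
            end = e if partial_extension else s + count * k
            found[(s, end, k)] = (s, end, k, seq[s : s + k], count)
    return sorted(found.values())


def brute_force_orfs(seq: str, min_orf_nt: int = 300, strands=("+", "-")):
    """Walk every (strand, ATG) pair codon by codon to the first stop."""
    n = len(seq)
    out = set()
    for strand in strands:
        s = seq if strand == "+" else seq.translate(_RC)[::-1]
        for p in range(0, n - 2):
            if s[p : p + 3] != "ATG":
                continue
            q = p
            while q + 3 <= n and s[q : q + 3] not in _STOPS:
                q += 3
            if q + 3 > n:
                continue
            end = q + 3
            if end - p < min_orf_nt:
                continue
            if strand == "+":
                out.add((p, end, "+", p % 3))
            else:
                out.add((n - end, n - p, "-", p % 3))
    return sorted(out)


def random_sequence(rng: np.random.Generator, length: int, n_rate: float = 0.0) -> str:
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=length)]
    if n_rate > 0:
        mask = rng.random(length) < n_rate
        seq[mask] = "N"
    return "".join(seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20100712)
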