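"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by brute force —
exhaustive structure enumeration, position-by-position substring scanning,
assignment search over all permutations — so the dynamic programs and
optimized scanners in the package are checked against a second, independent
route.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest

from draictools.structure import (
    GAS_CONSTANT_KCAL,
    EnergyModel,
    shape_pseudo_energy,
)
from draictools.synthetic import SimConfig, build_synthetic_locus


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def locus(default_config):
    return build_synthetic_locus(default_config)


# ---------------------------------------------------------------------------
# Oracle: exhaustive Boltzmann enumeration of pair probabilities
# ---------------------------------------------------------------------------

def enumerate_pair_probabilities(
    seq: str,
    reactivity=None,
    model: EnergyModel | None = None,
    temperature: float = 310.15,
) -> np.ndarray:
    """Pair probabilities by enumerating every pseudoknot-free structure.

    Energies follow the same model as the implementation (pair energies,
    stacking bonus, per-paired-nucleotide SHAPE pseudo-energy) but the sum
    over structures is explicit, not a dynamic program.
    """
    model = model or EnergyModel()
    n = len(seq)
    kt = GAS_CONSTANT_KCAL * temperature
    if reactivity is None:
        dg = np.zeros(n)
    else:
        dg = np.asarray(
            shape_pseudo_energy(np.asarray(reactivity, dtype=float))
        )
    minloop = model.min_hairpin_loop

    @lru_cache(maxsize=None)
    def structs(a: int, b: int):
        if b - a <= 0:
            return (frozenset(),)
        out = list(structs(a + 1, b))
        for k in range(a + minloop + 1, b):
            if model.pair_energy(seq[a], seq[k]) is not None:
                for left in structs(a + 1, k):
                    for right in structs(k + 1, b):
                        out.append(left | right | {(a, k)})
        return tuple(out)

    Z = 0.0
    P = np.zeros((n, n))
    for S in structs(0, n):
        e = sum(model.pair_energy(seq[i], seq[j]) + dg[i] + dg[j]
                for i, j in S)
        e += model.stack_bonus * sum((i + 1, j - 1) in S for i, j in S)
        w = math.exp(-e / kt)
        Z += w
        for i, j in S:
            P[i, j] += w
    P /= Z
    return P + P.T


@pytest.fixture(scope="session")
def enum_pair_probs():
    return enumerate_pair_probabilities


# ---------------------------------------------------------------------------
# Oracle: position-by-position substring scan
# ---------------------------------------------------------------------------

def brute_force_probe_count(
    reads, probe: str, max_mismatches: int = 0, strand: str = "both"
) -> int:
    """Count reads containing the probe by scanning every offset explicitly."""
    from draictools.junctions import reverse_complement

    targets = [probe]
    if strand == "both":
        targets.append(reverse_complement(probe))
    m = len(probe)
    n_hit = 0
    for read in reads:
        s = str(read.seq) if hasattr(read, "seq") else str(read)
        hit = False
        for t in targets:
            for off in range(len(s) - m + 1):
                mm = sum(1 for a, b in zip(s[off:off + m], t) if a != b)
                if mm <= max_mismatches:
                    hit = True
                    break
            if hit:
                break
        n_hit += hit
    return n_hit


@pytest.fixture(scope="session")
def probe_scan_oracle():
    return brute_force_probe_count


# ---------------------------------------------------------------------------
# Oracle: exhaustive assignment search
# ---------------------------------------------------------------------------

def brute_force_matching(case_values: dict, control_pool: dict) -> float:
    """Minimum total |CPM difference| over every one-to-one assignment."""
    case_ids = sorted(case_values)
    pool_ids = sorted(control_pool)
    best = math.inf
    for perm in itertools.permutations(pool_ids, len(case_ids)):
        cost = sum(
            abs(case_values[c] - control_pool[p])
            for c, p in zip(case_ids, perm)
        )
        best = min(best, cost)
    return best


@pytest.fixture(scope="session")
def matching_oracle():
    return brute_force_matching


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
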