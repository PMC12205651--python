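"""SHAPE reactivities and restrained RNA secondary-structure modeling.

The chain implemented here converts two-channel mutational-profiling counts
into per-nucleotide SHAPE reactivities, normalizes them, and folds the RNA
under pseudo-free-energy restraints:

1. raw reactivity = modified-channel mutation rate - untreated-channel rate
   (low-depth positions become no-data);
2. normalization by the 2%/8% rule: the top 2% of defined values are treated
   as outliers, the mean of the next 8% is the normalization factor;
3. a per-nucleotide pseudo-energy dG(i) = m * ln(S_i + 1) + b is added to
   the folding energy for every paired nucleotide, steering the Boltzmann
   ensemble toward structures that leave reactive nucleotides unpaired;
4. an inside-outside dynamic program over all pseudoknot-free structures
   (minimum hairpin loop 3) yields base-pair probabilities P(i, j).

The energy model is deliberately compact and configurable — pair energies
for GC/AU/GU plus a helix-stacking bonus — rather than a full
nearest-neighbor parameterization; correctness is defined against exhaustive
enumeration of the same model, and pairing-probability classes (> 0.50 /
0.75 / 0.8 / 0.95) plus "well-determined" helix calls (every pair > 0.95)
are computed from the resulting ensemble, matching how probed structures
are reported in the SHAPE-MaP literature.

Coordinates are 1-based inclusive transcript positions throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ReactivityProfile",
    "PseudoEnergyParams",
    "EnergyModel",
    "PairProbMatrix",
    "WellDeterminedRegion",
    "FusedConstruct",
    "raw_reactivity",
    "normalize_reactivity",
    "shape_pseudo_energy",
    "partition_pair_probabilities",
    "classify_pairing_level",
    "classify_pairing_levels",
    "call_well_determined_regions",
    "extract_fused_construct",
    "predict_structure",
]

GAS_CONSTANT_KCAL = 0.0019872041  # kcal/(mol*K)

NO_DATA = float("nan")


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-nucleotide SHAPE reactivities; NaN marks no-data positions."""

    positions: tuple[int, ...]
    bases: tuple[str, ...]
    raw: tuple[float, ...]
    normalized: tuple[float, ...] | None = None
    norm_factor: float | None = None

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "position": self.positions,
            "base": self.bases,
            "raw": self.raw,
        }
        if self.normalized is not None:
            data["normalized"] = self.normalized
        return pd.DataFrame(data)


@dataclass(frozen=True)
class PseudoEnergyParams:
    """Slope/intercept of the SHAPE pseudo-energy dG = m*ln(S+1) + b (kcal/mol).

    The defaults (m=1.8, b=-0.6) are the values in common use for
    SHAPE-restrained folding; they are configuration, not fitted constants.
    """

    m: float = 1.8
    b: float = -0.6

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("pseudo-energy slope m must be > 0")


@dataclass(frozen=True)
class EnergyModel:
    """Compact base-pairing energy model (kcal/mol).

    ``pair_energies`` maps unordered canonical pairs to stabilization
    energies; ``stack_bonus`` is added once per directly stacked pair
    ((i, j) on (i+1, j-1)).  ``stack_bonus`` must be <= 0 so that all
    Boltzmann decomposition terms stay nonnegative.
    """

    pair_energies: dict = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    stack_bonus: float = -1.0
    min_hairpin_loop: int = 3
    name: str = "compact-v1"

    def __post_init__(self) -> None:
        if self.stack_bonus > 0:
            raise ValueError("stack_bonus must be <= 0")
        if self.min_hairpin_loop < 0:
            raise ValueError("min_hairpin_loop must be >= 0")

    def pair_energy(self, a: str, b: str) -> float | None:
        """Energy of pairing bases a and b, or None if non-canonical."""
        for key in (a + b, b + a):
            if key in self.pair_energies:
                return self.pair_energies[key]
        return None


@dataclass(frozen=True)
class PairProbMatrix:
    """Symmetric base-pair probability matrix over a sequence."""

    matrix: np.ndarray
    sequence: str
    energy_model_id: str

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.sequence)
        if m.shape != (n, n):
            raise ValueError("matrix shape must match sequence length")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("pair probability matrix must be symmetric")

    def prob(self, i: int, j: int) -> float:
        """P(i, j) for 1-based positions."""
        return float(self.matrix[i - 1, j - 1])

    def to_triplets(self) -> pd.DataFrame:
        """Upper-triangle nonzero entries as (i, j, probability), 1-based."""
        i, j = np.nonzero(np.triu(self.matrix))
        return pd.DataFrame(
            {"i": i + 1, "j": j + 1, "probability": self.matrix[i, j]}
        )


@dataclass(frozen=True)
class WellDeterminedRegion:
    """A helix whose every pair exceeds the probability threshold."""

    pairs: tuple[tuple[int, int], ...]
    min_probability: float
    span: tuple[int, int]


@dataclass(frozen=True)
class FusedConstruct:
    """Concatenation of transcript intervals (1-based inclusive)."""

    intervals: tuple[tuple[int, int], ...]
    sequence: str
    linker: str = ""


# ---------------------------------------------------------------------------
# Reactivity
# ---------------------------------------------------------------------------

def raw_reactivity(
    counts: pd.DataFrame, min_depth: int = 1000
) -> ReactivityProfile:
    """Raw SHAPE reactivity: modified mutation rate minus untreated rate.

    ``counts`` needs columns position, base, mod_mutations, mod_reads,
    untr_mutations, untr_reads.  Positions where either channel has fewer
    than ``min_depth`` reads are no-data (NaN).  Negative differences are
    retained — they carry information about the untreated background.
    """
    required = {
        "position", "base", "mod_mutations", "mod_reads",
        "untr_mutations", "untr_reads",
    }
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"mutation-count table missing columns: {sorted(missing)}")
    for chan in ("mod", "untr"):
        if (counts[f"{chan}_mutations"] > counts[f"{chan}_reads"]).any():
            raise ValueError(f"{chan} channel has mutations > reads")

    mod_reads = counts["mod_reads"].to_numpy(dtype=float)
    untr_reads = counts["untr_reads"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (
            counts["mod_mutations"].to_numpy(dtype=float) / mod_reads
            - counts["untr_mutations"].to_numpy(dtype=float) / untr_reads
        )
    low = (mod_reads < min_depth) | (untr_reads < min_depth)
    raw = np.where(low, NO_DATA, raw)
    return ReactivityProfile(
        positions=tuple(int(p) for p in counts["position"]),
        bases=tuple(str(b) for b in counts["base"]),
        raw=tuple(float(x) for x in raw),
    )


def normalize_reactivity(profile: ReactivityProfile) -> ReactivityProfile:
    """Normalize a raw profile by the 2%/8% rule.

    The top 2% of defined raw values are excluded as outliers and the mean
    of the next 8% is the normalization factor; every defined value is
    divided by it.  Requires at least 50 defined positions.
    """
    raw = np.asarray(profile.raw, dtype=float)
    defined = raw[~np.isnan(raw)]
    n = len(defined)
    if n < 50:
        raise ValueError(f"need >= 50 positions with data to normalize, got {n}")
    desc = np.sort(defined)[::-1]
    n_excl = int(n * 0.02)
    n_top = int(n * 0.10)
    factor = float(np.mean(desc[n_excl:n_top]))
    if factor <= 0:
        raise ValueError(f"normalization factor must be positive, got {factor}")
    return ReactivityProfile(
        positions=profile.positions,
        bases=profile.bases,
        raw=profile.raw,
        normalized=tuple(float(x) for x in raw / factor),
        norm_factor=factor,
    )


def shape_pseudo_energy(
    reactivity, params: PseudoEnergyParams = PseudoEnergyParams()
):
    """Per-nucleotide pseudo-energy dG = m*ln(S+1) + b (kcal/mol).

    Negative reactivities are clamped to 0 before the log; no-data (NaN)
    contributes zero pseudo-energy.  Accepts a scalar or an array and is
    added once per paired nucleotide during folding.
    """
    s = np.asarray(reactivity, dtype=float)
    nodata = np.isnan(s)
    dg = params.m * np.log1p(np.clip(s, 0.0, None)) + params.b
    dg = np.where(nodata, 0.0, dg)
    if dg.ndim == 0:
        return float(dg)
    return dg


# ---------------------------------------------------------------------------
# Partition function
# ---------------------------------------------------------------------------

def _pair_weight_matrix(
    seq: str,
    dg: np.ndarray,
    model: EnergyModel,
    kt: float,
    scale: float,
) -> np.ndarray:
    """w[i, j] = scale^2 * exp(-(E_pair + dG_i + dG_j)/kT) for allowed pairs."""
    n = len(seq)
    w = np.zeros((n, n))
    minloop = model.min_hairpin_loop
    for i in range(n):
        for j in range(i + minloop + 1, n):
            e = model.pair_energy(seq[i], seq[j])
            if e is None:
                continue
            w[i, j] = scale * scale * math.exp(-(e + dg[i] + dg[j]) / kt)
    return w


def _mfe(seq: str, dg: np.ndarray, model: EnergyModel, kt: float) -> float:
    """Minimum free energy under the same model (used to pick the scale)."""
    n = len(seq)
    minloop = model.min_hairpin_loop
    epair = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + minloop + 1, n):
            e = model.pair_energy(seq[i], seq[j])
            if e is not None:
                epair[i, j] = e + dg[i] + dg[j]

    E = np.zeros((n + 1, n + 1))       # half-open E[a, b] over s[a:b]
    Eb = np.full((n, n), np.inf)
    for span in range(1, n + 1):
        for a in range(0, n - span + 1):
            b = a + span
            j = b - 1
            if j - a > minloop and np.isfinite(epair[a, j]):
                interior = E[a + 1, j]
                if j - 1 - (a + 1) > minloop and np.isfinite(Eb[a + 1, j - 1]):
                    interior = min(
                        interior, Eb[a + 1, j - 1] + model.stack_bonus
                    )
                Eb[a, j] = epair[a, j] + interior
            best = E[a + 1, b]
            ks = np.arange(a + minloop + 1, b)
            if len(ks):
                cand = Eb[a, ks] + E[ks + 1, b]
                if len(cand):
                    best = min(best, cand.min())
            E[a, b] = best
    return float(E[0, n])


def partition_pair_probabilities(
    sequence: str,
    reactivity: Sequence[float] | None = None,
    energy_model: EnergyModel | None = None,
    pseudo_params: PseudoEnergyParams = PseudoEnergyParams(),
    temperature: float = 310.15,
    max_length: int = 2000,
) -> PairProbMatrix:
    """Base-pair probabilities from an inside-outside partition function.

    Sums Boltzmann weights over every pseudoknot-free structure with hairpin
    loops of at least ``min_hairpin_loop`` nucleotides.  A structure's energy
    is the sum of its pair energies, helix-stacking bonuses, and — when a
    reactivity profile is supplied — SHAPE pseudo-energies for each paired
    nucleotide.  P(i, j) is the probability that (i, j) is paired in the
    ensemble.

    ``reactivity`` must align with the sequence (NaN = no data).  T is read
    as U; any other non-ACGU character raises.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n < 5:
        raise ValueError("sequence must be at least 5 nt")
    if set(seq) - set("ACGU"):
        raise ValueError(
            f"invalid characters in sequence: {sorted(set(seq) - set('ACGU'))}"
        )
    if n > max_length:
        raise ValueError(
            f"sequence of {n} nt exceeds max_length={max_length}; fold in windows"
        )
    model = energy_model if energy_model is not None else EnergyModel()
    if reactivity is None:
        dg = np.zeros(n)
    else:
        if len(reactivity) != n:
            raise ValueError("reactivity length must match sequence length")
        dg = np.asarray(
            shape_pseudo_energy(np.asarray(reactivity, float), pseudo_params)
        )

    kt = GAS_CONSTANT_KCAL * temperature
    minloop = model.min_hairpin_loop

    # Per-nucleotide rescaling keeps the partition function within float64
    # range; exact in exact arithmetic, standard McCaskill-style trick.
    e_mfe = _mfe(seq, dg, model, kt)
    q = math.exp(e_mfe / (kt * n)) / 1.4 if n > 60 else 1.0

    wp = _pair_weight_matrix(seq, dg, model, kt, q)
    ws = math.exp(-model.stack_bonus / kt)

    Z = np.ones((n + 2, n + 2))        # half-open Z[a, b] over s[a:b]
    Zb = np.zeros((n, n))              # closed pair (i, j)
    for span in range(1, n + 1):
        for a in range(0, n - span + 1):
            b = a + span
            j = b - 1
            if j - a > minloop and wp[a, j] > 0:
                inner = Z[a + 1, j]
                if j - a >= minloop + 3:
                    inner = inner + (ws - 1.0) * Zb[a + 1, j - 1]
                Zb[a, j] = wp[a, j] * inner
            total = q * Z[a + 1, b]
            ks = np.arange(a + minloop + 1, b)
            if len(ks):
                total += float(Zb[a, ks] @ Z[ks + 1, b])
            Z[a, b] = total

    z_total = Z[0, n]
    if not np.isfinite(z_total) or z_total <= 0:
        raise FloatingPointError("partition function under/overflowed")

    O = np.zeros((n + 2, n + 2))       # outside values of Z nodes
    Ob = np.zeros((n, n))              # outside values of Zb nodes
    O[0, n] = 1.0
    for span in range(n, 0, -1):
        for a in range(0, n - span + 1):
            b = a + span
            v = O[a, b]
            if v != 0.0:
                O[a + 1, b] += q * v
                ks = np.arange(a + minloop + 1, b)
                if len(ks):
                    Ob[a, ks] += v * Z[ks + 1, b]
                    np.add.at(O, (ks + 1, b), v * Zb[a, ks])
            # Zb[a, b-1] spans the same width; propagate after Z[a, b]
            j = b - 1
            vb = Ob[a, j]
            if vb != 0.0 and wp[a, j] > 0 and j - a > minloop:
                O[a + 1, j] += wp[a, j] * vb
                if j - a >= minloop + 3:
                    Ob[a + 1, j - 1] += wp[a, j] * (ws - 1.0) * vb

    P = Zb * Ob / z_total
    P = np.clip(P, 0.0, 1.0)
    P = P + P.T
    return PairProbMatrix(matrix=P, sequence=seq, energy_model_id=model.name)


# ---------------------------------------------------------------------------
# Ensemble interpretation
# ---------------------------------------------------------------------------

_LEVELS = ((0.95, ">0.95"), (0.8, ">0.8"), (0.75, ">0.75"), (0.50, ">0.50"))


def classify_pairing_level(p: float) -> str:
    """Highest strictly exceeded pairing-probability threshold class."""
    for cut, label in _LEVELS:
        if p > cut:
            return label
    return "<=0.5"


def classify_pairing_levels(pp: PairProbMatrix) -> pd.DataFrame:
    """Classify every nonzero pair into probability-threshold classes.

    Returns (i, j, probability, level) rows for the upper triangle, the
    display convention of circle plots with rings at 0.50/0.75/0.8/0.95.
    """
    df = pp.to_triplets()
    df["level"] = [classify_pairing_level(p) for p in df["probability"]]
    return df


def call_well_determined_regions(
    pp: PairProbMatrix, threshold: float = 0.95, min_helix: int = 3
) -> list[WellDeterminedRegion]:
    """Find helices whose every pair has probability above ``threshold``.

    A region is a maximal run of consecutive pairs (i, j), (i+1, j-1), ...
    all with P > threshold and at least ``min_helix`` pairs long.  Regions
    are returned sorted by 5' coordinate.
    """
    P = pp.matrix
    n = P.shape[0]
    regions = []
    above = P > threshold
    for i in range(n):
        for j in range(i + 1, n):
            if not above[i, j]:
                continue
            if i > 0 and j < n - 1 and above[i - 1, j + 1]:
                continue  # interior of a run already walked
            run = []
            a, b = i, j
            while a < b and above[a, b]:
                run.append((a + 1, b + 1))
                a, b = a + 1, b - 1
            if len(run) >= min_helix:
                regions.append(
                    WellDeterminedRegion(
                        pairs=tuple(run),
                        min_probability=float(
                            min(P[x - 1, y - 1] for x, y in run)
                        ),
                        span=(run[0][0], run[0][1]),
                    )
                )
    regions.sort(key=lambda r: r.span[0])
    return regions


def extract_fused_construct(
    transcript: str,
    intervals: Sequence[tuple[int, int]],
    linker: str = "",
) -> FusedConstruct:
    """Concatenate 1-based inclusive transcript intervals into one construct.

    This is how a fused hairpin construct (e.g. strand A at 705–722 joined
    to strand B at 741–758, 36 nt total) is built from a transcript.
    Intervals must be in bounds, ascending, and non-overlapping.
    """
    n = len(transcript)
    prev_end = 0
    parts = []
    for lo, hi in intervals:
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"interval ({lo}, {hi}) outside transcript 1..{n}")
        if lo <= prev_end:
            raise ValueError(
                f"interval ({lo}, {hi}) overlaps or is out of order with the "
                "previous interval"
            )
        parts.append(transcript[lo - 1:hi])
        prev_end = hi
    return FusedConstruct(
        intervals=tuple((int(lo), int(hi)) for lo, hi in intervals),
        sequence=linker.join(parts) if linker else "".join(parts),
        linker=linker,
    )


def predict_structure(pp: PairProbMatrix, threshold: float = 0.5) -> str:
    """Greedy nested structure from the probability matrix, as dot-bracket.

    Pairs with P > threshold are accepted in descending probability as long
    as they neither reuse a nucleotide nor cross an accepted pair.
    """
    P = pp.matrix
    n = P.shape[0]
    iu = np.triu_indices(n, k=1)
    order = np.argsort(-P[iu], kind="stable")
    chosen: list[tuple[int, int]] = []
    used = np.zeros(n, dtype=bool)
    for k in order:
        p = P[iu[0][k], iu[1][k]]
        if p <= threshold:
            break
        i, j = int(iu[0][k]), int(iu[1][k])
        if used[i] or used[j]:
            continue
        if any(a < i < b < j or i < a < j < b for a, b in chosen):
            continue
        chosen.append((i, j))
        used[i] = used[j] = True
    db = ["."] * n
    for i, j in chosen:
        db[i], db[j] = "(", ")"
    return "".join(db)
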