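"""Synthetic data generation with known ground truth.

Every downstream stage of the pipeline (junction quantification, enrichment,
SHAPE-restrained folding, SPR kinetics) consumes inputs that this module can
fabricate with a recorded ground truth, so recovery can be tested end to end
without external downloads.

The generator emulates the study conditions of the DRAIC exon-4a analysis:

* a three-exon locus in which the 30-nt middle exon (the exon-4a analog)
  carries the bottom strand of a hairpin whose top strand sits in the
  upstream exon — so the hairpin only exists in the middle-exon-containing
  isoform;
* single-end RNA-seq reads drawn from a two-isoform mixture with i.i.d.
  substitution errors;
* a two-group log-normal expression matrix with a log2 fold-change applied
  to a target gene set in the exon-4a-expressing group;
* two-channel (modified / untreated) mutational-profiling counts whose rates
  reflect the paired/unpaired status of each nucleotide;
* noisy 1:1 Langmuir sensorgrams from known (ka, kd, Rmax).

All randomness flows from ``SimConfig.seed`` through fixed per-stage offsets
(:data:`STAGE_SEED_OFFSETS`), so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SprParams",
    "SimConfig",
    "SyntheticLocus",
    "STAGE_SEED_OFFSETS",
    "build_synthetic_locus",
    "simulate_reads",
    "simulate_expression_matrix",
    "simulate_map_counts",
    "simulate_sensorgram",
]

#: Fixed offsets mixed with the master seed to derive per-stage child streams.
STAGE_SEED_OFFSETS = {
    "locus": 11,
    "reads": 23,
    "expression": 37,
    "map_counts": 53,
    "sensorgram": 71,
}

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass(frozen=True)
class SprParams:
    """Ground-truth 1:1 binding parameters for sensorgram simulation.

    Defaults mirror a slow-off, picomolar-KD RNA-protein interaction:
    ka in 1/(M*s), kd in 1/s, rmax in response units (RU), analyte
    concentrations in M.  The long dissociation window is what makes a
    ~1e-5 1/s off-rate identifiable from the decay.
    """

    ka: float = 2.04e4
    kd: float = 1.31e-5
    rmax: float = 100.0
    concentrations: tuple[float, ...] = (6.25e-9, 1.25e-8, 2.5e-8, 5e-8, 1e-7)
    t_assoc_end: float = 600.0
    t_dissoc_end: float = 4200.0
    dt: float = 5.0
    noise_sd: float = 2.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ConfigurationError("ka, kd and rmax must be positive")
        conc = tuple(self.concentrations)
        if len(conc) == 0 or any(c <= 0 for c in conc):
            raise ConfigurationError("concentrations must be strictly positive")
        if len(set(conc)) != len(conc):
            raise ConfigurationError("concentrations must be distinct")
        if not (0 < self.t_assoc_end < self.t_dissoc_end):
            raise ConfigurationError(
                "association must end before the dissociation window ends"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    """Master configuration for all synthetic inputs.

    Parameters
    ----------
    seed:
        Master seed; per-stage child streams are derived with fixed offsets.
    read_length, depth, error_rate:
        Single-end read geometry, reads per sample, and per-base substitution
        probability.
    mixture:
        Fraction of transcripts carrying the middle exon.  Either a single
        float applied to every sample or a mapping ``sample_id -> fraction``.
    n_samples_per_group, n_genes, target_set_size, delta:
        Two-group expression design; ``delta`` is the log2 fold-change applied
        to the target gene set in the exon-4a-expressing group (negative =
        downregulation).
    gc_content:
        GC fraction of randomly generated exon sequence.
    shape_depth, rate_paired, rate_loop, rate_background:
        Mutational-profiling read depth per nucleotide and mutation-rate
        increments: the modified channel mutates at ``rate_background`` plus
        ``rate_paired`` (paired nt) or ``rate_loop`` (unpaired nt); the
        untreated channel mutates at ``rate_background``.
    exon_upstream_len, exon_middle_len, exon_downstream_len:
        Exon lengths of the synthetic locus; the middle exon defaults to
        30 nt so one 40-mer probe spans both of its junctions.
    spr:
        Ground truth for sensorgram simulation.
    """

    seed: int = 0
    read_length: int = 100
    depth: int = 20_000
    error_rate: float = 0.001
    mixture: float | Mapping[str, float] = 0.5
    n_samples_per_group: int = 20
    n_genes: int = 1000
    target_set_size: int = 50
    delta: float = -1.0
    gc_content: float = 0.5
    shape_depth: int = 10_000
    rate_paired: float = 0.005
    rate_loop: float = 0.04
    rate_background: float = 0.01
    exon_upstream_len: int = 100
    exon_middle_len: int = 30
    exon_downstream_len: int = 100
    spr: SprParams = field(default_factory=SprParams)

    def __post_init__(self) -> None:
        for name in ("error_rate", "gc_content", "rate_paired", "rate_loop",
                     "rate_background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if isinstance(self.mixture, Mapping):
            bad = {k: v for k, v in self.mixture.items() if not 0 <= v <= 1}
            if bad:
                raise ConfigurationError(f"mixture fractions outside [0,1]: {bad}")
        elif not (0.0 <= float(self.mixture) <= 1.0):
            raise ConfigurationError("mixture must be in [0, 1]")
        if self.depth <= 0:
            raise ConfigurationError("depth must be > 0")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be > 0")
        if self.shape_depth < 0:
            raise ConfigurationError("shape_depth must be >= 0")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be > 0")
        if self.target_set_size > self.n_genes:
            raise ConfigurationError(
                f"target_set_size ({self.target_set_size}) exceeds "
                f"n_genes ({self.n_genes})"
            )

    def mixture_for(self, sample_id: str) -> float:
        """Resolve the middle-exon mixture fraction for one sample."""
        if isinstance(self.mixture, Mapping):
            try:
                return float(self.mixture[sample_id])
            except KeyError:
                raise ConfigurationError(
                    f"no mixture fraction defined for sample {sample_id!r}"
                ) from None
        return float(self.mixture)


@dataclass(frozen=True)
class SyntheticLocus:
    """A three-exon locus with ground-truth structure and reactivity.

    ``coordinates`` are 1-based inclusive intervals of each exon on the
    middle-exon-containing transcript.  ``true_structure`` lists base pairs
    (1-based positions on that transcript); the helix pairs the end of the
    upstream exon with the body of the middle exon, so the hairpin exists
    only in the inclusion isoform.  ``true_reactivity`` is low on paired and
    high on unpaired nucleotides.
    """

    exon_upstream: str
    exon_middle: str
    exon_downstream: str
    coordinates: dict[str, tuple[int, int]]
    true_structure: tuple[tuple[int, int], ...]
    true_reactivity: tuple[float, ...]
    helix_intervals: tuple[tuple[int, int], tuple[int, int]]

    @property
    def transcript_with_middle(self) -> str:
        return self.exon_upstream + self.exon_middle + self.exon_downstream

    @property
    def transcript_without_middle(self) -> str:
        return self.exon_upstream + self.exon_downstream


def _rng(config: SimConfig, stage: str, extra: int | None = None):
    entropy = [config.seed, STAGE_SEED_OFFSETS[stage]]
    if extra is not None:
        entropy.append(extra)
    return np.random.default_rng(entropy)


def _random_seq(rng, n: int, gc: float) -> np.ndarray:
    """Random DNA as uint8 codes 0..3 (= A,C,G,T) at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTacgt", b"TGCATGCA"):
    _COMPLEMENT[a] = b


def _codes_to_str(codes: np.ndarray) -> str:
    return _DNA[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Locus
# ---------------------------------------------------------------------------

# Reactivity ground truth: flexible loops probe high (the display scale tops
# out around 0.8), paired stems probe low.
_REACTIVITY_PAIRED = 0.1
_REACTIVITY_UNPAIRED = 0.8

_HELIX_LEN = 18          # mirrors the 18-bp A:B duplex geometry
_UPSTREAM_TAIL = 4       # unpaired nts between strand A and the 3' exon end
_MIDDLE_LEAD = 3         # unpaired nts before strand B inside the middle exon


def build_synthetic_locus(config: SimConfig) -> SyntheticLocus:
    """Build a three-exon locus whose middle exon closes a hairpin.

    Strand A (18 nt) sits near the 3' end of the upstream exon; its reverse
    complement, strand B, sits inside the middle exon.  The intervening
    nucleotides form the loop, so the inclusion transcript can fold into an
    A+B-style hairpin while the skipping transcript cannot.
    """
    lu, lm, ld = (config.exon_upstream_len, config.exon_middle_len,
                  config.exon_downstream_len)
    for name, length, minimum in (
        ("exon_upstream", lu, 20),
        ("exon_middle", lm, 30),
        ("exon_downstream", ld, 20),
    ):
        if length < minimum:
            raise ConfigurationError(
                f"{name} length {length} below required minimum {minimum}"
            )

    helix_len = min(_HELIX_LEN, lu - _UPSTREAM_TAIL - 1, lm - _MIDDLE_LEAD - 1)
    if helix_len < 4:
        raise ConfigurationError(
            "exons too short to host a hairpin helix (need >= 4 bp)"
        )

    rng = _rng(config, "locus")
    up = _random_seq(rng, lu, config.gc_content)
    mid = _random_seq(rng, lm, config.gc_content)
    down = _random_seq(rng, ld, config.gc_content)

    # Strand A occupies upstream positions [a0, a0+helix_len); strand B is its
    # reverse complement inside the middle exon.
    a0 = lu - _UPSTREAM_TAIL - helix_len
    b0 = _MIDDLE_LEAD
    mid[b0:b0 + helix_len] = 3 - up[a0:a0 + helix_len][::-1]  # revcomp in codes

    n = lu + lm + ld
    pairs = tuple(
        (a0 + k + 1, lu + b0 + helix_len - k)  # 1-based on the inclusion tx
        for k in range(helix_len)
    )
    paired = np.zeros(n, dtype=bool)
    for i, j in pairs:
        paired[i - 1] = paired[j - 1] = True
    reactivity = np.where(paired, _REACTIVITY_PAIRED, _REACTIVITY_UNPAIRED)

    return SyntheticLocus(
        exon_upstream=_codes_to_str(up),
        exon_middle=_codes_to_str(mid),
        exon_downstream=_codes_to_str(down),
        coordinates={
            "exon_upstream": (1, lu),
            "exon_middle": (lu + 1, lu + lm),
            "exon_downstream": (lu + lm + 1, n),
        },
        true_structure=pairs,
        true_reactivity=tuple(float(x) for x in reactivity),
        helix_intervals=(
            (a0 + 1, a0 + helix_len),
            (lu + b0 + 1, lu + b0 + helix_len),
        ),
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    locus: SyntheticLocus, config: SimConfig, sample_id: str
) -> list[SeqRecord]:
    """Simulate single-end reads from the two-isoform mixture.

    Each read picks the inclusion isoform with probability ``mixture``, a
    uniform start position, a uniform strand (forward or reverse
    complement), and i.i.d. substitution errors at ``error_rate``.  Exactly
    ``depth`` reads are returned, with constant Sanger quality.
    """
    mixture = config.mixture_for(sample_id)
    rng = _rng(config, "reads", zlib.crc32(sample_id.encode()))

    tx_with = np.frombuffer(locus.transcript_with_middle.encode(), np.uint8)
    tx_without = np.frombuffer(locus.transcript_without_middle.encode(), np.uint8)
    L = config.read_length
    if L > min(len(tx_with), len(tx_without)):
        raise ConfigurationError(
            f"read_length {L} exceeds shorter transcript "
            f"({min(len(tx_with), len(tx_without))} nt)"
        )

    n = config.depth
    from_with = rng.random(n) < mixture
    starts = np.empty(n, dtype=np.int64)
    starts[from_with] = rng.integers(0, len(tx_with) - L + 1,
                                     size=int(from_with.sum()))
    starts[~from_with] = rng.integers(0, len(tx_without) - L + 1,
                                      size=int((~from_with).sum()))

    reads = np.empty((n, L), dtype=np.uint8)
    offs = np.arange(L)
    if from_with.any():
        reads[from_with] = tx_with[starts[from_with, None] + offs]
    if (~from_with).any():
        reads[~from_with] = tx_without[starts[~from_with, None] + offs]

    rc = rng.random(n) < 0.5
    reads[rc] = _COMPLEMENT[reads[rc, ::-1]]

    if config.error_rate > 0:
        err = rng.random((n, L)) < config.error_rate
        idx = np.searchsorted(_DNA, reads[err])  # base -> 0..3
        reads[err] = _DNA[(idx + rng.integers(1, 4, size=idx.shape)) % 4]

    qual = [30] * L
    records = []
    for i in range(n):
        iso = "incl" if from_with[i] else "skip"
        rec = SeqRecord(
            Seq(reads[i].tobytes().decode("ascii")),
            id=f"{sample_id}:read{i}:{iso}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def simulate_expression_matrix(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Two-group log-normal expression with a shifted target gene set.

    Returns ``(matrix, labels, target_genes)``: a genes x samples DataFrame
    of normalized expression values, a per-sample phenotype Series with
    labels ``"exon4a"`` / ``"no4a"``, and the target gene ids.  Target genes
    are shifted by ``delta`` log2 units in the exon-4a group; all other
    genes are identically distributed across groups.
    """
    if config.n_samples_per_group < 3:
        raise ConfigurationError("need at least 3 samples per group")
    rng = _rng(config, "expression")

    g, n = config.n_genes, config.n_samples_per_group
    genes = [f"G{i + 1:05d}" for i in range(g)]
    samples = [f"S4A_{i + 1:03d}" for i in range(n)] + [
        f"SNO_{i + 1:03d}" for i in range(n)
    ]
    labels = pd.Series(["exon4a"] * n + ["no4a"] * n, index=samples,
                       name="phenotype")

    base_mu = rng.normal(5.0, 2.0, size=g)          # per-gene log2 mean
    sigma = rng.uniform(0.3, 0.8, size=g)           # per-gene log2 dispersion
    log2x = base_mu[:, None] + sigma[:, None] * rng.standard_normal((g, 2 * n))

    target = sorted(rng.choice(genes, size=config.target_set_size,
                               replace=False).tolist())
    tmask = np.isin(np.array(genes), target)
    log2x[np.ix_(tmask, np.arange(n))] += config.delta

    matrix = pd.DataFrame(np.exp2(log2x), index=genes, columns=samples)
    return matrix, labels, target


# ---------------------------------------------------------------------------
# Mutational-profiling counts
# ---------------------------------------------------------------------------

def simulate_map_counts(
    locus: SyntheticLocus,
    config: SimConfig,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Two-channel per-nucleotide mutation counts over the inclusion transcript.

    The modified channel draws Binomial(shape_depth, background + paired/loop
    rate) counts per position according to the ground-truth structure; the
    untreated channel draws Binomial(shape_depth, background).  ``window``
    restricts output to a 1-based inclusive coordinate range.

    Returns a DataFrame with columns
    ``position, base, mod_mutations, mod_reads, untr_mutations, untr_reads``.
    """
    for name in ("rate_paired", "rate_loop", "rate_background"):
        if not 0 <= getattr(config, name) <= 1:
            raise ConfigurationError(f"{name} outside [0, 1]")
    seq = locus.transcript_with_middle
    n = len(seq)
    lo, hi = (1, n) if window is None else window
    if not (1 <= lo <= hi <= n):
        raise ConfigurationError(
            f"window ({lo}, {hi}) outside transcript bounds 1..{n}"
        )

    paired = np.zeros(n, dtype=bool)
    for i, j in locus.true_structure:
        paired[i - 1] = paired[j - 1] = True

    mod_rate = config.rate_background + np.where(
        paired, config.rate_paired, config.rate_loop
    )
    mod_rate = np.clip(mod_rate, 0.0, 1.0)

    rng = _rng(config, "map_counts")
    depth = config.shape_depth
    pos = np.arange(lo, hi + 1)
    idx = pos - 1
    mod_mut = rng.binomial(depth, mod_rate[idx])
    untr_mut = rng.binomial(depth, config.rate_background, size=len(idx))
    return pd.DataFrame(
        {
            "position": pos,
            "base": list(seq[lo - 1:hi]),
            "mod_mutations": mod_mut,
            "mod_reads": depth,
            "untr_mutations": untr_mut,
            "untr_reads": depth,
        }
    )


# ---------------------------------------------------------------------------
# Sensorgrams
# ---------------------------------------------------------------------------

def simulate_sensorgram(config: SimConfig) -> pd.DataFrame:
    """Simulate noisy 1:1 Langmuir sensorgrams for each dose and replicate.

    Association follows ``R(t) = Req (1 - exp(-(ka C + kd) t))`` with
    ``Req = Rmax C / (C + kd/ka)``; dissociation decays exponentially from
    the association endpoint at rate ``kd``.  Gaussian noise of sd
    ``noise_sd`` RU is added to every point.

    Returns a tidy DataFrame with columns
    ``time_s, response_RU, conc_M, phase, replicate``.
    """
    p = config.spr
    t_assoc = np.arange(0.0, p.t_assoc_end + p.dt / 2, p.dt)
    t_dissoc = np.arange(p.t_assoc_end + p.dt, p.t_dissoc_end + p.dt / 2, p.dt)
    kD = p.kd / p.ka

    frames = []
    for rep in range(1, p.n_replicates + 1):
        rng = _rng(config, "sensorgram", rep)
        for conc in p.concentrations:
            req = p.rmax * conc / (conc + kD)
            kobs = p.ka * conc + p.kd
            r_assoc = req * (1.0 - np.exp(-kobs * t_assoc))
            r_end = req * (1.0 - np.exp(-kobs * p.t_assoc_end))
            r_dissoc = r_end * np.exp(-p.kd * (t_dissoc - p.t_assoc_end))
            times = np.concatenate([t_assoc, t_dissoc])
            resp = np.concatenate([r_assoc, r_dissoc])
            if p.noise_sd > 0:
                resp = resp + rng.normal(0.0, p.noise_sd, size=resp.size)
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": times,
                        "response_RU": resp,
                        "conc_M": conc,
                        "phase": ["assoc"] * len(t_assoc)
                        + ["dissoc"] * len(t_dissoc),
                        "replicate": rep,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
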