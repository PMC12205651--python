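"""Splice-junction probe design, alignment-free read counting, and matching.

The inclusion isoform of DRAIC carries exon 4a between exons 3 and 4; the
skipping isoform joins exon 3 directly to exon 4.  Each isoform is detected
by a single 40-base probe spanning its diagnostic junction(s):

* inclusion probe (``exon3-4a-4``): last 5 bases of exon 3 + 30 bases from
  the 5' end of exon 4a + first 5 bases of exon 4 — one 40-mer crossing both
  junctions of a 30-nt middle exon;
* skipping probe (``exon3-4``): last 20 bases of exon 3 + first 20 bases of
  exon 4.

Reads are scanned alignment-free: a read supports a probe when the full
probe occurs as an ungapped substring of the read or its reverse complement
with at most ``max_mismatches`` mismatches.  Abundance is reported as
CPM = (raw counts / total mapped reads) x 1e6.

Samples are classified into exclusive isoform subsets (A: inclusion only,
B: skipping only) and matched one-to-one across subsets by total transcript
expression using an optimal assignment that minimizes the summed absolute
CPM difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "PROBE_LENGTH",
    "JunctionProbe",
    "JunctionQuantResult",
    "SubsetLabel",
    "MatchedPairs",
    "design_junction_probes",
    "count_junction_reads",
    "cpm",
    "classify_isoform_subsets",
    "match_samples_by_expression",
    "reverse_complement",
]

PROBE_LENGTH = 40

_RC = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA sequence (returned as DNA)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class JunctionProbe:
    """A 40-base probe spanning one or two splice junctions.

    ``junction_offsets`` are 1-based positions within the probe of the last
    base contributed by each upstream segment (i.e. the exon boundaries).
    """

    name: str
    sequence: str
    junction_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError(
                f"probe {self.name!r} must be {PROBE_LENGTH} bases, "
                f"got {len(self.sequence)}"
            )
        seq = self.sequence
        if seq != seq.upper() or set(seq) - set("ACGTU"):
            raise ValueError(f"probe {self.name!r} must be uppercase ACGT/U")
        offs = self.junction_offsets
        if list(offs) != sorted(set(offs)) or any(
            not 1 < o < PROBE_LENGTH for o in offs
        ):
            raise ValueError("junction offsets must be increasing, inside (1, 40)")


@dataclass(frozen=True)
class JunctionQuantResult:
    """Per-sample probe counts and CPM values."""

    sample_id: str
    counts: dict[str, int]
    total_mapped_reads: int
    cpm: dict[str, float]


@dataclass(frozen=True)
class SubsetLabel:
    """Isoform-subset call for one sample: A, B, both, or neither."""

    sample_id: str
    label: str


@dataclass(frozen=True)
class MatchedPairs:
    """Optimal one-to-one case/control matching by expression.

    ``pairs`` holds ``(case_id, control_id, case_cpm, control_cpm, abs_diff)``
    tuples; ``objective_value`` is the minimized sum of absolute differences.
    """

    pairs: tuple[tuple[str, str, float, float, float], ...]
    objective_value: float


def design_junction_probes(
    exon_upstream: str,
    exon_middle: str,
    exon_downstream: str,
    strict: bool = True,
) -> tuple[JunctionProbe, JunctionProbe]:
    """Design the inclusion and skipping 40-mer junction probes.

    In strict mode the middle exon must be exactly 30 nt (the geometry under
    which one 40-mer covers both of its junctions); with ``strict=False`` a
    longer middle exon is allowed and its first 30 bases are used.
    """
    up = exon_upstream.upper()
    mid = exon_middle.upper()
    down = exon_downstream.upper()
    for name, seq, minimum in (
        ("upstream exon", up, 20),
        ("middle exon", mid, 30),
        ("downstream exon", down, 20),
    ):
        if len(seq) < minimum:
            raise ValueError(
                f"{name} is {len(seq)} nt; needs at least {minimum} nt"
            )
    if strict and len(mid) != 30:
        raise ValueError(
            f"middle exon is {len(mid)} nt, not 30; pass strict=False to use "
            "its first 30 bases"
        )

    inclusion = JunctionProbe(
        name="exon3-4a-4",
        sequence=up[-5:] + mid[:30] + down[:5],
        junction_offsets=(5, 35),
    )
    skipping = JunctionProbe(
        name="exon3-4",
        sequence=up[-20:] + down[:20],
        junction_offsets=(20,),
    )
    return inclusion, skipping


def _read_sequences(reads: Iterable) -> list[str]:
    out = []
    for r in reads:
        out.append(str(r.seq) if hasattr(r, "seq") else str(r))
    return out


def _count_with_mismatches(seqs: Sequence[str], probe: str, k: int) -> int:
    """Reads containing the probe ungapped with <= k mismatches (one strand)."""
    pat = np.frombuffer(probe.encode(), dtype=np.uint8)
    m = len(pat)
    n_hit = 0
    for s in seqs:
        if len(s) < m:
            continue
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, m)
        if (windows != pat).sum(axis=1).min() <= k:
            n_hit += 1
    return n_hit


def count_junction_reads(
    reads: Iterable,
    probes: Sequence[JunctionProbe],
    sample_id: str = "sample",
    max_mismatches: int = 0,
    strand: str = "both",
    min_anchor: int = 5,
) -> JunctionQuantResult:
    """Count reads supporting each probe by full ungapped containment.

    A read supports a probe when the entire probe occurs as an ungapped
    substring of the read (or of its reverse complement when
    ``strand="both"``) with at most ``max_mismatches`` substitutions.  Each
    read counts at most once per probe.  ``total_mapped_reads`` is the number
    of reads scanned.  ``min_anchor`` is retained for interface
    compatibility; the default scan requires full containment, so reads
    shorter than the probe can never support it (a warning is emitted).
    """
    if strand not in ("both", "forward"):
        raise ValueError("strand must be 'both' or 'forward'")
    seqs = [s.upper() for s in _read_sequences(reads)]
    if not seqs:
        raise ValueError("empty read set")
    if any(len(s) < PROBE_LENGTH for s in seqs):
        warnings.warn(
            "some reads are shorter than the 40-base probes and can never "
            "support a junction",
            stacklevel=2,
        )
        if all(len(s) < PROBE_LENGTH for s in seqs):
            raise ValueError("all reads are shorter than the probes")

    counts: dict[str, int] = {}
    for probe in probes:
        targets = [probe.sequence]
        if strand == "both":
            targets.append(reverse_complement(probe.sequence))
        if max_mismatches == 0:
            n = sum(1 for s in seqs if any(t in s for t in targets))
        else:
            # per-read OR over strands, still counting each read once
            n = 0
            for s in seqs:
                hit = False
                for t in targets:
                    if _count_with_mismatches([s], t, max_mismatches):
                        hit = True
                        break
                n += hit
        counts[probe.name] = n

    total = len(seqs)
    return JunctionQuantResult(
        sample_id=sample_id,
        counts=counts,
        total_mapped_reads=total,
        cpm={name: cpm(c, total) for name, c in counts.items()},
    )


def cpm(count: int, total_mapped_reads: int) -> float:
    """Counts per million: (raw counts / total mapped reads) x 1e6."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if count < 0 or count > total_mapped_reads:
        raise ValueError("count must be in [0, total_mapped_reads]")
    return count / total_mapped_reads * 1_000_000


def classify_isoform_subsets(
    results: Sequence[JunctionQuantResult],
    inclusion_probe: str = "exon3-4a-4",
    skipping_probe: str = "exon3-4",
    min_count: int = 1,
) -> tuple[list[SubsetLabel], pd.DataFrame]:
    """Classify samples into exclusive isoform subsets.

    Subset A expresses only the inclusion junction (exon3-4a-4 yes / exon3-4
    no); subset B only the skipping junction.  Samples expressing both or
    neither are labeled accordingly and excluded from A/B analyses.  A probe
    is "expressed" when its raw count is at least ``min_count``.

    Returns the per-sample labels and a summary table of counts per label.
    """
    labels = []
    for res in results:
        for probe in (inclusion_probe, skipping_probe):
            if probe not in res.counts:
                raise ValueError(
                    f"sample {res.sample_id!r} is missing probe {probe!r}"
                )
        has_incl = res.counts[inclusion_probe] >= min_count
        has_skip = res.counts[skipping_probe] >= min_count
        if has_incl and not has_skip:
            label = "A"
        elif has_skip and not has_incl:
            label = "B"
        elif has_incl and has_skip:
            label = "both"
        else:
            label = "neither"
        labels.append(SubsetLabel(sample_id=res.sample_id, label=label))

    summary = pd.DataFrame(
        {
            "label": ["A", "B", "both", "neither"],
            "n_samples": [
                sum(1 for s in labels if s.label == lab)
                for lab in ("A", "B", "both", "neither")
            ],
        }
    )
    return labels, summary


def match_samples_by_expression(
    case_values: Mapping[str, float],
    control_pool: Mapping[str, float],
) -> MatchedPairs:
    """Match every case to a distinct control minimizing total |CPM difference|.

    Solves the optimal one-to-one assignment (Hungarian algorithm) of cases
    to controls with cost |case CPM - control CPM|.  Inputs are sorted by
    sample id first, so ties between equally good assignments resolve
    deterministically.
    """
    if len(control_pool) < len(case_values):
        raise ValueError(
            f"control pool ({len(control_pool)}) smaller than the case set "
            f"({len(case_values)})"
        )
    case_ids = sorted(case_values)
    pool_ids = sorted(control_pool)
    cases = np.array([case_values[c] for c in case_ids], dtype=float)
    pool = np.array([control_pool[c] for c in pool_ids], dtype=float)

    cost = np.abs(cases[:, None] - pool[None, :])
    rows, cols = linear_sum_assignment(cost)

    pairs = tuple(
        (
            case_ids[i],
            pool_ids[j],
            float(cases[i]),
            float(pool[j]),
            float(cost[i, j]),
        )
        for i, j in sorted(zip(rows, cols))
    )
    return MatchedPairs(pairs=pairs, objective_value=float(cost[rows, cols].sum()))
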