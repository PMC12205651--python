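"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; the line-oriented formats of the
enrichment and structure worlds (GMT gene sets, CLS phenotype labels,
``.shape``/``.map`` reactivity profiles, CT and dot-bracket structure
files, pair-probability triplets) are small enough to handle directly with
the error reporting the pipeline needs (line numbers, balanced-bracket
checks, no-data sentinels).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .enrichment import GeneSet
from .structure import PairProbMatrix, ReactivityProfile

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "load_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_cls",
    "write_cls",
    "write_shape_profile",
    "read_shape_profile",
    "write_pair_probabilities",
    "read_pair_probabilities",
    "dotbracket_to_pairs",
    "write_structure_ct",
    "read_structure_ct",
    "file_sha256",
]


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str] | Iterable, path) -> None:
    """Write sequences to FASTA; accepts a {name: seq} dict or SeqRecords."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if isinstance(records, dict):
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records.items()
        ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(records: Iterable, path) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list:
    return list(SeqIO.parse(str(path), "fastq"))


# ---------------------------------------------------------------------------
# Gene sets and phenotype labels
# ---------------------------------------------------------------------------

def load_gene_sets_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line — name, description, genes...

    Duplicate genes within a set are de-duplicated with a warning; a line
    with fewer than three fields is an error naming the line number.
    """
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: GMT lines need name, description "
                f"and at least one gene (got {len(fields)} fields)"
            )
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            warnings.warn(
                f"{path}: line {lineno}: duplicate genes in set {name!r} "
                "de-duplicated",
                stacklevel=2,
            )
        sets.append(GeneSet.from_iterable(name, unique))
    return sets


def write_gene_sets_gmt(sets: Sequence[GeneSet], path,
                        descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for s in sets:
        desc = (descriptions or {}).get(s.name, "na")
        lines.append("\t".join([s.name, desc, *sorted(s.members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cls(path) -> list[str]:
    """Read a CLS phenotype file, returning one label per sample."""
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if len(lines) < 3:
        raise ValueError(f"{path}: CLS files need 3 lines")
    n_samples, n_classes, _ = lines[0].split()
    class_names = lines[1].lstrip("#").split()
    tokens = lines[2].split()
    if len(tokens) != int(n_samples):
        raise ValueError(
            f"{path}: header declares {n_samples} samples but line 3 has "
            f"{len(tokens)}"
        )
    if len(class_names) != int(n_classes):
        raise ValueError(f"{path}: class-name count mismatch")
    # tokens may be numeric indices or the names themselves
    if set(tokens) <= set(class_names):
        return tokens
    return [class_names[int(t)] for t in tokens]


def write_cls(labels: Sequence[str], path) -> None:
    classes = list(dict.fromkeys(labels))
    lines = [
        f"{len(labels)} {len(classes)} 1",
        "# " + " ".join(classes),
        " ".join(str(classes.index(lab)) for lab in labels),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reactivity profiles and pair probabilities
# ---------------------------------------------------------------------------

NO_DATA_SENTINEL = -999.0


def write_shape_profile(profile: ReactivityProfile, path,
                        stderr: Sequence[float] | None = None) -> None:
    """Write a profile in .shape/.map convention.

    Tab-separated columns: position, reactivity, stderr, base; no-data is
    written as -999.  Normalized values are written when present, raw
    otherwise.
    """
    values = profile.normalized if profile.normalized is not None else profile.raw
    errs = stderr if stderr is not None else [0.0] * len(profile)
    lines = []
    for pos, val, err, base in zip(profile.positions, values, errs,
                                   profile.bases):
        out = NO_DATA_SENTINEL if np.isnan(val) else val
        err_out = NO_DATA_SENTINEL if np.isnan(val) else err
        lines.append(f"{pos}\t{out:.6f}\t{err_out:.6f}\t{base}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_shape_profile(path) -> ReactivityProfile:
    positions, values, bases = [], [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 columns")
        positions.append(int(fields[0]))
        v = float(fields[1])
        values.append(float("nan") if v == NO_DATA_SENTINEL else v)
        bases.append(fields[3])
    return ReactivityProfile(
        positions=tuple(positions), bases=tuple(bases), raw=tuple(values)
    )


def write_pair_probabilities(pp: PairProbMatrix, path) -> None:
    """Write the upper-triangle nonzero P(i, j) as TSV triplets (1-based)."""
    pp.to_triplets().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pair_probabilities(path, sequence: str,
                            energy_model_id: str = "unknown") -> PairProbMatrix:
    df = pd.read_csv(path, sep="\t")
    n = len(sequence)
    m = np.zeros((n, n))
    for i, j, p in zip(df["i"], df["j"], df["probability"]):
        m[i - 1, j - 1] = m[j - 1, i - 1] = p
    return PairProbMatrix(matrix=m, sequence=sequence.upper().replace("T", "U"),
                          energy_model_id=energy_model_id)


# ---------------------------------------------------------------------------
# Structures: dot-bracket and CT
# ---------------------------------------------------------------------------

def dotbracket_to_pairs(dot_bracket: str) -> list[tuple[int, int]]:
    """1-based pairs from a dot-bracket string; raises on unbalanced brackets."""
    stack: list[int] = []
    pairs = []
    for k, ch in enumerate(dot_bracket, start=1):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise ValueError(
                    f"unbalanced dot-bracket: ')' at position {k} has no match"
                )
            pairs.append((stack.pop(), k))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError(
            f"unbalanced dot-bracket: unmatched '(' at position {stack[-1]}"
        )
    return sorted(pairs)


def write_structure_ct(sequence: str, dot_bracket: str, path,
                       name: str = "structure") -> None:
    """Write a standard CT file for one structure.

    Header: length and a name; then one line per nucleotide with index,
    base, 5'/3' neighbor indices, pairing partner (0 if unpaired), and the
    index again.
    """
    if len(sequence) != len(dot_bracket):
        raise ValueError("sequence and dot-bracket lengths differ")
    partner = [0] * (len(sequence) + 1)
    for i, j in dotbracket_to_pairs(dot_bracket):
        partner[i], partner[j] = j, i
    n = len(sequence)
    lines = [f"{n}\t{name}"]
    for k in range(1, n + 1):
        lines.append(
            f"{k}\t{sequence[k - 1]}\t{k - 1}\t{(k + 1) if k < n else 0}"
            f"\t{partner[k]}\t{k}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure_ct(path) -> tuple[str, str]:
    """Read a CT file back into (sequence, dot_bracket)."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    n = int(lines[0].split()[0])
    seq = []
    db = ["."] * n
    for ln in lines[1:n + 1]:
        fields = ln.split()
        k, base, partner = int(fields[0]), fields[1], int(fields[4])
        seq.append(base)
        if partner > k:
            db[k - 1] = "("
        elif 0 < partner < k:
            db[k - 1] = ")"
    return "".join(seq), "".join(db)


# ---------------------------------------------------------------------------
# Checksums
# ---------------------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
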