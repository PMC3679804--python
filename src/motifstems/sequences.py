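"""Sequence containers, FASTA I/O and synthetic planted-motif benchmarks.

A planted (l, d) instance is the standard benchmark for exact motif search:
``n`` i.i.d.-uniform random sequences of common length ``m``, each carrying
one copy of a hidden motif mutated in at most ``d`` positions and inserted
at a random offset.  The generator here reproduces that protocol for any
alphabet (DNA, protein, or a custom character set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: character standing for "matches anything"; never part of a sequence alphabet
WILDCARD = "*"


@dataclass(frozen=True)
class SequenceSet:
    """An ordered set of equal-length sequences over a declared alphabet.

    The first sequence (``sequences[0]``) is the designated candidate
    sequence from which search drivers draw their l-mer candidates.
    """

    sequences: tuple[str, ...]
    alphabet: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        if len(self.sequences) < 2:
            raise ValueError("a SequenceSet needs at least two sequences")
        if len(set(self.alphabet)) != len(self.alphabet) or len(self.alphabet) < 2:
            raise ValueError("alphabet must hold at least two distinct characters")
        if WILDCARD in self.alphabet:
            raise ValueError(f"alphabet must not contain the wildcard {WILDCARD!r}")
        m = len(self.sequences[0])
        allowed = set(self.alphabet)
        for idx, seq in enumerate(self.sequences):
            if len(seq) != m:
                raise ValueError(
                    f"sequence {idx + 1} has length {len(seq)}, expected {m}"
                )
            bad = set(seq) - allowed
            if bad:
                raise ValueError(
                    f"sequence {idx + 1} contains characters outside the "
                    f"alphabet: {sorted(bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def m(self) -> int:
        return len(self.sequences[0])

    @property
    def sigma(self) -> int:
        return len(self.alphabet)

    def encoded(self) -> list[np.ndarray]:
        """Sequences as uint8 arrays (ASCII codes), for vectorised scans."""
        return [
            np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in self.sequences
        ]


@dataclass(frozen=True)
class PlantedInstance:
    """A synthetic benchmark: sequences plus the hidden ground truth."""

    sequence_set: SequenceSet
    motif: str
    plant_positions: tuple[int, ...]
    planted_instances: tuple[str, ...]
    d: int
    seed: int

    @property
    def l(self) -> int:  # noqa: E743 - field-standard symbol
        return len(self.motif)

    def __post_init__(self) -> None:
        object.__setattr__(self, "plant_positions", tuple(self.plant_positions))
        object.__setattr__(self, "planted_instances", tuple(self.planted_instances))
        l = self.l
        for i, (pos, inst) in enumerate(
            zip(self.plant_positions, self.planted_instances)
        ):
            window = self.sequence_set.sequences[i][pos : pos + l]
            if window != inst:
                raise ValueError(f"planted instance {i} disagrees with its sequence")
            mism = sum(a != b for a, b in zip(inst, self.motif))
            if mism > self.d:
                raise ValueError(
                    f"planted instance {i} is {mism} mismatches from the motif, "
                    f"more than d={self.d}"
                )


def read_fasta(path: str | Path, alphabet: str) -> SequenceSet:
    """Read an equal-length FASTA file into a :class:`SequenceSet`.

    Records are kept in file order; the first record becomes the candidate
    sequence.  Raises :class:`ValueError` naming the offending record on
    length mismatch or out-of-alphabet characters.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seqs = []
    m = len(records[0].seq)
    allowed = set(alphabet)
    for idx, rec in enumerate(records):
        s = str(rec.seq)
        if len(s) != m:
            raise ValueError(
                f"record {idx + 1} ({rec.id!r}) has length {len(s)}, expected {m}"
            )
        bad = set(s) - allowed
        if bad:
            raise ValueError(
                f"record {idx + 1} ({rec.id!r}) contains characters outside "
                f"the alphabet: {sorted(bad)}"
            )
        seqs.append(s)
    return SequenceSet(tuple(seqs), alphabet)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write a SequenceSet as FASTA with ids ``seq_1 .. seq_n``."""
    records = [
        SeqRecord(Seq(s), id=f"seq_{i + 1}", description="")
        for i, s in enumerate(seqs.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_stems(stems: Iterable[str], path: str | Path) -> None:
    """Write stems one per line, lexicographically sorted (determinism contract)."""
    stems = sorted(set(str(s) for s in stems))
    if stems:
        lengths = {len(s) for s in stems}
        if len(lengths) != 1:
            raise ValueError(f"stems have mixed lengths {sorted(lengths)}")
    Path(path).write_text("".join(s + "\n" for s in stems))


def read_stems(path: str | Path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line]


def generate_planted_instance(
    n: int,
    m: int,
    l: int,
    d: int,
    alphabet: str = PROTEIN_ALPHABET,
    seed: int = 0,
) -> PlantedInstance:
    """Generate a planted (l, d) instance.

    Each sequence is drawn i.i.d. uniform over the alphabet.  One motif of
    length ``l`` is drawn uniformly; per sequence, a mismatch count is drawn
    uniformly from ``{0, ..., d}``, that many distinct positions are mutated
    to a *different* character (uniform over the remaining sigma-1), and the
    mutated copy overwrites a uniformly chosen window.  Deterministic for a
    fixed seed; one private random stream per call.
    """
    if l > m:
        raise ValueError(f"motif length l={l} exceeds sequence length m={m}")
    if d > l:
        raise ValueError(f"mismatch bound d={d} exceeds motif length l={l}")
    sigma = len(alphabet)
    if sigma < 2:
        raise ValueError("alphabet must hold at least two characters")
    rng = np.random.default_rng(seed)
    chars = np.array(list(alphabet))
    raw = [
        "".join(rng.choice(chars, size=m, replace=True)) for _ in range(n)
    ]
    motif = "".join(rng.choice(chars, size=l, replace=True))

    seqs, positions, instances = [], [], []
    for i in range(n):
        k = int(rng.integers(0, d + 1))
        inst = list(motif)
        for pos in rng.choice(l, size=k, replace=False):
            others = [c for c in alphabet if c != motif[pos]]
            inst[pos] = others[int(rng.integers(0, sigma - 1))]
        inst = "".join(inst)
        p = int(rng.integers(0, m - l + 1))
        seqs.append(raw[i][:p] + inst + raw[i][p + l :])
        positions.append(p)
        instances.append(inst)

    return PlantedInstance(
        sequence_set=SequenceSet(tuple(seqs), alphabet),
        motif=motif,
        plant_positions=tuple(positions),
        planted_instances=tuple(instances),
        d=d,
        seed=seed,
    )


def write_instance_metadata(instance: PlantedInstance, path: str | Path) -> None:
    """Sidecar ground-truth file in a simple ``key: value`` text format."""
    lines = [
        f"motif: {instance.motif}",
        f"l: {instance.l}",
        f"d: {instance.d}",
        f"seed: {instance.seed}",
        f"alphabet: {instance.sequence_set.alphabet}",
        f"plant_positions: {','.join(map(str, instance.plant_positions))}",
        f"planted_instances: {','.join(instance.planted_instances)}",
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_instance_metadata(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, _, value = line.partition(":")
            out[key.strip()] = value.strip()
    return out
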