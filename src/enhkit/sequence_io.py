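"""DNA sequence I/O and synthetic benchmark-shaped dataset generation.

Sequences are plain strings over the {A, C, G, T} alphabet; ambiguity codes
are rejected by default because every downstream descriptor (dinucleotide
covariances, k-mer embeddings) is defined only on the four canonical bases.

The synthetic generator emulates the shape of enhancer benchmark sets: fixed
length records (200 bp by default) in a non-enhancer : strong-enhancer :
weak-enhancer ratio of 2:1:1, with per-class dinucleotide composition planted
through first-order Markov chains so that exactly the signal the dinucleotide
descriptors measure can be controlled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
DINUCLEOTIDES: tuple[str, ...] = tuple(
    a + b for a, b in itertools.product(ALPHABET, ALPHABET)
)

NON_ENHANCER = "non_enhancer"
STRONG_ENHANCER = "strong_enhancer"
WEAK_ENHANCER = "weak_enhancer"
LABELS: tuple[str, str, str] = (NON_ENHANCER, STRONG_ENHANCER, WEAK_ENHANCER)


class SequenceError(ValueError):
    """Invalid residue content or insufficient sequence length."""


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


class ConfigError(ValueError):
    """Inconsistent generator or pipeline configuration."""


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence: identifier plus residues over {A,C,G,T}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        for pos, ch in enumerate(residues, start=1):
            if ch not in ALPHABET:
                raise SequenceError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos} "
                    "(only A/C/G/T are allowed)"
                )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def dinucleotides(self) -> list[str]:
        """The L-1 overlapping dinucleotides, left to right."""
        if len(self) < 2:
            raise SequenceError(
                f"sequence {self.id!r}: length {len(self)} < 2, no dinucleotides"
            )
        r = self.residues
        return [r[i : i + 2] for i in range(len(r) - 1)]


@dataclass
class LabeledDataset:
    """Sequences with aligned class labels and a split tag."""

    sequences: list[DnaSequence]
    labels: list[str]
    split: str = "train"

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ConfigError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def subset(self, indices: Sequence[int], split: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            [self.sequences[i] for i in indices],
            [self.labels[i] for i in indices],
            split if split is not None else self.split,
        )


def read_fasta(path: str | Path, on_invalid: str = "error") -> list[DnaSequence]:
    """Read a FASTA file into validated sequences, order preserved.

    Parameters
    ----------
    path : file path to a multi-record FASTA file (at least one record).
    on_invalid : "error" (default) raises on any non-ACGT residue, naming the
        record and position; "drop" silently skips offending records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if on_invalid not in ("error", "drop"):
        raise ConfigError(f"on_invalid must be 'error' or 'drop', got {on_invalid!r}")
    sequences: list[DnaSequence] = []
    with open(path) as handle:
        first = handle.read(1)
        if not first:
            raise FastaError(f"{path}: empty FASTA file")
        if first != ">":
            raise FastaError(f"{path}: not FASTA-formatted (expected '>' header)")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            try:
                sequences.append(DnaSequence(record.id, str(record.seq)))
            except SequenceError:
                if on_invalid == "error":
                    raise
    if not sequences and on_invalid == "error":
        raise FastaError(f"{path}: no records found")
    return sequences


def write_fasta(sequences: Iterable[DnaSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sequence id, label) -> id->label map."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigError(f"{path}:{lineno}: expected 2 tab-separated columns")
        labels[parts[0]] = parts[1]
    return labels


def write_labels_tsv(dataset: LabeledDataset, path: str | Path) -> None:
    lines = [f"{s.id}\t{lab}" for s, lab in zip(dataset.sequences, dataset.labels)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_labeled_fasta(
    fasta_path: str | Path, labels_path: str | Path, split: str = "train"
) -> LabeledDataset:
    sequences = read_fasta(fasta_path)
    label_map = read_labels_tsv(labels_path)
    missing = [s.id for s in sequences if s.id not in label_map]
    if missing:
        raise ConfigError(f"no label for sequence ids: {missing[:5]}")
    return LabeledDataset(sequences, [label_map[s.id] for s in sequences], split)


# --- synthetic generation ---------------------------------------------------

#: Default planted dinucleotide composition, per class. Weights are relative
#: frequencies of the 16 dinucleotides; classes share a uniform background and
#: differ in CpG/GC-step enrichment, mimicking the GC- and CpG-rich character
#: of active enhancers: strong enhancers carry the heaviest enrichment, weak
#: enhancers an intermediate one, the background none.
DEFAULT_BIAS_SPEC: dict[str, dict[str, float]] = {
    NON_ENHANCER: {},
    STRONG_ENHANCER: {"CG": 5.0, "GC": 5.0, "CC": 2.0, "GG": 2.0},
    WEAK_ENHANCER: {"CG": 2.0, "GC": 2.0, "CC": 1.5, "GG": 1.5},
}


def _bias_to_weights(bias: Mapping[str, float]) -> np.ndarray:
    """Expand a sparse dinucleotide->weight map to the full 16-vector."""
    w = np.ones(16)
    for dinuc, weight in bias.items():
        if dinuc not in DINUCLEOTIDES:
            raise ConfigError(f"unknown dinucleotide {dinuc!r} in bias spec")
        if weight <= 0:
            raise ConfigError(f"bias weight for {dinuc!r} must be positive")
        w[DINUCLEOTIDES.index(dinuc)] = weight
    return w


def _markov_from_weights(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-order Markov chain whose transitions follow dinucleotide weights.

    Returns (initial distribution over bases, 4x4 row-stochastic transition
    matrix). Transition P(y|x) is proportional to the weight of dinucleotide
    xy; the initial distribution follows the weight marginal over the first
    base.
    """
    m = weights.reshape(4, 4)
    transition = m / m.sum(axis=1, keepdims=True)
    initial = m.sum(axis=1) / m.sum()
    return initial, transition


def generate_synthetic_dataset(
    n_total: int,
    length: int = 200,
    ratio: tuple[int, int, int] = (2, 1, 1),
    bias_spec: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    split: str = "train",
) -> LabeledDataset:
    """Generate a labeled dataset with exact class counts in the given ratio.

    Sequences are drawn from per-class first-order Markov chains derived from
    ``bias_spec`` (class -> dinucleotide -> relative weight; unlisted
    dinucleotides weigh 1). Deterministic for a fixed seed.
    """
    if length < 2:
        raise ConfigError(f"length must be >= 2, got {length}")
    parts = sum(ratio)
    if any(r <= 0 for r in ratio) or parts <= 0:
        raise ConfigError(f"ratio parts must be positive, got {ratio}")
    if n_total % parts != 0:
        raise ConfigError(
            f"n_total={n_total} is not divisible by ratio sum {parts} "
            f"(ratio {ratio}); class counts would not be exact"
        )
    if bias_spec is None:
        bias_spec = DEFAULT_BIAS_SPEC
    rng = np.random.default_rng(seed)
    unit = n_total // parts
    sequences: list[DnaSequence] = []
    labels: list[str] = []
    for label, r in zip(LABELS, ratio):
        n_class = unit * r
        initial, transition = _markov_from_weights(
            _bias_to_weights(bias_spec.get(label, {}))
        )
        # cumulative-probability inverse sampling, vectorized over sequences
        cum_init = np.cumsum(initial)
        cum_trans = np.cumsum(transition, axis=1)
        states = np.empty((n_class, length), dtype=np.int8)
        states[:, 0] = np.searchsorted(cum_init, rng.random(n_class), side="right")
        u = rng.random((n_class, length - 1))
        for t in range(1, length):
            rows = cum_trans[states[:, t - 1]]
            states[:, t] = (u[:, t - 1, None] > rows).sum(axis=1)
        base = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
        for j in range(n_class):
            residues = base[states[j]].tobytes().decode()
            sequences.append(DnaSequence(f"{label}_{j:05d}", residues))
            labels.append(label)
    return LabeledDataset(sequences, labels, split)
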