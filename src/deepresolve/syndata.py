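"""Synthetic combinatorial-logic sequence datasets.

Two benchmark datasets of fixed-length DNA sequences with short motifs
planted at random non-overlapping positions on an i.i.d. uniform ACGT
background:

* **Dataset I** (single task, AND-of-XOR logic): each patterned sequence
  carries three patterns drawn i.i.d. with replacement from {CGCTTG,
  CAGGTC, GCTCAT}; the label is 1 iff CAGGTC is present AND exactly one of
  GCTCAT/CGCTTG is present. Pure-random negatives are added on top. The
  with-replacement draw leaves motif presences negatively correlated,
  which is what makes the XOR arm of the rule learnable by gradient
  descent (under independent balanced presences it carries no first-order
  signal at all).
* **Dataset II** (four mutually exclusive classes sharing motifs): class 1
  contains GATA and CAGATG, class 2 TCAT and CAGATG, class 3 GATA and TCAT,
  and class 4 only CGCTTG, so classes 1-3 pairwise share one motif while
  class 4 shares none.

Because the planting positions are recorded (`provenance`), tests can verify
every motif occurrence, and downstream channel-to-motif matching has ground
truth to compare against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

DATASET_I_PATTERNS = ("CGCTTG", "CAGGTC", "GCTCAT")

#: motif pairs defining each of the four classes of dataset II
DATASET_II_CLASS_PATTERNS = (
    ("GATA", "CAGATG"),
    ("TCAT", "CAGATG"),
    ("GATA", "TCAT"),
    ("CGCTTG",),
)


@dataclass(frozen=True)
class MotifPattern:
    """A named exact DNA pattern planted into synthetic sequences."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("pattern must be non-empty")
        if not set(self.bases) <= set(ALPHABET):
            raise ValueError(f"pattern {self.bases!r} contains non-ACGT characters")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class LabeledSequenceSet:
    """Fixed-length DNA sequences with binary labels and planting provenance.

    ``labels`` is an (n, C) 0/1 array (C=1 for dataset I, C=4 for dataset II).
    ``provenance[i]`` lists ``(pattern_name, start)`` for every motif planted
    in sequence ``i`` (0-based starts).
    """

    sequences: list[str]
    labels: np.ndarray
    provenance: list[list[tuple[str, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        if len(self.sequences) != self.labels.shape[0]:
            raise ValueError("labels and sequences disagree in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
        if not self.provenance:
            self.provenance = [[] for _ in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def seq_len(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_classes(self) -> int:
        return self.labels.shape[1]

    def one_hot_matrix(self) -> np.ndarray:
        """All sequences one-hot encoded, shape (n, 4, L), float32."""
        return encode_batch(self.sequences)


def label_dataset_i(present: set[str] | frozenset[str]) -> int:
    """AND-of-XOR label rule for dataset I.

    Returns 1 iff CAGGTC is present and exactly one of GCTCAT, CGCTTG is.
    """
    unknown = set(present) - set(DATASET_I_PATTERNS)
    if unknown:
        raise ValueError(f"unknown pattern name(s): {sorted(unknown)}")
    xor = ("GCTCAT" in present) != ("CGCTTG" in present)
    return int("CAGGTC" in present and xor)


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a DNA string to a 4xL matrix, rows in A,C,G,T order."""
    idx = np.empty(len(seq), dtype=np.intp)
    for i, b in enumerate(seq):
        try:
            idx[i] = _BASE_INDEX[b]
        except KeyError:
            raise ValueError(f"non-ACGT character {b!r} at position {i}") from None
    out = np.zeros((4, len(seq)), dtype=np.float32)
    out[idx, np.arange(len(seq))] = 1.0
    return out


def decode_one_hot(mat: np.ndarray) -> str:
    """Argmax-decode a 4xL matrix back to a DNA string."""
    return "".join(ALPHABET[i] for i in np.argmax(mat, axis=0))


def encode_batch(seqs: list[str]) -> np.ndarray:
    if not seqs:
        return np.zeros((0, 4, 0), dtype=np.float32)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    out = np.zeros((len(seqs), 4, arr.shape[1]), dtype=np.float32)
    for i, b in enumerate(ALPHABET):
        out[:, i, :] = arr == ord(b)
    if not np.all(out.sum(axis=1) == 1.0):
        raise ValueError("non-ACGT character in sequence batch")
    return out


def _plant(rng: np.random.Generator, seq_len: int, patterns: list[str],
           max_tries: int = 1000) -> list[tuple[str, int]]:
    """Choose non-overlapping uniform-random start positions for *patterns*.

    Rejection-samples position tuples so every pattern is preserved verbatim.
    """
    if sum(len(p) for p in patterns) > seq_len:
        raise ValueError(
            f"sequence length {seq_len} too small for patterns {patterns}")
    for _ in range(max_tries):
        placed: list[tuple[str, int]] = []
        for p in patterns:
            placed.append((p, int(rng.integers(0, seq_len - len(p) + 1))))
        spans = sorted((s, s + len(p)) for p, s in placed)
        if all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1)):
            return placed
    raise RuntimeError("could not place patterns without overlap")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _assemble(rng: np.random.Generator, seq_len: int,
              patterns: list[str]) -> tuple[str, list[tuple[str, int]]]:
    base = _random_seq(rng, seq_len)
    placed = _plant(rng, seq_len, patterns)
    for pat, start in placed:
        for j, b in enumerate(pat):
            base[start + j] = _BASE_INDEX[b]
    seq = "".join(ALPHABET[i] for i in base)
    return seq, placed


def expected_positive_fraction(n_draws: int = 3) -> float:
    """Exact positive fraction among patterned sequences, by enumeration
    of all 3**n_draws equally likely ordered pattern draws."""
    hits = 0
    for combo in itertools.product(DATASET_I_PATTERNS, repeat=n_draws):
        hits += label_dataset_i(set(combo))
    return hits / 3 ** n_draws


def generate_dataset_i(n_patterned: int = 100_000, n_random: int = 20_000,
                       seq_len: int = 100, seed: int = 0,
                       n_draws: int = 3) -> LabeledSequenceSet:
    """Generate dataset I: AND-of-XOR logic over three planted motifs.

    Each patterned sequence receives ``n_draws`` patterns drawn i.i.d.
    (with replacement) from the three, planted at non-overlapping random
    positions — so a sequence can carry repeated copies of one motif, and
    motif presences are negatively correlated. Labels follow
    :func:`label_dataset_i` on the set of distinct patterns present.
    ``n_random`` additional sequences are pure background (label 0).
    """
    if seq_len < n_draws * max(len(p) for p in DATASET_I_PATTERNS):
        raise ValueError(
            f"seq_len={seq_len} too small for {n_draws} planted patterns")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    labels = np.zeros(n_patterned + n_random, dtype=np.int8)
    prov: list[list[tuple[str, int]]] = []
    draw_idx = rng.integers(0, 3, size=(n_patterned, n_draws))
    for i in range(n_patterned):
        patterns = [DATASET_I_PATTERNS[j] for j in draw_idx[i]]
        seq, placed = _assemble(rng, seq_len, patterns)
        seqs.append(seq)
        prov.append(placed)
        labels[i] = label_dataset_i(set(patterns))
    for _ in range(n_random):
        seqs.append("".join(ALPHABET[i] for i in _random_seq(rng, seq_len)))
        prov.append([])
    return LabeledSequenceSet(seqs, labels[:, None], prov)


def generate_dataset_ii(n_per_class: int = 25_000, seq_len: int = 100,
                        seed: int = 0) -> LabeledSequenceSet:
    """Generate dataset II: four mutually exclusive motif-defined classes."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    prov: list[list[tuple[str, int]]] = []
    n = 4 * n_per_class
    labels = np.zeros((n, 4), dtype=np.int8)
    row = 0
    for cls, patterns in enumerate(DATASET_II_CLASS_PATTERNS):
        for _ in range(n_per_class):
            seq, placed = _assemble(rng, seq_len, list(patterns))
            seqs.append(seq)
            prov.append(placed)
            labels[row, cls] = 1
            row += 1
    # shuffle so train/test splits are class-balanced
    order = rng.permutation(n)
    return LabeledSequenceSet([seqs[i] for i in order], labels[order],
                              [prov[i] for i in order])


def write_fasta(sset: LabeledSequenceSet, path) -> None:
    """Write a FASTA with labels encoded in headers as ``label=0,1,...``."""
    records = []
    for i, (seq, lab) in enumerate(zip(sset.sequences, sset.labels)):
        prov = ";".join(f"{p}@{s}" for p, s in sset.provenance[i])
        desc = "label=" + ",".join(str(int(v)) for v in lab)
        if prov:
            desc += f" motifs={prov}"
        records.append(SeqRecord(Seq(seq), id=f"seq{i}", description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> LabeledSequenceSet:
    """Read a FASTA written by :func:`write_fasta` (labels in headers)."""
    seqs: list[str] = []
    labels: list[list[int]] = []
    prov: list[list[tuple[str, int]]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split() if "=" in t)
        if "label" not in tokens:
            raise ValueError(f"record {rec.id!r} has no label= token")
        labels.append([int(v) for v in tokens["label"].split(",")])
        entry: list[tuple[str, int]] = []
        for item in tokens.get("motifs", "").split(";"):
            if item:
                pat, start = item.split("@")
                entry.append((pat, int(start)))
        prov.append(entry)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        return LabeledSequenceSet([], np.zeros((0, 1), dtype=np.int8), [])
    return LabeledSequenceSet(seqs, np.asarray(labels, dtype=np.int8), prov)
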