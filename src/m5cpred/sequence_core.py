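"""Sequence I/O and cytosine-centered fragment extraction.

RNA modification-site predictors operate on fixed-width windows centered on
a candidate cytosine: a window of 2*lambda + 1 nucleotides (default lambda
= 20, i.e. 41 nt) with the candidate C at the middle position.  This module
reads FASTA input, normalizes it onto the {A, C, G, U, N} alphabet (DNA is
accepted via T -> U), and extracts one window per cytosine, N-padding
flanks that run off the sequence ends.

Coordinates in every public report are 1-based (the candidate C of a 41-nt
training fragment sits at position 21); internal indices are 0-based.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical residue alphabet.  'N' is a padding/unknown symbol: encoders
#: never count it as a nucleotide.
ALPHABET = "ACGUN"

#: Integer codes used by the vectorized encoders (A=0, C=1, G=2, U=3, N=4).
NUC_TO_CODE = {c: i for i, c in enumerate(ALPHABET)}
CODE_N = NUC_TO_CODE["N"]

_NORMALIZE_TABLE = {c: c for c in "ACGU"}
_NORMALIZE_TABLE["T"] = "U"


class SequenceError(ValueError):
    """Raised for malformed or invalid sequence input."""


@dataclass(frozen=True)
class RNASequence:
    """A normalized RNA sequence over {A, C, G, U, N}."""

    id: str
    residues: str
    n_substitutions: int = 0  # non-ACGUT characters mapped to 'N'

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty sequence")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains unnormalized characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RNAFragment:
    """A fixed-width window with a candidate cytosine at its center.

    ``center_pos_1based`` is the 1-based position of the central C in the
    parent sequence; ``window`` has length ``2 * lambda_flank + 1``.
    """

    parent_id: str
    center_pos_1based: int
    window: str
    lambda_flank: int = 20

    def __post_init__(self) -> None:
        width = 2 * self.lambda_flank + 1
        if len(self.window) != width:
            raise SequenceError(
                f"fragment {self.parent_id!r}@{self.center_pos_1based}: window "
                f"length {len(self.window)} != 2*lambda+1 = {width}"
            )
        if self.window[self.lambda_flank] != "C":
            raise SequenceError(
                f"fragment {self.parent_id!r}@{self.center_pos_1based}: center "
                f"residue {self.window[self.lambda_flank]!r} is not 'C'"
            )
        bad = set(self.window) - set(ALPHABET)
        if bad:
            raise SequenceError(
                f"fragment {self.parent_id!r}: invalid characters {sorted(bad)}"
            )

    def codes(self) -> np.ndarray:
        """Window as an integer code array (A=0, C=1, G=2, U=3, N=4)."""
        return np.frombuffer(
            self.window.translate(_CODE_TRANSLATION).encode("ascii"), dtype=np.uint8
        ).copy()


_CODE_TRANSLATION = str.maketrans({c: chr(i) for c, i in NUC_TO_CODE.items()})


@dataclass
class LabeledDataset:
    """Fragments plus binary labels (1 = m5C, 0 = non-m5C)."""

    fragments: list[RNAFragment]
    labels: np.ndarray
    lambda_flank: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.fragments) != len(self.labels):
            raise ValueError("fragments and labels differ in length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        for f in self.fragments:
            if f.lambda_flank != self.lambda_flank:
                raise ValueError("all fragments must share lambda_flank")

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def code_matrix(self) -> np.ndarray:
        """(n, 2*lambda+1) uint8 matrix of residue codes for all fragments."""
        if not self.fragments:
            return np.empty((0, 2 * self.lambda_flank + 1), dtype=np.uint8)
        return np.stack([f.codes() for f in self.fragments])

    def fingerprint(self) -> str:
        """Stable digest of windows + labels (used as a leakage guard)."""
        h = hashlib.sha256()
        for frag, lab in zip(self.fragments, self.labels):
            h.update(frag.window.encode())
            h.update(b"1" if lab else b"0")
        return h.hexdigest()

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            fragments=[self.fragments[i] for i in idx],
            labels=self.labels[idx],
            lambda_flank=self.lambda_flank,
        )


def normalize_sequence(raw: str, seq_id: str = "seq") -> RNASequence:
    """Uppercase, map T->U, and map any other non-ACGU character to 'N'.

    The number of forced substitutions (characters outside A/C/G/U/T) is
    recorded on the returned sequence.
    """
    if not raw:
        raise SequenceError("empty sequence")
    out = []
    n_sub = 0
    for ch in raw.upper():
        mapped = _NORMALIZE_TABLE.get(ch)
        if mapped is None:
            mapped = "N"
            if ch != "N":
                n_sub += 1
        out.append(mapped)
    return RNASequence(id=seq_id, residues="".join(out), n_substitutions=n_sub)


def read_fasta(path: str | Path) -> list[RNASequence]:
    """Read a FASTA file and normalize every record onto {A,C,G,U,N}."""
    path = Path(path)
    records = []
    with open(path) as handle:
        # Biopython silently skips leading junk; reject sequence-before-header
        # explicitly so truncated files fail loudly.
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise SequenceError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(normalize_sequence(str(rec.seq), seq_id=rec.id))
    return records


def write_fasta(sequences: Iterable[RNASequence], path: str | Path) -> None:
    """Write sequences as FASTA (one line per sequence body)."""
    recs = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(recs, str(path), "fasta-2line")


def extract_fragments(seq: RNASequence, lambda_flank: int = 20) -> list[RNAFragment]:
    """Extract one cytosine-centered window per 'C' in the sequence.

    Flank positions falling outside the sequence are filled with 'N',
    mirroring how a site scanner treats cytosines near sequence ends.
    """
    if lambda_flank < 1:
        raise ValueError("lambda_flank must be >= 1")
    padded = "N" * lambda_flank + seq.residues + "N" * lambda_flank
    fragments = []
    for i, ch in enumerate(seq.residues):
        if ch == "C":
            window = padded[i : i + 2 * lambda_flank + 1]
            fragments.append(
                RNAFragment(
                    parent_id=seq.id,
                    center_pos_1based=i + 1,
                    window=window,
                    lambda_flank=lambda_flank,
                )
            )
    return fragments


def _fragment_from_record(
    seq: RNASequence, lambda_flank: int
) -> RNAFragment:
    width = 2 * lambda_flank + 1
    if len(seq) != width:
        raise SequenceError(
            f"record {seq.id!r}: length {len(seq)} != expected {width}"
        )
    if seq.residues[lambda_flank] != "C":
        raise SequenceError(
            f"record {seq.id!r}: center residue {seq.residues[lambda_flank]!r} is not 'C'"
        )
    return RNAFragment(
        parent_id=seq.id,
        center_pos_1based=lambda_flank + 1,
        window=seq.residues,
        lambda_flank=lambda_flank,
    )


def load_dataset(
    pos_path: str | Path, neg_path: str | Path, lambda_flank: int = 20
) -> LabeledDataset:
    """Load positive/negative fragment FASTA files into a labeled dataset.

    Every record must be exactly 2*lambda+1 nt with a central C after
    normalization; offending records are reported together by id.
    """
    fragments: list[RNAFragment] = []
    labels: list[int] = []
    bad: list[str] = []
    for path, label in ((pos_path, 1), (neg_path, 0)):
        for seq in read_fasta(path):
            try:
                fragments.append(_fragment_from_record(seq, lambda_flank))
                labels.append(label)
            except SequenceError as exc:
                bad.append(str(exc))
    if bad:
        raise SequenceError(
            "rejected records:\n" + "\n".join(bad)
        )
    return LabeledDataset(fragments=fragments, labels=np.array(labels), lambda_flank=lambda_flank)
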