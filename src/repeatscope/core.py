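"""Shared containers and small sequence utilities.

Coordinates are 0-based half-open throughout the library; 1-based inclusive
coordinates appear only in human-readable report headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Repeat taxonomy vocabulary used by annotation and census tables
#: (Wicker-style superfamilies plus the bookkeeping labels).
CLASS_LABELS = (
    "Tc1-Mariner",
    "hAT",
    "Mutator",
    "PIF-Harbinger",
    "CACTA",
    "Helitron",
    "MITE",
    "LTR-Copia",
    "LTR-Gypsy",
    "LTR-Unknown",
    "Non-LTR",
    "Pararetrovirus",
    "tandem/SSR",
    "rDNA",
    "gene",
    "unknown-repeat",
    "no-hit",
)

#: Class II (DNA transposon) labels.
DNA_TRANSPOSON_LABELS = frozenset(
    {"Tc1-Mariner", "hAT", "Mutator", "PIF-Harbinger", "CACTA", "Helitron", "MITE"}
)

#: LTR retrotransposon labels (element = LTR + internal + LTR).
LTR_LABELS = frozenset({"LTR-Copia", "LTR-Gypsy", "LTR-Unknown"})

#: Retrotransposon labels in general.
RETRO_LABELS = LTR_LABELS | {"Non-LTR", "Pararetrovirus"}

DNA_ALPHABET = "ACGT"
_DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """i.i.d. uniform A/C/G/T string of length ``n``."""
    if n < 0:
        raise ValueError("length must be non-negative")
    idx = rng.integers(0, 4, size=n)
    return _DNA_BYTES[idx].tobytes().decode("ascii")


@dataclass
class Read:
    """A sequenced fragment.

    ``origin`` records the simulator's ground truth when available:
    ``(source, start, end, strand)`` with source ``"nuclear"`` or
    ``"organellar"`` and the interval on the source sequence the read was
    drawn from (before error injection).
    """

    read_id: str
    sequence: str
    origin: tuple | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Contig:
    """An assembled consensus sequence.

    ``average_coverage`` is filled in after mapping a read set back to the
    contig (sum of aligned read bases / contig length); it is ``None`` until
    then.
    """

    contig_id: str
    sequence: str
    member_read_ids: list = field(default_factory=list)
    depth_profile: np.ndarray | None = None
    average_coverage: float | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Placement:
    """One read's best-match alignment to one reference.

    ``aligned_bases`` counts read bases inside the aligned segment (the
    numerator of the average-coverage statistic); ``start``/``end`` delimit
    the matched region on the reference.
    """

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    aligned_bases: int
    identity: float


def total_bases(reads) -> int:
    """Total sequence length over an iterable of reads."""
    return sum(len(r.sequence) for r in reads)
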