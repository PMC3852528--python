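"""Synthetic genomes with planted repeat structure, and shotgun read simulation.

The generator plants a configurable census of repetitive elements into a
random background genome so that every downstream stage (assembly, mapping,
redundancy classification, family clustering, composition, solo-LTR
inference) can be validated against known truth:

* LTR retrotransposon families — two identical long terminal repeats
  flanking an internal region, planted both as full elements and as
  solo-LTRs (single LTR copies left behind by unequal recombination);
* DNA transposon families (MITEs carry terminal inverted repeats);
* tandem repeat arrays and rDNA-like multi-copy elements;
* single-copy gene segments;
* an organellar contaminant pool, kept apart from the nuclear sequence and
  sampled into the read stream at a configurable fraction.

Background sequence and canonical elements are i.i.d. uniform over
{A,C,G,T}; copies of a family diverge from the canonical element by
independent per-base substitutions. Elements are planted without overlap
(nesting is a non-goal), with positions uniform over the remaining free
space. All randomness derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CLASS_LABELS, LTR_LABELS, Read, random_dna, revcomp

_MITE_TIR_LEN = 15


@dataclass
class RepeatFamilySpec:
    """Declared anatomy and census of one planted repeat family.

    For LTR kinds the element is ``ltr_length + internal_length +
    ltr_length`` nt; ``solo_ltr_copies`` additional bare LTRs are planted.
    For all other kinds the element is ``element_length`` nt and
    ``solo_ltr_copies`` must be 0. ``divergence`` is the per-base
    substitution probability applied independently to every planted copy.
    """

    family_id: str
    class_label: str
    full_copies: int
    ltr_length: int = 0
    internal_length: int = 0
    element_length: int = 0
    solo_ltr_copies: int = 0
    divergence: float = 0.0

    @property
    def is_ltr(self) -> bool:
        return self.class_label in LTR_LABELS

    @property
    def full_length(self) -> int:
        if self.is_ltr:
            return 2 * self.ltr_length + self.internal_length
        return self.element_length

    def validate(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.full_copies < 0:
            raise ValueError("full_copies must be >= 0")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must lie in [0, 0.3]")
        if self.is_ltr:
            if self.ltr_length < 50 or self.internal_length < 200:
                raise ValueError(
                    f"{self.family_id}: LTR families need ltr_length >= 50 and "
                    "internal_length >= 200 so both regions are separately mappable"
                )
            if self.solo_ltr_copies < 0:
                raise ValueError("solo_ltr_copies must be >= 0")
        else:
            if self.solo_ltr_copies != 0:
                raise ValueError(
                    f"{self.family_id}: solo_ltr_copies only applies to LTR families"
                )
            if self.element_length < 1:
                raise ValueError(f"{self.family_id}: element_length must be positive")


@dataclass
class ReadProfile:
    """Length/error model for one sequencing technology.

    ``length`` gives a fixed read length (short-read style); alternatively
    ``length_mean``/``length_sd`` describe a truncated normal (pyrosequencing
    style). Lengths are never below ``min_length``. Errors are per-base
    substitutions and single-base indels.
    """

    name: str
    length: int | None = None
    length_mean: float | None = None
    length_sd: float | None = None
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    min_length: int = 30

    def validate(self) -> None:
        if not 0.0 <= self.substitution_rate <= 0.1:
            raise ValueError("substitution_rate must lie in [0, 0.1]")
        if not 0.0 <= self.indel_rate <= 0.1:
            raise ValueError("indel_rate must lie in [0, 0.1]")
        if self.length is None and self.length_mean is None:
            raise ValueError("profile needs a fixed length or a (mean, sd)")
        if self.length is not None and self.length < self.min_length:
            raise ValueError("fixed length below min_length")

    def draw_length(self, rng: np.random.Generator) -> int:
        if self.length is not None:
            return self.length
        sd = self.length_sd or 0.0
        val = int(round(rng.normal(self.length_mean, sd)))
        return max(val, self.min_length)


@dataclass
class TandemSpec:
    """A tandem repeat array: ``unit_length`` nt repeated ``unit_count``
    times, planted ``array_copies`` times."""

    unit_length: int
    unit_count: int
    array_copies: int


@dataclass
class SimulationConfig:
    genome_length: int
    seed: int
    families: list = field(default_factory=list)
    gene_count: int = 0
    gene_length: int = 1000
    tandem_specs: list = field(default_factory=list)
    organellar_length: int = 0
    organellar_read_fraction: float = 0.0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.organellar_read_fraction < 1.0:
            raise ValueError("organellar_read_fraction must lie in [0, 1)")
        if self.organellar_read_fraction > 0 and self.organellar_length <= 0:
            raise ValueError("organellar reads requested without an organellar pool")
        for fam in self.families:
            fam.validate()


@dataclass
class Instance:
    """One planted occurrence: interval on the genome, 0-based half-open."""

    instance_id: str
    family_id: str
    class_label: str
    start: int
    end: int
    kind: str  # full | solo_ltr | gene | tandem


@dataclass
class GenomeTruth:
    """Ground truth of a simulated genome.

    ``instances`` lists every planted occurrence; positions not covered by
    any instance are unique background. The organellar contaminant sequence
    is carried separately — it is never part of the nuclear genome.
    """

    genome_sequence: str
    instances: list
    organellar_sequence: str = ""
    organellar_read_fraction: float = 0.0

    def per_base_class(self) -> np.ndarray:
        """Class label index per genome position ('unique' background = -1)."""
        arr = np.full(len(self.genome_sequence), -1, dtype=np.int16)
        for inst in self.instances:
            label = inst.class_label
            arr[inst.start : inst.end] = CLASS_LABELS.index(label)
        return arr

    def class_genome_fractions(self) -> dict:
        """Fraction of the nuclear genome occupied by each class label
        (background reported under ``"unique"``)."""
        g = len(self.genome_sequence)
        out: dict = {}
        covered = 0
        for inst in self.instances:
            span = inst.end - inst.start
            out[inst.class_label] = out.get(inst.class_label, 0) + span
            covered += span
        fractions = {label: n / g for label, n in out.items()}
        fractions["unique"] = (g - covered) / g
        return fractions

    def instances_by_kind(self, kind: str) -> list:
        return [i for i in self.instances if i.kind == kind]


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``divergence``."""
    if divergence <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < divergence
    n_hit = int(hit.sum())
    if n_hit == 0:
        return seq
    # replace with one of the three other bases, uniformly
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    cur = arr[hit]
    shift = rng.integers(1, 4, size=n_hit)
    code = np.searchsorted(bases, cur)
    arr[hit] = bases[(code + shift) % 4]
    return arr.tobytes().decode("ascii")


def build_repeat_library(config: SimulationConfig) -> dict:
    """Canonical (undiverged) element sequence per family.

    LTR families: ``LTR + internal + identical LTR``. MITEs carry a 15-nt
    terminal inverted repeat. Deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    library: dict = {}
    for fam in config.families:
        fam.validate()
        if fam.is_ltr:
            ltr = random_dna(rng, fam.ltr_length)
            internal = random_dna(rng, fam.internal_length)
            library[fam.family_id] = ltr + internal + ltr
        elif fam.class_label == "MITE":
            if fam.element_length < 2 * _MITE_TIR_LEN + 1:
                raise ValueError(f"{fam.family_id}: MITE too short for terminal repeats")
            tir = random_dna(rng, _MITE_TIR_LEN)
            mid = random_dna(rng, fam.element_length - 2 * _MITE_TIR_LEN)
            library[fam.family_id] = tir + mid + revcomp(tir)
        else:
            library[fam.family_id] = random_dna(rng, fam.element_length)
    return library


def _uniform_gaps(rng: np.random.Generator, free: int, n_gaps: int) -> np.ndarray:
    """Split ``free`` background bases uniformly into ``n_gaps`` gaps."""
    if n_gaps == 1:
        return np.array([free], dtype=np.int64)
    return rng.multinomial(free, np.full(n_gaps, 1.0 / n_gaps))


def plant_genome(library: dict, config: SimulationConfig) -> GenomeTruth:
    """Place every declared copy into a random background genome.

    Placements are non-overlapping, in seeded-random order, with positions
    uniform over the free space (gap lengths multinomial over background
    bases). Fails if the planted material exceeds the genome length.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    pieces = []  # (family_id, class_label, kind, sequence)
    for fam in config.families:
        if fam.family_id not in library:
            raise ValueError(f"library is missing family {fam.family_id!r}")
        canonical = library[fam.family_id]
        for _ in range(fam.full_copies):
            pieces.append(
                (fam.family_id, fam.class_label, "full", mutate(canonical, fam.divergence, rng))
            )
        if fam.is_ltr:
            ltr = canonical[: fam.ltr_length]
            for _ in range(fam.solo_ltr_copies):
                pieces.append(
                    (fam.family_id, fam.class_label, "solo_ltr", mutate(ltr, fam.divergence, rng))
                )
    for t_idx, spec in enumerate(config.tandem_specs):
        unit = random_dna(rng, spec.unit_length)
        array = unit * spec.unit_count
        for _ in range(spec.array_copies):
            pieces.append((f"tandem_{t_idx}", "tandem/SSR", "tandem", array))
    for g_idx in range(config.gene_count):
        pieces.append((f"gene_{g_idx}", "gene", "gene", random_dna(rng, config.gene_length)))

    planted = sum(len(p[3]) for p in pieces)
    if planted > config.genome_length:
        raise ValueError(
            f"planted material ({planted} nt) exceeds genome_length ({config.genome_length} nt)"
        )

    order = rng.permutation(len(pieces))
    gaps = _uniform_gaps(rng, config.genome_length - planted, len(pieces) + 1)

    parts = []
    instances = []
    pos = 0
    for slot, piece_idx in enumerate(order):
        gap = int(gaps[slot])
        parts.append(random_dna(rng, gap))
        pos += gap
        family_id, class_label, kind, seq = pieces[piece_idx]
        parts.append(seq)
        instances.append(
            Instance(
                instance_id=f"inst_{len(instances)}",
                family_id=family_id,
                class_label=class_label,
                start=pos,
                end=pos + len(seq),
                kind=kind,
            )
        )
        pos += len(seq)
    parts.append(random_dna(rng, int(gaps[-1])))
    genome = "".join(parts)
    assert len(genome) == config.genome_length

    org_rng = np.random.default_rng([config.seed, 2])
    organellar = random_dna(org_rng, config.organellar_length)
    return GenomeTruth(
        genome_sequence=genome,
        instances=instances,
        organellar_sequence=organellar,
        organellar_read_fraction=config.organellar_read_fraction,
    )


def _apply_errors(seq: str, profile: ReadProfile, rng: np.random.Generator) -> str:
    if profile.substitution_rate > 0.0:
        seq = mutate(seq, profile.substitution_rate, rng)
    if profile.indel_rate > 0.0:
        hits = np.nonzero(rng.random(len(seq)) < profile.indel_rate)[0]
        if hits.size:
            out = []
            prev = 0
            for pos in hits:
                out.append(seq[prev:pos])
                if rng.random() < 0.5:  # insertion of one random base before pos
                    out.append("ACGT"[rng.integers(0, 4)])
                    out.append(seq[pos])
                # else: deletion of the base at pos
                prev = pos + 1
            out.append(seq[prev:])
            seq = "".join(out)
    return seq


def simulate_reads(
    truth: GenomeTruth,
    profile: ReadProfile,
    coverage: float,
    seed: int,
    name_prefix: str | None = None,
) -> list:
    """Sample error-bearing single-end reads at the requested coverage.

    Coverage is total read bases / genome length; sampling stops once the
    target is reached, so the total is within one read length of it. Start
    positions are uniform, strands equiprobable; a configurable fraction of
    reads is drawn from the organellar pool instead of the nuclear genome.
    Each read records its true (pre-error) origin interval.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    profile.validate()
    rng = np.random.default_rng(seed)
    genome = truth.genome_sequence
    target = coverage * len(genome)
    prefix = name_prefix if name_prefix is not None else profile.name
    reads: list = []
    total = 0
    i = 0
    while total < target:
        length = profile.draw_length(rng)
        from_org = (
            truth.organellar_read_fraction > 0.0
            and rng.random() < truth.organellar_read_fraction
        )
        source_seq = truth.organellar_sequence if from_org else genome
        source = "organellar" if from_org else "nuclear"
        length = min(length, len(source_seq))
        start = int(rng.integers(0, len(source_seq) - length + 1))
        fragment = source_seq[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = revcomp(fragment)
        seq = _apply_errors(fragment, profile, rng)
        reads.append(
            Read(
                read_id=f"{prefix}_{i}",
                sequence=seq,
                origin=(source, start, start + length, strand),
            )
        )
        total += len(seq)
        i += 1
    return reads


def expected_solo_ltr_ratio(spec: RepeatFamilySpec) -> float:
    """Closed-form LTR / inter-LTR redundancy ratio for a planted family.

    Each intact element contributes two LTRs and one internal region, each
    solo-LTR one more LTR, so the ratio of LTR to internal copy number is
    ``(2 * full + solo) / full`` — exactly 2 when every element is intact.
    """
    if not spec.is_ltr:
        raise ValueError("solo-LTR ratio is defined for LTR families only")
    if spec.full_copies == 0:
        raise ValueError("ratio undefined: no intact copies planted")
    return (2.0 * spec.full_copies + spec.solo_ltr_copies) / spec.full_copies
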