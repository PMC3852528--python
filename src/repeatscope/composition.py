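"""Genome composition tables and the LTR / inter-LTR solo-LTR analysis.

Because reads are sampled uniformly from the genome, the fraction of
reads assigned to a sequence class estimates the genomic proportion of
that class. Reads are attributed to classes via the classification and
annotation of the contig they map to; reads on low-copy contigs count as
"unique or low redundant". Accounting identities (matched + unmatched =
total nuclear reads; class counts sum to the matched total) are enforced
on every table, not merely reported.

For LTR retrotransposons, mapping reads to an intact element while
keeping the two LTRs separate from the internal (inter-LTR) region
yields a coverage ratio that equals 2 when every genomic copy is intact;
each solo-LTR (an LTR left behind after unequal recombination removed
the rest of the element) pushes the ratio above 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .mapping import region_coverage
from .simulate import expected_solo_ltr_ratio

UNIQUE_LABEL = "Unique or low redundant"


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed tables."""
    if math.isinf(x) or math.isnan(x):
        return x
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(quant, rounding=ROUND_HALF_UP))


@dataclass
class CompositionRow:
    class_label: str
    matched_read_count: int
    pct_total_nuclear: float
    pct_matched: float


@dataclass
class CompositionTable:
    rows: list
    matched_total: int
    unmatched: int
    total_nuclear: int
    organellar: int

    @property
    def total_reads(self) -> int:
        return self.total_nuclear + self.organellar

    def pct_of_total(self, label: str) -> float:
        return next(r.pct_total_nuclear for r in self.rows if r.class_label == label)

    def pct_of_matched(self, label: str) -> float:
        return next(r.pct_matched for r in self.rows if r.class_label == label)

    def count(self, label: str) -> int:
        return next(r.matched_read_count for r in self.rows if r.class_label == label)

    def validate(self) -> None:
        if sum(r.matched_read_count for r in self.rows) != self.matched_total:
            raise ValueError("class counts do not sum to the matched total")
        if self.matched_total + self.unmatched != self.total_nuclear:
            raise ValueError("matched + unmatched must equal total nuclear reads")
        if self.rows:
            pct_sum = sum(r.pct_matched for r in self.rows)
            if abs(pct_sum - 100.0) > 0.05:
                raise ValueError(f"matched percentages sum to {pct_sum}, not 100.00 +/- 0.05")


def composition_table(class_counts: dict, total_nuclear: int, organellar: int) -> CompositionTable:
    """Build and validate a composition table from per-class matched read
    counts. Percentages are exact ratios rounded half-up to 2 decimals."""
    matched_total = sum(class_counts.values())
    if matched_total > total_nuclear:
        raise ValueError("matched reads exceed total nuclear reads")
    rows = [
        CompositionRow(
            class_label=label,
            matched_read_count=count,
            pct_total_nuclear=round_half_up(100.0 * count / total_nuclear),
            pct_matched=round_half_up(100.0 * count / matched_total) if matched_total else 0.0,
        )
        for label, count in class_counts.items()
    ]
    table = CompositionTable(
        rows=rows,
        matched_total=matched_total,
        unmatched=total_nuclear - matched_total,
        total_nuclear=total_nuclear,
        organellar=organellar,
    )
    table.validate()
    return table


def composition_by_class(placements, repeated_ids, annotations, total_nuclear: int,
                         organellar: int) -> CompositionTable:
    """Tally placed reads by the class of their reference contig.

    ``repeated_ids``: contigs classified repeated; their class comes from
    ``annotations`` (contig_id -> class label or AnnotationRecord). Reads
    on any other reference count as unique / low redundant.
    """
    label_of = {}
    for cid, ann in (annotations or {}).items():
        label_of[cid] = ann if isinstance(ann, str) else ann.class_label
    repeated = set(repeated_ids)
    missing = repeated - set(label_of)
    if missing:
        raise ValueError(f"repeated contigs lack annotations: {sorted(missing)[:5]}")
    counts: dict = {}
    n_placed = 0
    for p in placements:
        n_placed += 1
        label = label_of[p.ref_id] if p.ref_id in repeated else UNIQUE_LABEL
        counts[label] = counts.get(label, 0) + 1
    if n_placed > total_nuclear:
        raise ValueError("more placements than nuclear reads")
    return composition_table(counts, total_nuclear, organellar)


def class_ratio(count_a: float, count_b: float, decimals: int = 2) -> float:
    """Abundance ratio a/b, rounded half-up to the requested decimals."""
    if count_b == 0:
        raise ZeroDivisionError("undefined ratio: zero denominator")
    return round_half_up(count_a / count_b, decimals)


@dataclass
class LTRElementModel:
    """Region anatomy of one intact LTR retrotransposon reference:
    two LTR intervals flanking one internal interval (0-based half-open
    on the element sequence, ordered LTR - internal - LTR)."""

    element_id: str
    superfamily: str  # Copia | Gypsy | Unknown
    ltr_intervals: tuple
    internal_interval: tuple

    def validate(self) -> None:
        (a1, a2), (b1, b2) = self.ltr_intervals
        (i1, i2) = self.internal_interval
        if not (a1 < a2 <= i1 < i2 <= b1 < b2):
            raise ValueError("intervals must be ordered LTR - internal - LTR, non-overlapping")

    @classmethod
    def from_family_spec(cls, spec, superfamily: str | None = None):
        """Anatomy of a simulated family's canonical element."""
        if not spec.is_ltr:
            raise ValueError("need an LTR family")
        ltr, internal = spec.ltr_length, spec.internal_length
        fam = superfamily or spec.class_label.replace("LTR-", "")
        return cls(
            element_id=spec.family_id,
            superfamily=fam,
            ltr_intervals=((0, ltr), (ltr + internal, 2 * ltr + internal)),
            internal_interval=(ltr, ltr + internal),
        )


@dataclass
class LTRRatioRecord:
    element_id: str
    superfamily: str
    ltr_avg_cov: float
    internal_avg_cov: float

    @property
    def ratio(self) -> float:
        if self.internal_avg_cov == 0:
            return math.inf
        return self.ltr_avg_cov / self.internal_avg_cov

    @property
    def solo_ltr_flag(self) -> bool:
        return self.ratio > 2.0


def ltr_inter_ltr_ratio(element: LTRElementModel, placements, element_length: int | None = None
                        ) -> LTRRatioRecord:
    """LTR vs inter-LTR average coverage of one element from placements on
    it.

    The two LTRs of an element are copies of one sequence, and the LTR is
    treated as a single reference: aligned bases falling in either LTR
    interval are pooled and divided by the length of *one* LTR. With that
    convention an all-intact family gives a ratio of 2 (two LTRs per
    internal region), and every solo-LTR in the genome pushes it higher.
    """
    element.validate()
    (a1, a2), (b1, b2) = element.ltr_intervals
    i1, i2 = element.internal_interval
    length = element_length if element_length is not None else b2
    covs = region_coverage(placements, element.element_id, length,
                           [(a1, a2), (b1, b2), (i1, i2)])
    single_ltr_len = ((a2 - a1) + (b2 - b1)) / 2.0
    ltr_cov = (covs[0] * (a2 - a1) + covs[1] * (b2 - b1)) / single_ltr_len
    return LTRRatioRecord(
        element_id=element.element_id,
        superfamily=element.superfamily,
        ltr_avg_cov=ltr_cov,
        internal_avg_cov=covs[2],
    )


def ratio_means(records, decimals: int = 2):
    """Per-superfamily and overall means of the *unrounded* ratios,
    rounded half-up only for display. Records with an infinite ratio
    (internal coverage 0) are excluded from the means."""
    finite = [r for r in records if math.isfinite(r.ratio)]
    groups: dict = {}
    for rec in finite:
        groups.setdefault(rec.superfamily, []).append(rec.ratio)
    group_means = {
        fam: round_half_up(sum(vals) / len(vals), decimals)
        for fam, vals in groups.items()
        if vals
    }
    overall = (
        round_half_up(sum(r.ratio for r in finite) / len(finite), decimals) if finite else None
    )
    return group_means, overall


def solo_ltr_recovery(family_specs, records) -> list:
    """Join observed LTR/inter-LTR ratios with the closed-form expectation
    (2 + solo/full) per planted family; returns rows of
    (family_id, expected_ratio, observed_ratio, abs_error)."""
    by_id = {r.element_id: r for r in records}
    rows = []
    for spec in family_specs:
        if not getattr(spec, "is_ltr", False) or spec.family_id not in by_id:
            continue
        expected = expected_solo_ltr_ratio(spec)
        observed = by_id[spec.family_id].ratio
        err = abs(observed - expected) if math.isfinite(observed) else math.inf
        rows.append((spec.family_id, expected, observed, err))
    return rows
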