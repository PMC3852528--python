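"""Redundancy classification, repeat annotation and family clustering.

The repeat database construction follows a read-depth logic: map a
high-coverage read set to the merged contig pool together with a handful
of known single-copy genes, set the redundancy threshold at a multiple
(default 5x) of the mean average coverage of those genes, and call every
contig strictly above the threshold *repeated*. Repeated contigs are
annotated against a labeled repeat library (best = longest significant
match), screened for tandem/low-complexity structure, and grouped into
families by single-linkage over all-by-all best hits.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .align import ScoreScheme, all_local_hits
from .core import CLASS_LABELS

_SSR_MAX_UNIT = 6
_SSR_MIN_ARRAY = 24
_ENTROPY_WINDOW = 64
_ENTROPY_MIN_BITS = 1.0
_LOW_COMPLEXITY_FRACTION = 0.5


@dataclass
class RedundancyThreshold:
    """Average-coverage cutoff separating repeated from low-copy contigs."""

    reference_gene_ids: list
    mean_reference_coverage: float
    multiplier: float = 5.0

    @property
    def value(self) -> float:
        return self.multiplier * self.mean_reference_coverage


@dataclass
class AnnotationRecord:
    contig_id: str
    hit_id: str | None
    class_label: str
    match_length: int
    e_value: float
    identity: float


def calibrate_threshold(coverage_report, reference_gene_ids, multiplier: float = 5.0):
    """Threshold = multiplier x mean average coverage of the reference
    single-copy genes."""
    reference_gene_ids = list(reference_gene_ids)
    if not reference_gene_ids:
        raise ValueError("need at least one reference gene")
    covs = [coverage_report.average_coverage(g) for g in reference_gene_ids]
    return RedundancyThreshold(
        reference_gene_ids=reference_gene_ids,
        mean_reference_coverage=sum(covs) / len(covs),
        multiplier=multiplier,
    )


def classify_contigs(coverage_report, threshold: RedundancyThreshold):
    """Partition contigs into (repeated, low-copy) by strict comparison
    with the threshold — a coverage exactly at the cutoff is low-copy."""
    repeated, low_copy = [], []
    cutoff = threshold.value
    for ref_id, (_count, cov) in coverage_report.per_ref.items():
        (repeated if cov > cutoff else low_copy).append(ref_id)
    return sorted(repeated), sorted(low_copy)


def mask_fraction(contig_seq: str, contaminant_db, scheme: ScoreScheme | None = None,
                  e_cutoff: float = 1e-10) -> float:
    """Fraction of the contig covered by contaminant similarity (interval
    union over all significant hits). The exclusion rule applies at >= 1%."""
    if not contig_seq:
        return 0.0
    intervals = []
    for entry in contaminant_db:
        subject = entry[1] if isinstance(entry, tuple) else entry.sequence
        if not subject:
            continue
        for hit in all_local_hits(contig_seq, subject, scheme, e_cutoff=e_cutoff):
            intervals.append((hit.query_start, hit.query_end))
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / len(contig_seq)


def exclude_contaminated(contigs, contaminant_db, scheme: ScoreScheme | None = None,
                         e_cutoff: float = 1e-10, max_fraction: float = 0.01):
    """Drop contigs with at least ``max_fraction`` of their length similar
    to contaminant sequences. Returns (kept, excluded)."""
    kept, excluded = [], []
    for contig in contigs:
        frac = mask_fraction(contig.sequence, contaminant_db, scheme, e_cutoff)
        (excluded if frac >= max_fraction else kept).append(contig)
    return kept, excluded


def annotate_contigs(contigs, library, scheme: ScoreScheme | None = None,
                     e_cutoff: float = 1e-10) -> list:
    """One annotation per contig by the longest significant library match.

    ``library``: iterable of ``(seq_id, class_label, sequence)``. Ties on
    match length prefer the smaller E-value, then the lexicographically
    first hit id. Contigs without a qualifying hit are labeled "no-hit".
    """
    if scheme is None:
        scheme = ScoreScheme()
    library = list(library)
    for entry in library:
        if entry[1] not in CLASS_LABELS:
            raise ValueError(f"library entry {entry[0]!r} has unknown class {entry[1]!r}")
    records = []
    for contig in contigs:
        cid, seq = (contig.contig_id, contig.sequence) if hasattr(contig, "sequence") else contig
        best = None
        for hit_id, label, subject in library:
            for hit in all_local_hits(seq, subject, scheme, e_cutoff=e_cutoff):
                key = (-hit.match_length, hit.e_value, hit_id)
                if best is None or key < best[0]:
                    best = (key, hit_id, label, hit)
        if best is None:
            records.append(AnnotationRecord(cid, None, "no-hit", 0, math.inf, 0.0))
        else:
            _key, hit_id, label, hit = best
            records.append(
                AnnotationRecord(cid, hit_id, label, hit.match_length, hit.e_value, hit.identity)
            )
    return records


def _shannon_entropy_bits(window: str) -> float:
    counts = Counter(window)
    n = len(window)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def detect_tandem_low_complexity(contig_seq: str):
    """Flag perfect SSRs (unit 1-6 nt, array >= 24 nt) and low-entropy
    windows (< 1 bit over 64 nt); returns a dict annotation when flagged
    bases reach 50% of the contig, else None."""
    n = len(contig_seq)
    if n == 0:
        return None
    flagged = [False] * n
    ssr_hits = []
    for unit in range(1, _SSR_MAX_UNIT + 1):
        i = 0
        while i + unit <= n:
            run = unit
            while i + run + unit <= n and contig_seq[i + run : i + run + unit] == contig_seq[i : i + unit]:
                run += unit
            # extend by the partial trailing unit
            j = i + run
            while j < n and contig_seq[j] == contig_seq[j - unit]:
                j += 1
            run = j - i
            if run >= max(_SSR_MIN_ARRAY, 2 * unit):
                ssr_hits.append((i, i + run, unit))
                for pos in range(i, i + run):
                    flagged[pos] = True
                i += run
            else:
                i += 1
    if n >= _ENTROPY_WINDOW:
        for i in range(0, n - _ENTROPY_WINDOW + 1, _ENTROPY_WINDOW // 2):
            win = contig_seq[i : i + _ENTROPY_WINDOW]
            if _shannon_entropy_bits(win) < _ENTROPY_MIN_BITS:
                for pos in range(i, i + _ENTROPY_WINDOW):
                    flagged[pos] = True
    frac = sum(flagged) / n
    if frac >= _LOW_COMPLEXITY_FRACTION:
        return {
            "class_label": "tandem/SSR",
            "flagged_fraction": frac,
            "ssr_hits": ssr_hits,
        }
    return None


def all_by_all_best_hits(contigs, scheme: ScoreScheme | None = None,
                         e_cutoff: float = 1e-50) -> list:
    """Directed best-hit edges: each contig points to its single most
    similar other contig with E-value <= cutoff (self-hits excluded, ties
    broken lexicographically)."""
    entries = []
    for contig in contigs:
        if hasattr(contig, "sequence"):
            entries.append((contig.contig_id, contig.sequence))
        else:
            entries.append(tuple(contig))
    if len(entries) < 2:
        raise ValueError("all-by-all search needs at least 2 contigs")
    if scheme is None:
        scheme = ScoreScheme()
    # strand-canonical word sets prefilter the quadratic pair scan: a
    # significant ungapped hit necessarily shares seed words
    from .assembly import _canonical_kmers

    word_sets = []
    for _cid, seq in entries:
        canon, _flags, ok = _canonical_kmers(seq)
        word_sets.append(set(canon[ok].tolist()))
    # pairwise best scores, computed once per unordered pair
    best_for: dict = {}
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if not word_sets[i] & word_sets[j]:
                continue
            qid, qseq = entries[i]
            sid, sseq = entries[j]
            hits = all_local_hits(qseq, sseq, scheme, e_cutoff=e_cutoff)
            if not hits:
                continue
            ev = hits[0].e_value
            for a, b in ((qid, sid), (sid, qid)):
                cur = best_for.get(a)
                if cur is None or (ev, b) < cur:
                    best_for[a] = (ev, b)
    return sorted((a, b) for a, (_ev, b) in best_for.items())


def build_families(edge_list, contig_ids):
    """Families = connected components (edges undirected) of size >= 2;
    everything else is a singleton. Invariant to input order."""
    graph = nx.Graph()
    graph.add_nodes_from(contig_ids)
    graph.add_edges_from(edge_list)
    families, singletons = [], []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        if len(members) >= 2:
            families.append(members)
        else:
            singletons.extend(members)
    families.sort(key=lambda m: m[0])
    return families, sorted(singletons)


def family_size_distribution(families, singletons, top_n: int = 30):
    """Histogram {family size: number of families} plus a top-N table of
    (family id, size) sorted by size descending, ties lexicographic."""
    histogram = Counter(len(fam) for fam in families)
    named = [(fam[0], len(fam)) for fam in families]
    named.sort(key=lambda t: (-t[1], t[0]))
    return dict(sorted(histogram.items())), named[:top_n], len(singletons)
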