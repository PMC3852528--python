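"""Best-match read mapping and the average-coverage redundancy statistic.

A read is placed at its best-scoring valid locus; among equally good loci
one is drawn uniformly at random from a seeded stream (the standard
treatment of multi-reads, which spreads the copies of a repeat evenly
over the references that represent it). The redundancy of a reference is
then summarized as its *average coverage*: the sum of the aligned bases
of all reads placed on it, divided by its length.

Candidate loci come from exact k-mer seeding on both strands; candidates
are verified with edlib alignment, trimmed to the maximum-scoring
segment (so read ends may be soft-clipped), and scored as
``matches - mismatch_cost*mismatches - insertion_cost*ins -
deletion_cost*del``. A placement is valid when the aligned read fraction
and the alignment identity reach the configured thresholds.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy import stats

from .core import Placement, revcomp
from .assembly import _kmer_ints

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_MAX_CANDIDATES = 8
_SEED_STRIDE = 3
_BUCKET_CAP = 200


@dataclass
class MappingParams:
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.5
    similarity: float = 0.8
    seed_k: int = 15
    rng_seed: int = 0

    def validate(self) -> None:
        for cost in (self.mismatch_cost, self.insertion_cost, self.deletion_cost):
            if cost < 1:
                raise ValueError("alignment costs must be >= 1")
        if not 0 < self.length_fraction <= 1:
            raise ValueError("length_fraction must lie in (0, 1]")
        if not 0 < self.similarity <= 1:
            raise ValueError("similarity must lie in (0, 1]")
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")


@dataclass
class CoverageReport:
    """Per-reference matched-read counts and average coverage."""

    per_ref: dict = field(default_factory=dict)  # ref_id -> (count, avg_cov)

    def average_coverage(self, ref_id: str) -> float:
        return self.per_ref[ref_id][1]

    def matched_reads(self, ref_id: str) -> int:
        return self.per_ref[ref_id][0]


class ReferenceIndex:
    """Exact k-mer index over a reference set (forward strands)."""

    def __init__(self, refs, k: int):
        self.refs = list(refs)
        self.ids = [r[0] for r in self.refs]
        self.seqs = [r[1] for r in self.refs]
        self.k = k
        buckets: dict = defaultdict(list)
        for ridx, seq in enumerate(self.seqs):
            for pos, val in enumerate(_kmer_ints(seq, k)):
                if val >= 0:
                    bucket = buckets[int(val)]
                    if len(bucket) < _BUCKET_CAP:
                        bucket.append((ridx, pos))
        self.buckets = dict(buckets)


def _parse_cigar(cigar: str):
    ops = []
    for count, op in _CIGAR_RE.findall(cigar):
        ops.append((int(count), op))
    return ops


def _evaluate_candidate(read_seq, ref_seq, ref_start_hint, params):
    """Align the read near the hinted diagonal and trim to the best-scoring
    segment. Returns (score, ref_start, ref_end, aligned_bases, identity)
    or None."""
    L = len(read_seq)
    pad = 12 + L // 8
    lo = max(0, ref_start_hint - pad)
    hi = min(len(ref_seq), ref_start_hint + L + pad)
    if hi - lo < params.seed_k:
        return None
    window = ref_seq[lo:hi]
    res = edlib.align(read_seq, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t_start = res["locations"][0][0]
    # per-column contributions: read-base use, ref-base use, score
    cols_score = []
    cols_read = []
    cols_ref = []
    cols_match = []
    for count, op in _parse_cigar(res["cigar"]):
        if op == "=":
            cols_score.extend([1.0] * count)
            cols_read.extend([1] * count)
            cols_ref.extend([1] * count)
            cols_match.extend([1] * count)
        elif op in "XM":
            cols_score.extend([-float(params.mismatch_cost)] * count)
            cols_read.extend([1] * count)
            cols_ref.extend([1] * count)
            cols_match.extend([0] * count)
        elif op == "I":  # read base absent from the reference
            cols_score.extend([-float(params.insertion_cost)] * count)
            cols_read.extend([1] * count)
            cols_ref.extend([0] * count)
            cols_match.extend([0] * count)
        elif op == "D":  # reference base absent from the read
            cols_score.extend([-float(params.deletion_cost)] * count)
            cols_read.extend([0] * count)
            cols_ref.extend([1] * count)
            cols_match.extend([0] * count)
    # maximum-scoring contiguous segment (Kadane), deterministic leftmost
    best_sum, best_lo, best_hi = 0.0, 0, 0
    cur_sum, cur_lo = 0.0, 0
    for idx, val in enumerate(cols_score):
        if cur_sum <= 0:
            cur_sum, cur_lo = val, idx
        else:
            cur_sum += val
        if cur_sum > best_sum:
            best_sum, best_lo, best_hi = cur_sum, cur_lo, idx + 1
    if best_hi <= best_lo:
        return None
    seg = slice(best_lo, best_hi)
    matches = int(sum(cols_match[seg]))
    read_bases = int(sum(cols_read[seg]))
    ref_bases = int(sum(cols_ref[seg]))
    n_cols = best_hi - best_lo
    identity = matches / n_cols
    if read_bases / L < params.length_fraction or identity < params.similarity:
        return None
    ref_off = int(sum(cols_ref[:best_lo]))
    ref_seg_start = lo + t_start + ref_off
    return (best_sum, ref_seg_start, ref_seg_start + ref_bases, read_bases, identity)


def _read_candidates(read_seq, index: ReferenceIndex):
    """(ref_idx, strand, diagonal) candidates ranked by seed votes."""
    votes = Counter()
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        kmers = _kmer_ints(seq, index.k)
        for pos in range(0, len(kmers), _SEED_STRIDE):
            val = int(kmers[pos])
            if val < 0:
                continue
            for ridx, rpos in index.buckets.get(val, ()):
                votes[(ridx, strand, rpos - pos)] += 1
    if not votes:
        return []
    # merge adjacent diagonals (small indels) into one candidate
    merged = Counter()
    rep = {}
    for (ridx, strand, diag), n in votes.items():
        key = (ridx, strand, diag // 12)
        merged[key] += n
        if key not in rep or votes[(ridx, strand, rep[key])] < n:
            rep[key] = diag
    ranked = sorted(
        merged.items(), key=lambda kv: (-kv[1], index.ids[kv[0][0]], kv[0][2], kv[0][1])
    )
    if len(ranked) > _MAX_CANDIDATES:
        cutoff = ranked[_MAX_CANDIDATES - 1][1]
        ranked = [kv for kv in ranked if kv[1] >= cutoff][: 4 * _MAX_CANDIDATES]
    return [(ridx, strand, rep[(ridx, strand, dbin)]) for (ridx, strand, dbin), _n in ranked]


def map_reads(reads, refs, params: MappingParams | None = None) -> list:
    """Best-match placement of each read on a reference set.

    ``refs`` is an iterable of ``(ref_id, sequence)`` pairs (Contig objects
    are also accepted). Ties between equal-best loci are broken uniformly
    at random from the ``rng_seed`` stream; reads with no valid locus are
    left unplaced.
    """
    if params is None:
        params = MappingParams()
    params.validate()
    ref_pairs = []
    for ref in refs:
        if isinstance(ref, tuple):
            ref_pairs.append(ref)
        else:
            ref_pairs.append((ref.contig_id, ref.sequence))
    if not ref_pairs:
        raise ValueError("reference set is empty")
    index = ReferenceIndex(ref_pairs, params.seed_k)
    rng = np.random.default_rng(params.rng_seed)
    placements = []
    for read in reads:
        candidates = _read_candidates(read.sequence, index)
        results = {}
        for ridx, strand, diag in candidates:
            query = read.sequence if strand == "+" else revcomp(read.sequence)
            hit = _evaluate_candidate(query, index.seqs[ridx], diag, params)
            if hit is None:
                continue
            score, start, end, aligned, ident = hit
            key = (ridx, strand, start)
            if key not in results or results[key][0] < score:
                results[key] = (score, start, end, aligned, ident)
        if not results:
            continue
        best_score = max(v[0] for v in results.values())
        ties = sorted(
            (index.ids[k[0]], k[1], k[2], k[0]) for k, v in results.items()
            if v[0] == best_score
        )
        pick = ties[int(rng.integers(0, len(ties)))] if len(ties) > 1 else ties[0]
        ref_id, strand, start, ridx = pick
        score, start, end, aligned, ident = results[(ridx, strand, start)]
        placements.append(
            Placement(
                read_id=read.read_id,
                ref_id=ref_id,
                start=start,
                end=end,
                strand=strand,
                aligned_bases=aligned,
                identity=ident,
            )
        )
    return placements


def average_coverage(placements, refs) -> CoverageReport:
    """Average coverage per reference: sum of aligned read bases divided by
    the reference length; references without placements get 0."""
    lengths = {}
    for ref in refs:
        if isinstance(ref, tuple):
            lengths[ref[0]] = len(ref[1])
        else:
            lengths[ref.contig_id] = len(ref.sequence)
    sums = defaultdict(int)
    counts = defaultdict(int)
    for p in placements:
        if p.ref_id not in lengths:
            raise ValueError(f"placement on unknown reference {p.ref_id!r}")
        sums[p.ref_id] += p.aligned_bases
        counts[p.ref_id] += 1
    report = CoverageReport()
    for ref_id, length in lengths.items():
        report.per_ref[ref_id] = (counts[ref_id], sums[ref_id] / length)
    return report


def filter_organellar(reads, organellar_refs, params: MappingParams | None = None):
    """Remove reads with a valid placement on any organellar sequence.

    Returns ``(nuclear_reads, organellar_count)``.
    """
    organellar_refs = list(organellar_refs)
    if not organellar_refs:
        return list(reads), 0
    placements = map_reads(reads, organellar_refs, params)
    placed = {p.read_id for p in placements}
    nuclear = [r for r in reads if r.read_id not in placed]
    return nuclear, len(placed)


def calibrate_mapping_params(refs_known, reads, grid, method: str = "pearson"):
    """Select mapping parameters by correlating known redundancy with
    average coverage over reference sequences of known copy number.

    ``refs_known``: iterable of ``(ref_id, sequence, known_redundancy)``.
    Returns ``(best_params, table)`` where table rows are
    ``(params, correlation or None)``; grid points with degenerate
    (zero-variance) coverage get ``None`` and are never selected. Ties
    keep the earliest grid point.
    """
    refs_known = list(refs_known)
    if len(refs_known) < 3:
        raise ValueError("need at least 3 references of known redundancy")
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    if method not in {"pearson", "spearman"}:
        raise ValueError("method must be 'pearson' or 'spearman'")
    refs = [(r[0], r[1]) for r in refs_known]
    known = np.array([float(r[2]) for r in refs_known])
    table = []
    best = None
    for params in grid:
        placements = map_reads(reads, refs, params)
        report = average_coverage(placements, refs)
        covs = np.array([report.average_coverage(r[0]) for r in refs])
        if np.std(covs) == 0 or np.std(known) == 0:
            corr = None
        else:
            if method == "pearson":
                corr = float(stats.pearsonr(known, covs).statistic)
            else:
                corr = float(stats.spearmanr(known, covs).statistic)
        table.append((params, corr))
        if corr is not None and (best is None or corr > best[1]):
            best = (params, corr)
    if best is None:
        raise ValueError("every grid point had degenerate coverage; cannot calibrate")
    return best[0], table


def region_coverage(placements, ref_id: str, ref_length: int, sub_intervals) -> list:
    """Average coverage per sub-interval of one reference.

    A placement spanning an interval boundary contributes its aligned
    bases proportionally to the per-base overlap on each side.
    """
    sub_intervals = [(int(s), int(e)) for s, e in sub_intervals]
    for s, e in sub_intervals:
        if e <= s:
            raise ValueError(f"empty interval ({s}, {e})")
        if s < 0 or e > ref_length:
            raise ValueError(f"interval ({s}, {e}) outside reference of length {ref_length}")
    sums = [0.0] * len(sub_intervals)
    for p in placements:
        if p.ref_id != ref_id:
            continue
        span = p.end - p.start
        if span <= 0:
            continue
        per_base = p.aligned_bases / span
        for idx, (s, e) in enumerate(sub_intervals):
            ov = min(e, p.end) - max(s, p.start)
            if ov > 0:
                sums[idx] += per_base * ov
    return [sums[idx] / (e - s) for idx, (s, e) in enumerate(sub_intervals)]
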