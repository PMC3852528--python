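"""Split-then-assemble strategy: subpackage splitting, greedy
overlap-layout-consensus assembly, second-pass contig merging, and contig
set statistics.

Splitting a read set into many very-low-coverage subpackages before
assembly leaves only high-copy repeats with enough local depth to
assemble, so the contigs from split subpackages are strongly enriched for
repeat consensus sequences. A single greedy OLC engine serves both the
read-assembly pass and the contig-merge pass, differing only in its
overlap thresholds.

Engine outline: candidate pairs are found through shared canonical
k-mers (k=16, hash-subsampled on large inputs), verified by banded
overlap alignment (edlib) at the most-supported diagonal, then merged
greedily from the highest-scoring overlap down. Dovetail overlaps chain
sequences into layout paths; containments absorb a sequence into its
host. Consensus is per-column majority vote with ties to the
alphabetically first base. All tie-breaking is lexicographic by sequence
id, making the output deterministic for a given input order.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np

from .core import Contig, Read, revcomp, total_bases

_KMER_K = 16
_BUCKET_CAP = 32
_MAX_PARTNERS = 16
_OFFSET_SLACK = 8


@dataclass
class AssemblyParams:
    """Read-pass thresholds. Identity is a percentage; contigs shorter
    than ``min_contig_length`` are discarded."""

    min_overlap_len: int = 40
    min_overlap_identity: float = 95.0
    min_contig_length: int = 300

    def validate(self) -> None:
        if not 0 < self.min_overlap_identity <= 100:
            raise ValueError("min_overlap_identity must lie in (0, 100]")
        if self.min_contig_length < 1:
            raise ValueError("min_contig_length must be >= 1")
        if self.min_overlap_len < _KMER_K:
            raise ValueError(f"min_overlap_len must be >= {_KMER_K}")


@dataclass
class MergeParams:
    """Second-pass (contig merging) thresholds. ``refcount=0`` means every
    input sequence acts as query and reference alike; that is the only
    supported mode."""

    min_identity: float = 90.0
    min_overlap_len: int = 40
    refcount: int = 0

    def validate(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must lie in (0, 100]")
        if self.refcount != 0:
            raise ValueError("only refcount=0 (all-vs-all) is supported")


@dataclass
class SplitPlan:
    """Partition of a read set into coverage-targeted subpackages."""

    n_subpackages: int
    target_subpackage_coverage: float
    assignment: dict  # read_id -> subpackage index

    def subpackages(self, reads) -> list:
        groups = [[] for _ in range(self.n_subpackages)]
        for read in reads:
            groups[self.assignment[read.read_id]].append(read)
        return groups


def split_reads(reads, genome_size: int, target_coverage: float, seed: int) -> SplitPlan:
    """Partition reads into ``ceil(total_coverage / target_coverage)``
    subpackages, uniformly at random, sizes differing by at most one read."""
    if target_coverage <= 0:
        raise ValueError("target_coverage must be positive")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    coverage = total_bases(reads) / genome_size
    n_sub = int(np.ceil(coverage / target_coverage))
    if n_sub < 1:
        n_sub = 1
    if coverage < target_coverage:
        warnings.warn(
            f"target coverage {target_coverage} exceeds total coverage "
            f"{coverage:.4g}; using a single subpackage",
            stacklevel=2,
        )
        n_sub = 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    assignment = {reads[int(idx)].read_id: slot % n_sub for slot, idx in enumerate(order)}
    return SplitPlan(
        n_subpackages=n_sub,
        target_subpackage_coverage=target_coverage,
        assignment=assignment,
    )


# ---------------------------------------------------------------------------
# k-mer machinery


_POWERS = 4 ** np.arange(_KMER_K - 1, -1, -1, dtype=np.int64)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_ints(seq: str, k: int = _KMER_K) -> np.ndarray:
    """Integer encodings of all k-mers; -1 where the window has non-ACGT."""
    codes = _codes(seq)
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    vals = win.astype(np.int64) @ _POWERS[-k:]
    bad = (win < 0).any(axis=1)
    vals[bad] = -1
    return vals


def _canonical_kmers(seq: str):
    """(canonical kmer int, strand flag) arrays; flag 0 when the forward
    k-mer is canonical."""
    fwd = _kmer_ints(seq)
    rc = _kmer_ints(revcomp(seq))[::-1] if fwd.size else fwd
    canon = np.minimum(fwd, rc)
    flags = (fwd > rc).astype(np.int8)
    ok = fwd >= 0
    return canon, flags, ok


def _subsample_mask(canon: np.ndarray, rate: int) -> np.ndarray:
    if rate <= 1:
        return np.ones(canon.size, dtype=bool)
    mixed = (canon.astype(np.uint64) * np.uint64(2654435761)) & np.uint64(0xFFFFFFFF)
    return mixed < np.uint64((1 << 32) // rate)


# ---------------------------------------------------------------------------
# overlap detection


@dataclass
class _Overlap:
    kind: str  # "dovetail" or "contain"
    u: int  # leading / container sequence index
    ou: int  # orientation of u in the overlap frame (0 fwd, 1 rc)
    v: int  # trailing / contained sequence index
    ov: int
    offset: int  # start of v relative to start of u, in the frame where u has ou
    overlap_len: int
    identity: float
    score: float


def _verify_pair(seqs, i, j, orient, min_len, min_ident):
    """Best overlap between seqs[i] (forward) and seqs[j] (oriented), or None."""
    a = seqs[i]
    b = seqs[j] if orient == 0 else revcomp(seqs[j])
    ka = _kmer_ints(a)
    kb = _kmer_ints(b)
    pos_a = defaultdict(list)
    for p, v in enumerate(ka):
        if v >= 0:
            pos_a[int(v)].append(p)
    offsets = Counter()
    for p, v in enumerate(kb):
        if v >= 0:
            for q in pos_a.get(int(v), ()):
                offsets[q - p] += 1
    if not offsets:
        return None
    best = None
    # examine the best-supported diagonals only
    for d, _votes in sorted(offsets.most_common(3), key=lambda t: (-t[1], t[0])):
        rec = _align_at_offset(a, b, i, j, orient, d, min_len, min_ident)
        if rec is not None and (best is None or rec.score > best.score):
            best = rec
    return best


def _align_at_offset(a, b, i, j, orient, d, min_len, min_ident):
    la, lb = len(a), len(b)
    slack = _OFFSET_SLACK
    if d >= 0 and d + lb <= la:  # b contained in a
        lo = max(0, d - slack)
        hi = min(la, d + lb + slack)
        res = edlib.align(b, a[lo:hi], mode="HW", task="locations")
        dist = res["editDistance"]
        ident = 1.0 - dist / lb
        if lb >= min_len and ident >= min_ident:
            start = lo + res["locations"][0][0]
            return _Overlap("contain", i, 0, j, orient, start, lb, ident, lb - dist)
        return None
    if d <= 0 and -d + la <= lb:  # a contained in b
        lo = max(0, -d - slack)
        hi = min(lb, -d + la + slack)
        res = edlib.align(a, b[lo:hi], mode="HW", task="locations")
        dist = res["editDistance"]
        ident = 1.0 - dist / la
        if la >= min_len and ident >= min_ident:
            # re-frame with j as the container in its oriented frame
            start = lo + res["locations"][0][0]
            return _Overlap("contain", j, orient, i, 0, start, la, ident, la - dist)
        return None
    if d > 0:  # dovetail: suffix of a onto prefix of b
        ov = la - d
        if ov < min_len:
            return None
        query = a[d:]
        target = b[: min(lb, ov + slack)]
        res = edlib.align(query, target, mode="SHW", task="distance")
        dist = res["editDistance"]
        ident = 1.0 - dist / ov
        if ident < min_ident:
            return None
        return _Overlap("dovetail", i, 0, j, orient, d, ov, ident, ov - dist)
    if d < 0:  # dovetail: suffix of oriented b onto prefix of a
        ov = lb + d
        if ov < min_len:
            return None
        query = b[-d:]
        target = a[: min(la, ov + slack)]
        res = edlib.align(query, target, mode="SHW", task="distance")
        dist = res["editDistance"]
        ident = 1.0 - dist / ov
        if ident < min_ident:
            return None
        # frame where oriented b leads: b with orientation `orient` at 0, a fwd at -d
        return _Overlap("dovetail", j, orient, i, 0, -d, ov, ident, ov - dist)
    return None  # d == 0 with equal lengths is handled as containment above


def _candidate_pairs(seqs, ids):
    """Shared-k-mer candidate partner sets: {(i, j): {orientations}}."""
    n = len(seqs)
    rate = 1 if n <= 500 else 4
    buckets = defaultdict(list)
    for idx, seq in enumerate(seqs):
        canon, flags, ok = _canonical_kmers(seq)
        if canon.size == 0:
            continue
        keep = ok & _subsample_mask(canon, rate)
        seen = {}
        for v, f in zip(canon[keep].tolist(), flags[keep].tolist()):
            if v not in seen:  # one entry per (seq, kmer)
                seen[v] = f
        for v, f in seen.items():
            bucket = buckets[v]
            if len(bucket) < _BUCKET_CAP:
                bucket.append((idx, f))
    votes = Counter()
    for bucket in buckets.values():
        if len(bucket) < 2:
            continue
        for x in range(len(bucket)):
            ix, fx = bucket[x]
            for y in range(x + 1, len(bucket)):
                iy, fy = bucket[y]
                if ix == iy:
                    continue
                a, b = (ix, iy) if ix < iy else (iy, ix)
                votes[(a, b, fx ^ fy)] += 1
    by_seq = defaultdict(list)
    for (a, b, orient), count in votes.items():
        by_seq[a].append((count, b, orient))
        by_seq[b].append((count, a, orient))
    pairs = defaultdict(set)
    for idx, cand in by_seq.items():
        cand.sort(key=lambda t: (-t[0], ids[t[1]], t[2]))
        for _count, other, orient in cand[:_MAX_PARTNERS]:
            a, b = (idx, other) if idx < other else (other, idx)
            pairs[(a, b)].add(orient)
    return pairs


# ---------------------------------------------------------------------------
# greedy merging


def _greedy_layouts(entries, min_overlap_len, min_identity_pct, seed_pairs=None):
    """Greedy overlap merging of ``entries`` = [(id, sequence)].

    Returns a list of layouts; each layout is a list of
    ``(entry_index, orientation, offset)`` sorted by offset.
    """
    ids = [e[0] for e in entries]
    seqs = [e[1] for e in entries]
    min_ident = min_identity_pct / 100.0
    pairs = seed_pairs if seed_pairs is not None else _candidate_pairs(seqs, ids)

    overlaps = []
    for (a, b), orients in pairs.items():
        best = None
        for orient in sorted(orients):
            rec = _verify_pair(seqs, a, b, orient, min_overlap_len, min_ident)
            if rec is not None and (best is None or rec.score > best.score):
                best = rec
        if best is not None:
            overlaps.append(best)
    overlaps.sort(key=lambda o: (-o.score, ids[min(o.u, o.v)], ids[max(o.u, o.v)], o.ou, o.ov))

    n = len(seqs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    port_used = [[False, False] for _ in range(n)]  # [left, right] in own frame
    absorbed = {}  # contained -> (host, orient_rel, offset_in_host_fwd_frame)
    hosts = defaultdict(list)
    out_edge = {}  # (node, orient) -> (next node, next orient, offset delta)

    def exit_port(o):
        return 1 if o == 0 else 0  # right port when forward

    def entry_port(o):
        return 0 if o == 0 else 1

    for ov_rec in overlaps:
        u, ou, v, vv = ov_rec.u, ov_rec.ou, ov_rec.v, ov_rec.ov
        if u in absorbed or v in absorbed:
            continue
        if ov_rec.kind == "contain":
            contained = v
            if any(port_used[contained]):
                continue
            if find(u) == find(contained):
                continue
            # offset recorded in u-forward frame
            if ou == 0:
                off, orel = ov_rec.offset, vv
            else:
                off = len(seqs[u]) - (ov_rec.offset + len(seqs[contained]))
                orel = 1 - vv
            absorbed[contained] = (u, orel, off)
            hosts[u].append(contained)
            parent[find(contained)] = find(u)
            continue
        # dovetail
        pu, pv = exit_port(ou), entry_port(vv)
        if port_used[u][pu] or port_used[v][pv]:
            continue
        if find(u) == find(v):
            continue
        port_used[u][pu] = True
        port_used[v][pv] = True
        parent[find(v)] = find(u)
        d = ov_rec.offset
        d_mirror = d + len(seqs[v]) - len(seqs[u])
        out_edge[(u, ou)] = (v, vv, d)
        out_edge[(v, 1 - vv)] = (u, 1 - ou, d_mirror)

    # walk chains from their terminal (no-incoming) orientations
    incoming = set()
    for (_u, _ou), (v2, ov2, _d) in out_edge.items():
        incoming.add((v2, ov2))
    layouts = []
    visited = set()
    for start in range(n):
        if start in absorbed or start in visited:
            continue
        starts = [(start, o) for o in (0, 1) if (start, o) not in incoming]
        if not starts:
            continue  # interior node; reached from its chain start
        node, orient = starts[0]
        chain = [(node, orient, 0)]
        visited.add(node)
        pos = 0
        while (node, orient) in out_edge:
            nxt, nxt_orient, d = out_edge[(node, orient)]
            if nxt in visited:
                break
            pos += d
            chain.append((nxt, nxt_orient, pos))
            visited.add(nxt)
            node, orient = nxt, nxt_orient
        layouts.append(chain)

    # attach absorbed sequences at their resolved positions
    def attach(host, host_orient, host_pos):
        placed = []
        for child in hosts.get(host, ()):
            _h, orel, off = absorbed[child]
            if host_orient == 0:
                c_orient = orel
                c_pos = host_pos + off
            else:
                c_orient = 1 - orel
                c_pos = host_pos + len(seqs[host]) - (off + len(seqs[child]))
            placed.append((child, c_orient, c_pos))
            placed.extend(attach(child, c_orient, c_pos))
        return placed

    full_layouts = []
    for chain in layouts:
        members = list(chain)
        for node, orient, pos in chain:
            members.extend(attach(node, orient, pos))
        base = min(p for _n, _o, p in members)
        members = sorted(
            ((node, orient, pos - base) for node, orient, pos in members),
            key=lambda t: (t[2], ids[t[0]]),
        )
        full_layouts.append(members)
    full_layouts.sort(key=lambda mem: ids[mem[0][0]])
    return full_layouts


def _weighted_consensus(entries, depths, layout):
    """Depth-weighted majority-vote consensus over a layout; ties go to
    the alphabetically first base. Returns (sequence, depth_profile)."""
    seqs = [e[1] for e in entries]
    span = max(pos + len(seqs[node]) for node, _o, pos in layout)
    counts = np.zeros((span, 4), dtype=np.int64)
    for node, orient, pos in layout:
        seq = seqs[node]
        weight = depths[node]
        if orient == 1:
            seq = revcomp(seq)
            weight = weight[::-1]
        codes = _codes(seq)
        ok = codes >= 0
        idx = np.arange(pos, pos + len(seq))[ok]
        counts[idx, codes[ok]] += weight[ok]
    depth = counts.sum(axis=1)
    covered = depth > 0
    consensus_codes = counts.argmax(axis=1)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_arr = bases[consensus_codes]
    # trim any uncovered flanks (cannot occur for dovetail-only layouts)
    nz = np.nonzero(covered)[0]
    lo, hi = int(nz[0]), int(nz[-1]) + 1
    sequence = seq_arr[lo:hi].tobytes().decode("ascii")
    return sequence, depth[lo:hi]


def _assemble_rounds(entries, depths, members, min_overlap_len, min_identity_pct,
                     max_rounds: int = 4):
    """Iterate greedy chaining to convergence: each round merges the
    previous round's consensus fragments, so paths interrupted by local
    port conflicts still coalesce. Returns (entries, depths, members)."""
    for rnd in range(max_rounds):
        layouts = _greedy_layouts(entries, min_overlap_len, min_identity_pct)
        if all(len(layout) == 1 for layout in layouts):
            break
        new_entries, new_depths, new_members = [], [], []
        for l_idx, layout in enumerate(layouts):
            if len(layout) == 1:
                node = layout[0][0]
                new_entries.append(entries[node])
                new_depths.append(depths[node])
                new_members.append(members[node])
                continue
            sequence, depth = _weighted_consensus(entries, depths, layout)
            merged_members = []
            for node, _o, _p in layout:
                merged_members.extend(members[node])
            new_entries.append((f"_r{rnd}_{l_idx}", sequence))
            new_depths.append(depth)
            new_members.append(merged_members)
        entries, depths, members = new_entries, new_depths, new_members
    return entries, depths, members


def greedy_assemble(reads, params: AssemblyParams | None = None, contig_prefix: str = "contig") -> list:
    """Assemble reads into consensus contigs by greedy overlap merging.

    Chaining is iterated to convergence so that consensus fragments keep
    merging while valid overlaps remain. Contigs shorter than
    ``params.min_contig_length`` (default 300 nt, including unmerged
    single reads) are discarded. Deterministic for a given input order.
    """
    if params is None:
        params = AssemblyParams()
    params.validate()
    if not reads:
        return []
    entries = [(r.read_id, r.sequence) for r in reads]
    depths = [np.ones(len(r.sequence), dtype=np.int64) for r in reads]
    members = [[r.read_id] for r in reads]
    entries, depths, members = _assemble_rounds(
        entries, depths, members, params.min_overlap_len, params.min_overlap_identity
    )
    order = sorted(range(len(entries)), key=lambda i: min(members[i]))
    contigs = []
    for idx in order:
        sequence = entries[idx][1]
        if len(sequence) < params.min_contig_length:
            continue
        contigs.append(
            Contig(
                contig_id=f"{contig_prefix}_{len(contigs)}",
                sequence=sequence,
                member_read_ids=list(members[idx]),
                depth_profile=depths[idx],
            )
        )
    return contigs


def merge_contig_sets(contig_sets, params: MergeParams | None = None, prefix: str = "super"):
    """Pool contig sets and merge overlapping contigs in a second pass.

    Returns ``(supercontigs, singletons)``: supercontigs are consensus
    sequences absorbing at least two input contigs; singletons are the
    untouched inputs. Merging is iterated to convergence, so applying it
    to its own output produces no further merges.
    """
    if params is None:
        params = MergeParams()
    params.validate()
    pool = [c for cset in contig_sets for c in cset]
    if not pool:
        return [], []
    by_id = {c.contig_id: c for c in pool}
    if len(by_id) != len(pool):
        raise ValueError("contig ids must be unique across sets")
    entries = [(c.contig_id, c.sequence) for c in pool]
    depths = [
        c.depth_profile if c.depth_profile is not None
        else np.ones(len(c.sequence), dtype=np.int64)
        for c in pool
    ]
    members = [[c.contig_id] for c in pool]
    entries, depths, members = _assemble_rounds(
        entries, depths, members, params.min_overlap_len, params.min_identity, max_rounds=5
    )
    supercontigs, singletons = [], []
    for idx in sorted(range(len(entries)), key=lambda i: min(members[i])):
        if len(members[idx]) == 1:
            singletons.append(by_id[members[idx][0]])
            continue
        member_reads = []
        for cid in members[idx]:
            member_reads.extend(by_id[cid].member_read_ids)
        supercontigs.append(
            Contig(
                contig_id=f"{prefix}_{len(supercontigs)}",
                sequence=entries[idx][1],
                member_read_ids=member_reads,
                depth_profile=depths[idx],
            )
        )
    return supercontigs, singletons


def assembly_stats(contigs):
    """(count, mean length, N50). N50 is the largest length L such that
    contigs of length >= L hold at least half of all assembled bases.
    Empty input gives (0, 0.0, 0)."""
    lengths = sorted(
        (len(c) if not isinstance(c, (int, np.integer)) else int(c)) for c in contigs
    )
    if not lengths:
        return 0, 0.0, 0
    total = sum(lengths)
    half = total / 2.0
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return len(lengths), total / len(lengths), length
    raise AssertionError("unreachable")
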