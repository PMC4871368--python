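"""Curation of redundant contig sets into one consensus transcript per locus.

A k-mer-sweep assembly emits many near-identical contigs per transcript,
differing mostly at their ends. Curation proceeds in four steps:

1. drop contigs below a minimum length (assembler floor, 200 b),
2. remove contigs contained within longer contigs on either strand
   (overlapping-but-not-contained contigs are all retained),
3. cluster the survivors by shared canonical k-mers with single linkage,
   so each cluster gathers the contigs of one locus,
4. lay the members of each cluster out by best ungapped overlap, trim
   discordant 5-base contig ends, and take the per-column majority
   consensus; where a cluster yields several disconnected super-contigs the
   longest is selected and the cluster flagged.

All tie-breaks are lexicographic on sequence, then identifier, so the whole
procedure is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import canonical_kmers, revcomp, seq_to_array


@dataclass
class ContigSet:
    """Contigs keyed by identifier; construction drops those under min_length."""

    contigs: dict[str, str]
    min_length: int = 200

    def __post_init__(self) -> None:
        self.contigs = {
            cid: seq for cid, seq in self.contigs.items() if len(seq) >= self.min_length
        }

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class Placement:
    """One contig laid out in cluster coordinates (sequence already oriented)."""

    contig_id: str
    offset: int
    sequence: str


@dataclass
class ClusterAlignment:
    """Ungapped multiple layout of a cluster's members."""

    members: list[Placement]

    def span(self) -> int:
        return max(p.offset + len(p.sequence) for p in self.members)


@dataclass
class Cluster:
    cluster_id: str
    members: dict[str, str]
    super_contigs: list[str] = field(default_factory=list)
    selected: str = ""
    multi_supercontig: bool = False


def remove_contained(contig_set: ContigSet) -> ContigSet:
    """Drop every contig that is a substring of a longer (or equal, for exact
    duplicates) retained contig on either strand.

    Idempotent; overlapping-but-not-contained contigs are never removed.
    """
    if not contig_set.contigs:
        warnings.warn("remove_contained called on an empty contig set")
        return ContigSet({}, contig_set.min_length)
    ordered = sorted(contig_set.contigs.items(), key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    kept: list[tuple[str, str]] = []
    for cid, seq in ordered:
        rc = revcomp(seq)
        contained = any(seq in kseq or rc in kseq for _, kseq in kept)
        if not contained:
            kept.append((cid, seq))
    return ContigSet(dict(kept), contig_set.min_length)


def cluster_contigs(
    contig_set: ContigSet,
    kmer_size: int = 21,
    min_shared_fraction: float = 0.5,
) -> list[Cluster]:
    """Single-linkage clustering on shared canonical k-mers.

    Two contigs are linked when they share at least ``min_shared_fraction``
    of the smaller contig's canonical k-mer set; clusters are the connected
    components of that graph (an exhaustive, disjoint partition).
    """
    if kmer_size < 8:
        raise ValueError("kmer_size must be >= 8")
    ids = sorted(contig_set.contigs)
    kmers = {cid: canonical_kmers(contig_set.contigs[cid], kmer_size) for cid in ids}
    parent = {cid: cid for cid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ka, kb = kmers[a], kmers[b]
            smaller = min(len(ka), len(kb))
            if smaller == 0:
                continue
            if len(ka & kb) / smaller >= min_shared_fraction:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for cid in ids:
        groups.setdefault(find(cid), []).append(cid)
    clusters = []
    for n, root in enumerate(sorted(groups)):
        members = {cid: contig_set.contigs[cid] for cid in groups[root]}
        clusters.append(Cluster(cluster_id=f"cluster{n:04d}", members=members))
    return clusters


_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _column_majorities(aln: ClusterAlignment) -> np.ndarray:
    """Per-column majority ASCII code over the layout.

    Ties resolve to the alphabetically smallest base; uncovered columns are 0.
    """
    span = aln.span()
    counts = np.zeros((4, span), dtype=np.int32)
    for p in aln.members:
        arr = seq_to_array(p.sequence)
        for bi, code in enumerate(_CODES):
            idx = np.nonzero(arr == code)[0] + p.offset
            np.add.at(counts[bi], idx, 1)
    majority = _CODES[counts.argmax(axis=0)]  # argmax ties -> lowest index
    majority[counts.max(axis=0) == 0] = 0
    return majority


def trim_discordant_ends(aln: ClusterAlignment, window: int = 5) -> ClusterAlignment:
    """Delete the terminal ``window`` bases of any member whose first or last
    ``window`` bases disagree with the column majority.

    Interior bases are never touched. Members left empty are dropped.
    """
    majority = _column_majorities(aln)
    out: list[Placement] = []
    for p in aln.members:
        arr = seq_to_array(p.sequence)
        cols = majority[p.offset : p.offset + len(arr)]
        start, end = 0, len(arr)
        w = min(window, len(arr))
        if np.any(arr[:w] != cols[:w]):
            start = w
        if end - start > 0 and np.any(arr[end - w : end] != cols[end - w : end]):
            end = max(start, end - w)
        if end > start:
            out.append(Placement(p.contig_id, p.offset + start, p.sequence[start:end]))
    return ClusterAlignment(out)


def _best_placement(
    cons: np.ndarray, member: str, min_overlap: int, min_identity: float
) -> tuple[int, int, str] | None:
    """Best ungapped placement of member against cons.

    Returns (score, offset, oriented_sequence) or None if nothing reaches
    min_overlap aligned bases at min_identity.
    """
    best: tuple[int, int, str] | None = None
    lc = len(cons)
    for oriented in (member, revcomp(member)):
        arr = seq_to_array(oriented)
        lm = len(arr)
        # match counts for every offset at once: one correlation per base
        matches = np.zeros(lc + lm - 1)
        for code in _CODES:
            matches += np.correlate(
                (cons == code).astype(np.float64),
                (arr == code).astype(np.float64),
                mode="full",
            )
        matches = np.rint(matches)
        offsets = np.arange(-(lm - 1), lc)
        overlap = np.minimum(lc, offsets + lm) - np.maximum(0, offsets)
        ok = (overlap >= min_overlap) & (
            matches >= min_identity * overlap
        )
        if not ok.any():
            continue
        score = np.where(ok, 2 * matches - overlap, -np.inf)  # matches - mismatches
        top = score.max()
        idx = int(np.nonzero(score == top)[0][0])  # ties: smallest offset
        cand = (int(top), int(offsets[idx]), oriented)
        if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    return best


def build_consensus(
    cluster: Cluster,
    min_overlap: int = 15,
    min_identity: float = 0.8,
    trim_window: int = 5,
) -> Cluster:
    """Lay cluster members out by best ungapped overlap and take the
    per-column majority consensus.

    Disconnected layouts yield multiple super-contigs; the longest (ties:
    lexicographically smallest sequence) is selected and the cluster flagged
    ``multi_supercontig``.
    """
    if not cluster.members:
        raise ValueError("cluster has no members")
    ordered = sorted(cluster.members.items(), key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    components: list[list[Placement]] = []
    for cid, seq in ordered:
        placed = False
        best_choice: tuple[int, int, int, str] | None = None  # score, comp, offset, seq
        for ci, comp in enumerate(components):
            cons = _layout_consensus(ClusterAlignment(comp))
            hit = _best_placement(cons, seq, min_overlap, min_identity)
            if hit is not None:
                score, offset, oriented = hit
                if best_choice is None or score > best_choice[0]:
                    best_choice = (score, ci, offset, oriented)
        if best_choice is not None:
            _, ci, offset, oriented = best_choice
            comp = components[ci]
            comp.append(Placement(cid, offset, oriented))
            shift = min(p.offset for p in comp)
            if shift < 0:
                components[ci] = [
                    Placement(p.contig_id, p.offset - shift, p.sequence) for p in comp
                ]
            placed = True
        if not placed:
            components.append([Placement(cid, 0, seq)])

    supers: list[str] = []
    for comp in components:
        aln = trim_discordant_ends(ClusterAlignment(comp), window=trim_window)
        if not aln.members:
            continue
        supers.extend(_covered_runs(aln))
    supers.sort(key=lambda s: (-len(s), s))
    cluster.super_contigs = supers
    cluster.selected = supers[0] if supers else ""
    cluster.multi_supercontig = len(supers) > 1
    return cluster


def _layout_consensus(aln: ClusterAlignment) -> np.ndarray:
    shift = min(p.offset for p in aln.members)
    if shift != 0:
        aln = ClusterAlignment(
            [Placement(p.contig_id, p.offset - shift, p.sequence) for p in aln.members]
        )
    return _column_majorities(aln)


def _covered_runs(aln: ClusterAlignment) -> list[str]:
    """Majority consensus over each maximal run of covered columns."""
    span = aln.span()
    coverage = np.zeros(span, dtype=int)
    for p in aln.members:
        coverage[p.offset : p.offset + len(p.sequence)] += 1
    majority = _column_majorities(aln)
    runs: list[str] = []
    pos = 0
    while pos < span:
        if coverage[pos] == 0:
            pos += 1
            continue
        end = pos
        while end < span and coverage[end] > 0:
            end += 1
        runs.append(majority[pos:end].tobytes().decode("ascii"))
        pos = end
    return runs


def curate(
    contigs: dict[str, str],
    min_length: int = 200,
    kmer_size: int = 21,
    min_shared_fraction: float = 0.5,
) -> tuple[dict[str, str], list[Cluster]]:
    """Full curation: length filter, containment removal, clustering,
    per-cluster consensus. Returns {cluster_id: selected consensus} and the
    clusters themselves.
    """
    cset = remove_contained(ContigSet(dict(contigs), min_length))
    clusters = cluster_contigs(cset, kmer_size, min_shared_fraction)
    transcripts: dict[str, str] = {}
    for cluster in clusters:
        build_consensus(cluster)
        if cluster.selected:
            transcripts[cluster.cluster_id] = cluster.selected
    return transcripts, clusters
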