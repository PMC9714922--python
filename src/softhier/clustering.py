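"""Sequence clustering and mapping onto a cluster representative.

Near-identical protein chains are grouped by greedy single-linkage
clustering: two chains co-cluster iff their global-alignment sequence
identity is >= 90 % (inclusive) and the shorter chain is at least 90 % of
the longer chain's length.  Nucleic chains never become cluster members;
they only appear as interaction partners.  Per cluster, the member from
the best-resolution experiment is the representative (falling back to the
best R-value, then to the lexicographically smallest id), and every
member's residue annotations are mapped onto the representative's 1-based
sequence positions via global pairwise alignment with match-only scoring
(match = 1, mismatch = 0, gap = 0).  Member positions aligned to a
representative gap are dropped from all downstream residue sets.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from .structures import ChainRecord

logger = logging.getLogger(__name__)

IDENTITY_MIN = 90.0     # %, inclusive
LENGTH_RATIO_MIN = 0.9  # shorter / longer, inclusive


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global")
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = 0
    a.extend_gap_score = 0
    return a


@dataclass
class ClusterRecord:
    """A group of near-identical chains with alignment maps onto one
    representative."""

    representative_id: str
    member_ids: list[str]
    identity: dict[str, float] = field(default_factory=dict)   # % vs rep
    maps: dict[str, dict[int, int]] = field(default_factory=dict)

    def __contains__(self, structure_id: str) -> bool:
        return structure_id in self.member_ids


def align_pair(seq_a: str, seq_b: str) -> tuple[float, list[tuple[int, int]]]:
    """Globally align two sequences; return (identity %, aligned pairs).

    Identity = matches / length of the shorter sequence.  With match-only
    scoring the optimal alignment routes substitutions through gap-gap
    columns, so the raw alignment length over-counts and would deflate the
    identity of same-length variants; the shorter-sequence denominator
    keeps a 10 %-substituted equal-length pair at exactly 90 %.  Aligned
    pairs are 1-based (pos_a, pos_b).
    """
    aln = _aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(int(a1 - a0)):
            i, j = int(a0) + off, int(b0) + off
            pairs.append((i + 1, j + 1))
            if seq_a[i] == seq_b[j]:
                matches += 1
    denom = min(len(seq_a), len(seq_b))
    identity = 100.0 * matches / denom if denom else 0.0
    return identity, pairs


def _co_cluster(a: ChainRecord, b: ChainRecord,
                identity_min: float = IDENTITY_MIN,
                length_ratio_min: float = LENGTH_RATIO_MIN) -> tuple[bool, float]:
    la, lb = len(a.sequence), len(b.sequence)
    if min(la, lb) < length_ratio_min * max(la, lb):
        return False, 0.0
    identity, _ = align_pair(a.sequence, b.sequence)
    return identity >= identity_min, identity


def cluster_chains(chains: list[ChainRecord],
                   metadata: dict[str, tuple[float | None, float | None]] | None = None,
                   identity_min: float = IDENTITY_MIN,
                   length_ratio_min: float = LENGTH_RATIO_MIN,
                   ) -> list[ClusterRecord]:
    """Greedy single-linkage clustering of protein chains.

    Chains are pre-sorted by structure_id, which makes the result invariant
    to input order.  ``metadata`` maps structure_id to (resolution, r_value)
    and drives representative selection.

    Nucleic chains are ignored (partners only).
    """
    proteins = sorted((c for c in chains if c.molecule_type == "protein"),
                      key=lambda c: c.structure_id)
    if not proteins:
        return []
    # union-find over single-linkage pairs
    parent = list(range(len(proteins)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # cache pairwise decisions only between distinct sequences
    seq_cache: dict[tuple[str, str], bool] = {}
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            key = (proteins[i].sequence, proteins[j].sequence)
            if key not in seq_cache:
                seq_cache[key], _ = _co_cluster(
                    proteins[i], proteins[j], identity_min, length_ratio_min)
            if seq_cache[key]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[ChainRecord]] = {}
    for i, c in enumerate(proteins):
        groups.setdefault(find(i), []).append(c)

    clusters: list[ClusterRecord] = []
    for members in groups.values():
        member_ids = [m.structure_id for m in members]
        rep_id = select_representative(member_ids, metadata or {})
        rep = next(m for m in members if m.structure_id == rep_id)
        record = ClusterRecord(representative_id=rep_id, member_ids=member_ids)
        for m in members:
            identity, pairs = align_pair(m.sequence, rep.sequence)
            record.identity[m.structure_id] = identity
            record.maps[m.structure_id] = dict(pairs)
        clusters.append(record)
    clusters.sort(key=lambda c: c.representative_id)
    return clusters


def select_representative(
    member_ids: list[str],
    metadata: dict[str, tuple[float | None, float | None]],
) -> str:
    """Best-resolution member; ties and missing values fall back to best
    R-value, then to the lexicographically smallest id (logged)."""
    if not member_ids:
        raise ValueError("empty cluster")

    def sort_key(mid: str):
        res, r_val = metadata.get(mid, (None, None))
        return (
            res is None, res if res is not None else 0.0,
            r_val is None, r_val if r_val is not None else 0.0,
            mid,
        )

    ordered = sorted(member_ids, key=sort_key)
    if all(metadata.get(m, (None, None)) == (None, None) for m in member_ids):
        logger.info("cluster %s: no resolution/R metadata, representative "
                    "chosen lexicographically", ordered[0])
    return ordered[0]


def map_to_representative(member: ChainRecord, rep: ChainRecord) -> dict[int, int]:
    """Alignment map from member positions to representative positions.

    Global match-scoring alignment; member positions aligned to
    representative gaps are absent from the map.
    """
    _, pairs = align_pair(member.sequence, rep.sequence)
    if not pairs:
        raise ValueError(
            f"empty alignment between {member.structure_id} and {rep.structure_id}")
    return dict(pairs)


def write_cluster_tsv(clusters: list[ClusterRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["representative_id", "member_id", "identity_pct"])
        for cl in clusters:
            for mid in cl.member_ids:
                w.writerow([cl.representative_id, mid,
                            f"{cl.identity.get(mid, 100.0):.2f}"])


def read_cluster_tsv(path: str | Path,
                     chains: dict[str, ChainRecord]) -> list[ClusterRecord]:
    """Ingest an externally computed cluster TSV (clustering hook).

    Alignment maps to the representative are recomputed locally for every
    member present in ``chains``.
    """
    grouped: dict[str, list[tuple[str, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            grouped.setdefault(row["representative_id"], []).append(
                (row["member_id"], float(row.get("identity_pct") or 0.0)))
    clusters = []
    for rep_id, members in sorted(grouped.items()):
        record = ClusterRecord(representative_id=rep_id,
                               member_ids=[m for m, _ in members])
        rep = chains.get(rep_id)
        for mid, ident in members:
            record.identity[mid] = ident
            if rep is not None and mid in chains:
                record.maps[mid] = map_to_representative(chains[mid], rep)
        clusters.append(record)
    return clusters
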