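"""B-factor normalisation and soft-disorder calling.

The B-factor of residue *i* is the B-factor of its Cα.  Within each chain
the B-factors are standardised,

    b_i = (B_i - <B>) / sigma_B,

with mean and standard deviation taken over all observed Cα B-factors of
that chain (population convention, divide by n).  Normalisation is per
chain, never per complex: only residues anomalously mobile *relative to
their own chain* matter.  A residue is softly disordered when b_i > 1
(strict), or when it is missing from at least one of the crystals grouped
into a hierarchy node.  Positions missing from *every* structure of a node
are tracked separately ("always missing"): they stand for intrinsic
disorder and enter the prediction tests only if they become ordered
further down the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import ChainRecord


@dataclass
class BProfile:
    """Per-chain normalised b-factors on observed positions."""

    structure_id: str
    positions: np.ndarray   # 1-based observed positions, sorted
    b: np.ndarray           # normalised b-factor, parallel to positions
    degenerate: bool = False  # True iff sigma_B == 0 (constant-B chain)

    def as_dict(self) -> dict[int, float]:
        return {int(p): float(v) for p, v in zip(self.positions, self.b)}


def normalize_b(chain: ChainRecord) -> BProfile:
    """Standardise a chain's Cα B-factors (z-score, population sigma).

    A constant-B chain has ``sigma_B == 0``; instead of failing, the profile
    is flagged degenerate with all b set to 0, so no residue can exceed any
    positive threshold (plausible for tiny synthetic chains).
    """
    positions = np.array(sorted(chain.ca_b), dtype=int)
    if len(positions) < 2:
        raise ValueError(
            f"{chain.structure_id}: need >= 2 observed residues to normalise")
    raw = np.array([chain.ca_b[int(p)] for p in positions], dtype=float)
    mean = raw.mean()
    sigma = raw.std()  # population (divide-by-n) convention
    if sigma == 0.0:
        return BProfile(chain.structure_id, positions,
                        np.zeros_like(raw), degenerate=True)
    return BProfile(chain.structure_id, positions, (raw - mean) / sigma)


def high_b_set(profile: BProfile, threshold: float = 1.0) -> set[int]:
    """Positions with b strictly above ``threshold`` (default 1)."""
    return {int(p) for p, v in zip(profile.positions, profile.b) if v > threshold}


def node_sdr(
    members: list[tuple[ChainRecord, BProfile, dict[int, int]]],
    threshold: float = 1.0,
) -> tuple[set[int], set[int]]:
    """Soft-disorder region of a hierarchy node, in representative coordinates.

    Parameters
    ----------
    members
        ``(chain, profile, mapping)`` per structure of the node, where
        ``mapping`` sends the member's 1-based sequence positions to the
        cluster representative's.  Positions aligned to a representative
        gap are absent from the mapping and are dropped.

    Returns
    -------
    (sdr, always_missing)
        ``sdr`` is the union over members of high-b positions and of
        positions unobserved in at least one member.  ``always_missing``
        is the subset unobserved in *every* member.
    """
    if not members:
        raise ValueError("node_sdr: empty member list")
    sdr: set[int] = set()
    missing_per_member: list[set[int]] = []
    for chain, profile, mapping in members:
        high = {mapping[p] for p in high_b_set(profile, threshold) if p in mapping}
        missing = {mapping[p] for p in chain.missing_positions() if p in mapping}
        sdr |= high | missing
        missing_per_member.append(missing)
    always_missing = set.intersection(*missing_per_member)
    return sdr, always_missing
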