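"""Consensus-docking pose agreement.

Two docking programs run against the same prepared receptor produce two
poses per ligand. If the programs agree, the in-place heavy-atom RMSD
between the poses is small; a large RMSD flags an inconsistent, likely
false-positive pose. The filter accepts a compound when its RMSD is at or
below a threshold (2 Å is the common convention; relaxing to 3 Å recovers
more true actives at the cost of extra decoys).

No superposition is performed before the RMSD: both poses live in the
receptor frame, and aligning them would mask exactly the disagreement the
filter measures. Hydrogens are dropped first because programs differ in
hydrogen placement conventions. Atom correspondence is file order, checked
against the element sequence; symmetry-equivalent atom permutations are a
documented limitation, not handled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, PairingError
from .io import PoseRecord


@dataclass(frozen=True)
class PosePair:
    """One ligand's poses from two programs, plus its active/decoy label."""

    compound_id: str
    pose_a: PoseRecord
    pose_b: PoseRecord
    label: str = "unknown"


@dataclass
class ConsensusResult:
    threshold: float
    per_compound: list  # (compound_id, rmsd, accepted)
    actives_accepted: int
    actives_rejected: int
    decoys_accepted: int
    decoys_rejected: int
    unknown_accepted: int
    unknown_rejected: int

    @property
    def n_accepted(self) -> int:
        return self.actives_accepted + self.decoys_accepted + self.unknown_accepted

    @property
    def n_rejected(self) -> int:
        return self.actives_rejected + self.decoys_rejected + self.unknown_rejected

    def summary_row(self) -> dict:
        return {
            "threshold": self.threshold,
            "accepted": self.n_accepted,
            "rejected": self.n_rejected,
            "actives_accepted": self.actives_accepted,
            "actives_rejected": self.actives_rejected,
            "decoys_accepted": self.decoys_accepted,
            "decoys_rejected": self.decoys_rejected,
        }


def pose_rmsd(pair: PosePair) -> float:
    """Heavy-atom in-place RMSD between the two poses of one ligand, in Å.

    sqrt(mean over atoms of squared Euclidean displacement); raises
    :class:`PairingError` when the heavy-atom element sequences differ.
    """
    a = pair.pose_a.heavy()
    b = pair.pose_b.heavy()
    if a.n_atoms != b.n_atoms:
        raise PairingError(
            f"{pair.compound_id!r}: heavy-atom counts differ "
            f"({a.n_atoms} vs {b.n_atoms})"
        )
    if a.elements != b.elements:
        raise PairingError(
            f"{pair.compound_id!r}: element sequences differ between poses"
        )
    if a.n_atoms < 1:
        raise DataError(f"{pair.compound_id!r}: pose has no atoms")
    diff = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def consensus_filter(pairs, threshold: float) -> ConsensusResult:
    """Accept every pair with rmsd ≤ threshold; tally by label.

    The boundary is inclusive: a pose exactly at the threshold passes.
    An empty input yields an all-zero result, not an error.
    """
    if threshold <= 0:
        raise DataError(f"threshold must be positive, got {threshold}")
    per_compound = []
    counts = {("active", True): 0, ("active", False): 0,
              ("decoy", True): 0, ("decoy", False): 0,
              ("unknown", True): 0, ("unknown", False): 0}
    for pair in pairs:
        rmsd = pose_rmsd(pair)
        accepted = rmsd <= threshold
        per_compound.append((pair.compound_id, rmsd, accepted))
        counts[(pair.label, accepted)] += 1
    return ConsensusResult(
        threshold=threshold,
        per_compound=per_compound,
        actives_accepted=counts[("active", True)],
        actives_rejected=counts[("active", False)],
        decoys_accepted=counts[("decoy", True)],
        decoys_rejected=counts[("decoy", False)],
        unknown_accepted=counts[("unknown", True)],
        unknown_rejected=counts[("unknown", False)],
    )


def threshold_sweep(pairs, thresholds) -> list[dict]:
    """One consensus summary row per threshold (ascending)."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise DataError("thresholds must be sorted ascending")
    pairs = list(pairs)
    return [consensus_filter(pairs, t).summary_row() for t in thresholds]
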