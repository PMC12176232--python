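"""CD-HIT-style greedy redundancy removal.

Homologous sequences above an identity cutoff (default 0.6, the cutoff used
for the CML dataset this toolkit models) are collapsed to one representative
per cluster.  Identity between two sequences is computed from an exact global
alignment (match +1, mismatch 0, linear gap -1) as the number of identical
aligned columns divided by the length of the shorter sequence — the
denominator convention of CD-HIT.  No k-mer prefilter heuristics: exact
alignment is affordable at the dataset sizes this package targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from .sequence_io import LabeledDataset, ProteinRecord

logger = logging.getLogger(__name__)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of one greedy clustering pass."""

    threshold: float
    representatives: list[str]
    membership: dict[str, str]

    def __post_init__(self) -> None:
        reps = set(self.representatives)
        for rep in reps:
            if self.membership.get(rep) != rep:
                raise ValueError(f"representative {rep!r} does not map to itself")
        for member, rep in self.membership.items():
            if rep not in reps:
                raise ValueError(f"{member!r} assigned to unknown representative {rep!r}")

    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {rep: 0 for rep in self.representatives}
        for rep in self.membership.values():
            sizes[rep] += 1
        return sizes


def pairwise_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Global-alignment identity fraction in [0, 1].

    Identical aligned columns of the optimal alignment divided by the shorter
    sequence length.  Symmetric, and 1.0 for identical sequences.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("pairwise identity requires non-empty sequences")
    if a.sequence == b.sequence:
        return 1.0
    alignment = _ALIGNER.align(a.sequence, b.sequence)[0]
    identities = alignment.counts().identities
    return min(1.0, identities / min(len(a), len(b)))


def greedy_cluster(records: list[ProteinRecord], threshold: float = 0.6) -> ClusterResult:
    """Greedy incremental clustering at an identity ``threshold``.

    Records are visited by descending length (ties broken by ascending id);
    each joins the first existing representative with identity >= threshold,
    otherwise it founds a new cluster.  Deterministic.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    representatives: list[ProteinRecord] = []
    membership: dict[str, str] = {}
    for rec in ordered:
        for rep in representatives:
            if pairwise_identity(rec, rep) >= threshold:
                membership[rec.id] = rep.id
                break
        else:
            representatives.append(rec)
            membership[rec.id] = rec.id
    return ClusterResult(threshold, [r.id for r in representatives], membership)


def dedupe_dataset(ds: LabeledDataset, threshold: float = 0.6) -> LabeledDataset:
    """Remove redundant sequences within each class separately.

    Per-class clustering prevents a positive sequence from being absorbed by
    a negative representative.  Representatives keep their original dataset
    order and labels.
    """
    keep: set[str] = set()
    for label in (1, 0):
        class_records = [r for r, y in zip(ds.records, ds.labels) if y == label]
        if not class_records:
            continue
        result = greedy_cluster(class_records, threshold)
        keep.update(result.representatives)
        logger.info(
            "class %d: %d sequences -> %d representatives at threshold %.2f",
            label, len(class_records), len(result.representatives), threshold,
        )
    indices = [i for i, r in enumerate(ds.records) if r.id in keep]
    return ds.subset(indices)
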