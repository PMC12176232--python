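"""Seeded synthetic data and bundled reference evaluation tables.

The generator emits protein sequences whose amino-acid composition differs
between classes by a planted, analytically known shift: negatives draw
residues i.i.d. from the uniform composition, positives from a composition
where a designated residue subset's probabilities are multiplied by
(1 + delta) and renormalized.  AAC/PseAAC are exactly the statistics this
shift moves, so the pipeline has a knowable signal to recover.  It does not
emulate real CML biology (domain structure, motifs, phylogeny) — passing
tests demonstrate pipeline correctness, not clinical performance.

``reported_confusion_matrices`` bundles the eighteen confusion matrices
(6 algorithms x 3 encodings) and the metric cells printed alongside them in
the study this toolkit models, as golden inputs for the evaluation
arithmetic.  Consistency between each matrix and its printed metrics is
computed at run time by ``table_check``, never assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import ConfusionMatrix, table_check
from .redundancy import pairwise_identity
from .sequence_io import ALPHABET, LabeledDataset, ProteinRecord

#: Residues whose probability is boosted in the positive class.
DEFAULT_BOOSTED = ("A", "L", "K")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-class sequence set."""

    n_pos: int
    n_neg: int
    length_range: tuple[int, int] = (80, 120)
    delta: float = 2.0
    seed: int = 0
    boosted: tuple[str, ...] = DEFAULT_BOOSTED

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class counts must be non-negative")
        if self.n_pos + self.n_neg < 1:
            raise ValueError("at least one sequence is required")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if not set(self.boosted) <= set(ALPHABET):
            raise ValueError("boosted residues must be canonical")

    def positive_composition(self) -> np.ndarray:
        """Analytic residue probabilities of the positive class."""
        p = np.full(20, 1 / 20)
        for ch in self.boosted:
            p[ALPHABET.index(ch)] *= 1 + self.delta
        return p / p.sum()

    def negative_composition(self) -> np.ndarray:
        return np.full(20, 1 / 20)


def _draw(rng: np.random.Generator, n: int, prefix: str, p: np.ndarray, lo: int, hi: int):
    alphabet = np.array(list(ALPHABET))
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=p))
        records.append(ProteinRecord(f"{prefix}{i + 1:04d}", "synthetic", seq))
    return records


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Seeded two-class sequence set with a planted composition shift.

    At ``delta = 0`` the classes are exchangeable (no signal).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    pos = _draw(rng, spec.n_pos, "POS", spec.positive_composition(), lo, hi)
    neg = _draw(rng, spec.n_neg, "NEG", spec.negative_composition(), lo, hi)
    records = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg))
    return LabeledDataset(records, labels)


def plant_homologs(
    base: ProteinRecord, n: int, identity_target: float, seed: int = 0
) -> list[ProteinRecord]:
    """Mutated copies of ``base`` at a controlled identity level.

    Each copy substitutes ceil((1 - identity_target) * L) distinct random
    positions with a different residue.  The resulting alignment identity to
    the base is verified to be >= identity_target - 0.05, not assumed.
    """
    if not 0 < identity_target <= 1:
        raise ValueError("identity_target must be in (0, 1]")
    if len(base) < 10:
        raise ValueError("base sequence must have at least 10 residues")
    rng = np.random.default_rng(seed)
    L = len(base)
    n_mut = math.ceil((1 - identity_target) * L)
    copies = []
    for i in range(n):
        seq = list(base.sequence)
        for pos in rng.choice(L, size=n_mut, replace=False):
            current = seq[pos]
            alternatives = [ch for ch in ALPHABET if ch != current]
            seq[pos] = str(rng.choice(alternatives))
        copy = ProteinRecord(f"{base.id}_hom{i + 1}", "planted homolog", "".join(seq))
        achieved = pairwise_identity(base, copy)
        if achieved < identity_target - 0.05:
            raise RuntimeError(
                f"planted homolog identity {achieved:.3f} fell below target "
                f"{identity_target} - 0.05"
            )
        copies.append(copy)
    return copies


# ---------------------------------------------------------------------------
# reference evaluation tables (18 confusion matrices, 6 algorithms x 3 encodings)


@dataclass(frozen=True)
class ReferenceEvaluation:
    """One reported confusion matrix with its printed metric cells.

    ``printed`` maps metric name to a point value or an (lo, hi) range, as
    printed in the source tables; ``consistency`` recomputes the metrics
    from the counts and flags each cell.
    """

    scheme: str
    algo: str
    cm: ConfusionMatrix
    printed: dict

    @property
    def label(self) -> str:
        return f"{self.scheme}/{self.algo}"

    def consistency(self) -> dict:
        return table_check(self.cm, self.printed)


def _ref(scheme, algo, tn, fp, fn, tp, accuracy, f1, recall, specificity):
    return ReferenceEvaluation(
        scheme, algo, ConfusionMatrix(tn, fp, fn, tp),
        {"accuracy": accuracy, "f1": f1, "recall": recall, "specificity": specificity},
    )


def reported_confusion_matrices() -> list[ReferenceEvaluation]:
    """The eighteen bundled reference evaluations.

    Ranges appear where the source printed an interval across repeated runs;
    points where it printed a single value.
    """
    return [
        # --- PseAAC ---
        _ref("PseAAC", "SVC", 424, 28, 14, 211, (92, 94), (91, 92), (91, 93), (92, 94)),
        _ref("PseAAC", "XGB", 26159, 2271, 3435, 10890, (79, 85), (63, 70), (51, 55), (92, 94)),
        _ref("PseAAC", "LR", 25817, 2849, 11010, 3445, (66, 69), (10, 20), (6, 10), (97, 98)),
        _ref("PseAAC", "DT", 24388, 4278, 3803, 10652, (81, 84), (73, 76), (74, 76), (84, 86)),
        _ref("PseAAC", "RF", 28014, 808, 2753, 11546, (87, 91), (85, 87), (80, 83), (96, 97)),
        _ref("PseAAC", "KNN", 419, 23, 95, 140, (82, 86), (72, 74), (61, 64), (93, 95)),
        # --- AAC ---
        _ref("AAC", "SVC", 271, 0, 121, 62, 54.95, 14.3, 0.7, 100),
        _ref("AAC", "XGB", 409, 23, 119, 103, 56.8, 52.9, 45.9, 69),
        _ref("AAC", "LR", 9028, 2022, 8519, 2025, 51.1, 27.6, 19.1, 81.7),
        _ref("AAC", "DT", 124, 98, 95, 107, 54.4, 52.25, 52.9, 55.8),
        _ref("AAC", "RF", 12612, 6817, 11832, 6510, 50.6, 41.1, 35.4, 64.9),
        _ref("AAC", "KNN", 112, 105, 89, 118, 54.2, 54.8, 57, 51),
        # --- DPC ---
        _ref("DPC", "SVC", 416, 37, 17, 207, (92, 94), (87, 88), (91, 93), (90, 93)),
        _ref("DPC", "XGB", 413, 25, 105, 134, (79, 84), (66, 68), (55, 57), (92, 94)),
        _ref("DPC", "LR", 453, 0, 224, 0, (66, 69), (0, 0), (6, 10), 100),
        _ref("DPC", "DT", 433, 16, 54, 134, (81, 84), (70, 73), (56, 59), (96, 97)),
        _ref("DPC", "RF", 437, 23, 93, 124, (82, 84), (67, 68), (57, 58), (94, 95)),
        _ref("DPC", "KNN", 438, 15, 179, 45, (72, 73), (31, 32), (20, 21), (95, 97)),
    ]


def reference_consistency_report() -> dict[str, dict]:
    """``table_check`` results for every bundled reference evaluation."""
    return {ref.label: ref.consistency() for ref in reported_confusion_matrices()}
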