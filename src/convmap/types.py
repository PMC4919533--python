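"""Shared domain types: condition labels, beta-image sets, statistic maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CATEGORIES = ("face", "house", "body")
PHASES = ("retrieval", "iti")


@dataclass(frozen=True)
class ConditionLabel:
    """One condition-instance regressor of the retrieval design.

    ``order_index`` selects which member of the learned pair acts as cue:
    for a fixed ``association_id``, order 0 and order 1 have swapped
    cue/associate categories.
    """

    association_id: int
    cue_category: str
    associate_category: str
    order_index: int
    phase: str
    instance_index: int
    run_id: int

    def __post_init__(self) -> None:
        if self.cue_category not in CATEGORIES:
            raise ValueError(f"unknown cue category {self.cue_category!r}")
        if self.associate_category not in CATEGORIES:
            raise ValueError(f"unknown associate category {self.associate_category!r}")
        if self.cue_category == self.associate_category:
            raise ValueError(
                "cue and associate categories must differ "
                f"(got {self.cue_category!r} twice for association {self.association_id})"
            )
        if self.order_index not in (0, 1):
            raise ValueError(f"order_index must be 0 or 1, got {self.order_index}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def category_pair(self) -> frozenset[str]:
        """Unordered category pair; constant across a given association."""
        return frozenset((self.cue_category, self.associate_category))


def validate_labels(labels: list[ConditionLabel]) -> None:
    """Enforce cross-label invariants of a design."""
    order_cats: dict[tuple[int, int], tuple[str, str]] = {}
    for lab in labels:
        key = (lab.association_id, lab.order_index)
        cats = (lab.cue_category, lab.associate_category)
        if order_cats.setdefault(key, cats) != cats:
            raise ValueError(
                f"association {lab.association_id} order {lab.order_index} "
                "has inconsistent categories"
            )
    for (aid, order), cats in order_cats.items():
        other = order_cats.get((aid, 1 - order))
        if other is not None and other != (cats[1], cats[0]):
            raise ValueError(
                f"association {aid}: orders 0 and 1 must have swapped categories"
            )


@dataclass
class BetaImageSet:
    """A labeled 4-D stack of beta volumes (x, y, z, condition-instance)."""

    data: np.ndarray
    labels: list[ConditionLabel]
    mask: np.ndarray
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D, got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} != data grid {self.data.shape[:3]}"
            )
        if len(self.labels) != self.data.shape[3]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[3]} volumes"
            )
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        validate_labels(self.labels)
        n_ret = sum(1 for lab in self.labels if lab.phase == "retrieval")
        n_iti = sum(1 for lab in self.labels if lab.phase == "iti")
        if n_ret and n_iti and n_ret != n_iti:
            raise ValueError(
                f"retrieval ({n_ret}) and iti ({n_iti}) instance counts differ"
            )

    def phase_indices(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        return np.array([i for i, lab in enumerate(self.labels) if lab.phase == phase])

    def phase_labels(self, phase: str) -> list[ConditionLabel]:
        return [lab for lab in self.labels if lab.phase == phase]

    def phase_data(self, phase: str) -> np.ndarray:
        """(n_instances, n_mask_voxels) matrix for one phase, mask order = C order."""
        idx = self.phase_indices(phase)
        return self.data[..., idx][self.mask].T


@dataclass
class StatMap:
    """A voxel-wise statistic map with optional p-values.

    ``values`` are defined (finite) inside ``mask`` only; ``p`` where present
    lives on the same support.
    """

    values: np.ndarray
    mask: np.ndarray
    level: str = "subject"
    metric: str = ""
    p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.level not in ("subject", "group"):
            raise ValueError(f"level must be subject|group, got {self.level!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside mask")
        if self.p is not None:
            self.p = np.asarray(self.p, dtype=np.float64)
            if self.p.shape != self.values.shape:
                raise ValueError("p map shape differs from values")
            pm = self.p[self.mask]
            if np.any((pm < 0) | (pm > 1)):
                raise ValueError("p values outside [0, 1] inside mask")

    def masked(self) -> np.ndarray:
        return self.values[self.mask]
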