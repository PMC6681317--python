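"""Core domain types for traced root system architectures.

A traced plant is represented as a :class:`RootSystem`: the primary root (PR)
is stored as the ordered inter-branch segment lengths plus the unbranched tip,
and each lateral root (LR) as its total length, index-aligned with the branch
point it emerges from.  Positions run shootward-to-rootward, so segment 1
spans the root--shoot junction to the first lateral root.

All lengths are millimetres; readers and writers never rescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator


class SchemaError(ValueError):
    """A tabular input violates the measurement-table schema."""


class RSMLFormatError(ValueError):
    """An RSML document violates the subset of the format this package reads."""


@dataclass(frozen=True)
class RootSystem:
    """One plant's traced root architecture at a single observation time.

    Parameters
    ----------
    plant_id:
        Unique label for the individual plant (within a day/treatment).
    accession:
        Genotype / natural-accession label; may be empty.
    day:
        Days after sowing at which the plant was traced.
    treatment:
        Free-text treatment label; the empty string denotes control.
    pr_segments:
        Ordered PR lengths between successive branch points, in mm.  Segment
        ``k`` runs from branch point ``k-1`` (the shoot junction for ``k=1``)
        to branch point ``k``.
    pr_tip:
        PR length from the last branch point to the root apex, in mm.  For an
        unbranched plant this is the whole primary root.
    lr_lengths:
        Ordered LR lengths in mm, shoot-to-tip order, aligned with
        ``pr_segments`` (LR ``k`` emerges at branch point ``k``).
    """

    plant_id: str
    accession: str = ""
    day: int = 0
    treatment: str = ""
    pr_segments: tuple[float, ...] = ()
    pr_tip: float = 0.0
    lr_lengths: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pr_segments", tuple(float(s) for s in self.pr_segments))
        object.__setattr__(self, "lr_lengths", tuple(float(s) for s in self.lr_lengths))
        object.__setattr__(self, "pr_tip", float(self.pr_tip))
        if len(self.pr_segments) != len(self.lr_lengths):
            raise SchemaError(
                f"plant {self.plant_id!r}: {len(self.pr_segments)} PR segments but "
                f"{len(self.lr_lengths)} lateral roots; counts must match"
            )
        if any(s < 0 for s in self.pr_segments):
            raise ValueError(f"plant {self.plant_id!r}: negative PR segment length")
        if any(s < 0 for s in self.lr_lengths):
            raise ValueError(f"plant {self.plant_id!r}: negative LR length")
        if self.pr_tip < 0:
            raise ValueError(f"plant {self.plant_id!r}: negative PR tip length")

    @property
    def n_lr(self) -> int:
        """Number of lateral roots."""
        return len(self.lr_lengths)

    @property
    def pr_length(self) -> float:
        """Total primary root length (segments plus tip), mm."""
        return sum(self.pr_segments) + self.pr_tip


@dataclass
class TraitRecord:
    """Conventional root-architecture trait panel for one plant.

    Trait fields follow the field's standard abbreviations: TRL (total root
    length), PRL (primary root length), TLRL (total lateral root length),
    RD (root density, LRs per mm of PR), TLr = TLRL/TRL, PLr = TLRL/PRL, and
    the branching-zone partition preBZ + BZ + postBZ = PRL.  The slope fields
    ``m``/``b``/``r2`` hold the per-plant rhizochron fit once merged by
    :func:`rhizochron.fitting.batch_fit`; they are ``None`` for discarded
    plants or when only traits were computed.
    """

    plant_id: str
    accession: str = ""
    day: int = 0
    treatment: str = ""
    TRL: float = 0.0
    PRL: float = 0.0
    TLRL: float = 0.0
    RD: float | None = 0.0
    TLr: float = 0.0
    PLr: float = 0.0
    BZ: float = 0.0
    preBZ: float = 0.0
    postBZ: float = 0.0
    n_lr: int = 0
    m: float | None = None
    b: float | None = None
    r2: float | None = None
    discarded: bool = False
    discard_reason: str = ""

    #: column order used by the trait-table CSV writer
    COLUMNS = (
        "plant_id", "accession", "day", "treatment",
        "TRL", "PRL", "TLRL", "RD", "TLr", "PLr", "BZ", "preBZ", "postBZ",
        "m", "b", "r2", "n_lr", "discarded", "discard_reason",
    )


@dataclass(frozen=True)
class RhizochronFit:
    """Per-plant linear fit of LR length on LR position along the PR.

    ``m`` is the rhizochron index (mm of LR length per mm of PR position,
    hence dimensionless), ``b`` the intercept in mm.  ``r2`` is ``None`` when
    the response is constant (zero total sum of squares).  A plant that
    cannot be fitted is flagged ``discarded`` with a human-readable reason
    and carries no coefficients.
    """

    m: float | None
    b: float | None
    n_points: int
    r2: float | None
    discarded: bool = False
    discard_reason: str = ""

    REASON_TOO_FEW = "fewer than two elongated lateral roots"
    REASON_DEGENERATE = "degenerate positions"


@dataclass(frozen=True)
class DiscardEntry:
    plant_id: str
    accession: str
    day: int
    treatment: str
    reason: str


@dataclass
class DiscardLog:
    """Bookkeeping of every plant excluded from rhizochron fitting."""

    entries: list[DiscardEntry] = field(default_factory=list)

    def add(self, root: RootSystem, reason: str) -> None:
        self.entries.append(
            DiscardEntry(root.plant_id, root.accession, root.day, root.treatment, reason)
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[DiscardEntry]:
        return iter(self.entries)


__all__ = [
    "RootSystem",
    "TraitRecord",
    "RhizochronFit",
    "DiscardEntry",
    "DiscardLog",
    "SchemaError",
    "RSMLFormatError",
    "replace",
    "fields",
]
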