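"""The 557-class repair-outcome taxonomy.

Template-free Cas9 repair outcomes are summarised as one of 557 classes:
536 deletion classes (position + length), 4 single-nucleotide insertions,
16 dinucleotide insertions, and a single catch-all class for insertions of
3 bp or more.

Coordinate convention
---------------------
Positions are cut-relative integers.  The blunt Cas9 cut lies *between*
position -1 and position 0; position 0 is the first base 3' of the cut.
A deletion class is written ``<start>+<length>``, e.g. ``-5+4`` deletes
4 bp beginning 5 nt upstream of the cut.

Deletion enumeration
--------------------
A deletion (start s, length L) is in the taxonomy when

* 1 <= L <= 29 (events of 30 bp or more are too rare to model), and
* the deleted interval [s, s+L) overlaps the window from 3 nt upstream to
  2 nt downstream of the cut (positions -3 .. +1), and
* s >= -26 (calibration floor).

The per-length class count is then min(L+4, 28) and the total is exactly
536.  The verbal window rule alone admits 551 (start, length) pairs; the
-26 start floor is the explicit calibration constant that reproduces the
published 536-class deletion panel, and it is versioned here rather than
derived at run time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Kind",
    "RepairLabel",
    "LabelSpace",
    "IndelDescriptor",
    "OutOfTaxonomy",
    "OUT_OF_TAXONOMY",
    "LabelError",
    "TaskSummary",
    "AggregationResult",
    "enumerate_label_space",
    "format_label",
    "parse_label",
    "parse_indel_descriptor",
    "descriptor_to_label",
    "frame_class",
    "aggregate_outcomes",
    "tasks_from_distribution",
]

NUCLEOTIDES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

#: Start positions below this floor are excluded from the deletion panel.
#: Together with the -3..+2 overlap window this calibrates the deletion
#: class count to the published 536.
DELETION_START_FLOOR = -26


class LabelError(ValueError):
    """Raised for malformed label/descriptor strings or invalid labels."""


class Kind(str, Enum):
    DELETION = "DELETION"
    INS1 = "INS1"
    INS2 = "INS2"
    INS3PLUS = "INS3PLUS"


@dataclass(frozen=True)
class RepairLabel:
    """One repair-outcome class.

    ``start`` and ``length`` are meaningful for deletions; insertions of
    1 or 2 bp carry the inserted sequence, and the >=3 bp insertion class
    carries no sequence (its length is stored as 3 by convention).
    """

    kind: Kind
    start: int = 0
    length: int = 0
    inserted: str = ""

    def __post_init__(self) -> None:
        if self.kind is Kind.DELETION:
            if not 1 <= self.length <= 29:
                raise LabelError(f"deletion length must be 1..29, got {self.length}")
            if self.inserted:
                raise LabelError("deletions carry no inserted sequence")
        elif self.kind is Kind.INS1:
            if self.inserted not in NUCLEOTIDES:
                raise LabelError(f"INS1 needs a single nucleotide, got {self.inserted!r}")
            object.__setattr__(self, "length", 1)
        elif self.kind is Kind.INS2:
            if self.inserted not in DINUCLEOTIDES:
                raise LabelError(f"INS2 needs a dinucleotide, got {self.inserted!r}")
            object.__setattr__(self, "length", 2)
        elif self.kind is Kind.INS3PLUS:
            if self.inserted:
                raise LabelError("INS3PLUS carries no inserted sequence")
            object.__setattr__(self, "length", 3)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_label(self)


class OutOfTaxonomy(NamedTuple):
    """Sentinel returned for events outside the 557-class taxonomy.

    Carried (never silently dropped) so callers can log and renormalize.
    """

    reason: str


OUT_OF_TAXONOMY = OutOfTaxonomy("out of taxonomy")


@dataclass(frozen=True)
class IndelDescriptor:
    """A sequencing-pipeline indel descriptor such as ``D1_L-2C1R1``.

    ``left``/``right`` are the rightmost and leftmost intact cut-relative
    positions flanking the event; ``mh_shift`` is the optional ``C{m}``
    microhomology shift component (deletions only).
    """

    op: str  # "D" or "I"
    size: int
    left: int
    right: int
    mh_shift: int = 0
    inserted: str = ""

    def __post_init__(self) -> None:
        if self.op not in ("D", "I"):
            raise LabelError(f"descriptor op must be D or I, got {self.op!r}")
        if self.size < 1:
            raise LabelError(f"descriptor size must be positive, got {self.size}")
        if self.op == "D" and self.right - self.left - 1 - self.mh_shift != self.size:
            raise LabelError(
                f"inconsistent deletion descriptor: right-left-1-mh = "
                f"{self.right - self.left - 1 - self.mh_shift} != size {self.size}"
            )


# ---------------------------------------------------------------------------
# Label space


@dataclass(frozen=True)
class LabelSpace:
    """The ordered universe of repair classes with a string codec.

    Ordering: deletions sorted by (length, start), then the four 1 bp
    insertions A,C,G,T, then the 16 dinucleotide insertions in
    lexicographic order, then the >=3 bp insertion class.
    """

    labels: tuple[RepairLabel, ...]
    max_del_len: int
    window_up: int
    window_down: int
    _index: dict = field(repr=False, hash=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._index.update({lab: i for i, lab in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i: int) -> RepairLabel:
        return self.labels[i]

    def index_of(self, label: RepairLabel) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise LabelError(f"label {format_label(label)} not in the taxonomy") from None

    def __contains__(self, label: RepairLabel) -> bool:
        return label in self._index

    # -- cached boolean masks over the class axis ---------------------------

    @property
    def deletion_mask(self) -> np.ndarray:
        return np.array([lab.kind is Kind.DELETION for lab in self.labels])

    @property
    def ins1_mask(self) -> np.ndarray:
        return np.array([lab.kind is Kind.INS1 for lab in self.labels])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([lab.length for lab in self.labels])

    @property
    def ins3_mask(self) -> np.ndarray:
        return np.array([lab.kind is Kind.INS3PLUS for lab in self.labels])

    def n_deletions(self) -> int:
        return int(self.deletion_mask.sum())

    def n_insertions(self) -> int:
        return len(self) - self.n_deletions()

    def strings(self) -> list[str]:
        return [format_label(lab) for lab in self.labels]


def enumerate_label_space(
    max_del_len: int = 29,
    window_up: int = 3,
    window_down: int = 2,
    start_floor: int = DELETION_START_FLOOR,
) -> LabelSpace:
    """Enumerate the full ordered label space (557 classes at defaults).

    A deletion (start s, length L) is admitted when 1 <= L <= max_del_len,
    [s, s+L) overlaps the window positions -window_up .. window_down-1, and
    s >= start_floor.  Insertion classes are always the fixed 4 + 16 + 1.
    """
    if max_del_len < 0:
        raise LabelError("max_del_len must be >= 0")
    if window_up < 0 or window_down < 0:
        raise LabelError("window bounds must be >= 0")
    dels: list[RepairLabel] = []
    for length in range(1, max_del_len + 1):
        lo = max(start_floor, -window_up - length + 1)
        hi = window_down - 1
        for start in range(lo, hi + 1):
            dels.append(RepairLabel(Kind.DELETION, start=start, length=length))
    dels.sort(key=lambda lab: (lab.length, lab.start))
    ins: list[RepairLabel] = [RepairLabel(Kind.INS1, inserted=n) for n in NUCLEOTIDES]
    ins += [RepairLabel(Kind.INS2, inserted=d) for d in DINUCLEOTIDES]
    ins.append(RepairLabel(Kind.INS3PLUS))
    return LabelSpace(
        labels=tuple(dels + ins),
        max_del_len=max_del_len,
        window_up=window_up,
        window_down=window_down,
    )


# ---------------------------------------------------------------------------
# Codec

_MINUS = "−"  # unicode minus accepted on input

_DEL_RE = re.compile(r"^([+-]?\d+)\+(\d+)$")
_INS1_RE = re.compile(r"^1\+([ACGT])$")
_INS2_RE = re.compile(r"^2\+([ACGT]{2})$")


def format_label(label: RepairLabel) -> str:
    """Canonical string for a label: ``-5+4``, ``1+T``, ``2+AG`` or ``3``."""
    if label.kind is Kind.DELETION:
        return f"{label.start}+{label.length}"
    if label.kind is Kind.INS1:
        return f"1+{label.inserted}"
    if label.kind is Kind.INS2:
        return f"2+{label.inserted}"
    return "3"


def parse_label(s: str) -> RepairLabel:
    """Parse a codec string back into a :class:`RepairLabel`.

    Whitespace-tolerant; accepts the unicode minus sign U+2212.
    """
    t = s.strip().replace(" ", "").replace(_MINUS, "-").upper()
    if t == "3":
        return RepairLabel(Kind.INS3PLUS)
    m = _INS1_RE.match(t)
    if m:
        return RepairLabel(Kind.INS1, inserted=m.group(1))
    m = _INS2_RE.match(t)
    if m:
        return RepairLabel(Kind.INS2, inserted=m.group(1))
    m = _DEL_RE.match(t)
    if m:
        return RepairLabel(Kind.DELETION, start=int(m.group(1)), length=int(m.group(2)))
    raise LabelError(f"cannot parse repair label {s!r}")


# ---------------------------------------------------------------------------
# Descriptor conversion

_DESC_RE = re.compile(
    r"^([DI])(\d+)_L(-?\d+)(?:C(\d+))?R(-?\d+)(?:_([ACGT]+))?$"
)


def parse_indel_descriptor(s: str, inserted: str = "") -> IndelDescriptor:
    """Parse a descriptor string like ``D1_L-2C1R1`` or ``I1_L-1R0``.

    The inserted sequence of an insertion is usually reported in a separate
    column; it may be passed via ``inserted`` or appended to the string
    after an underscore (``I1_L-1R0_T``).
    """
    t = s.strip().replace(_MINUS, "-")
    m = _DESC_RE.match(t)
    if m is None:
        raise LabelError(f"cannot parse indel descriptor {s!r}")
    op, size, left, mh, right, ins_suffix = m.groups()
    if ins_suffix and inserted and ins_suffix != inserted:
        raise LabelError(f"conflicting inserted sequences for {s!r}")
    ins = (ins_suffix or inserted or "").upper()
    if op == "D" and ins:
        raise LabelError(f"deletion descriptor {s!r} cannot carry an inserted sequence")
    return IndelDescriptor(
        op=op,
        size=int(size),
        left=int(left),
        right=int(right),
        mh_shift=int(mh) if mh else 0,
        inserted=ins,
    )


def descriptor_to_label(
    d: IndelDescriptor, space: LabelSpace
) -> RepairLabel | OutOfTaxonomy:
    """Convert a descriptor into a taxonomy label.

    Deletions map via ``start = left + 1 + mh_shift`` and
    ``length = right - left - 1 - mh_shift`` (a ``C{m}`` microhomology
    component shifts the reported deletion m bases rightward).  Deletions
    longer than the panel maximum or not overlapping the cut window return
    the :data:`OUT_OF_TAXONOMY` sentinel so the caller can drop and
    renormalize explicitly.
    """
    if d.op == "I":
        if d.size == 1:
            if len(d.inserted) != 1:
                raise LabelError("1 bp insertion descriptor needs its inserted base")
            return RepairLabel(Kind.INS1, inserted=d.inserted)
        if d.size == 2:
            if len(d.inserted) != 2:
                raise LabelError("2 bp insertion descriptor needs its inserted dinucleotide")
            return RepairLabel(Kind.INS2, inserted=d.inserted)
        return RepairLabel(Kind.INS3PLUS)
    start = d.left + 1 + d.mh_shift
    length = d.right - d.left - 1 - d.mh_shift
    if not 1 <= length <= space.max_del_len:
        return OutOfTaxonomy(f"deletion length {length} outside 1..{space.max_del_len}")
    label = RepairLabel(Kind.DELETION, start=start, length=length)
    if label not in space:
        return OutOfTaxonomy(
            f"deletion {format_label(label)} outside the cut window panel"
        )
    return label


# ---------------------------------------------------------------------------
# Frame classes and task aggregation


def frame_class(label: RepairLabel, ins3_as_inframe: bool = True) -> int:
    """Reading-frame class of a label: indel length mod 3.

    The >=3 bp insertion class has unknown true length; by default it is
    treated as length 3 (in-frame, class 0).
    """
    if label.kind is Kind.INS3PLUS and not ins3_as_inframe:
        raise LabelError("INS3PLUS has no frame class when excluded by config")
    return label.length % 3


class TaskSummary(NamedTuple):
    """The six aggregate prediction tasks derived from a 557-distribution."""

    ins1: float
    del1: float
    deletion: float
    frameshift1: float
    frameshift2: float
    frameshift_overall: float


class AggregationResult(NamedTuple):
    distribution: np.ndarray
    dropped: list[tuple[str, float, str]]  # (row string, count, reason)


def _row_to_label(s: str, space: LabelSpace) -> RepairLabel | OutOfTaxonomy:
    try:
        return parse_label(s)
    except LabelError:
        pass
    return descriptor_to_label(parse_indel_descriptor(s), space)


def aggregate_outcomes(
    rows: Iterable[tuple[str, float]], space: LabelSpace
) -> AggregationResult:
    """Aggregate (label-or-descriptor string, count) rows into a distribution.

    Out-of-taxonomy rows are excluded before normalization and reported in
    the drop log.  Raises :class:`LabelError` if no in-taxonomy mass remains.
    """
    p = np.zeros(len(space))
    dropped: list[tuple[str, float, str]] = []
    for s, count in rows:
        if count < 0:
            raise LabelError(f"negative count {count} for row {s!r}")
        lab = _row_to_label(s, space)
        if isinstance(lab, OutOfTaxonomy):
            dropped.append((s, count, lab.reason))
            continue
        p[space.index_of(lab)] += count
    total = p.sum()
    if total <= 0:
        raise LabelError("no in-taxonomy outcome mass to normalize")
    return AggregationResult(p / total, dropped)


def tasks_from_distribution(
    p: Sequence[float],
    space: LabelSpace,
    ins3_as_inframe: bool = True,
    tol: float = 1e-6,
) -> TaskSummary:
    """Collapse a 557-class distribution into the six aggregate tasks.

    Tasks: 1 bp insertion frequency, 1 bp deletion frequency, overall
    deletion frequency, 1 bp (frame class 1) and 2 bp (frame class 2)
    frameshift frequency, and their sum.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (len(space),):
        raise LabelError(f"distribution must have length {len(space)}")
    if np.any(p < -tol) or abs(p.sum() - 1.0) > tol:
        raise LabelError("input is not a probability distribution over the taxonomy")
    dele = space.deletion_mask
    ins1 = space.ins1_mask
    lengths = space.lengths
    frames = lengths % 3
    include = np.ones(len(space), dtype=bool)
    if not ins3_as_inframe:
        include &= ~space.ins3_mask
    fs1 = float(p[include & (frames == 1)].sum())
    fs2 = float(p[include & (frames == 2)].sum())
    return TaskSummary(
        ins1=float(p[ins1].sum()),
        del1=float(p[dele & (lengths == 1)].sum()),
        deletion=float(p[dele].sum()),
        frameshift1=fs1,
        frameshift2=fs2,
        frameshift_overall=fs1 + fs2,
    )
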