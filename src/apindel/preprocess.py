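"""Canonical model-input construction.

Model inputs are 60 bp target windows with the PAM's first base at 0-based
index 33, so the Cas9 blunt cut (3 nt upstream of the PAM) falls between
indices 29 and 30 — i.e. at the center of the window.  Reverse-strand
targets and their outcome tables are mapped onto the forward strand before
windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .labels import Kind, LabelError, RepairLabel

__all__ = [
    "PAM_INDEX",
    "CUT_INDEX",
    "WINDOW_LEN",
    "TargetRecord",
    "ValidationReport",
    "window_target",
    "orient_label",
    "orient_record",
    "reverse_complement",
    "validate_dataset",
]

WINDOW_LEN = 60
PAM_INDEX = 33  # 0-based index of the PAM's first base in the 60 bp window
CUT_INDEX = 30  # cut lies between indices CUT_INDEX-1 and CUT_INDEX

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Pad literals for too-short inputs: filler appended after forward
#: sequences and prepended before reverse sequences.  Implemented as cyclic
#: filler truncated to the needed length (right pads take the first n
#: characters of the cycle, left pads the last n), which keeps padding
#: deterministic for any deficit.
PAD_FORWARD = "ATGC"
PAD_REVERSE = "ATG"


def reverse_complement(seq: str) -> str:
    s = seq.upper()
    _check_alphabet(s)
    return s.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise LabelError(f"sequence contains non-ACGT characters: {sorted(bad)}")


@dataclass
class TargetRecord:
    """A 60 bp cut-centered target, optionally with its outcome distribution."""

    id: str
    sequence: str
    distribution: np.ndarray | None = None
    strand_of_origin: str = "forward"
    ground_truth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def has_canonical_pam(self) -> bool:
        return self.sequence[PAM_INDEX + 1 : PAM_INDEX + 3] == "GG"


def _cyclic_pad(literal: str, n: int, side: str) -> str:
    if n <= 0:
        return ""
    reps = literal * (n // len(literal) + 2)
    return reps[:n] if side == "right" else reps[-n:]


def window_target(seq: str, pam_index: int, pad: bool = True) -> str:
    """Cut a 60 nt window placing the PAM first base at index 33.

    ``pam_index`` is the 0-based index of the PAM's first base in ``seq``.
    Short sequences are padded ("ATG"-cycle before, "ATGC"-cycle after)
    when ``pad`` is true, else an error is raised.
    """
    s = seq.strip().upper()
    _check_alphabet(s)
    lo = pam_index - PAM_INDEX
    hi = lo + WINDOW_LEN
    left_deficit = max(0, -lo)
    right_deficit = max(0, hi - len(s))
    if (left_deficit or right_deficit) and not pad:
        raise LabelError(
            f"pam_index {pam_index} leaves a {left_deficit}+{right_deficit} nt "
            f"deficit in a {len(s)} nt sequence and padding is disabled"
        )
    core = s[max(lo, 0) : min(hi, len(s))]
    left = _cyclic_pad(PAD_REVERSE, left_deficit, "left")
    right = _cyclic_pad(PAD_FORWARD, right_deficit, "right")
    out = left + core + right
    assert len(out) == WINDOW_LEN
    return out


def orient_label(label: RepairLabel) -> RepairLabel:
    """Map a cut-relative label onto the opposite strand.

    With the cut between positions -1 and 0, strand reversal reflects
    position p to -1 - p, so a deletion [s, s+L) maps to start
    -(s + L) with unchanged length; inserted sequences are
    reverse-complemented.  The map is an involution.
    """
    if label.kind is Kind.DELETION:
        return replace(label, start=-(label.start + label.length))
    if label.kind in (Kind.INS1, Kind.INS2):
        return replace(label, inserted=reverse_complement(label.inserted))
    return label


def orient_record(
    seq: str,
    outcomes: Iterable[tuple[RepairLabel, float]] | None,
    strand: str,
) -> tuple[str, list[tuple[RepairLabel, float]] | None]:
    """Express a target and its outcomes on the forward strand.

    Forward records pass through unchanged; reverse records are
    reverse-complemented and each outcome label is reflected through the
    cut (frequencies unchanged).
    """
    if strand not in ("forward", "reverse"):
        raise LabelError(f"strand must be 'forward' or 'reverse', got {strand!r}")
    s = seq.upper()
    _check_alphabet(s)
    if strand == "forward":
        return s, list(outcomes) if outcomes is not None else None
    flipped = None
    if outcomes is not None:
        flipped = [(orient_label(lab), f) for lab, f in outcomes]
    return reverse_complement(s), flipped


@dataclass
class ValidationReport:
    n_records: int = 0
    length_violations: list[str] = field(default_factory=list)
    alphabet_violations: list[str] = field(default_factory=list)
    normalization_violations: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    missing_pam: list[str] = field(default_factory=list)

    def is_clean(self) -> bool:
        return not (
            self.length_violations
            or self.alphabet_violations
            or self.normalization_violations
            or self.duplicate_ids
        )


def validate_dataset(
    records: Sequence[TargetRecord], tol: float = 1e-9
) -> ValidationReport:
    """Report (never remove) structural problems in a target dataset.

    A missing canonical NGG PAM is reported separately and does not make
    the dataset unclean — synthetic and edge inputs may lack it.
    """
    report = ValidationReport(n_records=len(records))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            report.duplicate_ids.append(rec.id)
        seen.add(rec.id)
        if len(rec.sequence) != WINDOW_LEN:
            report.length_violations.append(rec.id)
        if set(rec.sequence) - set("ACGT"):
            report.alphabet_violations.append(rec.id)
        elif len(rec.sequence) == WINDOW_LEN and not rec.has_canonical_pam():
            report.missing_pam.append(rec.id)
        if rec.distribution is not None:
            p = np.asarray(rec.distribution, dtype=float)
            if np.any(p < -tol) or abs(p.sum() - 1.0) > 1e-6:
                report.normalization_violations.append(rec.id)
    return report
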