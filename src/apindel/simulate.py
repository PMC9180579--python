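"""Seeded synthetic targets with sequence-dependent outcome distributions.

The generator emulates the data regime of large-scale Cas9 repair screens
(thousands of 60 bp cut-centered NGG targets, per-target outcome
frequencies from a few hundred UMI-deduplicated reads each) with a
mechanistic, deliberately simple ground truth:

* deletion classes get weight ``background_del * exp(-L/tau) *
  mh_bonus**m`` where m is the length of the exact microhomology flanking
  that deletion — mimicking length-penalised end joining plus
  microhomology-mediated deletions;
* 1 bp insertions preferentially duplicate the base immediately 5' of the
  cut, as observed in real repair data;
* dinucleotide and >=3 bp insertions carry small fixed weights.

All sequence dependence is confined to bases within ``locality`` (10) bp
of the cut, so attention-localization is a falsifiable property of models
trained on this data.  The generator is not a biological-fidelity
simulator: no cell-line effects, no large structural variants, and the
weight scales are chosen for a realistic deletion/insertion balance, not
fitted to any screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import Kind, LabelSpace, enumerate_label_space
from .preprocess import CUT_INDEX, PAM_INDEX, TargetRecord, WINDOW_LEN

__all__ = ["SimConfig", "sample_target", "ground_truth_distribution", "generate_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generator parameters; defaults define the study conditions.

    ``noise_counts`` is the multinomial sampling depth used to perturb the
    stored distribution (0 = store the exact ground truth).
    """

    n_targets: int = 2000
    seed: int = 0
    mh_decay: float = 6.0        # tau in the deletion length weight e^{-L/tau}
    mh_bonus: float = 4.0        # multiplier per bp of flanking microhomology
    ins1_match_weight: float = 3.0  # weight of duplicating the -1 base
    ins1_other_weight: float = 1.0
    background_del: float = 0.25
    ins2_weight: float = 0.02
    ins3_weight: float = 0.1
    noise_counts: int = 500
    locality: int = 10

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        for name in ("mh_bonus", "ins1_match_weight", "ins1_other_weight",
                     "background_del", "ins2_weight", "ins3_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def sample_target(rng: np.random.Generator) -> str:
    """Uniform random 60 nt sequence with GG forced at indices 34-35,
    i.e. a canonical NGG PAM at 33-35 and the cut between 29 and 30."""
    seq = rng.choice(_BASES, size=WINDOW_LEN)
    seq[PAM_INDEX + 1] = "G"
    seq[PAM_INDEX + 2] = "G"
    return "".join(seq)


def _microhomology(seq: str, start: int, length: int, locality: int) -> int:
    """Length of the exact microhomology templating deletion [start, start+L).

    Counts matching bases between the deleted prefix and the sequence
    immediately 3' of the deletion, using only bases within ``locality``
    of the cut so the ground truth stays local by construction.
    """
    lo, hi = -locality, locality - 1  # admissible cut-relative positions
    m = 0
    while m < length:
        p_del = start + m          # base inside the deleted segment
        p_flank = start + length + m  # base just past the segment
        if not (lo <= p_del <= hi and lo <= p_flank <= hi):
            break
        if seq[CUT_INDEX + p_del] != seq[CUT_INDEX + p_flank]:
            break
        m += 1
    return m


def ground_truth_distribution(
    seq: str, cfg: SimConfig, space: LabelSpace | None = None
) -> np.ndarray:
    """Deterministic sequence -> 557-class outcome distribution."""
    if len(seq) != WINDOW_LEN:
        raise ValueError(f"expected a {WINDOW_LEN} nt sequence, got {len(seq)}")
    if space is None:
        space = enumerate_label_space()
    w = np.empty(len(space))
    minus_one = seq[CUT_INDEX - 1]  # base immediately 5' of the cut
    for idx, lab in enumerate(space.labels):
        if lab.kind is Kind.DELETION:
            m = _microhomology(seq, lab.start, lab.length, cfg.locality)
            w[idx] = (
                cfg.background_del
                * np.exp(-lab.length / cfg.mh_decay)
                * cfg.mh_bonus**m
            )
        elif lab.kind is Kind.INS1:
            w[idx] = (
                cfg.ins1_match_weight
                if lab.inserted == minus_one
                else cfg.ins1_other_weight
            )
        elif lab.kind is Kind.INS2:
            w[idx] = cfg.ins2_weight
        else:
            w[idx] = cfg.ins3_weight
    total = w.sum()
    if total <= 0:
        raise ValueError("all outcome weights are zero; check the configuration")
    return w / total


def generate_dataset(
    cfg: SimConfig, space: LabelSpace | None = None
) -> list[TargetRecord]:
    """Generate ``cfg.n_targets`` records with observed + true distributions.

    The stored ``distribution`` is a multinomial resample of the ground
    truth at depth ``noise_counts`` (renormalized); the exact ground truth
    is kept on ``record.ground_truth`` for oracle-based evaluation.
    """
    if space is None:
        space = enumerate_label_space()
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.n_targets):
        seq = sample_target(rng)
        p = ground_truth_distribution(seq, cfg, space)
        if cfg.noise_counts > 0:
            counts = rng.multinomial(cfg.noise_counts, p)
            observed = counts / counts.sum()
        else:
            observed = p.copy()
        records.append(
            TargetRecord(
                id=f"sim_{i:05d}",
                sequence=seq,
                distribution=observed,
                ground_truth=p,
            )
        )
    return records
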