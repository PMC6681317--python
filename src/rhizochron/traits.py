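"""Conventional root-architecture traits and the elongation filter.

Positions along the primary root are measured from the root--shoot junction,
increasing rootward.  The branching zone (BZ) spans the first to the last
elongated lateral root; pre-BZ is shootward of it and post-BZ runs from the
last lateral root to the PR apex, so PRL = preBZ + BZ + postBZ exactly.
"""

from __future__ import annotations

import itertools

from .core import RootSystem, TraitRecord


def apply_elongation_filter(root: RootSystem, min_lr_length: float = 0.0) -> RootSystem:
    """Drop lateral roots shorter than ``min_lr_length`` mm.

    Removing an LR merges its flanking PR segments (their lengths are summed);
    when the last LR is removed the trailing merge is absorbed into the tip.
    Total PR length is conserved.  A threshold of 0 keeps every traced LR,
    which treats the tracer's visibility judgement as the elongation call.

    Returns a new :class:`RootSystem`; metadata is preserved.  Removing every
    LR yields a valid unbranched root.
    """
    if min_lr_length < 0:
        raise ValueError("min_lr_length must be non-negative")
    if min_lr_length == 0 or not root.lr_lengths:
        return root

    segments: list[float] = []
    lrs: list[float] = []
    carry = 0.0  # PR length accumulated from removed branch points
    for seg, lr in zip(root.pr_segments, root.lr_lengths):
        carry += seg
        if lr >= min_lr_length:
            segments.append(carry)
            lrs.append(lr)
            carry = 0.0
    return RootSystem(
        plant_id=root.plant_id,
        accession=root.accession,
        day=root.day,
        treatment=root.treatment,
        pr_segments=tuple(segments),
        pr_tip=root.pr_tip + carry,
        lr_lengths=tuple(lrs),
    )


def lr_positions(root: RootSystem) -> list[float]:
    """Shoot-to-branch-point distance of each LR along the PR, in mm.

    Position ``k`` is the cumulative sum of the first ``k`` PR segments; the
    list is non-decreasing (two LRs at the same branch point are allowed and
    share a position).
    """
    return list(itertools.accumulate(root.pr_segments))


def compute_traits(root: RootSystem) -> TraitRecord:
    """Compute the conventional trait panel for one plant.

    Ratios TLr and PLr are 0 for a plant without lateral roots; root density
    RD is undefined (``None``) only for the degenerate zero-length trace.
    An unbranched plant has preBZ = BZ = 0 and the whole PR in postBZ, which
    keeps the branching-zone partition additive in the limit.
    """
    prl = root.pr_length
    tlrl = sum(root.lr_lengths)
    n_lr = root.n_lr
    if prl == 0 and n_lr > 0:
        raise ValueError(
            f"plant {root.plant_id!r}: zero primary root length with lateral roots "
            "present is a degenerate trace"
        )
    trl = prl + tlrl
    positions = lr_positions(root)
    if n_lr == 0:
        pre_bz, bz, post_bz = 0.0, 0.0, prl
    else:
        pre_bz = root.pr_segments[0]
        bz = positions[-1] - positions[0]
        post_bz = root.pr_tip
    return TraitRecord(
        plant_id=root.plant_id,
        accession=root.accession,
        day=root.day,
        treatment=root.treatment,
        TRL=trl,
        PRL=prl,
        TLRL=tlrl,
        RD=(n_lr / prl) if prl > 0 else None,
        TLr=(tlrl / trl) if tlrl > 0 else 0.0,
        PLr=(tlrl / prl) if tlrl > 0 else 0.0,
        BZ=bz,
        preBZ=pre_bz,
        postBZ=post_bz,
        n_lr=n_lr,
    )


__all__ = ["apply_elongation_filter", "lr_positions", "compute_traits"]
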