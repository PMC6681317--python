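"""The rhizochron index: a per-plant linear model of LR length vs. position.

Longer lateral roots sit shootward because they are older; rootward laterals
are younger and shorter.  Regressing LR length y on LR position x along the
primary root summarises this allometry in a single slope m — the rhizochron
index — typically negative.  A plant needs at least two elongated lateral
roots for the fit; anything else is discarded with an explicit reason rather
than raising, mirroring how such individuals are excluded from cohorts.
"""

from __future__ import annotations

import numpy as np

from .core import DiscardLog, RhizochronFit, RootSystem, TraitRecord
from .traits import apply_elongation_filter, compute_traits, lr_positions


def fit_rhizochron(root: RootSystem, min_lr_length: float = 0.0) -> RhizochronFit:
    """Ordinary least squares of LR length on LR position for one plant.

    The elongation filter is applied first; the surviving laterals provide
    the points (x_i, y_i) with x_i the shoot-to-branch-point distance and
    y_i the LR length, both in mm.  Duplicate positions (two LRs at one
    branch point) are kept as distinct observations.

    Returns a :class:`RhizochronFit`.  ``r2`` is ``None`` when the response
    is constant; with exactly two distinct positions the line interpolates
    and ``r2`` is exactly 1.
    """
    filtered = apply_elongation_filter(root, min_lr_length)
    x = np.asarray(lr_positions(filtered), dtype=float)
    y = np.asarray(filtered.lr_lengths, dtype=float)
    n = x.size
    if n < 2:
        return RhizochronFit(None, None, n, None, True, RhizochronFit.REASON_TOO_FEW)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return RhizochronFit(None, None, n, None, True, RhizochronFit.REASON_DEGENERATE)
    m = float(xc @ y) / sxx
    b = float(y.mean() - m * x.mean())
    resid = y - (m * x + b)
    ss_res = float(resid @ resid)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0.0:
        r2: float | None = None
    else:
        r2 = min(1.0, max(0.0, 1.0 - ss_res / ss_tot))
    if n == 2:
        r2 = 1.0  # two distinct x: exact interpolation
    return RhizochronFit(m, b, n, r2)


def batch_fit(
    roots: list[RootSystem], min_lr_length: float = 0.0
) -> tuple[list[TraitRecord], DiscardLog]:
    """Fit a cohort, merging trait panel and rhizochron fit per plant.

    Every input plant yields exactly one :class:`TraitRecord`; plants whose
    fit is discarded keep their trait values but have empty ``m``/``b``/``r2``
    and are additionally listed in the returned :class:`DiscardLog`, so
    ``fitted + discarded == len(roots)`` always holds.

    All traits are computed on the filtered root, so the same set of
    elongated laterals underlies both the panel and the fit.

    Raises
    ------
    ValueError
        If two plants share (plant_id, day, treatment).
    """
    if not roots:
        return [], DiscardLog()
    seen: dict[tuple[str, int, str], int] = {}
    dupes = []
    for r in roots:
        key = (r.plant_id, r.day, r.treatment)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] == 2:
            dupes.append(key)
    if dupes:
        raise ValueError(f"duplicate plant identities in cohort: {sorted(dupes)}")

    records: list[TraitRecord] = []
    log = DiscardLog()
    for root in roots:
        filtered = apply_elongation_filter(root, min_lr_length)
        rec = compute_traits(filtered)
        fit = fit_rhizochron(root, min_lr_length)
        rec.m, rec.b, rec.r2 = fit.m, fit.b, fit.r2
        rec.discarded = fit.discarded
        rec.discard_reason = fit.discard_reason
        if fit.discarded:
            log.add(root, fit.discard_reason)
        records.append(rec)
    return records, log


__all__ = ["fit_rhizochron", "batch_fit"]
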