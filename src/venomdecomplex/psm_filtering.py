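"""PSM validation filters and target-decoy FDR control.

Identifications pass a fixed score cascade (protein score > 20, peptide score
> 10, SPI > 70%, all strict) and are then thresholded on peptide score so the
estimated false discovery rate among retained PSMs stays below 1%.  The FDR
estimate is the field-default decoy/target ratio

    fdr(c) = #decoys(score >= c) / max(1, #targets(score >= c))

smoothed into a q-value-style monotone non-increasing curve (running minimum
over all cutoffs at or below each cutoff), which guarantees a well-defined
lowest admissible cutoff.  Decoys are removed from the output; ties at the
chosen cutoff are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import FilterThresholds, PsmRecord
from .errors import FdrUnattainable


def apply_score_filters(
    psms: list[PsmRecord], thresholds: FilterThresholds | None = None
) -> list[PsmRecord]:
    """Retain PSMs passing all three strict score filters (set semantics).

    Decoy PSMs are subjected to the same cascade so the subsequent FDR
    estimate reflects the post-cascade score distribution.
    """
    th = thresholds or FilterThresholds()
    return [
        p
        for p in psms
        if p.protein_score > th.min_protein_score
        and p.peptide_score > th.min_peptide_score
        and p.spi > th.min_spi
    ]


@dataclass(frozen=True)
class FdrCurve:
    """FDR as a function of candidate peptide-score cutoff.

    ``raw`` is the decoy/target ratio at each cutoff, ``smoothed`` its
    monotone non-increasing envelope.  ``no_decoys`` flags the degenerate
    all-target case (fdr reported as 0); ``no_targets`` flags the pure-decoy
    case.
    """

    cutoffs: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    no_decoys: bool = False
    no_targets: bool = False

    def __iter__(self):
        return iter(zip(self.cutoffs, self.smoothed))


def estimate_fdr_curve(psms: list[PsmRecord]) -> FdrCurve:
    """Decoy/target FDR at every candidate cutoff (sorted unique peptide scores)."""
    scores = np.array([p.peptide_score for p in psms], dtype=float)
    decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    cutoffs = np.unique(scores)
    n_dec = int(decoy.sum())
    n_tgt = int((~decoy).sum())
    if n_dec == 0:
        warnings.warn("no decoy PSMs present; FDR reported as 0 at every cutoff")
    if n_tgt == 0:
        warnings.warn("no target PSMs present; FDR curve is decoy counts only")
    raw = np.empty_like(cutoffs)
    for i, c in enumerate(cutoffs):
        sel = scores >= c
        d = int(np.count_nonzero(decoy & sel))
        t = int(np.count_nonzero(~decoy & sel))
        raw[i] = d / max(1, t)
    smoothed = np.minimum.accumulate(raw)  # running min over cutoffs <= c
    return FdrCurve(cutoffs, raw, smoothed, no_decoys=n_dec == 0, no_targets=n_tgt == 0)


@dataclass(frozen=True)
class FdrResult:
    psms: list[PsmRecord]
    cutoff: float
    achieved_fdr: float
    no_decoys: bool = False

    def __iter__(self):  # allow tuple-unpacking (psms, cutoff)
        return iter((self.psms, self.cutoff))


def filter_at_fdr(psms: list[PsmRecord], max_fdr: float = 0.01) -> FdrResult:
    """Threshold on peptide score at the lowest cutoff with smoothed FDR < ``max_fdr``.

    Returns the retained target PSMs (decoys removed), the chosen cutoff and
    the achieved (smoothed) FDR estimate.  With no decoys present every
    target passes at the minimum score, flagged on the result.  Raises
    :class:`FdrUnattainable` when no cutoff reaches the requested level.
    """
    if not psms:
        raise FdrUnattainable("empty PSM list")
    curve = estimate_fdr_curve(psms)
    if curve.no_targets:
        raise FdrUnattainable("no target PSMs; requested FDR cannot be attained")
    ok = np.flatnonzero(curve.smoothed < max_fdr)
    if ok.size == 0:
        raise FdrUnattainable(
            f"no peptide-score cutoff achieves FDR < {max_fdr} "
            f"(best {curve.smoothed.min():.4f})"
        )
    cutoff = float(curve.cutoffs[ok[0]])
    achieved = float(curve.smoothed[ok[0]])
    kept = [p for p in psms if not p.is_decoy and p.peptide_score >= cutoff]
    return FdrResult(kept, cutoff, achieved, no_decoys=curve.no_decoys)


def filter_report(
    psms: list[PsmRecord], thresholds: FilterThresholds | None = None
) -> tuple[list[PsmRecord], dict]:
    """Full cascade + FDR control, with per-rule attrition counts for the run log."""
    th = thresholds or FilterThresholds()
    n_in = len(psms)
    after_protein = [p for p in psms if p.protein_score > th.min_protein_score]
    after_peptide = [p for p in after_protein if p.peptide_score > th.min_peptide_score]
    after_spi = [p for p in after_peptide if p.spi > th.min_spi]
    result = filter_at_fdr(after_spi, th.max_fdr)
    report = {
        "n_input": n_in,
        "n_after_protein_score": len(after_protein),
        "n_after_peptide_score": len(after_peptide),
        "n_after_spi": len(after_spi),
        "n_retained": len(result.psms),
        "peptide_score_cutoff": result.cutoff,
        "achieved_fdr": result.achieved_fdr,
        "no_decoys": result.no_decoys,
        "thresholds": {
            "min_protein_score": th.min_protein_score,
            "min_peptide_score": th.min_peptide_score,
            "min_spi": th.min_spi,
            "max_fdr": th.max_fdr,
        },
    }
    return result.psms, report
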