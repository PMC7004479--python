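"""Antivenom immunoprofiling from indirect-ELISA plate readings.

Wells are read at 492 nm against plate blanks; each (antigen fraction,
antivenom) cell is summarised as the mean of its (typically triplicate)
blank-corrected replicates with the standard error of the mean.  Reactivity
is classified against the two empirically observed absorbance regimes — below
0.1 (no meaningful immunorecognition) and 0.2–1.5 (clear binding) — with the
gap in between reported as indeterminate rather than forced to a side.
Cross-antivenom comparison expresses the comparator's corrected absorbance as
a percentage of the reference antivenom's, per fraction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import ElisaPlate
from .errors import AlignmentError, ContractViolation, NoBlank

#: Corrected-absorbance bands for qualitative classification.
LOW_THRESHOLD = 0.1
REACTIVE_THRESHOLD = 0.2

#: Reference means below this are too close to instrument noise for ratios.
REFERENCE_FLOOR = 0.02


def summarize_plate(plate: ElisaPlate) -> pd.DataFrame:
    """Blank-corrected mean, SEM and n per (fraction, antivenom) cell.

    The plate-wide blank mean is subtracted from every replicate and negative
    corrected values are clipped to 0 before averaging.  SEM is sd/sqrt(n)
    (ddof=1); a single-replicate cell gets SEM = NaN with a warning.  Control
    wells are summarised like sample wells and flagged in ``is_control``.
    """
    wells = plate.wells
    blanks = wells.loc[wells["is_blank"], "a492"]
    if blanks.empty:
        raise NoBlank("plate has no blank well")
    blank_mean = float(blanks.mean())
    sample = wells.loc[~wells["is_blank"]].copy()
    sample["corrected"] = np.clip(sample["a492"] - blank_mean, 0.0, None)
    rows = []
    for (fid, av), cell in sample.groupby(["fraction_id", "antivenom"], sort=True):
        n = len(cell)
        mean = float(cell["corrected"].mean())
        if n >= 2:
            sem = float(cell["corrected"].std(ddof=1) / np.sqrt(n))
        else:
            warnings.warn(f"cell ({fid}, {av}) has a single replicate; SEM undefined")
            sem = float("nan")
        rows.append(
            {
                "fraction_id": fid,
                "antivenom": av,
                "mean_a492": mean,
                "sem": sem,
                "n": n,
                "is_control": bool(cell["is_control"].any()),
            }
        )
    return pd.DataFrame(rows)


def classify_reactivity(mean_a492: float) -> str:
    """Classify a blank-corrected cell mean as low / indeterminate / reactive."""
    if mean_a492 < 0:
        raise ContractViolation(f"corrected absorbance must be >= 0, got {mean_a492}")
    if mean_a492 < LOW_THRESHOLD:
        return "low"
    if mean_a492 >= REACTIVE_THRESHOLD:
        return "reactive"
    return "indeterminate"


def relative_immunoreactivity(
    profile_ref: pd.DataFrame,
    profile_cmp: pd.DataFrame,
    floor: float = REFERENCE_FLOOR,
) -> pd.DataFrame:
    """Comparator absorbance as percent of the reference antivenom, per fraction.

    Both inputs are single-antivenom summaries from :func:`summarize_plate`
    (control rows excluded by the caller or shared between both).  Fractions
    whose reference mean falls below ``floor`` get ``relative_pct = NaN`` and
    ``undefined = True`` instead of a noise-blown ratio.
    """
    ref = profile_ref.set_index("fraction_id")
    cmp_ = profile_cmp.set_index("fraction_id")
    if set(ref.index) != set(cmp_.index):
        raise AlignmentError(
            f"fraction sets differ: {sorted(set(ref.index) ^ set(cmp_.index))}"
        )
    cmp_ = cmp_.loc[ref.index]
    undefined = ref["mean_a492"] < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * cmp_["mean_a492"].to_numpy() / ref["mean_a492"].to_numpy()
    pct = np.where(undefined.to_numpy(), np.nan, pct)
    return pd.DataFrame(
        {
            "fraction_id": ref.index,
            "reference_mean": ref["mean_a492"].to_numpy(),
            "comparator_mean": cmp_["mean_a492"].to_numpy(),
            "relative_pct": pct,
            "undefined": undefined.to_numpy(),
        }
    ).reset_index(drop=True)


def control_check(summary: pd.DataFrame, expectations: dict) -> dict:
    """Verify control wells classify as expected; report-only, never raises.

    ``expectations`` maps a control key to ``"negative"`` (must classify low)
    or ``"positive"`` (must classify reactive).  Keys are either
    ``(fraction_id, antivenom)`` pairs or bare fraction labels; the same
    control antigen can legitimately be a negative control for one antivenom
    and a positive control for another, so the pair form takes precedence.
    Controls in the summary but not in ``expectations`` are ignored.
    """
    results = []
    for _, row in summary.loc[summary["is_control"]].iterrows():
        expect = expectations.get(
            (row["fraction_id"], row["antivenom"]), expectations.get(row["fraction_id"])
        )
        if expect is None:
            continue
        cls = classify_reactivity(row["mean_a492"])
        ok = (expect == "negative" and cls == "low") or (
            expect == "positive" and cls == "reactive"
        )
        results.append(
            {
                "fraction_id": row["fraction_id"],
                "antivenom": row["antivenom"],
                "expected": expect,
                "classified": cls,
                "mean_a492": float(row["mean_a492"]),
                "pass": bool(ok),
            }
        )
    return {"controls": results, "all_pass": all(r["pass"] for r in results)}


def immunoprofile_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Attach the qualitative class to each summarised cell."""
    out = summary.copy()
    out["reactivity"] = [classify_reactivity(m) for m in out["mean_a492"]]
    return out
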