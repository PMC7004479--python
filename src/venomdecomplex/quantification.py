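"""Label-free abundance estimation and comparative venomics.

The abundance model is hierarchical, reflecting the experimental design in
which an equal protein mass (10 µg) of every collected fraction is digested
and analysed regardless of how much of the venom that fraction represents:

* within a fraction, a protein's mean spectral intensity (MSI — the mean of
  its peptide spectral intensities) relative to the fraction's total MSI
  gives the within-fraction proportion ``p_ij``;
* the whole-venom abundance of protein j in fraction i is then
  ``a_ij = 100 * f_i * p_ij`` percent of total venom protein, where ``f_i``
  is the fraction's chromatographic share;
* collected fractions in which no protein was identified contribute their
  whole share to an explicit *unidentified* bucket, so per-venom abundances
  plus the bucket always sum to 100.

A flat normalisation (MSI relative to the total MSI across all fractions,
ignoring chromatographic shares) is available via ``mode="global"`` for
comparison; it cannot populate the unidentified bucket.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceTable,
    FamilyMap,
    FractionShareTable,
    PsmRecord,
)
from .errors import EmptyFraction, MissingShare, UnassignedFraction


def within_fraction_abundance(
    psms: list[PsmRecord], merge_duplicates: bool = True
) -> pd.DataFrame:
    """Within-fraction MSI proportions ``p_ij`` from filtered target PSMs.

    Returns a DataFrame with columns (fraction_id, accession, protein_name,
    species, n_peptides, msi, p).  With ``merge_duplicates`` (default) all
    rows of one accession within a fraction pool their peptides before the
    MSI is taken; otherwise proteins are kept at (accession, protein_name)
    granularity.
    """
    target = [p for p in psms if not p.is_decoy]
    if not target:
        raise EmptyFraction("no target PSMs to quantify")
    df = pd.DataFrame(
        {
            "fraction_id": [p.fraction_id for p in target],
            "accession": [p.accession for p in target],
            "protein_name": [p.protein_name for p in target],
            "species": [p.species for p in target],
            "intensity": [p.intensity for p in target],
        }
    )
    if merge_duplicates:
        keys = ["fraction_id", "accession"]
        grouped = (
            df.groupby(keys, sort=True)
            .agg(
                protein_name=("protein_name", "first"),
                species=("species", "first"),
                n_peptides=("intensity", "size"),
                msi=("intensity", "mean"),
            )
            .reset_index()
        )
    else:
        keys = ["fraction_id", "accession", "protein_name"]
        grouped = (
            df.groupby(keys, sort=True)
            .agg(
                species=("species", "first"),
                n_peptides=("intensity", "size"),
                msi=("intensity", "mean"),
            )
            .reset_index()
        )
    totals = grouped.groupby("fraction_id")["msi"].transform("sum")
    zero = grouped.loc[totals <= 0, "fraction_id"].unique()
    if len(zero):
        raise EmptyFraction(f"fraction(s) {sorted(zero)} have zero total MSI")
    grouped["p"] = grouped["msi"] / totals
    return grouped


def whole_venom_abundance(
    shares: FractionShareTable,
    wft: pd.DataFrame,
    unidentified: Iterable[str] = (),
    venom_id: str = "venom",
    mode: str = "hierarchical",
) -> AbundanceTable:
    """Whole-venom per-protein abundances (% of total venom protein).

    ``unidentified`` names collected fractions that carry a chromatographic
    share but yielded no identification; their shares populate the
    unidentified bucket.  Every fraction present in ``wft`` must have a share
    (else :class:`MissingShare`); every fraction with a share must either
    appear in ``wft`` or be declared unidentified (else
    :class:`UnassignedFraction`), so that conservation to 100% is meaningful.
    """
    unidentified = set(map(str, unidentified))
    wft_fracs = set(wft["fraction_id"].unique())
    missing = wft_fracs - set(shares)
    if missing:
        raise MissingShare(f"fraction(s) {sorted(missing)} have PSMs but no share")
    overlap = wft_fracs & unidentified
    if overlap:
        raise UnassignedFraction(
            f"fraction(s) {sorted(overlap)} declared unidentified but have PSMs"
        )
    stray = set(shares) - wft_fracs - unidentified
    if stray:
        raise UnassignedFraction(
            f"fraction(s) {sorted(stray)} have shares but neither PSMs nor an "
            "'unidentified' declaration"
        )

    out = wft.copy()
    if mode == "hierarchical":
        out["abundance_pct"] = [
            100.0 * shares[fid] * p for fid, p in zip(out["fraction_id"], out["p"])
        ]
        unidentified_pct = 100.0 * sum(shares[fid] for fid in unidentified)
    elif mode == "global":
        total_msi = float(out["msi"].sum())
        out["abundance_pct"] = 100.0 * out["msi"] / total_msi
        unidentified_pct = 0.0
        if unidentified:
            warnings.warn(
                "global-MSI mode cannot apportion unidentified fractions; "
                "their shares are ignored"
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    proteins = out.assign(family="OTHER").loc[
        :, ["accession", "protein_name", "family", "fraction_id", "abundance_pct"]
    ]
    table = AbundanceTable(
        venom_id=venom_id,
        proteins=proteins.reset_index(drop=True),
        unidentified_pct=unidentified_pct,
        meta={
            "mode": mode,
            "unidentified_fractions": sorted(unidentified),
            "unidentified_by_fraction": {
                fid: 100.0 * shares[fid] for fid in sorted(unidentified)
            },
        },
    )
    return table


def assign_families(table: AbundanceTable, fmap: FamilyMap) -> AbundanceTable:
    """Return a copy of ``table`` with the family column filled from ``fmap``."""
    proteins = table.proteins.copy()
    proteins["family"] = [fmap.family_of(a) for a in proteins["accession"]]
    return AbundanceTable(table.venom_id, proteins, table.unidentified_pct, dict(table.meta))


def aggregate_families(table: AbundanceTable, fmap: FamilyMap | None = None) -> pd.DataFrame:
    """Per-family whole-venom abundances, sorted descending (ties by family name).

    Family totals are exact sums of member rows; each accession belongs to
    exactly one family, so no abundance is double-counted.
    """
    proteins = table.proteins
    if fmap is not None:
        families = [fmap.family_of(a) for a in proteins["accession"]]
    else:
        families = proteins["family"]
    agg = (
        pd.DataFrame({"family": families, "abundance_pct": proteins["abundance_pct"]})
        .groupby("family", sort=True)["abundance_pct"]
        .sum()
        .reset_index()
        .sort_values(["abundance_pct", "family"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return agg


def count_nonredundant(table: AbundanceTable, fmap: FamilyMap | None = None) -> dict:
    """Non-redundant protein and family counts for one venom.

    A protein counts once per distinct accession with abundance > 0 (the same
    accession identified in several fractions is one protein); a family
    counts when its total abundance is > 0.  ``per_family`` gives the
    distinct-accession count within each detected family.
    """
    proteins = table.proteins
    if fmap is not None:
        fam = pd.Series([fmap.family_of(a) for a in proteins["accession"]],
                        index=proteins.index)
    else:
        fam = proteins["family"]
    detected = proteins.loc[proteins["abundance_pct"] > 0]
    fam = fam.loc[detected.index]
    per_family = (
        detected.assign(family=fam)
        .groupby("family")["accession"]
        .nunique()
        .to_dict()
    )
    return {
        "proteins": int(detected["accession"].nunique()),
        "families": len(per_family),
        "per_family": per_family,
    }


def compare_venoms(
    a: AbundanceTable, b: AbundanceTable, fmap: FamilyMap
) -> pd.DataFrame:
    """Per-family comparison of two venoms sharing one family map.

    Returns columns (family, abundance_a_pct, abundance_b_pct, delta, status)
    with status ``shared`` / ``unique_to_a`` / ``unique_to_b``; a family is
    unique to one venom exactly when the other venom's total is 0.  Sorted by
    descending combined abundance, ties by family name.
    """
    fa = aggregate_families(a, fmap).set_index("family")["abundance_pct"]
    fb = aggregate_families(b, fmap).set_index("family")["abundance_pct"]
    families = sorted(set(fa.index) | set(fb.index))
    rows = []
    for fam in families:
        va = float(fa.get(fam, 0.0))
        vb = float(fb.get(fam, 0.0))
        if va > 0 and vb == 0:
            status = "unique_to_a"
        elif vb > 0 and va == 0:
            status = "unique_to_b"
        else:
            status = "shared"
        rows.append(
            {
                "family": fam,
                "abundance_a_pct": va,
                "abundance_b_pct": vb,
                "delta": va - vb,
                "status": status,
            }
        )
    df = pd.DataFrame(rows)
    df["_tot"] = df["abundance_a_pct"] + df["abundance_b_pct"]
    df = (
        df.sort_values(["_tot", "family"], ascending=[False, True], kind="mergesort")
        .drop(columns="_tot")
        .reset_index(drop=True)
    )
    return df


def comparison_summary(a: AbundanceTable, b: AbundanceTable, fmap: FamilyMap) -> dict:
    """Comparison table plus per-venom non-redundant counts, JSON-ready."""
    comp = compare_venoms(a, b, fmap)
    return {
        "venom_a": a.venom_id,
        "venom_b": b.venom_id,
        "families": comp.to_dict(orient="records"),
        "unique_to_a": comp.loc[comp["status"] == "unique_to_a", "family"].tolist(),
        "unique_to_b": comp.loc[comp["status"] == "unique_to_b", "family"].tolist(),
        "counts_a": count_nonredundant(a, fmap),
        "counts_b": count_nonredundant(b, fmap),
        "unidentified_a_pct": a.unidentified_pct,
        "unidentified_b_pct": b.unidentified_pct,
    }
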