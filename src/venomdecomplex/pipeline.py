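"""End-to-end orchestration: trace -> shares -> filtered PSMs -> abundances ->
comparison and immunoprofiles, with a structured run log.

Three entry modes:

* ``simulate`` — generate a full synthetic experiment from a preset and seed,
  then run the analysis on it (ground truth recorded in the log);
* ``files`` — analyse user-supplied trace/boundaries/PSM/family-map (and
  optionally ELISA) files;
* ``precomputed-abundance`` — start from per-protein abundance tables (e.g.
  the packaged reference proteomes) and run aggregation, counting and
  comparison only.

Outputs are deterministic for a fixed config and seed: no timestamps are
written, so re-runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .chromatography import correct_baseline, integrate_fractions
from .datamodel import (
    AbundanceTable,
    FamilyMap,
    FilterThresholds,
    read_abundance_table,
    read_boundaries,
    read_chromatogram,
    read_elisa_plate,
    read_family_map,
    read_psm_table,
    write_abundance_table,
    write_comparison,
)
from .errors import ConfigError
from .immunoprofile import (
    immunoprofile_table,
    relative_immunoreactivity,
    summarize_plate,
)
from .psm_filtering import filter_report
from .quantification import (
    aggregate_families,
    assign_families,
    comparison_summary,
    count_nonredundant,
    whole_venom_abundance,
    within_fraction_abundance,
)

log = logging.getLogger("venomdecomplex")


def _require(config: dict, key: str) -> object:
    if key not in config:
        raise ConfigError(f"config missing required key {key!r}")
    return config[key]


def analyze_experiment(
    chrom,
    bounds,
    psms,
    fmap: FamilyMap,
    unidentified=(),
    thresholds: FilterThresholds | None = None,
    venom_id: str = "venom",
    baseline_method: str = "linear_endpoints",
    merge_duplicates: bool = True,
    mode: str = "hierarchical",
):
    """Run the full quantification chain on in-memory inputs.

    Returns (AbundanceTable with families assigned, family aggregate
    DataFrame, filter report dict, FractionShareTable).
    """
    corrected = correct_baseline(chrom, method=baseline_method)
    shares = integrate_fractions(corrected, bounds)
    log.info("integrated %d fraction shares", len(shares))
    kept, report = filter_report(psms, thresholds)
    log.info(
        "filter cascade: %d -> %d PSMs (cutoff %.2f, FDR %.4f)",
        report["n_input"], report["n_retained"],
        report["peptide_score_cutoff"], report["achieved_fdr"],
    )
    wft = within_fraction_abundance(kept, merge_duplicates=merge_duplicates)
    # a collected fraction whose identifications are all removed by the filter
    # cascade is, operationally, an unidentified fraction: its share joins the
    # unidentified bucket rather than silently vanishing from the denominator
    unidentified = set(map(str, unidentified))
    empty = set(shares) - set(wft["fraction_id"].unique()) - unidentified
    if empty:
        log.warning(
            "fraction(s) %s lost all identifications in filtering; "
            "moved to the unidentified bucket", sorted(empty)
        )
        unidentified |= empty
    table = whole_venom_abundance(
        shares, wft, unidentified=unidentified, venom_id=venom_id, mode=mode
    )
    table = assign_families(table, fmap)
    families = aggregate_families(table)
    return table, families, report, shares


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute a configured run and write the report bundle into ``outdir``.

    Returns the run log (also written as ``run_log.json``).  The bundle
    contains, per venom: per-protein and per-family abundance TSVs; plus the
    two-venom comparison JSON, the immunoprofile TSV (when ELISA data are
    configured) and the run log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mode = str(_require(config, "mode"))
    run_log: dict = {"version": __version__, "mode": mode, "stages": []}

    if mode == "simulate":
        tables = _run_simulated(config, outdir, run_log)
    elif mode == "files":
        tables = [_run_files(config, outdir, run_log)]
    elif mode == "precomputed-abundance":
        tables = _run_precomputed(config, outdir, run_log)
    else:
        raise ConfigError(f"unknown mode {mode!r}")

    fmap = run_log.pop("_fmap")
    for table in tables:
        stem = outdir / table.venom_id.replace(" ", "_")
        write_abundance_table(table, f"{stem}.proteins.tsv", f"{stem}.families.tsv")
        run_log["stages"].append(
            {
                "stage": "quantify",
                "venom": table.venom_id,
                "n_proteins": count_nonredundant(table)["proteins"],
                "unidentified_pct": table.unidentified_pct,
            }
        )
    if len(tables) == 2:
        summary = comparison_summary(tables[0], tables[1], fmap)
        write_comparison(summary, outdir / "comparison.json")
        run_log["stages"].append(
            {
                "stage": "compare",
                "unique_to_a": summary["unique_to_a"],
                "unique_to_b": summary["unique_to_b"],
            }
        )
    if "elisa" in config or mode == "simulate":
        _run_immunoprofile(config, outdir, run_log)
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    return run_log


def _analyze_and_log(chrom, bounds, psms, fmap, unidentified, config, venom_id, run_log):
    th = FilterThresholds(**config.get("thresholds", {}))
    table, families, report, shares = analyze_experiment(
        chrom, bounds, psms, fmap,
        unidentified=unidentified,
        thresholds=th,
        venom_id=venom_id,
        baseline_method=config.get("baseline_method", "linear_endpoints"),
        mode=config.get("abundance_mode", "hierarchical"),
    )
    run_log["stages"].append({"stage": "filter", "venom": venom_id, **report})
    return table


def _run_simulated(config: dict, outdir: Path, run_log: dict) -> list[AbundanceTable]:
    from .synthetic import make_truth, simulate_chromatogram, simulate_elisa, simulate_psms

    seed = int(_require(config, "seed"))
    presets = config.get("presets", ["thai-like", "indo-like"])
    tables = []
    fmap_all: dict = {}
    run_log["seed"] = seed
    run_log["truth"] = {}
    plates = {}
    for i, preset in enumerate(presets):
        truth = make_truth(seed + i, preset=preset)
        chrom, bounds = simulate_chromatogram(truth)
        sim = simulate_psms(truth)
        fmap = truth.family_map()
        fmap_all.update(fmap)
        table = _analyze_and_log(
            chrom, bounds, sim.records, fmap, truth.unidentified_fractions,
            config, preset, run_log,
        )
        tables.append(table)
        run_log["truth"][preset] = {
            "family_pct": truth.true_family_pct,
            "unidentified_share": truth.unidentified_share,
        }
        plates[preset] = simulate_elisa(truth)
    config.setdefault("_plates", plates)
    run_log["_fmap"] = FamilyMap(fmap_all)
    return tables


def _run_files(config: dict, outdir: Path, run_log: dict) -> AbundanceTable:
    for key in ("trace", "boundaries", "psms", "family_map"):
        _require(config, key)
    chrom = read_chromatogram(_require(config, "trace"))
    bounds = read_boundaries(_require(config, "boundaries"))
    psms = read_psm_table(_require(config, "psms"))
    fmap = read_family_map(_require(config, "family_map"))
    run_log["_fmap"] = fmap
    return _analyze_and_log(
        chrom, bounds, psms, fmap,
        config.get("unidentified", []),
        config, config.get("venom_id", "venom"), run_log,
    )


def _run_precomputed(config: dict, outdir: Path, run_log: dict) -> list[AbundanceTable]:
    if config.get("reference_fixture"):
        from .synthetic import load_reference_proteomes

        a, b, fmap = load_reference_proteomes()
        run_log["_fmap"] = fmap
        return [a, b]
    fmap = read_family_map(_require(config, "family_map"))
    run_log["_fmap"] = fmap
    tables = []
    for key in ("abundance_a", "abundance_b"):
        if key in config:
            tables.append(read_abundance_table(config[key]))
    if not tables:
        raise ConfigError("precomputed-abundance mode needs abundance_a (and optionally abundance_b)")
    return tables


def _run_immunoprofile(config: dict, outdir: Path, run_log: dict) -> None:
    plates = config.get("_plates")
    if plates is None:
        plates = {"plate": read_elisa_plate(_require(config, "elisa"))}
    reference = config.get("reference_antivenom")
    for label, plate in plates.items():
        summary = summarize_plate(plate)
        profile = immunoprofile_table(summary)
        antivenoms = sorted(profile["antivenom"].unique())
        if reference and reference in antivenoms and len(antivenoms) == 2:
            other = next(av for av in antivenoms if av != reference)
            ref_prof = profile.loc[profile["antivenom"] == reference]
            cmp_prof = profile.loc[profile["antivenom"] == other]
            rel = relative_immunoreactivity(ref_prof, cmp_prof)
            rel = rel.rename(columns={"relative_pct": f"{other}_vs_{reference}_pct"})
            profile = profile.merge(
                rel[["fraction_id", f"{other}_vs_{reference}_pct"]],
                on="fraction_id", how="left",
            )
        profile.to_csv(outdir / f"immunoprofile_{label}.tsv", sep="\t", index=False)
        run_log["stages"].append(
            {
                "stage": "immunoprofile",
                "plate": label,
                "n_cells": int(len(profile)),
                "reference_antivenom": reference,
            }
        )
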