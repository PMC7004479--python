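"""Synthetic decomplexing-venomics experiments with known ground truth.

The generator emulates the structure of a Russell's viper venom study: a
venom of ~8-12 toxin families separated into 12-16 RP-HPLC fractions, equal
protein mass digested per fraction, lognormal peptide spectral intensities,
separable target/decoy score distributions, and triplicate ELISA readings in
the 0-1.5 absorbance range — every quantity the pipeline estimates is known
exactly, so recovery can be measured.

Determinism: one seed stored on :class:`SyntheticTruth` controls every stage.
Each stage draws from ``numpy.random.default_rng([seed, stage])`` with a
fixed stage index (truth construction 0, chromatogram 1, PSMs 2, ELISA 3) and
a fixed draw order, so regenerating any stage with the same truth is
bit-reproducible on any platform.

Also packaged here: the transcription of the published comparative proteome
of *Daboia siamensis* venoms from Thailand and Indonesia (per-protein
whole-venom abundances and family assignments), used as the reference
fixture for aggregation, counting and comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceTable,
    Chromatogram,
    ElisaPlate,
    FamilyMap,
    FractionBoundary,
    FractionBoundarySet,
    PsmRecord,
)

# Gaussian-peak and noise defaults for the simulated 215 nm trace
TRACE_END_MIN = 190.0
TRACE_DT_MIN = 0.1
PEAK_SIGMA_MIN = 1.0
TOTAL_AREA_MAU_MIN = 1000.0
BOUNDARY_HALF_WIDTH_SIGMAS = 4.5

# Score / intensity model defaults
TARGET_SCORE_LOC, TARGET_SCORE_SCALE = 35.0, 5.0
DECOY_SCORE_LOC, DECOY_SCORE_SCALE = 15.0, 5.0
DECOY_FRACTION = 0.05
SPI_LOW, SPI_HIGH = 60.0, 100.0
PEPTIDE_MEAN = 6.0
INTENSITY_SIGMA = 0.4
FRACTION_TOTAL_INTENSITY = 1e6  # equal-mass (10 µg) digestion convention

# ELISA response model: A492 = blank + Amax * aff / (aff + K) + noise
ELISA_AMAX = 1.5
ELISA_K = 0.25
ELISA_BLANK = 0.04
ELISA_NOISE_SD = 0.03
CONTROL_FRACTION = "CTRL"

#: Antivenom affinity presets: "high" emulates a homologous antivenom with
#: strong binding of late (high-molecular-weight) fractions and weak binding
#: of the early low-molecular-weight fractions; "zero" emulates a heterologous
#: antivenom with essentially no epitope recognition.
AFFINITY_PRESETS = {"high": "high", "zero": "zero"}


@dataclass
class SyntheticTruth:
    """Complete ground truth for one simulated venom experiment."""

    venom_id: str
    seed: int
    family_proportions: dict[str, float]      # over identified families, sums to 1
    unidentified_share: float                 # proportion of total venom
    proteins: pd.DataFrame                    # accession, family, fraction_id, venom_prop
    fraction_ids: list[str]
    fraction_centers: dict[str, float]        # retention time, min
    fraction_sigma: float
    unidentified_fractions: list[str]
    fraction_shares: dict[str, float]         # f_i over all collected fractions
    elisa_affinity: dict[str, dict[str, float]] = field(default_factory=dict)
    peptide_mean: float = PEPTIDE_MEAN
    intensity_sigma: float = INTENSITY_SIGMA
    decoy_fraction: float = DECOY_FRACTION

    def __post_init__(self) -> None:
        if abs(sum(self.family_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("family proportions must sum to 1")
        if not (0.0 <= self.unidentified_share < 1.0):
            raise ValueError("unidentified share must be in [0, 1)")
        if abs(sum(self.fraction_shares.values()) - 1.0) > 1e-9:
            raise ValueError("fraction shares must sum to 1")

    @property
    def true_family_pct(self) -> dict[str, float]:
        """True family composition as percent of total venom protein."""
        scale = 100.0 * (1.0 - self.unidentified_share)
        return {f: scale * p for f, p in self.family_proportions.items()}

    def family_map(self) -> FamilyMap:
        return FamilyMap(dict(zip(self.proteins["accession"], self.proteins["family"])))


#: Family composition presets: proportions resemble the two geographic venoms
#: (one KSPI/svVEGF-bearing profile without unidentified mass, one with
#: LAAO/disintegrin and two unidentified fractions).
_PRESETS = {
    "thai-like": {
        "n_fractions": 16,
        "unidentified_share": 0.0,
        "n_unidentified": 0,
        "families": {
            "KSPI": 0.224, "PLA2": 0.379, "snaclec": 0.106, "SVSP": 0.181,
            "SVMP": 0.030, "svVEGF": 0.054, "svNGF": 0.005, "5NUC": 0.019,
            "PDE": 0.002,
        },
    },
    "indo-like": {
        "n_fractions": 12,
        "unidentified_share": 0.1644,
        "n_unidentified": 2,
        "families": {
            "PLA2": 0.5788, "snaclec": 0.0123, "SVSP": 0.2682, "SVMP": 0.0257,
            "LAAO": 0.0176, "svNGF": 0.0102, "5NUC": 0.0022, "PDE": 0.0107,
            "DIS": 0.0743,
        },
    },
}


def make_truth(
    seed: int,
    preset: str = "thai-like",
    family_proportions: dict[str, float] | None = None,
    n_fractions: int | None = None,
    antivenom_presets: dict[str, str] | None = None,
) -> SyntheticTruth:
    """Construct a ground-truth venom (stage-0 draws: protein counts, splits,
    fraction assignment, ELISA affinities)."""
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    cfg = _PRESETS[preset]
    rng = np.random.default_rng([seed, 0])
    fams = dict(family_proportions or cfg["families"])
    total = sum(fams.values())
    fams = {f: p / total for f, p in fams.items()}
    m = int(n_fractions or cfg["n_fractions"])
    n_unident = int(cfg["n_unidentified"])
    unident_share = float(cfg["unidentified_share"])

    fraction_ids = [f"F{i + 1}" for i in range(m)]
    centers = np.linspace(25.0, 180.0, m)
    fraction_centers = dict(zip(fraction_ids, centers))
    # unidentified fractions: spread inside the run, never first/last
    unident_ids = (
        [fraction_ids[i] for i in np.linspace(2, m - 3, n_unident).astype(int)]
        if n_unident
        else []
    )
    identified_ids = [f for f in fraction_ids if f not in unident_ids]

    # proteins per family with a Dirichlet split of the family's mass
    rows = []
    for fam in sorted(fams):
        n_prot = 2 + int(rng.integers(0, 4))  # 2-5 proteoforms per family
        split = rng.dirichlet(np.full(n_prot, 1.5))
        for k in range(n_prot):
            rows.append(
                {
                    "accession": f"SYN_{fam}_{k:02d}",
                    "family": fam,
                    "venom_prop": fams[fam] * split[k] * (1.0 - unident_share),
                }
            )
    proteins = pd.DataFrame(rows)

    # assign proteins to identified fractions: each fraction gets at least one,
    # larger proteins first so no fraction's share collapses to ~0
    order = rng.permutation(len(proteins))
    assignment = [""] * len(proteins)
    for slot, idx in enumerate(order):
        if slot < len(identified_ids):
            assignment[idx] = identified_ids[slot]
        else:
            assignment[idx] = identified_ids[int(rng.integers(0, len(identified_ids)))]
    proteins["fraction_id"] = assignment

    shares = {
        fid: float(proteins.loc[proteins["fraction_id"] == fid, "venom_prop"].sum())
        for fid in identified_ids
    }
    if unident_ids:
        split = rng.dirichlet(np.full(len(unident_ids), 2.0))
        for fid, s in zip(unident_ids, split):
            shares[fid] = unident_share * float(s)

    # ELISA affinities: late fractions (>=100 min) are strongly bound by the
    # "high" preset, early ones weakly; the "zero" preset binds nothing
    av_presets = antivenom_presets or {"DsMAV": "high", "SABU": "zero"}
    affinity: dict[str, dict[str, float]] = {}
    for av, kind in av_presets.items():
        aff = {}
        for fid in fraction_ids:
            if kind == "zero":
                aff[fid] = 0.002
            elif fraction_centers[fid] >= 100.0:
                aff[fid] = float(rng.uniform(0.6, 1.0))
            else:
                aff[fid] = 0.01
        # control antigen (heterologous venom): unbound by the homologous
        # antivenom, strongly bound by the one raised against it
        aff[CONTROL_FRACTION] = 0.0 if kind == "high" else 0.9
        affinity[av] = aff

    return SyntheticTruth(
        venom_id=preset,
        seed=int(seed),
        family_proportions=fams,
        unidentified_share=unident_share,
        proteins=proteins,
        fraction_ids=fraction_ids,
        fraction_centers=fraction_centers,
        fraction_sigma=PEAK_SIGMA_MIN,
        unidentified_fractions=unident_ids,
        fraction_shares=shares,
        elisa_affinity=affinity,
    )


# ---------------------------------------------------------------------------
# Stage 1: chromatogram
# ---------------------------------------------------------------------------

def simulate_chromatogram(
    truth: SyntheticTruth,
    noise_sd: float = 0.3,
    drift_mau_per_min: float = 0.02,
    dt: float = TRACE_DT_MIN,
) -> tuple[Chromatogram, FractionBoundarySet]:
    """Sum-of-Gaussians trace (areas proportional to fraction shares) plus a
    linear baseline drift and white noise; boundaries at the true peak edges."""
    rng = np.random.default_rng([truth.seed, 1])
    t = np.arange(0.0, TRACE_END_MIN + dt / 2, dt)
    y = np.zeros_like(t)
    sigma = truth.fraction_sigma
    for fid in truth.fraction_ids:
        area = TOTAL_AREA_MAU_MIN * truth.fraction_shares[fid]
        mu = truth.fraction_centers[fid]
        y += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    y += drift_mau_per_min * t
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=t.shape)
    half = BOUNDARY_HALF_WIDTH_SIGMAS * sigma
    entries = tuple(
        FractionBoundary(
            fid,
            truth.fraction_centers[fid] - half,
            truth.fraction_centers[fid] + half,
            True,
        )
        for fid in truth.fraction_ids
    )
    meta = {
        "flow_rate_ml_min": 1.0,
        "gradient": [((0, 10), 5), ((10, 30), 15), ((30, 150), 45), ((150, 170), 70)],
    }
    return Chromatogram(t, np.clip(y, 0.0, None), meta), FractionBoundarySet(entries)


# ---------------------------------------------------------------------------
# Stage 2: PSMs
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPsms:
    """PSM records plus the hidden per-record correctness label.

    ``is_correct[k]`` is True when record ``k`` is a correct target match;
    decoys and planted incorrect target matches are False.  The label is not
    part of the serialisable PSM schema — it exists only to measure realized
    false-discovery proportions on simulated data.
    """

    records: list[PsmRecord]
    is_correct: np.ndarray


def _random_peptide(rng: np.random.Generator, length: int = 10) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def simulate_psms(truth: SyntheticTruth, intensity_sigma: float | None = None) -> SimulatedPsms:
    """Per-fraction PSM tables with lognormal intensities and decoys.

    Peptide intensities are lognormal with unit mean scaled by the protein's
    true within-fraction proportion; intensities are then rescaled so every
    fraction has the same total (the equal-mass 10 µg digestion convention:
    only within-fraction proportions are MS-observable).  Incorrect target
    matches are planted at the decoy rate with the decoy score distribution,
    so the target-decoy FDR estimate has a measurable realized counterpart.
    """
    rng = np.random.default_rng([truth.seed, 2])
    sig = truth.intensity_sigma if intensity_sigma is None else intensity_sigma
    all_accessions = truth.proteins["accession"].tolist()
    name_of = dict(zip(truth.proteins["accession"], "Synthetic " + truth.proteins["family"]))
    records: list[PsmRecord] = []
    labels: list[bool] = []
    identified = [f for f in truth.fraction_ids if f not in truth.unidentified_fractions]
    for fid in identified:
        members = truth.proteins.loc[truth.proteins["fraction_id"] == fid]
        share = truth.fraction_shares[fid]
        frac_rows: list[PsmRecord] = []
        frac_labels: list[bool] = []
        intensities: list[float] = []
        for prot in members.itertuples():
            p_true = prot.venom_prop / share
            n_pep = max(1, int(rng.poisson(truth.peptide_mean)))
            protein_score = float(max(25.0, rng.normal(90.0, 30.0)))
            for _ in range(n_pep):
                if sig > 0:
                    inten = p_true * float(rng.lognormal(-0.5 * sig**2, sig))
                else:
                    inten = p_true
                frac_rows.append(
                    PsmRecord(
                        fraction_id=fid,
                        accession=prot.accession,
                        protein_name=name_of[prot.accession],
                        species="Synthetic viper",
                        peptide=_random_peptide(rng),
                        protein_score=protein_score,
                        peptide_score=float(rng.normal(TARGET_SCORE_LOC, TARGET_SCORE_SCALE)),
                        spi=float(rng.uniform(SPI_LOW, SPI_HIGH)),
                        intensity=inten,
                        is_decoy=False,
                    )
                )
                frac_labels.append(True)
                intensities.append(inten)
        n_true = len(frac_rows)
        # planted incorrect targets + decoys, both at the decoy rate
        n_false = int(rng.binomial(n_true, truth.decoy_fraction))
        n_decoy = int(rng.binomial(n_true, truth.decoy_fraction))
        low_scale = 0.01 * (sum(intensities) / max(1, n_true))
        for _ in range(n_false):
            acc = str(rng.choice(all_accessions))
            frac_rows.append(
                PsmRecord(
                    fraction_id=fid,
                    accession=acc,
                    protein_name=name_of[acc],
                    species="Synthetic viper",
                    peptide=_random_peptide(rng),
                    protein_score=float(max(0.0, rng.normal(DECOY_SCORE_LOC + 15, 10.0))),
                    peptide_score=float(rng.normal(DECOY_SCORE_LOC, DECOY_SCORE_SCALE)),
                    spi=float(rng.uniform(SPI_LOW, SPI_HIGH)),
                    intensity=float(rng.lognormal(np.log(max(low_scale, 1e-12)), 1.0)),
                    is_decoy=False,
                )
            )
            frac_labels.append(False)
        for k in range(n_decoy):
            frac_rows.append(
                PsmRecord(
                    fraction_id=fid,
                    accession=f"DECOY_{fid}_{k:03d}",
                    protein_name="Decoy",
                    species="Decoy",
                    peptide=_random_peptide(rng),
                    protein_score=float(max(0.0, rng.normal(DECOY_SCORE_LOC + 15, 10.0))),
                    peptide_score=float(rng.normal(DECOY_SCORE_LOC, DECOY_SCORE_SCALE)),
                    spi=float(rng.uniform(SPI_LOW, SPI_HIGH)),
                    intensity=float(rng.lognormal(np.log(max(low_scale, 1e-12)), 1.0)),
                    is_decoy=True,
                )
            )
            frac_labels.append(False)
        # equal-total rescaling (target rows only define the venom signal, but
        # the whole fraction is rescaled jointly, preserving all proportions)
        total = sum(r.intensity for r in frac_rows)
        scale = FRACTION_TOTAL_INTENSITY / total if total > 0 else 1.0
        from dataclasses import replace as _replace

        records.extend(_replace(r, intensity=r.intensity * scale) for r in frac_rows)
        labels.extend(frac_labels)
    return SimulatedPsms(records, np.asarray(labels, dtype=bool))


def simulate_benchmark_psms(
    n_psms: int = 2000, decoy_fraction: float = DECOY_FRACTION, seed: int = 0
) -> SimulatedPsms:
    """Score-model benchmark: one fraction, stated target/decoy distributions.

    ``n_psms`` rows total, a ``decoy_fraction`` share of decoys and the same
    share of planted incorrect targets; everything passes the fixed score/SPI
    cascade so the benchmark isolates the FDR-control step.
    """
    rng = np.random.default_rng([seed, 4])
    n_decoy = int(round(n_psms * decoy_fraction))
    n_false = int(round(n_psms * decoy_fraction))
    n_true = n_psms - n_decoy - n_false
    records: list[PsmRecord] = []
    labels: list[bool] = []

    def _mk(acc: str, score: float, decoy: bool) -> PsmRecord:
        return PsmRecord(
            fraction_id="F1",
            accession=acc,
            protein_name="Benchmark",
            species="Synthetic viper",
            peptide=_random_peptide(rng),
            protein_score=100.0,
            peptide_score=score,
            spi=90.0,
            intensity=1.0,
            is_decoy=decoy,
        )

    for i in range(n_true):
        records.append(_mk(f"T{i:05d}", float(rng.normal(TARGET_SCORE_LOC, TARGET_SCORE_SCALE)), False))
        labels.append(True)
    for i in range(n_false):
        records.append(_mk(f"T{n_true + i:05d}", float(rng.normal(DECOY_SCORE_LOC, DECOY_SCORE_SCALE)), False))
        labels.append(False)
    for i in range(n_decoy):
        records.append(_mk(f"DECOY_{i:05d}", float(rng.normal(DECOY_SCORE_LOC, DECOY_SCORE_SCALE)), True))
        labels.append(False)
    return SimulatedPsms(records, np.asarray(labels, dtype=bool))


# ---------------------------------------------------------------------------
# Stage 3: ELISA
# ---------------------------------------------------------------------------

def simulate_elisa(
    truth: SyntheticTruth,
    n_replicates: int = 3,
    n_blanks: int = 6,
    noise_sd: float = ELISA_NOISE_SD,
) -> ElisaPlate:
    """Triplicate indirect-ELISA plate from the truth's per-fraction affinities.

    A492 = blank level + Amax * aff / (aff + K) + Gaussian noise, truncated at
    0; blank wells carry the blank level with reduced noise; the control
    antigen wells are flagged ``is_control``.
    """
    rng = np.random.default_rng([truth.seed, 3])
    rows = []
    for av in sorted(truth.elisa_affinity):
        aff = truth.elisa_affinity[av]
        for fid in list(truth.fraction_ids) + [CONTROL_FRACTION]:
            signal = ELISA_AMAX * aff[fid] / (aff[fid] + ELISA_K) if aff[fid] > 0 else 0.0
            for rep in range(1, n_replicates + 1):
                a = max(0.0, ELISA_BLANK + signal + float(rng.normal(0.0, noise_sd)))
                rows.append(
                    {
                        "fraction_id": fid,
                        "antivenom": av,
                        "replicate": rep,
                        "a492": a,
                        "is_blank": False,
                        "is_control": fid == CONTROL_FRACTION,
                    }
                )
    for rep in range(1, n_blanks + 1):
        rows.append(
            {
                "fraction_id": "BLANK",
                "antivenom": "none",
                "replicate": rep,
                "a492": max(0.0, ELISA_BLANK + float(rng.normal(0.0, noise_sd / 3))),
                "is_blank": True,
                "is_control": False,
            }
        )
    return ElisaPlate(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Reference fixture (published comparative proteome transcription)
# ---------------------------------------------------------------------------

def _reference_path() -> Path:
    return Path(str(resources.files("venomdecomplex").joinpath(
        "data/daboia_siamensis_reference.tsv")))


#: Per-fraction unidentified shares of the Indonesia venom (fractions F6 and
#: F11 eluted protein that yielded no identification); the Thailand venom has
#: no unidentified mass.
REFERENCE_UNIDENTIFIED = {
    "Ds-Thailand": {},
    "Ds-Indonesia": {"F6": 7.47, "F11": 8.97},
}


def load_reference_proteomes() -> tuple[AbundanceTable, AbundanceTable, FamilyMap]:
    """The packaged *D. siamensis* (Thailand / Indonesia) comparison fixture.

    Returns per-protein whole-venom abundance tables for both venoms (percent
    of total venom protein, with the Indonesia unidentified bucket) and the
    accession -> family map.  Per-protein rows only; family totals are always
    recomputed by aggregation.
    """
    df = pd.read_csv(_reference_path(), sep="\t")
    fmap = FamilyMap(dict(zip(df["accession"], df["family"])))
    tables = []
    for venom_id, col in (("Ds-Thailand", "thailand_pct"), ("Ds-Indonesia", "indonesia_pct")):
        sub = df.loc[df[col].notna()].reset_index(drop=True)
        unident = REFERENCE_UNIDENTIFIED[venom_id]
        tables.append(
            AbundanceTable(
                venom_id=venom_id,
                proteins=pd.DataFrame(
                    {
                        "accession": sub["accession"],
                        "protein_name": sub["protein_name"],
                        "family": sub["family"],
                        "fraction_id": "",
                        "abundance_pct": sub[col].astype(float),
                    }
                ),
                unidentified_pct=float(sum(unident.values())),
                meta={
                    "unidentified_fractions": sorted(unident),
                    "unidentified_by_fraction": dict(unident),
                },
            )
        )
    return tables[0], tables[1], fmap
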