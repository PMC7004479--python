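"""MSI proportions, hierarchical whole-venom abundances, family aggregation,
non-redundant counts and two-venom comparison."""

import numpy as np
import pandas as pd
import pytest

import venomdecomplex as vd
from venomdecomplex.errors import EmptyFraction, MissingShare, UnassignedFraction

from .test_filtering import make_psm


def wft_from(rows):
    """Build a within-fraction table directly: rows of (fraction, accession, p, msi)."""
    return pd.DataFrame(
        [
            {
                "fraction_id": f,
                "accession": a,
                "protein_name": a,
                "species": "Viper",
                "n_peptides": 1,
                "msi": m,
                "p": p,
            }
            for f, a, p, m in rows
        ]
    )


class TestWithinFraction:
    def test_msi_80_20_gives_08_02(self):
        psms = [
            make_psm(accession="A", intensity=80.0),
            make_psm(accession="B", intensity=20.0),
        ]
        wft = vd.within_fraction_abundance(psms)
        assert dict(zip(wft["accession"], wft["p"])) == pytest.approx({"A": 0.8, "B": 0.2})

    def test_single_protein_gets_p_one(self):
        wft = vd.within_fraction_abundance([make_psm(accession="A", intensity=5.0)])
        assert wft["p"].tolist() == [1.0]

    def test_matches_hand_computed_mean_over_total(self, thai_experiment):
        # brute-force oracle: recompute MSI = mean(peptide intensities) and
        # p = MSI / sum(MSI) by explicit loops over one simulated fraction
        truth, _, _, sim = thai_experiment
        kept = vd.filter_at_fdr(vd.apply_score_filters(sim.records), 0.01).psms
        wft = vd.within_fraction_abundance(kept)
        fid = wft["fraction_id"].iloc[0]
        by_acc = {}
        for p in kept:
            if p.fraction_id == fid:
                by_acc.setdefault(p.accession, []).append(p.intensity)
        msi = {a: sum(v) / len(v) for a, v in by_acc.items()}
        total = sum(msi.values())
        sub = wft.loc[wft["fraction_id"] == fid]
        for acc, p_est in zip(sub["accession"], sub["p"]):
            assert p_est == pytest.approx(msi[acc] / total, abs=1e-12)

    def test_duplicate_accessions_pooled_when_merging(self):
        psms = [
            make_psm(accession="A", intensity=10.0),
            make_psm(accession="A", intensity=30.0),
            make_psm(accession="B", intensity=20.0),
        ]
        merged = vd.within_fraction_abundance(psms, merge_duplicates=True)
        assert len(merged) == 2
        a_row = merged.loc[merged["accession"] == "A"].iloc[0]
        assert a_row["msi"] == pytest.approx(20.0)  # pooled mean of {10, 30}
        assert a_row["n_peptides"] == 2

    def test_zero_intensity_fraction_rejected(self):
        with pytest.raises(EmptyFraction):
            vd.within_fraction_abundance([make_psm(intensity=0.0)])

    def test_decoys_never_quantified(self):
        psms = [make_psm(accession="A", intensity=10.0),
                make_psm(accession="D", intensity=99.0, is_decoy=True)]
        wft = vd.within_fraction_abundance(psms)
        assert wft["accession"].tolist() == ["A"]


class TestWholeVenom:
    def test_published_fraction_example(self):
        # fraction share 9.83% split over three proteins reproduces the
        # printed per-protein percentages 7.37 / 0.54 / 1.92 at 2 dp
        shares = vd.FractionShareTable({"F4": 0.0983, "rest": 0.9017})
        wft = wft_from(
            [
                ("F4", "A8Y7N4", 0.74975, 1.0),
                ("F4", "A8Y7N9", 0.05493, 1.0),
                ("F4", "A8Y7P6", 0.19532, 1.0),
                ("rest", "X", 1.0, 1.0),
            ]
        )
        table = vd.whole_venom_abundance(shares, wft)
        got = dict(zip(table.proteins["accession"], table.proteins["abundance_pct"]))
        assert round(got["A8Y7N4"], 2) == 7.37
        assert round(got["A8Y7N9"], 2) == 0.54
        assert round(got["A8Y7P6"], 2) == 1.92

    def test_unidentified_fraction_contributes_its_share(self):
        shares = vd.FractionShareTable({"F6": 0.0747, "F1": 0.9253})
        wft = wft_from([("F1", "X", 1.0, 1.0)])
        table = vd.whole_venom_abundance(shares, wft, unidentified=["F6"])
        assert table.unidentified_pct == pytest.approx(7.47)
        assert table.total_pct == pytest.approx(100.0, abs=1e-9)

    def test_conservation_exact_when_all_identified(self):
        shares = vd.FractionShareTable({"F1": 0.3, "F2": 0.7})
        wft = wft_from([("F1", "A", 0.6, 6.0), ("F1", "B", 0.4, 4.0), ("F2", "C", 1.0, 1.0)])
        table = vd.whole_venom_abundance(shares, wft)
        assert table.proteins["abundance_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_psms_without_share_rejected(self):
        wft = wft_from([("F9", "A", 1.0, 1.0)])
        with pytest.raises(MissingShare):
            vd.whole_venom_abundance(vd.FractionShareTable({"F1": 1.0}), wft)

    def test_share_without_psms_must_be_declared(self):
        shares = vd.FractionShareTable({"F1": 0.5, "F2": 0.5})
        wft = wft_from([("F1", "A", 1.0, 1.0)])
        with pytest.raises(UnassignedFraction):
            vd.whole_venom_abundance(shares, wft)

    def test_scale_invariance_of_intensities_within_fraction(self):
        psms = [
            make_psm(accession="A", intensity=10.0, fraction_id="F1"),
            make_psm(accession="B", intensity=30.0, fraction_id="F1"),
            make_psm(accession="C", intensity=7.0, fraction_id="F2"),
        ]
        scaled = [
            make_psm(
                accession=p.accession,
                intensity=p.intensity * (250.0 if p.fraction_id == "F1" else 1.0),
                fraction_id=p.fraction_id,
            )
            for p in psms
        ]
        shares = vd.FractionShareTable({"F1": 0.4, "F2": 0.6})
        t1 = vd.whole_venom_abundance(shares, vd.within_fraction_abundance(psms))
        t2 = vd.whole_venom_abundance(shares, vd.within_fraction_abundance(scaled))
        pd.testing.assert_series_equal(t1.proteins["abundance_pct"], t2.proteins["abundance_pct"])

    def test_global_mode_normalises_by_total_msi(self):
        shares = vd.FractionShareTable({"F1": 0.5, "F2": 0.5})
        wft = wft_from([("F1", "A", 1.0, 300.0), ("F2", "B", 1.0, 100.0)])
        table = vd.whole_venom_abundance(shares, wft, mode="global")
        got = dict(zip(table.proteins["accession"], table.proteins["abundance_pct"]))
        assert got == pytest.approx({"A": 75.0, "B": 25.0})


class TestAggregationOnReference:
    def test_family_totals_match_published_sums(self, reference):
        thai, indo, fmap = reference
        fa = vd.aggregate_families(thai, fmap).set_index("family")["abundance_pct"]
        fb = vd.aggregate_families(indo, fmap).set_index("family")["abundance_pct"]
        assert round(fa["KSPI"], 2) == 22.38
        assert round(fa["SVSP"], 2) == 18.07
        assert round(fb["SVSP"], 2) == 22.41
        assert round(fb["SVMP"], 2) == 2.15

    def test_sorted_descending(self, reference):
        thai, _, fmap = reference
        agg = vd.aggregate_families(thai, fmap)
        assert list(agg["abundance_pct"]) == sorted(agg["abundance_pct"], reverse=True)

    def test_family_without_members_is_absent_not_negative(self, reference):
        thai, _, fmap = reference
        agg = vd.aggregate_families(thai, fmap)
        assert "LAAO" not in set(agg["family"])  # not detected in this venom

    def test_family_totals_equal_member_row_sums(self, reference):
        _, indo, fmap = reference
        agg = vd.aggregate_families(indo, fmap).set_index("family")["abundance_pct"]
        manual = indo.proteins.groupby("family")["abundance_pct"].sum()
        for fam, v in manual.items():
            assert agg[fam] == pytest.approx(v, abs=1e-12)


class TestCounts:
    def test_reference_counts(self, reference):
        thai, indo, fmap = reference
        ct = vd.count_nonredundant(thai, fmap)
        ci = vd.count_nonredundant(indo, fmap)
        assert (ct["proteins"], ct["families"]) == (47, 9)
        assert (ci["proteins"], ci["families"]) == (25, 9)
        assert ct["per_family"]["PLA2"] == 6 and ct["per_family"]["SVSP"] == 10
        assert ci["per_family"]["PLA2"] == 4 and ci["per_family"]["SVSP"] == 8

    def test_empty_table_counts_zero(self):
        empty = vd.AbundanceTable(
            "none",
            pd.DataFrame(columns=["accession", "protein_name", "family",
                                  "fraction_id", "abundance_pct"]),
        )
        c = vd.count_nonredundant(empty)
        assert (c["proteins"], c["families"]) == (0, 0)

    def test_same_accession_across_fractions_counts_once(self):
        proteins = pd.DataFrame(
            {
                "accession": ["P1", "P1"],
                "protein_name": ["x", "x"],
                "family": ["PLA2", "PLA2"],
                "fraction_id": ["F1", "F2"],
                "abundance_pct": [1.0, 2.0],
            }
        )
        assert vd.count_nonredundant(vd.AbundanceTable("v", proteins))["proteins"] == 1


class TestComparison:
    def test_reference_unique_families(self, reference):
        thai, indo, fmap = reference
        comp = vd.compare_venoms(thai, indo, fmap)
        uniq_a = set(comp.loc[comp["status"] == "unique_to_a", "family"])
        uniq_b = set(comp.loc[comp["status"] == "unique_to_b", "family"])
        assert uniq_a == {"KSPI", "svVEGF"}
        assert uniq_b == {"LAAO", "DIS"}

    def test_identical_tables_all_shared_zero_delta(self, reference):
        thai, _, fmap = reference
        comp = vd.compare_venoms(thai, thai, fmap)
        assert (comp["status"] == "shared").all()
        assert np.allclose(comp["delta"], 0.0)

    def test_single_family_difference_flagged_exactly_once(self, reference):
        thai, _, fmap = reference
        reduced = vd.AbundanceTable(
            "reduced",
            thai.proteins.loc[thai.proteins["family"] != "PDE"].reset_index(drop=True),
        )
        comp = vd.compare_venoms(thai, reduced, fmap)
        assert (comp["status"] != "shared").sum() == 1
        assert comp.loc[comp["status"] == "unique_to_a", "family"].tolist() == ["PDE"]
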