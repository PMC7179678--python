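"""SNV filter cascade: each filter's fixtures, inheritance matching, and
the cascade's cohort-level invariants."""

import numpy as np
import pandas as pd
import pytest

from pidarray import snv
from pidarray.manifest import VariantAnnotation


def annotation(rows):
    return VariantAnnotation(pd.DataFrame(
        rows, columns=["probe_id", "pathogenicity", "pop_frequency",
                       "inheritance"]))


def candidates(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "probe_id", "chromosome",
                                     "gene", "zygosity"])
    df["caller"] = "primary"
    df["filter_trail"] = ""
    df["flagged_for_review"] = False
    return df


class TestSelectDiseaseCausing:
    ann = annotation([
        ("p1", "disease_causing", 1e-4, "AR"),
        ("p2", "benign", 0.2, "none"),
    ])

    def test_benign_dropped_disease_retained(self):
        cands = candidates([("s1", "p1", "1", "G1", "het"),
                            ("s1", "p2", "1", "G2", "het")])
        out, n_unannot = snv.select_disease_causing(cands, self.ann)
        assert list(out["probe_id"]) == ["p1"]
        assert n_unannot == 0

    def test_unannotated_probe_dropped_and_counted(self):
        cands = candidates([("s1", "p9", "1", "G9", "hom")])
        out, n_unannot = snv.select_disease_causing(cands, self.ann)
        assert out.empty and n_unannot == 1


class TestFrequencyFilter:
    ann = annotation([
        ("p1", "disease_causing", 0.004, "AR"),
        ("p2", "disease_causing", 0.005, "AR"),
        ("p3", "disease_causing", 0.20, "AR"),
    ])

    def test_strictly_below_half_percent(self):
        cands = candidates([("s1", "p1", "1", "G", "het"),
                            ("s1", "p2", "1", "G", "het"),
                            ("s1", "p3", "1", "G", "het")])
        out = snv.frequency_filter(cands, self.ann)
        # 0.004 retained; 0.005 dropped (strict "below"); 0.20 dropped
        assert list(out["probe_id"]) == ["p1"]

    def test_missing_frequency_treated_as_zero(self):
        cands = candidates([("s1", "px", "1", "G", "het")])
        out = snv.frequency_filter(cands, self.ann)
        assert list(out["probe_id"]) == ["px"]


class TestRecurrenceFilter:
    def test_singleton_retained_duplicate_dropped_in_both(self):
        cands = candidates([("s1", "p1", "1", "G", "het"),
                            ("s1", "p2", "1", "G", "het"),
                            ("s2", "p2", "1", "G", "het")])
        out = snv.recurrence_filter(cands)
        assert list(out["probe_id"]) == ["p1"]

    def test_faulty_probe_fully_removed(self):
        rows = [(f"s{i}", "bad", "1", "G", "het") for i in range(10)]
        rows.append(("s0", "ok", "1", "G", "hom"))
        out = snv.recurrence_filter(candidates(rows))
        assert list(out["probe_id"]) == ["ok"]


class TestMaleXHetFilter:
    sexes = {"m1": "male", "f1": "female", "a1": "ambiguous"}

    def test_male_x_het_dropped(self):
        out = snv.male_x_het_filter(
            candidates([("m1", "p1", "X", "G", "het")]), self.sexes)
        assert out.empty

    def test_female_x_het_retained(self):
        out = snv.male_x_het_filter(
            candidates([("f1", "p1", "X", "G", "het")]), self.sexes)
        assert list(out["zygosity"]) == ["het"]

    def test_male_x_hom_relabelled_hemizygous(self):
        out = snv.male_x_het_filter(
            candidates([("m1", "p1", "X", "G", "hom")]), self.sexes)
        assert list(out["zygosity"]) == ["hemizygous"]

    def test_autosomal_het_untouched(self):
        out = snv.male_x_het_filter(
            candidates([("m1", "p1", "7", "G", "het")]), self.sexes)
        assert list(out["zygosity"]) == ["het"]

    def test_ambiguous_sex_retained_and_flagged(self):
        out = snv.male_x_het_filter(
            candidates([("a1", "p1", "X", "G", "het")]), self.sexes)
        assert len(out) == 1 and bool(out["flagged_for_review"].iloc[0])


class TestMatchInheritance:
    ann = annotation([
        ("ad1", "disease_causing", 1e-4, "AD"),
        ("ar1", "disease_causing", 1e-4, "AR"),
        ("ar2", "disease_causing", 1e-4, "AR"),
        ("xl1", "disease_causing", 1e-4, "XL"),
    ])
    sexes = {"s1": "male", "s2": "female"}

    def _status(self, rows, patient="s1"):
        statuses, _ = snv.match_inheritance(candidates(rows), self.ann,
                                            self.sexes, [patient])
        return statuses[patient]

    def test_single_het_in_ar_gene_is_no_diagnosis(self):
        assert self._status([("s1", "ar1", "1", "G", "het")]) == "no_diagnosis"

    def test_hom_in_ar_gene_is_diagnosis(self):
        assert self._status([("s1", "ar1", "1", "G", "hom")]) \
            == "genetic_diagnosis"

    def test_compound_het_in_ar_gene_is_diagnosis(self):
        rows = [("s1", "ar1", "1", "G", "het"), ("s1", "ar2", "1", "G", "het")]
        assert self._status(rows) == "genetic_diagnosis"

    def test_two_hets_in_different_genes_is_no_diagnosis(self):
        rows = [("s1", "ar1", "1", "GA", "het"),
                ("s1", "ar2", "1", "GB", "het")]
        assert self._status(rows) == "no_diagnosis"

    def test_ad_het_is_diagnosis(self):
        assert self._status([("s1", "ad1", "1", "G", "het")]) \
            == "genetic_diagnosis"

    def test_xl_hemizygous_male_is_diagnosis(self):
        assert self._status([("s1", "xl1", "X", "G", "hemizygous")]) \
            == "genetic_diagnosis"

    def test_xl_het_female_is_carrier_not_diagnosis(self):
        assert self._status([("s2", "xl1", "X", "G", "het")],
                            patient="s2") == "no_diagnosis"


class TestClusterQualityCheck:
    def _setup(self, outlier_angle=None, dropout=False):
        """40-sample AA probe plus one het carrier; the carrier's point can
        be displaced in angle or dimmed in intensity."""
        from pidarray import calling
        from pidarray.simulate import IntensityRun
        rng = np.random.default_rng(3)
        angles = np.r_[rng.normal(0.05, 0.02, 40), 0.5].clip(0, 1)
        totals = np.full(41, 1000.0) * np.exp(rng.normal(0, 0.1, 41))
        if outlier_angle is not None:
            angles[-1] = outlier_angle
        if dropout:
            totals[-1] = 150.0
        half = np.pi / 2
        c, s = np.cos(angles * half), np.sin(angles * half)
        x = (totals * c / (c + s))[:, None]
        y = (totals * s / (c + s))[:, None]
        samples = np.array([f"s{i}" for i in range(41)])
        model = calling.fit_clusters(x, y, ["p"])
        run = IntensityRun("r", samples, np.array(["p"]), x, y)
        calls = calling.GenotypeMatrix(
            samples, np.array(["p"]),
            np.r_[np.zeros(40, np.int8), np.int8(1)][:, None],
            np.full((41, 1), 0.9), np.zeros((41, 1), np.int8))
        cand = candidates([("s40", "p", "1", "G", "het")])
        return cand, model, run, calls

    def test_candidate_at_cluster_center_retained_unflagged(self):
        cand, model, run, calls = self._setup()
        out = snv.cluster_quality_check(cand, model, run, calls)
        assert len(out) == 1 and not out["flagged_for_review"].iloc[0]

    def test_far_outlier_excluded(self):
        # ~10 canonical spreads below the heterozygote band
        cand, model, run, calls = self._setup(outlier_angle=0.99)
        out = snv.cluster_quality_check(cand, model, run, calls)
        assert out.empty

    def test_intensity_dropout_excluded(self):
        cand, model, run, calls = self._setup(dropout=True)
        out = snv.cluster_quality_check(cand, model, run, calls)
        assert out.empty


class TestCascadeInvariants:
    def test_sample_order_invariance(self, zero_noise_cohort,
                                     zero_noise_result):
        """Reversing sample order leaves the candidate set unchanged."""
        c = zero_noise_cohort
        res = zero_noise_result
        rev = res.postqc.subset(
            sample_mask=np.ones(res.postqc.n_samples, bool))
        order = np.arange(rev.n_samples)[::-1]
        rev.sample_ids = rev.sample_ids[order]
        rev.calls = rev.calls[order]
        rev.scores = rev.scores[order]
        rev.caller = rev.caller[order]
        cascade = snv.run_snv_cascade(
            rev, c.manifest, c.annotation, res.qc_report.inferred_sex,
            res.model, c.run1, c.patient_ids)
        a = set(zip(res.cascade.candidates["sample_id"],
                    res.cascade.candidates["probe_id"]))
        b = set(zip(cascade.candidates["sample_id"],
                    cascade.candidates["probe_id"]))
        assert a == b

    def test_zero_noise_candidates_match_planted_singletons(
            self, zero_noise_cohort, zero_noise_result):
        led = zero_noise_cohort.ledger.planted_snvs
        carriers = led.groupby("probe_id")["sample_id"].nunique()
        expected = led[led["probe_id"].map(carriers) < 2]
        got = set(zip(zero_noise_result.cascade.candidates["sample_id"],
                      zero_noise_result.cascade.candidates["probe_id"]))
        assert got == set(zip(expected["sample_id"], expected["probe_id"]))

    def test_filter_trail_records_every_stage(self, zero_noise_result):
        trails = zero_noise_result.cascade.candidates["filter_trail"]
        assert (trails == "disease_causing>rare>singleton>male_x_het"
                ">cluster_ok").all()
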