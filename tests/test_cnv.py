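"""CNV screening: LRR/BAF computation, segmentation rules, aneuploidy and
LCSH detection, and the CNV filter fixtures."""

import numpy as np
import pandas as pd
import pytest

from pidarray import cnv
from pidarray.manifest import BenignCnvTrack


def flat_track(n=200, sd=0.05, seed=0, chrom="1", spacing=100_000,
               baf=None, lrr_patch=None):
    """Synthetic single-sample LRR/BAF track with optional patched region."""
    rng = np.random.default_rng(seed)
    lrr = rng.normal(0.0, sd, (1, n))
    if lrr_patch is not None:
        a, b, value = lrr_patch
        lrr[0, a:b] = value + rng.normal(0, sd, b - a)
    if baf is None:
        baf = np.tile([0.0, 0.5, 1.0, 0.5], n)[:n][None]
    return cnv.BafLrrTrack(
        sample_ids=np.array(["s1"]),
        probe_ids=np.array([f"p{i}" for i in range(n)]),
        chromosomes=np.array([chrom] * n),
        positions=np.arange(n) * spacing,
        lrr=lrr, baf=np.asarray(baf, dtype=float))


class TestSegment:
    def test_flat_track_has_no_calls(self):
        assert cnv.segment(flat_track()).empty

    def test_forty_probe_deep_deletion_called_double_loss(self):
        t = flat_track(lrr_patch=(80, 120, -2.0))
        seg = cnv.segment(t)
        assert len(seg) == 1
        row = seg.iloc[0]
        assert row["event"] == "double_loss"
        assert row["n_probes"] == 40
        assert row["start"] == 80 * 100_000
        assert row["p_value"] < 5e-6

    def test_three_probe_deletion_not_called(self):
        t = flat_track(lrr_patch=(80, 83, -2.0))
        seg = cnv.segment(t)
        assert seg.empty

    def test_intermediate_loss_classified_single_not_double(self):
        t = flat_track(sd=0.03, lrr_patch=(50, 80, -0.45))
        seg = cnv.segment(t)
        assert len(seg) == 1
        assert seg.iloc[0]["event"] == "single_loss"

    @pytest.mark.parametrize("level, expected", [
        (-2.0, "double_loss"), (-0.45, "single_loss"),
        (0.35, "single_gain"), (1.0, "double_gain"),
    ])
    def test_threshold_classification(self, level, expected):
        t = flat_track(sd=0.03, lrr_patch=(50, 90, level))
        seg = cnv.segment(t)
        assert seg.iloc[0]["event"] == expected

    def test_probe_gap_splits_segments(self):
        t = flat_track(sd=0.03, lrr_patch=(50, 90, -2.0))
        t.positions = t.positions.copy()
        t.positions[70:] += 5_000_000   # > max spacing inside the event
        seg = cnv.segment(t)
        assert len(seg) == 2
        assert set(seg["n_probes"]) == {20, 20}

    def test_deterministic(self):
        t = flat_track(lrr_patch=(80, 120, -2.0))
        a = cnv.segment(t)
        b = cnv.segment(t)
        pd.testing.assert_frame_equal(a, b)

    def test_no_call_violates_min_probes_or_spacing(self, cnv_result):
        params = cnv.CnvCallingParams()
        for r in cnv_result.segments.itertuples(index=False):
            assert r.n_probes >= params.min_probes


class TestAneuploidy:
    def _tri_baf(self, n, rng):
        picks = rng.random(n)
        baf = np.where(picks < 0.4, 0.0, np.where(picks < 0.6, 1 / 3,
                       np.where(picks < 0.8, 2 / 3, 1.0)))
        return baf[None] + rng.normal(0, 0.02, (1, n))

    def test_trisomy_pattern_detected(self):
        rng = np.random.default_rng(1)
        t = flat_track(sd=0.05, baf=self._tri_baf(200, rng))
        t.lrr += np.log2(3 / 2)
        out = cnv.detect_aneuploidy(t)
        assert list(out["event"]) == ["trisomy"]
        assert not out["discordant"].iloc[0]

    def test_monosomy_pattern_detected(self):
        rng = np.random.default_rng(2)
        baf = np.where(rng.random(200) < 0.6, 0.0, 1.0)[None] \
            + rng.normal(0, 0.02, (1, 200))
        t = flat_track(sd=0.05, baf=np.clip(baf, 0, 1))
        t.lrr -= 1.0
        out = cnv.detect_aneuploidy(t)
        assert list(out["event"]) == ["monosomy"]

    def test_diploid_genome_has_no_events(self):
        assert cnv.detect_aneuploidy(flat_track()).empty

    def test_planted_whole_chromosome_events(self, cnv_cohort, cnv_result):
        out = cnv_result.aneuploidy
        keyed = {(r.sample_id, r.chromosome): r.event
                 for r in out.itertuples(index=False)}
        assert keyed.get(("P003", "8")) == "trisomy"
        assert keyed.get(("P004", "7")) == "monosomy"


class TestLcsh:
    def test_error_tolerant_runs(self):
        is_hom = np.array([True] * 60 + [False] + [True] * 60)
        runs = cnv._error_tolerant_runs(is_hom, 50)
        assert runs == [(0, 121)]
        # two close errors break the run early on
        is_hom2 = np.array([True] * 10 + [False, False] + [True] * 40)
        runs2 = cnv._error_tolerant_runs(is_hom2, 50)
        assert runs2[0] == (0, 10)

    def test_planted_lcsh_recovered_deletion_not_lcsh(
            self, cnv_cohort, cnv_result):
        lcsh = cnv_result.lcsh
        planted = cnv_cohort.ledger.lcsh_events[0]
        hit = lcsh[(lcsh["sample_id"] == planted["sample_id"])
                   & (lcsh["chromosome"] == planted["chromosome"])]
        assert len(hit) == 1
        row = hit.iloc[0]
        inter = (min(row["end"], planted["end"])
                 - max(row["start"], planted["start"]))
        assert inter / (planted["end"] - planted["start"]) > 0.5
        # the deep deletion region must never be reported as LCSH
        del_ev = cnv_cohort.ledger.cnv_events[0]
        overlap = lcsh[(lcsh["sample_id"] == del_ev["sample_id"])
                       & (lcsh["chromosome"] == del_ev["chromosome"])
                       & (lcsh["start"] < del_ev["end"])
                       & (lcsh["end"] > del_ev["start"])]
        assert overlap.empty

    def test_outbred_genome_has_no_lcsh(self, cnv_result, cnv_cohort):
        planted_samples = {e["sample_id"]
                           for e in cnv_cohort.ledger.lcsh_events}
        others = cnv_result.lcsh[
            ~cnv_result.lcsh["sample_id"].isin(planted_samples)]
        assert others.empty


def seg_row(sample="s1", chrom="1", start=1000, end=5000, event="single_loss",
            n_probes=10, mean_log2=-0.5):
    return {"sample_id": sample, "chromosome": chrom, "start": start,
            "end": end, "n_probes": n_probes, "mean_log2": mean_log2,
            "event": event, "p_value": 1e-9}


class TestFilterCnvs:
    genes = pd.DataFrame({"gene": ["G1"], "chromosome": ["1"],
                          "start": [0], "end": [10_000]})
    no_benign = BenignCnvTrack()

    def test_intergenic_event_dropped(self):
        seg = pd.DataFrame([seg_row(start=50_000, end=60_000)])
        out = cnv.filter_cnvs(seg, self.genes, self.no_benign)
        assert out.empty

    def test_het_event_dropped_at_single_bp_benign_overlap(self):
        benign = BenignCnvTrack(pd.DataFrame({
            "chromosome": ["1"], "start": [4999], "end": [7000],
            "zygosity": ["het"]}))
        seg = pd.DataFrame([seg_row()])   # ends at 5000: 1 bp overlap
        out = cnv.filter_cnvs(seg, self.genes, benign)
        assert out.empty

    def test_hom_event_exempt_from_benign_overlap(self):
        benign = BenignCnvTrack(pd.DataFrame({
            "chromosome": ["1"], "start": [0], "end": [10_000],
            "zygosity": ["het"]}))
        seg = pd.DataFrame([seg_row(event="double_loss", mean_log2=-2.0)])
        out = cnv.filter_cnvs(seg, self.genes, benign)
        assert len(out) == 1

    def test_recurrent_event_dropped_in_all_carriers(self):
        seg = pd.DataFrame([seg_row(sample="s1"), seg_row(sample="s2"),
                            seg_row(sample="s3", start=8000, end=9000)])
        out = cnv.filter_cnvs(seg, self.genes, self.no_benign)
        assert list(out["sample_id"]) == ["s3"]

    def test_reciprocal_overlap_definition(self):
        assert cnv._reciprocal_overlap(0, 100, 50, 150) == pytest.approx(0.5)
        assert cnv._reciprocal_overlap(0, 100, 0, 1000) == pytest.approx(0.1)
        assert cnv._reciprocal_overlap(0, 100, 100, 200) == 0.0


class TestComputeLrrBaf:
    def test_planted_copy_states_have_expected_lrr(self, cnv_cohort,
                                                   cnv_result):
        track = cnv_result.track
        sidx = {s: i for i, s in enumerate(track.sample_ids)}
        for ev in cnv_cohort.ledger.cnv_events:
            mask = ((track.chromosomes == ev["chromosome"])
                    & (track.positions >= ev["start"])
                    & (track.positions < ev["end"]))
            vals = track.lrr[sidx[ev["sample_id"]], mask]
            mean = np.nanmean(vals)
            if ev["copy_number"] == 0:
                assert mean < -1.1
            elif ev["copy_number"] == 1:
                assert -1.4 < mean < -0.6
            elif ev["copy_number"] == 3:
                assert 0.3 < mean < 0.9

    def test_baf_anchored_at_cluster_centers(self, cnv_result):
        track = cnv_result.track
        ok = ~np.isnan(track.baf)
        assert ((track.baf[ok] >= 0) & (track.baf[ok] <= 1)).all()
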