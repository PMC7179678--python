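"""Shared fixtures: simulated cohorts at the study conditions used across
the suite.  Session-scoped because cohort simulation plus full processing is
the expensive part of every end-to-end check."""

from __future__ import annotations

import numpy as np
import pytest

from pidarray import pipeline, simulate


def zero_noise_config(seed: int = 7) -> simulate.SimulationConfig:
    """1,000 probes x 60 samples with all noise sources off: downstream
    calling must be exact here."""
    return simulate.SimulationConfig(
        n_patients=35, n_controls=25,
        n_custom_probes=250, n_backbone_probes=750,
        noise_sd=0.0, intensity_cv=0.0,
        probe_failure_rate=0.0, sample_failure_rate=0.0,
        rare_variant_rate=1.0, seed=seed)


def cnv_study_events(manifest):
    """Planted CNV/LCSH events with exact probe counts, placed on backbone
    probe coordinates read from the manifest."""
    d = manifest.df
    lengths = simulate.genome_lengths()

    def span_of(chrom, first, n):
        pos = np.sort(d.loc[d["chromosome"] == chrom, "position"].to_numpy())
        return int(pos[first]) - 1, int(pos[first + n - 1]) + 2

    ev = []
    s, e = span_of("2", 30, 40)
    ev.append(simulate.CnvEvent("P001", "2", s, e, 0))      # 40-probe hom del
    s, e = span_of("3", 50, 10)
    ev.append(simulate.CnvEvent("P002", "3", s, e, 1))      # 10-probe loss
    ev.append(simulate.CnvEvent("P003", "8", 0, lengths["8"], 3))   # trisomy
    ev.append(simulate.CnvEvent("P004", "7", 0, lengths["7"], 1))   # monosomy
    s, e = span_of("4", 20, 3)
    ev.append(simulate.CnvEvent("P005", "4", s, e, 0))      # 3-probe del
    lcsh = [simulate.LcshEvent("P006", "5", 3_000_000, 13_000_000)]  # 10 Mb
    return tuple(ev), tuple(lcsh)


def cnv_config(seed: int = 5) -> simulate.SimulationConfig:
    manifest = simulate.synthetic_manifest(150, 3000, seed=0)
    events, lcsh = cnv_study_events(manifest)
    cfg = simulate.SimulationConfig(
        n_patients=12, n_controls=12,
        n_custom_probes=150, n_backbone_probes=3000,
        cnv_events=events, lcsh_events=lcsh,
        probe_failure_rate=0.0, sample_failure_rate=0.0, seed=seed)
    return cfg, manifest


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return simulate.simulate_cohort(zero_noise_config())


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_cohort):
    c = zero_noise_cohort
    return pipeline.process_run(c.run1, c.manifest, c.annotation,
                                c.benign_track, c.patient_ids, with_cnv=False)


@pytest.fixture(scope="session")
def cnv_cohort():
    cfg, manifest = cnv_config()
    return simulate.simulate_cohort(cfg, manifest=manifest)


@pytest.fixture(scope="session")
def cnv_result(cnv_cohort):
    c = cnv_cohort
    return pipeline.process_run(c.run1, c.manifest, c.annotation,
                                c.benign_track, c.patient_ids)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-noise two-run cohort at reduced size."""
    cfg = simulate.SimulationConfig(
        n_patients=30, n_controls=20,
        n_custom_probes=300, n_backbone_probes=2000, seed=11)
    return simulate.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_results(noisy_cohort):
    return pipeline.process_cohort(noisy_cohort, with_cnv=False)
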