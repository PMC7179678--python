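"""Shared study definition for the numbered analysis scripts.

One simulated screening experiment at the full study conditions: 95
patients + 56 controls, two array runs, desk-scale probe counts, and a set
of planted showcase events (a deep focal deletion, a single-copy loss, a
trisomy, a monosomy, and a 10 Mb run of homozygosity).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from pidarray import pipeline, simulate

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_SEED = 2024


def study_config(seed: int = STUDY_SEED) -> tuple:
    manifest = simulate.synthetic_manifest(600, 4000, seed=0)
    d = manifest.df
    lengths = simulate.genome_lengths()

    def span_of(chrom, first, n):
        pos = np.sort(d.loc[d["chromosome"] == chrom, "position"].to_numpy())
        return int(pos[first]) - 1, int(pos[first + n - 1]) + 2

    events = []
    s, e = span_of("2", 40, 40)
    events.append(simulate.CnvEvent("P001", "2", s, e, 0))
    s, e = span_of("3", 60, 10)
    events.append(simulate.CnvEvent("P002", "3", s, e, 1))
    events.append(simulate.CnvEvent("P003", "8", 0, lengths["8"], 3))
    events.append(simulate.CnvEvent("P004", "7", 0, lengths["7"], 1))
    lcsh = (simulate.LcshEvent("P006", "5", 3_000_000, 13_000_000),)
    cfg = simulate.SimulationConfig(cnv_events=tuple(events),
                                    lcsh_events=lcsh, seed=seed)
    return cfg, manifest


def load_cohort(seed: int = STUDY_SEED) -> simulate.SimulatedCohort:
    cfg, manifest = study_config(seed)
    return simulate.simulate_cohort(cfg, manifest=manifest)


def load_processed(seed: int = STUDY_SEED):
    cohort = load_cohort(seed)
    r1, r2 = pipeline.process_cohort(cohort)
    return cohort, r1, r2


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
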