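"""End-to-end orchestration of one array run: cluster fitting, primary
calling, QC with recalling, the SNV cascade, and CNV/LCSH/aneuploidy
screening.  The numbered analysis scripts and the acceptance checks drive
the pipeline through this module."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, cnv, qc, snv
from .manifest import BenignCnvTrack, ProbeManifest, VariantAnnotation
from .simulate import IntensityRun, SimulatedCohort


@dataclass
class RunResult:
    run: IntensityRun
    model: calling.ClusterModel
    primary: calling.GenotypeMatrix
    postqc: calling.GenotypeMatrix
    qc_report: qc.QcReport
    cascade: snv.CascadeResult
    track: cnv.BafLrrTrack
    segments: pd.DataFrame
    cnv_candidates: pd.DataFrame
    aneuploidy: pd.DataFrame
    lcsh: pd.DataFrame
    statuses: dict[str, str] = field(default_factory=dict)


def _subset_track(track: cnv.BafLrrTrack, sample_ids) -> cnv.BafLrrTrack:
    keep = np.isin(track.sample_ids, list(sample_ids))
    return cnv.BafLrrTrack(track.sample_ids[keep], track.probe_ids,
                           track.chromosomes, track.positions,
                           track.lrr[keep], track.baf[keep])


def combine_diagnoses(snv_statuses: dict[str, str],
                      cnv_candidates: pd.DataFrame,
                      aneuploidy: pd.DataFrame) -> dict[str, str]:
    """A patient is diagnosed by the screen when the SNV cascade or a
    retained CNV finding (including whole-chromosome events) supports it."""
    statuses = dict(snv_statuses)
    cnv_hits = set(cnv_candidates["sample_id"]) if len(cnv_candidates) else set()
    aneu_hits = set(aneuploidy["sample_id"]) if len(aneuploidy) else set()
    for sid in cnv_hits | aneu_hits:
        if sid in statuses:
            statuses[sid] = "genetic_diagnosis"
    return statuses


def process_run(run: IntensityRun, manifest: ProbeManifest,
                annotation: VariantAnnotation, benign: BenignCnvTrack,
                patient_ids,
                thresholds: qc.QcThresholds = qc.QcThresholds(),
                cnv_params: cnv.CnvCallingParams = cnv.CnvCallingParams(),
                zcall_z: float = calling.DEFAULT_ZCALL_Z,
                nocall_threshold: float = calling.DEFAULT_NOCALL_THRESHOLD,
                with_cnv: bool = True) -> RunResult:
    """Process one intensity run through the full screen."""
    model = calling.fit_clusters(run.x, run.y, run.probe_ids)
    primary = calling.primary_call(model, run.x, run.y, run.sample_ids,
                                   nocall_threshold=nocall_threshold)
    postqc, report = qc.apply_qc(primary, model, run.x, run.y, manifest,
                                 thresholds=thresholds, zcall_z=zcall_z)
    cascade = snv.run_snv_cascade(postqc, manifest, annotation,
                                  report.inferred_sex, model, run,
                                  patient_ids)

    if with_cnv:
        track = cnv.compute_lrr_baf(run, model, manifest)
        track = _subset_track(track, postqc.sample_ids)
        segments = cnv.segment(track, cnv_params)
        aneuploidy = cnv.detect_aneuploidy(track, cnv_params)
        # whole-chromosome events are reported separately, not as focal CNVs
        aneu_keys = set(zip(aneuploidy.get("sample_id", []),
                            aneuploidy.get("chromosome", [])))
        if len(segments):
            focal = np.array([(r.sample_id, r.chromosome) not in aneu_keys
                              for r in segments.itertuples(index=False)])
            segments_focal = segments[focal].reset_index(drop=True)
        else:
            segments_focal = segments
        lcsh = cnv.detect_lcsh(track, postqc, cnv_params)
        cnv_cands = cnv.filter_cnvs(segments_focal, manifest.gene_track(),
                                    benign, cnv_params)
    else:
        track = None
        segments = aneuploidy = lcsh = cnv_cands = pd.DataFrame()

    statuses = combine_diagnoses(
        cascade.statuses,
        cnv_cands[cnv_cands["sample_id"].isin(patient_ids)]
        if len(cnv_cands) else pd.DataFrame(columns=["sample_id"]),
        aneuploidy[aneuploidy["sample_id"].isin(patient_ids)]
        if len(aneuploidy) else pd.DataFrame(columns=["sample_id"]))

    return RunResult(run, model, primary, postqc, report, cascade, track,
                     segments, cnv_cands, aneuploidy, lcsh, statuses)


def process_cohort(cohort: SimulatedCohort, with_cnv: bool = True,
                   **kwargs) -> tuple[RunResult, RunResult]:
    """Process both runs of a simulated cohort."""
    r1 = process_run(cohort.run1, cohort.manifest, cohort.annotation,
                     cohort.benign_track, cohort.patient_ids,
                     with_cnv=with_cnv, **kwargs)
    r2 = process_run(cohort.run2, cohort.manifest, cohort.annotation,
                     cohort.benign_track, cohort.patient_ids,
                     with_cnv=with_cnv, **kwargs)
    return r1, r2
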