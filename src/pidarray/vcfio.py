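"""Plain-text writers: VCF 4.2 for genotypes, SEG/BED for CNV segments.

Internal coordinates are 0-based half-open; the +1 conversion to VCF's
1-based positions happens here and nowhere else.  SEG and BED stay 0-based
half-open.  Headers carry no timestamps, so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .calling import GenotypeMatrix
from .manifest import CHROM_ORDER, ProbeManifest

_GT_FIELD = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(calls: GenotypeMatrix, manifest: ProbeManifest, path) -> None:
    """Write called genotypes as VCF 4.2 with GT and SC (confidence score)
    per call.  Probes absent from the manifest raise."""
    info = manifest.positions_of(calls.probe_ids)
    order = np.lexsort((info["position"].to_numpy(),
                        info["chromosome"].map(CHROM_ORDER).to_numpy()))
    samples = list(calls.sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pidarray\n")
        seen = []
        for c in info["chromosome"].iloc[order]:
            if c not in seen:
                seen.append(c)
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write('##FORMAT=<ID=SC,Number=1,Type=Float,'
                 'Description="Call confidence score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in order:
            row = info.iloc[j]
            ref = row["ref_allele"] if row["ref_allele"] not in ("I", "D") \
                else "N"
            alt = row["alt_allele"] if row["alt_allele"] not in ("I", "D") \
                else "<INDEL>"
            fields = [row["chromosome"], str(int(row["position"]) + 1),
                      row["probe_id"], ref, alt, ".", "PASS", ".", "GT:SC"]
            col = calls.probe_index([row["probe_id"]])[0]
            for si in range(calls.n_samples):
                gt = _GT_FIELD[int(calls.calls[si, col])]
                sc = calls.scores[si, col]
                sc_s = "." if np.isnan(sc) else f"{sc:.3f}"
                fields.append(f"{gt}:{sc_s}")
            fh.write("\t".join(fields) + "\n")


def write_seg(segments: pd.DataFrame, path) -> None:
    """SEG-style table: sample, chrom, start, end, n_probes, mean_log2,
    event, p_value (0-based half-open)."""
    cols = ["sample_id", "chromosome", "start", "end", "n_probes",
            "mean_log2", "event"]
    if "p_value" in segments.columns:
        cols.append("p_value")
    out = segments[cols].copy()
    if "mean_log2" in out:
        out["mean_log2"] = out["mean_log2"].map(lambda v: f"{v:.4f}")
    if "p_value" in out:
        out["p_value"] = out["p_value"].map(lambda v: f"{v:.3e}")
    out.to_csv(path, sep="\t", index=False)


def write_bed(segments: pd.DataFrame, path) -> None:
    """BED of events: chrom, start, end, sample:event (0-based half-open)."""
    with open(path, "w") as fh:
        for r in segments.itertuples(index=False):
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t"
                     f"{r.sample_id}:{r.event}\n")


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting via repr."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
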