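#!/usr/bin/env python
"""CNV screening of run 1: LRR/BAF computation, segmentation, aneuploidy
and LCSH detection, and the disease-gene/benign-overlap/frequency filters.
Writes SEG/BED tables and a findings JSON."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_processed, outdir

from pidarray import vcfio


def main() -> None:
    cohort, r1, _r2 = load_processed()
    out = outdir("05_cnv")

    vcfio.write_seg(r1.segments, out / "segments.seg")
    vcfio.write_bed(r1.segments, out / "segments.bed")
    vcfio.write_seg(r1.cnv_candidates, out / "filtered_cnvs.seg")
    vcfio.write_json({
        "aneuploidy": r1.aneuploidy.to_dict(orient="records"),
        "lcsh": r1.lcsh.to_dict(orient="records"),
    }, out / "chromosomal_findings.json")

    print(f"raw segments called: {len(r1.segments)}; "
          f"after gene/benign/frequency filters: {len(r1.cnv_candidates)}")
    for r in r1.aneuploidy.itertuples(index=False):
        print(f"  whole-chromosome: {r.sample_id} chr{r.chromosome} "
              f"{r.event} (median LRR {r.median_lrr:.2f})")
    burden = r1.lcsh.groupby("sample_id")["end"].count() if len(r1.lcsh) \
        else {}
    for r in r1.lcsh.itertuples(index=False):
        size_mb = (r.end - r.start) / 1e6
        print(f"  LCSH: {r.sample_id} chr{r.chromosome} {size_mb:.1f} Mb "
              f"({r.n_probes} probes)")
    print(f"wrote CNV screen to {out}")


if __name__ == "__main__":
    main()
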