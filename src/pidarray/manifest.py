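"""Probe manifest, variant annotation, truth genotypes and benign-CNV track.

The manifest describes a customised genotyping array: a genome-wide SNP
*backbone* plus *custom* probes targeting known pathogenic variants (SNVs and
small INDELs) in primary-immunodeficiency (PID) genes.  All genomic
coordinates are 0-based half-open internally; conversion to 1-based happens
only at the VCF boundary (see :mod:`pidarray.vcfio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}
AUTOSOMES = frozenset(str(i) for i in range(1, 23))

PROBE_CLASSES = ("custom_pid_snv", "custom_pid_indel", "backbone")
MANIFEST_COLUMNS = ("probe_id", "chromosome", "position", "ref_allele",
                    "alt_allele", "gene", "probe_class")

PATHOGENICITY = ("disease_causing", "likely_benign", "benign")
INHERITANCE = ("AD", "AR", "XL", "none")


class ManifestError(ValueError):
    """Raised when a manifest or annotation table violates an invariant."""


def _chrom_sort_key(chroms: pd.Series) -> pd.Series:
    unknown = ~chroms.isin(CHROM_ORDER)
    if unknown.any():
        bad = sorted(chroms[unknown].unique())
        raise ManifestError(f"unknown chromosome label(s): {bad}")
    return chroms.map(CHROM_ORDER)


@dataclass
class ProbeManifest:
    """Sorted, validated table of array probes.

    ``df`` columns: probe_id, chromosome, position, ref_allele, alt_allele,
    gene, probe_class.  Rows are sorted by (chromosome, position) and probe
    ids are unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        dup = df["probe_id"][df["probe_id"].duplicated()]
        if len(dup):
            raise ManifestError(f"duplicate probe_id: {dup.iloc[0]!r}")
        if (df["position"] < 0).any():
            raise ManifestError("negative probe position")
        bad_class = set(df["probe_class"].unique()) - set(PROBE_CLASSES)
        if bad_class:
            raise ManifestError(f"unknown probe_class: {sorted(bad_class)}")
        key = _chrom_sort_key(df["chromosome"])
        order = np.lexsort((df["position"].to_numpy(), key.to_numpy()))
        df = df.iloc[order].reset_index(drop=True)
        df["gene"] = df["gene"].fillna("")
        self.df = df
        self._index = pd.Index(df["probe_id"])

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.df["probe_id"].to_numpy()

    def class_counts(self) -> dict[str, int]:
        counts = self.df["probe_class"].value_counts().to_dict()
        counts["custom"] = (counts.get("custom_pid_snv", 0)
                            + counts.get("custom_pid_indel", 0))
        return counts

    def positions_of(self, probe_ids) -> pd.DataFrame:
        idx = self._index.get_indexer(probe_ids)
        if (idx < 0).any():
            bad = np.asarray(probe_ids)[idx < 0][0]
            raise ManifestError(f"probe not in manifest: {bad!r}")
        return self.df.iloc[idx]

    def mask(self, *, chromosome: str | None = None,
             probe_class: str | None = None,
             custom: bool | None = None) -> np.ndarray:
        m = np.ones(len(self.df), dtype=bool)
        if chromosome is not None:
            m &= (self.df["chromosome"] == chromosome).to_numpy()
        if probe_class is not None:
            m &= (self.df["probe_class"] == probe_class).to_numpy()
        if custom is not None:
            is_custom = self.df["probe_class"].str.startswith("custom").to_numpy()
            m &= is_custom if custom else ~is_custom
        return m

    def gene_track(self) -> pd.DataFrame:
        """Per-gene interval spanned by its custom probes (0-based half-open)."""
        custom = self.df[self.mask(custom=True) & (self.df["gene"] != "")]
        g = custom.groupby("gene", sort=True).agg(
            chromosome=("chromosome", "first"),
            start=("position", "min"),
            end=("position", "max"),
        ).reset_index()
        g["end"] = g["end"] + 1
        return g


def read_manifest(path) -> ProbeManifest:
    """Read a CSV probe manifest; validates, sorts, and returns it."""
    df = pd.read_csv(path, dtype={"chromosome": str, "gene": str},
                     keep_default_na=False, na_values=[])
    df["position"] = df["position"].astype(np.int64)
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path) -> None:
    manifest.df.to_csv(path, index=False)


@dataclass
class VariantAnnotation:
    """Pathogenicity / population-frequency / inheritance table.

    Emulates the databases a diagnostic lab queries: a curated pathogenicity
    class (HGMD-like ``disease_causing``), a population allele frequency
    (gnomAD-like) and a per-gene Mendelian inheritance pattern (OMIM-like).
    """

    df: pd.DataFrame  # probe_id, pathogenicity, pop_frequency, inheritance

    def __post_init__(self) -> None:
        df = self.df
        f = df["pop_frequency"]
        if ((f < 0) | (f > 1)).any():
            raise ManifestError("pop_frequency outside [0, 1]")
        bad = set(df["pathogenicity"].unique()) - set(PATHOGENICITY)
        if bad:
            raise ManifestError(f"unknown pathogenicity class: {sorted(bad)}")
        bad = set(df["inheritance"].unique()) - set(INHERITANCE)
        if bad:
            raise ManifestError(f"unknown inheritance pattern: {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def validate_against(self, manifest: ProbeManifest) -> None:
        known = set(manifest.df["probe_id"])
        orphans = set(self.df["probe_id"]) - known
        if orphans:
            raise ManifestError(
                f"annotation refers to unknown probes: {sorted(orphans)[:5]}")

    def lookup(self, probe_ids) -> pd.DataFrame:
        """Annotation rows aligned to ``probe_ids``; NaN rows where absent."""
        idx = self.df.set_index("probe_id")
        return idx.reindex(probe_ids)


def read_annotation(path) -> VariantAnnotation:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    df["pop_frequency"] = df["pop_frequency"].astype(float)
    return VariantAnnotation(df)


def write_annotation(annotation: VariantAnnotation, path) -> None:
    annotation.df.to_csv(path, index=False)


@dataclass
class TruthGenotypes:
    """Long-form truth genotypes (emulating deep-WGS calls) on the manifest
    allele frame: genotype in {AA, AB, BB, missing}."""

    df: pd.DataFrame  # sample_id, probe_id, genotype

    def __post_init__(self) -> None:
        if self.df.duplicated(["sample_id", "probe_id"]).any():
            raise ManifestError("duplicate (sample, probe) truth record")
        bad = set(self.df["genotype"].unique()) - {"AA", "AB", "BB", "missing"}
        if bad:
            raise ManifestError(f"unknown truth genotype: {sorted(bad)}")

    def to_codes(self, sample_ids, probe_ids) -> np.ndarray:
        """Dense (sample, probe) int8 matrix: AA=0 AB=1 BB=2 missing=-1."""
        code = {"AA": 0, "AB": 1, "BB": 2, "missing": -1}
        wide = (self.df.assign(code=self.df["genotype"].map(code))
                .pivot(index="sample_id", columns="probe_id", values="code")
                .reindex(index=sample_ids, columns=probe_ids))
        return wide.fillna(-1).to_numpy(dtype=np.int8)


def read_truth(path) -> TruthGenotypes:
    return TruthGenotypes(pd.read_csv(path))


def write_truth(truth: TruthGenotypes, path) -> None:
    truth.df.to_csv(path, index=False)


@dataclass
class BenignCnvTrack:
    """Known benign copy-number intervals (0-based half-open); emulates a
    curated common-CNV database used to discard polymorphic events."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chromosome", "start", "end", "zygosity"]))

    def __post_init__(self) -> None:
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            raise ManifestError("benign interval with start >= end")

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval on the chromosome."""
        d = self.df
        hit = ((d["chromosome"] == chromosome)
               & (d["start"] < end) & (d["end"] > start))
        return bool(hit.any())


def read_benign_track(path) -> BenignCnvTrack:
    df = pd.read_csv(path, dtype={"chromosome": str})
    return BenignCnvTrack(df)
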