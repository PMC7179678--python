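"""Synthetic array-cohort generator with a complete planted-truth ledger.

Emulates a two-run custom-array screening study: a patient cohort carrying
rare planted pathogenic genotypes, a control cohort with deep-sequencing
truth genotypes, three-cluster two-channel intensity structure per biallelic
probe, probe/sample failures, copy-number events (including whole-chromosome
aneuploidy), long contiguous stretches of homozygosity (LCSH), and a second
technical replicate run over the same truth.

The genome is a 1/10-scale human karyotype so that desk-scale backbone probe
counts reproduce the per-megabase probe density that CNV and LCSH calling
depend on.  Every planted event is recorded in the ledger, which downstream
tests use as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import GT_NAME
from .manifest import BenignCnvTrack, ProbeManifest, TruthGenotypes, VariantAnnotation

# GRCh37 chromosome lengths (bp), scaled down by GENOME_SCALE
_GRCH37 = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}
GENOME_SCALE = 10


def genome_lengths(scale: int = GENOME_SCALE) -> dict[str, int]:
    return {c: length // scale for c, length in _GRCH37.items()}


@dataclass(frozen=True)
class CnvEvent:
    """A planted copy-number event (0-based half-open interval)."""
    sample_id: str
    chromosome: str
    start: int
    end: int
    copy_number: int  # 0..4; 1/3 on a whole chromosome = monosomy/trisomy


@dataclass(frozen=True)
class LcshEvent:
    """A planted run of homozygosity at normal copy number."""
    sample_id: str
    chromosome: str
    start: int
    end: int


@dataclass
class SimulationConfig:
    """Study conditions for one simulated screening experiment.

    Defaults mirror a two-run screening cohort of 95 patients and 56
    controls at desk-scale probe counts; rates are fractions in [0, 1].
    """

    n_patients: int = 95
    n_controls: int = 56
    n_custom_probes: int = 600
    n_backbone_probes: int = 4000
    rare_variant_rate: float = 2.0       # incidental rare het carriers / sample
    cluster_separation: float = 0.45     # angular distance between clusters
    noise_sd: float = 0.04               # intra-cluster angular spread
    probe_failure_rate: float = 0.01
    sample_failure_rate: float = 0.02
    cnv_events: tuple[CnvEvent, ...] = ()
    lcsh_events: tuple[LcshEvent, ...] = ()
    seed: int = 0
    # secondary knobs (see docs/methods.md)
    hom_noise_fraction: float = 0.15     # hom clusters are tighter than hets
    intensity_cv: float = 0.12           # lognormal sd of total intensity
    baseline_intensity: float = 2000.0
    baseline_log_sd: float = 0.25
    compound_het_fraction: float = 0.3   # AR diagnoses planted as 2 hets
    annotation_coverage: float = 0.95    # custom probes with annotation rows
    benign_custom_fraction: float = 0.15 # custom probes that are common/benign
    n_genes: int = 277
    run2_exclude: tuple[str, ...] = ()   # samples not re-assayed in run 2

    def __post_init__(self) -> None:
        for name in ("rare_variant_rate",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("probe_failure_rate", "sample_failure_rate",
                     "annotation_coverage", "benign_custom_fraction",
                     "compound_het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.cluster_separation <= 0.5:
            raise ValueError("cluster_separation must be in (0, 0.5]")


@dataclass
class IntensityRun:
    """Two-channel raw intensities for one array run (samples x probes)."""

    run_id: str
    sample_ids: np.ndarray
    probe_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.probe_ids = np.asarray(self.probe_ids)
        shape = (len(self.sample_ids), len(self.probe_ids))
        if self.x.shape != shape or self.y.shape != shape:
            raise ValueError("intensity matrices do not match ids")
        if (self.x < 0).any() or (self.y < 0).any():
            raise ValueError("negative intensities")


@dataclass
class PlantLedger:
    """Complete, exclusive inventory of everything that was planted."""

    planted_snvs: pd.DataFrame       # sample_id, probe_id, genotype, causal,
                                     # gene, inheritance
    causal_by_patient: dict[str, list[str]]  # patient -> causal probe ids
    cnv_events: list[dict]           # planted event + n_probes + sub_detectable
    lcsh_events: list[dict]
    failed_samples: dict[str, list[str]]
    failed_probes: dict[str, list[str]]


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    manifest: ProbeManifest
    annotation: VariantAnnotation
    truth: TruthGenotypes
    sexes: dict[str, str]            # sample -> male / female
    run1: IntensityRun
    run2: IntensityRun
    ledger: PlantLedger
    benign_track: BenignCnvTrack

    @property
    def patient_ids(self) -> list[str]:
        return [s for s in self.run1.sample_ids if s.startswith("P")]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.run1.sample_ids if s.startswith("C")]


_BASES = np.array(list("ACGT"))


def synthetic_manifest(n_custom: int = 9415, n_backbone: int = 696_375,
                       n_genes: int = 277, seed: int = 0,
                       indel_fraction: float = 0.2,
                       scale: int = GENOME_SCALE) -> ProbeManifest:
    """Build a probe manifest emulating a customised screening array:
    ``n_custom`` probes inside ``n_genes`` disease genes plus a genome-wide
    SNP backbone of ``n_backbone`` probes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11E1E]))
    lengths = genome_lengths(scale)
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    # X is double-weighted: arrays carry dense X content so that sex can be
    # inferred from X heterozygosity even at modest total probe counts
    weights[chroms.index("X")] *= 2
    weights /= weights.sum()

    # disease genes: fixed-width loci scattered proportionally to length
    gene_width = 2_000_000 // scale
    gene_chrom = rng.choice(len(chroms), size=n_genes, p=weights)
    gene_rows = []
    for i in range(n_genes):
        c = chroms[gene_chrom[i]]
        start = int(rng.integers(0, max(1, lengths[c] - gene_width)))
        gene_rows.append((f"PIDG{i + 1:03d}", c, start, start + gene_width))
    genes = pd.DataFrame(gene_rows,
                         columns=["gene", "chromosome", "start", "end"])

    # custom probes: round-robin across genes, unique positions inside loci
    gi = np.arange(n_custom) % n_genes
    rows = []
    for k in range(n_custom):
        g = genes.iloc[gi[k]]
        pos = int(rng.integers(g["start"], g["end"]))
        is_indel = rng.random() < indel_fraction
        if is_indel:
            ref, alt = "I", "D"
            cls = "custom_pid_indel"
        else:
            ref, alt = rng.choice(4, size=2, replace=False)
            ref, alt = _BASES[ref], _BASES[alt]
            cls = "custom_pid_snv"
        rows.append((f"cust{k + 1:06d}", g["chromosome"], pos, ref, alt,
                     g["gene"], cls))

    # backbone: near-even spacing with jitter, so no pathological gaps;
    # largest-remainder apportionment keeps the total exact
    ideal = weights * n_backbone
    alloc = np.floor(ideal).astype(int)
    short = n_backbone - alloc.sum()
    for ci in np.argsort(-(ideal - alloc))[:short]:
        alloc[ci] += 1
    k = 0
    for ci, c in enumerate(chroms):
        n = int(alloc[ci])
        if n == 0:
            continue
        spacing = lengths[c] / (n + 1)
        base = (np.arange(1, n + 1) * spacing)
        jitter = rng.uniform(-0.3, 0.3, size=n) * spacing
        pos = np.clip((base + jitter).astype(np.int64), 0, lengths[c] - 1)
        ref_i = rng.integers(0, 4, size=n)
        alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
        for j in range(n):
            rows.append((f"bb{k + j + 1:06d}", c, int(pos[j]),
                         _BASES[ref_i[j]], _BASES[alt_i[j]], "", "backbone"))
        k += n

    df = pd.DataFrame(rows, columns=["probe_id", "chromosome", "position",
                                     "ref_allele", "alt_allele", "gene",
                                     "probe_class"])
    # de-duplicate coincident positions deterministically
    df["position"] += df.groupby(["chromosome", "position"]).cumcount()
    return ProbeManifest(df)


def _synthetic_annotation(manifest: ProbeManifest, config: SimulationConfig,
                          rng: np.random.Generator) -> VariantAnnotation:
    custom = manifest.df[manifest.mask(custom=True)]
    covered = rng.random(len(custom)) < config.annotation_coverage
    custom = custom[covered]

    # inheritance pattern is a per-gene property: X-linked on X, AD/AR split
    # on the autosomes
    genes = sorted(custom["gene"].unique())
    gene_chrom = dict(zip(custom["gene"], custom["chromosome"]))
    inh_by_gene = {}
    for g in genes:
        if gene_chrom[g] == "X":
            inh_by_gene[g] = "XL"
        else:
            inh_by_gene[g] = "AD" if rng.random() < 0.5 else "AR"

    n = len(custom)
    benign = rng.random(n) < config.benign_custom_fraction
    patho = np.where(benign, "benign", "disease_causing").astype(object)
    likely = (~benign) & (rng.random(n) < 0.05)
    patho[likely] = "likely_benign"
    freq = np.where(benign | likely,
                    rng.uniform(0.02, 0.4, size=n),
                    10 ** rng.uniform(-5, -2.5, size=n))
    df = pd.DataFrame({
        "probe_id": custom["probe_id"].to_numpy(),
        "pathogenicity": patho,
        "pop_frequency": freq,
        "inheritance": custom["gene"].map(inh_by_gene).to_numpy(),
    })
    return VariantAnnotation(df)


def _event_probe_mask(manifest: ProbeManifest, chromosome: str,
                      start: int, end: int) -> np.ndarray:
    d = manifest.df
    return ((d["chromosome"] == chromosome)
            & (d["position"] >= start) & (d["position"] < end)).to_numpy()


def _plant_truth(config: SimulationConfig, manifest: ProbeManifest,
                 annotation: VariantAnnotation, sample_ids: np.ndarray,
                 sexes: dict[str, str], rng: np.random.Generator):
    """Build truth genotypes G, copy-number matrix C, true B-allele fraction
    matrix, and the planted-SNV ledger."""
    n_s, n_p = len(sample_ids), len(manifest)
    d = manifest.df
    is_x = (d["chromosome"] == "X").to_numpy()
    is_custom = manifest.mask(custom=True)
    male = np.array([sexes[s] == "male" for s in sample_ids])

    ann = annotation.lookup(d["probe_id"])
    alt_freq = np.zeros(n_p)
    backbone = ~is_custom
    alt_freq[backbone] = rng.uniform(0.05, 0.95, size=int(backbone.sum()))
    common_custom = is_custom & (ann["pathogenicity"].isin(
        ["benign", "likely_benign"]).to_numpy())
    alt_freq[common_custom] = ann["pop_frequency"].to_numpy()[common_custom]
    polymorphic = backbone | common_custom

    # base genotypes: HWE at polymorphic probes; hom-ref at disease probes
    u = rng.random((n_s, n_p))
    q = alt_freq[None, :]
    hw_aa = (1 - q) ** 2
    hw_ab = 2 * q * (1 - q)
    G_poly = np.where(u < hw_aa, 0, np.where(u < hw_aa + hw_ab, 1, 2))
    G = np.where(polymorphic[None, :], G_poly, 0).astype(np.int8)
    # hemizygous males on X: single allele, coded as a homozygote
    male_x = male[:, None] & is_x[None, :] & polymorphic[None, :]
    G_hemi = np.where(rng.random((n_s, n_p)) < q, 2, 0)
    G = np.where(male_x, G_hemi, G).astype(np.int8)

    # planted LCSH: force homozygosity, allele drawn at the population freq
    lcsh_records = []
    s_index = {s: i for i, s in enumerate(sample_ids)}
    for ev in config.lcsh_events:
        pm = _event_probe_mask(manifest, ev.chromosome, ev.start, ev.end)
        si = s_index[ev.sample_id]
        hom = np.where(rng.random(int(pm.sum())) < alt_freq[pm], 2, 0)
        G[si, pm] = hom
        lcsh_records.append({
            "sample_id": ev.sample_id, "chromosome": ev.chromosome,
            "start": ev.start, "end": ev.end, "n_probes": int(pm.sum()),
        })

    # causal planting: one diagnosis-compatible configuration per patient,
    # each at probes no other sample carries
    probe_ids = d["probe_id"].to_numpy()
    gene_arr = d["gene"].to_numpy()
    disease = is_custom & (ann["pathogenicity"] == "disease_causing").to_numpy()
    rare = disease & (ann["pop_frequency"].to_numpy() < 0.005)
    inh_arr = ann["inheritance"].to_numpy(dtype=object)

    pool_by_gene: dict[str, list[int]] = {}
    for j in np.flatnonzero(rare):
        pool_by_gene.setdefault(gene_arr[j], []).append(int(j))
    genes_cycle = sorted(g for g, idxs in pool_by_gene.items() if idxs)

    planted = []
    causal_by_patient: dict[str, list[str]] = {}
    patients = [s for s in sample_ids if s.startswith("P")]
    used: set[int] = set()
    gpos = 0
    for pat in patients:
        si = s_index[pat]
        chosen = None
        for _ in range(len(genes_cycle)):
            g = genes_cycle[gpos % len(genes_cycle)]
            gpos += 1
            free = [j for j in pool_by_gene[g] if j not in used]
            if not free:
                continue
            inh = inh_arr[free[0]]
            # X-linked disease is planted in males only (hemizygous
            # presentation dominates X-linked Mendelian disease)
            if inh == "XL" and not male[si]:
                continue
            chosen = (g, inh, free)
            break
        if chosen is None:
            causal_by_patient[pat] = []
            continue
        g, inh, free = chosen
        if inh == "AD":
            j = free[0]
            G[si, j] = 1
            plan = [(j, 1)]
        elif inh == "AR":
            if len(free) >= 2 and rng.random() < config.compound_het_fraction:
                plan = [(free[0], 1), (free[1], 1)]
            else:
                plan = [(free[0], 2)]
            for j, gt in plan:
                G[si, j] = gt
        else:  # XL: hemizygous male
            j = free[0]
            G[si, j] = 2
            plan = [(j, 2)]
        for j, gt in plan:
            used.add(j)
            planted.append({
                "sample_id": pat, "probe_id": probe_ids[j],
                "genotype": GT_NAME[gt], "causal": True,
                "gene": gene_arr[j], "inheritance": inh,
            })
        causal_by_patient[pat] = [probe_ids[j] for j, _ in plan]

    # incidental rare carriers: recessive-gene heterozygotes on autosomes,
    # never at a probe already used causally
    incidental_pool = [j for j in np.flatnonzero(rare)
                       if inh_arr[j] == "AR" and not is_x[j]
                       and j not in used]
    for s in sample_ids:
        si = s_index[s]
        k = rng.poisson(config.rare_variant_rate)
        if k == 0 or not incidental_pool:
            continue
        picks = rng.choice(len(incidental_pool),
                           size=min(k, len(incidental_pool)), replace=False)
        for idx in picks:
            j = incidental_pool[idx]
            if G[si, j] != 0:
                continue
            G[si, j] = 1
            planted.append({
                "sample_id": s, "probe_id": probe_ids[j],
                "genotype": "AB", "causal": False,
                "gene": gene_arr[j], "inheritance": inh_arr[j],
            })

    # copy-number matrix and the true allelic fraction seen by the array
    C = np.full((n_s, n_p), 2, dtype=np.int8)
    cnv_records = []
    for ev in config.cnv_events:
        pm = _event_probe_mask(manifest, ev.chromosome, ev.start, ev.end)
        si = s_index[ev.sample_id]
        C[si, pm] = ev.copy_number
        cnv_records.append({
            "sample_id": ev.sample_id, "chromosome": ev.chromosome,
            "start": ev.start, "end": ev.end,
            "copy_number": ev.copy_number, "n_probes": int(pm.sum()),
            "sub_detectable": bool(pm.sum() < 4),
        })

    BAF = np.where(G == 1, 0.5, G / 2.0)
    # trisomy: AB sites become AAB (1/3) or ABB (2/3); monosomy: one allele
    tri_het = (C == 3) & (G == 1)
    BAF = np.where(tri_het,
                   np.where(rng.random((n_s, n_p)) < 0.5, 1 / 3, 2 / 3), BAF)
    mono_het = (C == 1) & (G == 1)
    BAF = np.where(mono_het,
                   np.where(rng.random((n_s, n_p)) < 0.5, 0.0, 1.0), BAF)
    BAF = np.where(C == 0, np.nan, BAF)

    snv_df = pd.DataFrame(planted, columns=["sample_id", "probe_id",
                                            "genotype", "causal", "gene",
                                            "inheritance"])
    return G, C, BAF, snv_df, causal_by_patient, cnv_records, lcsh_records


def _render_run(run_id: str, sample_ids: np.ndarray, probe_ids: np.ndarray,
                config: SimulationConfig, baseline: np.ndarray,
                C: np.ndarray, BAF: np.ndarray, rng: np.random.Generator):
    """Turn copy number + allelic fraction into noisy two-channel signals."""
    n_s, n_p = BAF.shape
    sep = config.cluster_separation

    angle = 0.5 + (BAF - 0.5) * 2 * sep
    # allelic-fraction noise is largest for heterozygous points; homozygote
    # clusters sit on channel background and stay tight
    het_like = (BAF > 0.0) & (BAF < 1.0)
    sd = np.where(het_like, config.noise_sd,
                  config.hom_noise_fraction * config.noise_sd)
    angle = angle + sd * rng.standard_normal((n_s, n_p))
    # copy-0 points carry only background signal at an arbitrary angle
    angle = np.where(np.isnan(BAF), rng.uniform(0, 1, size=(n_s, n_p)), angle)

    dosage = np.where(C == 0, 0.05, C / 2.0)
    lognoise = (rng.normal(0, config.intensity_cv, size=(n_s, n_p))
                if config.intensity_cv > 0 else np.zeros((n_s, n_p)))
    total = baseline[None, :] * dosage * np.exp(lognoise)

    failed_samples = sorted(
        sample_ids[rng.random(n_s) < config.sample_failure_rate])
    failed_probes_mask = rng.random(n_p) < config.probe_failure_rate
    fs_mask = np.isin(sample_ids, failed_samples)[:, None]
    fail = fs_mask | failed_probes_mask[None, :]
    scramble = fail & (rng.random((n_s, n_p)) < 0.6)
    angle = np.where(scramble, rng.uniform(0, 1, size=(n_s, n_p)), angle)
    angle = np.where(fail & ~scramble,
                     angle + rng.normal(0, 4 * max(config.noise_sd, 0.05),
                                        size=(n_s, n_p)),
                     angle)
    total = np.where(fail, total * np.exp(rng.normal(0, 0.5, size=(n_s, n_p))),
                     total)
    angle = np.clip(angle, 0.0, 1.0)

    half = np.pi / 2
    c, s = np.cos(angle * half), np.sin(angle * half)
    x = total * c / (c + s)
    y = total * s / (c + s)
    return (IntensityRun(run_id, sample_ids, probe_ids, x, y),
            failed_samples, failed_probes_mask)


def _synthetic_benign_track(manifest: ProbeManifest,
                            rng: np.random.Generator,
                            n_intervals: int = 30) -> BenignCnvTrack:
    lengths = genome_lengths()
    chroms = list(lengths)
    rows = []
    for _ in range(n_intervals):
        c = chroms[int(rng.integers(0, len(chroms)))]
        width = int(rng.integers(20_000, 200_000))
        start = int(rng.integers(0, max(1, lengths[c] - width)))
        zyg = "het" if rng.random() < 0.8 else "hom"
        rows.append((c, start, start + width, zyg))
    return BenignCnvTrack(pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "zygosity"]))


def simulate_cohort(config: SimulationConfig,
                    manifest: ProbeManifest | None = None) -> SimulatedCohort:
    """Generate a full two-run cohort with planted truth.

    Returns runs over overlapping samples (run 2 re-noises the same truth,
    minus ``config.run2_exclude``), truth genotypes for every sample, and a
    ledger that inventories every planted SNV, CNV, LCSH region and failure.
    """
    ss = np.random.SeedSequence(config.seed)
    (ss_manifest, ss_ann, ss_truth, ss_base,
     ss_run1, ss_run2, ss_benign) = ss.spawn(7)

    if manifest is None:
        manifest = synthetic_manifest(
            n_custom=config.n_custom_probes,
            n_backbone=config.n_backbone_probes,
            n_genes=config.n_genes,
            seed=int(ss_manifest.generate_state(1)[0] % (2**31)))

    rng_ann = np.random.default_rng(ss_ann)
    rng_truth = np.random.default_rng(ss_truth)
    rng_base = np.random.default_rng(ss_base)

    sample_ids = np.array(
        [f"P{i + 1:03d}" for i in range(config.n_patients)]
        + [f"C{i + 1:03d}" for i in range(config.n_controls)])
    sexes = {s: ("male" if rng_truth.random() < 0.5 else "female")
             for s in sample_ids}

    annotation = _synthetic_annotation(manifest, config, rng_ann)
    (G, C, BAF, snv_df, causal_by_patient,
     cnv_records, lcsh_records) = _plant_truth(
        config, manifest, annotation, sample_ids, sexes, rng_truth)

    baseline = config.baseline_intensity * np.exp(
        rng_base.normal(0, config.baseline_log_sd, size=len(manifest)))

    run1, fail_s1, fail_p1 = _render_run(
        "run1", sample_ids, manifest.probe_ids, config, baseline, C, BAF,
        np.random.default_rng(ss_run1))

    keep2 = ~np.isin(sample_ids, list(config.run2_exclude))
    run2, fail_s2, fail_p2 = _render_run(
        "run2", sample_ids[keep2], manifest.probe_ids, config, baseline,
        C[keep2], BAF[keep2], np.random.default_rng(ss_run2))

    probe_ids = manifest.probe_ids
    truth_long = pd.DataFrame({
        "sample_id": np.repeat(sample_ids, len(probe_ids)),
        "probe_id": np.tile(probe_ids, len(sample_ids)),
        "genotype": np.vectorize(GT_NAME.get)(G).ravel(),
    })
    truth = TruthGenotypes(truth_long)

    ledger = PlantLedger(
        planted_snvs=snv_df,
        causal_by_patient=causal_by_patient,
        cnv_events=cnv_records,
        lcsh_events=lcsh_records,
        failed_samples={"run1": list(fail_s1), "run2": list(fail_s2)},
        failed_probes={"run1": list(probe_ids[fail_p1]),
                       "run2": list(probe_ids[fail_p2])},
    )
    benign = _synthetic_benign_track(manifest,
                                     np.random.default_rng(ss_benign))
    return SimulatedCohort(config, manifest, annotation, truth, sexes,
                           run1, run2, ledger, benign)
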