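"""Synthetic two-group breast-tumor cohorts with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a subset of case (BRCA2-mutant) tumors carries hemizygous deletions
over contiguous cytogenetic-band regions.  Each deletion, attenuated by the
sample's tumor-cell fraction f, drives four correlated read-outs:

* reduced log2 expression of the genes in the region
  (``x = mu_g + f * expr_effect + noise`` for deleted genes),
* a CGH probe log2 ratio shift of ``log2((f*c + 2*(1-f))/2)`` with c = 1
  tumor copy,
* splitting of heterozygous-SNP B-allele frequencies into symmetric bands at
  ``1/(2-f)`` and ``(1-f)/(2-f)``,
* reduced red (deletion-probe) FISH spot counts in tumor nuclei, with normal
  cells contaminating the nucleus pool at rate ``1 - f``.

One seed sequence is split per data modality in a fixed, documented order
(truth, expression, CGH, BAF, FISH), so adding a modality never perturbs
another's draws and fixed seeds reproduce byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .containers import CASE_LABEL, CONTROL_LABEL, ExpressionMatrix

# Genomic span allotted to each cytogenetic band (bp); features are laid out
# uniformly inside their band.
BAND_SIZE = 10_000_000

#: Layout of one cytogenetic band: (chromosome, band, n_genes, n_probes, n_snps)
BandSpec = tuple[str, str, int, int, int]

# Modality order for RNG stream splitting (documented; do not reorder).
_STREAMS = ("truth", "expression", "cgh", "baf", "fish")


def default_genome(genes_per_band: int = 25, probes_per_band: int = 10,
                   snps_per_band: int = 40) -> tuple[BandSpec, ...]:
    """A compact genome emulating chromosomes 13/14 plus neutral chromosomes.

    Chromosome 13 and 14 q-arms carry enough bands to host the two deletion
    regions (13q13-13q14 and 14q24-14q32, mirroring the commonly deleted
    regions in BRCA2-mutant tumors); five other chromosomes provide the
    neutral background for enrichment and copy-number nulls.
    """
    layout = {
        "13": ["13q12", "13q13", "13q14", "13q21", "13q22", "13q31", "13q32", "13q33"],
        "14": ["14q11", "14q21", "14q23", "14q24", "14q31", "14q32"],
        "1": ["1p36", "1p13", "1q21", "1q32"],
        "4": ["4p16", "4q12", "4q28", "4q35"],
        "10": ["10p14", "10q22", "10q26"],
        "17": ["17p13", "17p12", "17q12", "17q21"],
        "19": ["19p13", "19q13"],
    }
    return tuple(
        (chrom, band, genes_per_band, probes_per_band, snps_per_band)
        for chrom, bands in layout.items()
        for band in bands
    )


DEFAULT_DELETED_REGIONS: tuple[tuple[str, str, str], ...] = (
    ("13", "13q13", "13q14"),
    ("14", "14q24", "14q32"),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the study design being emulated: 7 case vs 24 control
    tumors, tumor-cell fractions spread over 50-95%, fully penetrant
    deletions of 13q13-q14 and 14q24-q32, and an expression effect of
    -0.7 log2 units for a fully hemizygous gene (partial dosage
    compensation).
    """

    n_case: int = 7
    n_control: int = 24
    genome: tuple[BandSpec, ...] = field(default_factory=default_genome)
    deleted_regions: tuple[tuple[str, str, str], ...] = DEFAULT_DELETED_REGIONS
    penetrance: float = 1.0
    tumor_fraction_range: tuple[float, float] = (0.50, 0.95)
    expr_effect: float = -0.7
    expr_noise_sd: float = 0.4
    cgh_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    fish_nuclei_per_sample: int = 100
    fish_detection_eff: float = 0.95
    seed: int = 0
    # Baseline gene means on the log2 scale (typical RMA intensity range).
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")
        scalars = (self.penetrance, self.expr_effect, self.expr_noise_sd,
                   self.cgh_noise_sd, self.baf_noise_sd, self.fish_detection_eff,
                   self.baseline_mean, self.baseline_sd, *self.tumor_fraction_range)
        if not all(math.isfinite(v) for v in scalars):
            raise ValueError("config values must be finite")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        lo, hi = self.tumor_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("tumor_fraction_range must be within (0, 1]")
        if min(self.expr_noise_sd, self.cgh_noise_sd, self.baf_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 < self.fish_detection_eff <= 1.0:
            raise ValueError("fish_detection_eff must be in (0, 1]")
        if self.fish_nuclei_per_sample < 1:
            raise ValueError("fish_nuclei_per_sample must be >= 1")


@dataclass
class GroundTruth:
    """Generative truth for one cohort.

    ``samples``: sample_id-indexed frame with ``group``, ``tumor_fraction``
    and ``regions`` (tuple of carried deletion-region ids).  ``genes``,
    ``probes`` and ``snps`` map each feature to its coordinates and the
    deletion region containing it (-1 if none).  Genes inside a carried
    region have one copy in that sample's tumor cells; all others have two.
    """

    samples: pd.DataFrame
    genes: pd.DataFrame
    probes: pd.DataFrame
    snps: pd.DataFrame
    regions: pd.DataFrame

    def deletion_mask(self, features: str = "genes") -> pd.DataFrame:
        """Boolean features x samples frame: feature deleted in the sample."""
        feats = getattr(self, features)
        mask = np.zeros((len(feats), len(self.samples)), dtype=bool)
        region = feats["region"].to_numpy()
        for j, carried in enumerate(self.samples["regions"]):
            if carried:
                mask[:, j] = np.isin(region, list(carried))
        return pd.DataFrame(mask, index=feats.index, columns=self.samples.index)

    def tumor_copies(self, features: str = "genes") -> pd.DataFrame:
        """Tumor-cell copy number (1 or 2) per feature per sample."""
        return 2 - self.deletion_mask(features).astype(int)


def _rng(config: CohortConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


def _band_positions(config: CohortConfig) -> dict[str, tuple[str, int]]:
    """band -> (chromosome, index of the band within its chromosome)."""
    out: dict[str, tuple[str, int]] = {}
    counters: dict[str, int] = {}
    for chrom, band, *_ in config.genome:
        counters[chrom] = counters.get(chrom, -1) + 1
        out[band] = (chrom, counters[chrom])
    return out


def _layout(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Deterministic feature layout: genes/probes/snps frames + regions."""
    positions = _band_positions(config)

    regions = []
    for rid, (chrom, band_start, band_end) in enumerate(config.deleted_regions):
        for b in (band_start, band_end):
            if b not in positions or positions[b][0] != chrom:
                raise ValueError(f"deleted region band {b!r} not in genome on chromosome {chrom!r}")
        i0, i1 = positions[band_start][1], positions[band_end][1]
        if i1 < i0:
            raise ValueError("deleted region band_end precedes band_start")
        regions.append({"region": rid, "chromosome": chrom,
                        "band_start": band_start, "band_end": band_end,
                        "start": i0 * BAND_SIZE, "end": (i1 + 1) * BAND_SIZE})
    regions_df = pd.DataFrame(regions, columns=["region", "chromosome", "band_start",
                                                "band_end", "start", "end"]).set_index("region")

    def region_of(chrom: str, band_idx: int) -> int:
        for rid, r in regions_df.iterrows():
            if r["chromosome"] == chrom:
                lo = positions[r["band_start"]][1]
                hi = positions[r["band_end"]][1]
                if lo <= band_idx <= hi:
                    return int(rid)
        return -1

    genes, probes, snps = [], [], []
    for chrom, band, n_genes, n_probes, n_snps in config.genome:
        bidx = positions[band][1]
        base = bidx * BAND_SIZE
        rid = region_of(chrom, bidx)
        for i in range(n_genes):
            start = base + int((i + 0.5) * BAND_SIZE / n_genes)
            genes.append({"gene_id": f"g{band}.{i:02d}", "chromosome": chrom,
                          "band": band, "start": start, "end": start + 10_000,
                          "region": rid})
        for i in range(n_probes):
            start = base + int(i * BAND_SIZE / n_probes)
            probes.append({"probe_id": f"p{band}.{i:02d}", "chromosome": chrom,
                           "band": band, "start": start,
                           "end": base + int((i + 1) * BAND_SIZE / n_probes),
                           "region": rid})
        for i in range(n_snps):
            snps.append({"snp_id": f"s{band}.{i:03d}", "chromosome": chrom,
                         "band": band,
                         "pos": base + int((i + 0.5) * BAND_SIZE / n_snps),
                         "region": rid})
    return (pd.DataFrame(genes).set_index("gene_id"),
            pd.DataFrame(probes).set_index("probe_id"),
            pd.DataFrame(snps).set_index("snp_id"),
            regions_df)


def make_truth(config: CohortConfig) -> GroundTruth:
    """Draw the per-sample latent state (group, tumor fraction, deletions)."""
    rng = _rng(config, "truth")
    genes, probes, snps, regions = _layout(config)

    ids = [f"B2_{i + 1:02d}" for i in range(config.n_case)] + \
          [f"BX_{i + 1:02d}" for i in range(config.n_control)]
    groups = [CASE_LABEL] * config.n_case + [CONTROL_LABEL] * config.n_control
    lo, hi = config.tumor_fraction_range
    fractions = rng.uniform(lo, hi, size=len(ids))
    carried = []
    for g in groups:
        if g == CASE_LABEL:
            carried.append(tuple(
                rid for rid in regions.index if rng.random() < config.penetrance
            ))
        else:
            carried.append(())
    samples = pd.DataFrame(
        {"group": groups, "tumor_fraction": fractions, "regions": carried},
        index=pd.Index(ids, name="sample_id"),
    )
    return GroundTruth(samples=samples, genes=genes, probes=probes,
                       snps=snps, regions=regions)


def simulate_expression(
    config: CohortConfig, truth: GroundTruth | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Gene x sample log2 expression with deletion-driven down-shifts.

    ``x_gj = mu_g + 1{g deleted in j} * f_j * expr_effect + N(0, sd)`` with a
    per-gene baseline ``mu_g ~ N(baseline_mean, baseline_sd)``.
    """
    if truth is None:
        truth = make_truth(config)
    rng = _rng(config, "expression")
    n_genes, n_samples = len(truth.genes), len(truth.samples)
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    noise = rng.normal(0.0, config.expr_noise_sd, size=(n_genes, n_samples))
    deleted = truth.deletion_mask("genes").to_numpy()
    f = truth.samples["tumor_fraction"].to_numpy()
    values = mu[:, None] + deleted * f[None, :] * config.expr_effect + noise
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=truth.genes.index, columns=truth.samples.index),
        labels=truth.samples["group"],
    )
    return matrix, truth


def simulate_cgh(config: CohortConfig, truth: GroundTruth) -> pd.DataFrame:
    """Array-CGH probe log2 ratios, long format.

    ``log2ratio = log2((f*c + 2*(1-f)) / 2) + N(0, cgh_noise_sd)`` where c is
    the tumor-cell copy number (1 inside a carried deletion, else 2).

    Returns a frame with columns sample_id, chromosome, start, end, probe_id,
    log2ratio, probes sorted by (chromosome, start) within each sample.
    """
    rng = _rng(config, "cgh")
    probes = truth.probes.sort_values(["chromosome", "start"], kind="stable")
    copies = truth.tumor_copies("probes").loc[probes.index]
    f = truth.samples["tumor_fraction"]
    frames = []
    for sample_id in truth.samples.index:
        c = copies[sample_id].to_numpy()
        fj = f[sample_id]
        ratio = np.log2((fj * c + 2.0 * (1.0 - fj)) / 2.0)
        ratio = ratio + rng.normal(0.0, config.cgh_noise_sd, size=len(c))
        frames.append(pd.DataFrame({
            "sample_id": sample_id,
            "chromosome": probes["chromosome"].to_numpy(),
            "start": probes["start"].to_numpy(),
            "end": probes["end"].to_numpy(),
            "probe_id": probes.index.to_numpy(),
            "log2ratio": ratio,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_baf(config: CohortConfig, truth: GroundTruth) -> pd.DataFrame:
    """SNP-array B-allele frequencies, long format.

    Heterozygous SNPs sit at 0.5 in neutral regions; inside a carried
    deletion they split into symmetric bands at ``1/(2-f)`` and
    ``(1-f)/(2-f)`` depending on which allele is lost.  Homozygous SNPs sit
    at 0 or 1 throughout.  Gaussian noise is added and values clipped to
    [0, 1].  The ``is_het`` column records the (paired-normal) genotype.
    """
    rng = _rng(config, "baf")
    snps = truth.snps.sort_values(["chromosome", "pos"], kind="stable")
    deleted = truth.deletion_mask("snps").loc[snps.index]
    f = truth.samples["tumor_fraction"]
    n = len(snps)
    frames = []
    for sample_id in truth.samples.index:
        fj = f[sample_id]
        het = rng.random(n) < 1.0 / 3.0
        hom_alt = rng.random(n) < 0.5
        lost_b = rng.random(n) < 0.5  # which allele lost in deleted hets
        baf = np.where(hom_alt, 1.0, 0.0)
        del_mask = deleted[sample_id].to_numpy()
        het_baf = np.where(
            del_mask,
            np.where(lost_b, (1.0 - fj) / (2.0 - fj), 1.0 / (2.0 - fj)),
            0.5,
        )
        baf = np.where(het, het_baf, baf)
        baf = np.clip(baf + rng.normal(0.0, config.baf_noise_sd, size=n), 0.0, 1.0)
        frames.append(pd.DataFrame({
            "sample_id": sample_id,
            "chromosome": snps["chromosome"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "snp_id": snps.index.to_numpy(),
            "baf": baf,
            "is_het": het,
        }))
    return pd.concat(frames, ignore_index=True)


def fish_chromosomes(truth: GroundTruth) -> list[str]:
    """Chromosomes probed by the FISH assay (those hosting a deletion region)."""
    return sorted(truth.regions["chromosome"].unique())


def simulate_fish(config: CohortConfig, truth: GroundTruth) -> pd.DataFrame:
    """Two-color FISH spot counts per nucleus.

    Each scored nucleus is a tumor cell with probability f (else a
    contaminating normal cell).  Green (pericentromeric) spots are
    Binomial(2, eff); red (deletion-probe) spots are Binomial(c_red, eff)
    with c_red = 1 in tumor cells of samples carrying the deletion on that
    chromosome, else 2.
    """
    rng = _rng(config, "fish")
    chroms = fish_chromosomes(truth)
    eff = config.fish_detection_eff
    n = config.fish_nuclei_per_sample
    rows = []
    for sample_id, srow in truth.samples.iterrows():
        carried_chroms = {
            truth.regions.loc[rid, "chromosome"] for rid in srow["regions"]
        }
        for chrom in chroms:
            tumor = rng.random(n) < srow["tumor_fraction"]
            c_red = np.where(tumor & (chrom in carried_chroms), 1, 2)
            green = rng.binomial(2, eff, size=n)
            red = rng.binomial(c_red, eff)
            rows.append(pd.DataFrame({
                "sample_id": sample_id,
                "chromosome": chrom,
                "nucleus_id": np.arange(1, n + 1),
                "green": green,
                "red": red,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(config: CohortConfig) -> SimpleNamespace:
    """Generate all four modalities plus truth for one cohort."""
    truth = make_truth(config)
    expression, _ = simulate_expression(config, truth)
    return SimpleNamespace(
        config=config,
        truth=truth,
        expression=expression,
        cgh=simulate_cgh(config, truth),
        baf=simulate_baf(config, truth),
        fish=simulate_fish(config, truth),
    )
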