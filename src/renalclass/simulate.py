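"""Synthetic data with the statistical structure of a two-subtype renal-tumor study.

Emulated design: two tumor classes (chromophobe RCC and oncocytoma, 15 + 15
profiles), a 12-sample normal kidney reference, probes mapped to genes and
cytobands on a miniature genome, class-specific arm-level expression shifts
(chRCC: losses of chromosomes 1, 2, 6, 10, 13, 17, 21; oncocytoma: loss of
the distal end of 1p), and an independent SNP copy-number cohort (6 + 8
samples) with injected loss/gain segments.

Every generator is deterministic given (config, seed); each draws from its
own child stream of ``numpy.random.default_rng([seed, tag])`` so that the
expression, copy-number and contingency generators do not share state.

A :class:`TruthLedger` records everything injected, so downstream stages can
be scored for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CnMatrix,
    ContingencyTable2x2,
    ExpressionMatrix,
    ProbeAnnotation,
    SnpAnnotation,
)

__all__ = [
    "ArmBias",
    "CnSegmentSpec",
    "SimulationConfig",
    "TruthLedger",
    "build_genome",
    "simulate_expression",
    "simulate_cn",
    "simulate_contingency",
]

CHRCC = "chRCC"
ONCOCYTOMA = "oncocytoma"

# Stream tags: keep the three generators on disjoint RNG streams per seed.
_STREAM_EXPRESSION = 1
_STREAM_CN = 2
_STREAM_CONTINGENCY = 3


@dataclass(frozen=True)
class ArmBias:
    """A class-specific log2 shift applied to all probes on a chromosome arm.

    ``terminal_fraction`` < 1 restricts the shift to the telomeric tail of
    the arm (by position: the lowest positions of a p arm, the highest of a
    q arm), modeling e.g. a distal 1p loss.
    """

    class_name: str
    arm: str  # e.g. "1p"
    shift: float
    terminal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.terminal_fraction <= 1.0):
            raise ValueError("terminal_fraction must be in (0, 1]")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")


@dataclass(frozen=True)
class CnSegmentSpec:
    """A copy-number segment injected into a fraction of one cohort's samples.

    ``start_fraction``/``end_fraction`` span the chromosome in relative
    coordinates (0 = start, 1 = end); CN values inside the segment are drawn
    from Normal(cn_mean, cn_sd), clipped at zero.
    """

    cohort: str
    chromosome: str
    start_fraction: float
    end_fraction: float
    cn_mean: float
    cn_sd: float
    sample_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_fraction < self.end_fraction <= 1.0):
            raise ValueError("segment span must satisfy 0 <= start < end <= 1")
        if not (0.0 <= self.sample_fraction <= 1.0):
            raise ValueError("sample_fraction must be in [0, 1]")


def _default_arm_biases() -> list[ArmBias]:
    biases = [
        ArmBias(CHRCC, f"{c}{arm}", -1.0)
        for c in ("1", "2", "6", "10", "13", "17", "21")
        for arm in ("p", "q")
    ]
    biases.append(ArmBias(ONCOCYTOMA, "1p", -1.0, terminal_fraction=0.30))
    return biases


def _default_cn_segments() -> list[CnSegmentSpec]:
    segments = [
        CnSegmentSpec(CHRCC, c, 0.0, 1.0, 1.0, 0.15, 0.8)
        for c in ("1", "2", "6", "10", "13", "17", "21")
    ]
    segments += [
        CnSegmentSpec(CHRCC, c, 0.0, 1.0, 4.0, 0.2, 0.5) for c in ("4", "7", "11", "12")
    ]
    segments += [
        CnSegmentSpec(CHRCC, "14", 0.5, 1.0, 4.0, 0.2, 0.5),
        CnSegmentSpec(CHRCC, "18", 0.5, 1.0, 4.0, 0.2, 0.5),
    ]
    # distal 1p on the miniature genome: the p arm is the first 40% of the
    # chromosome; its terminal 30% is the first 12% of the chromosome.
    segments.append(CnSegmentSpec(ONCOCYTOMA, "1", 0.0, 0.12, 1.0, 0.15, 0.8))
    return segments


@dataclass
class SimulationConfig:
    """Study-design parameters for all three generators.

    Defaults encode the emulated study: 15 + 15 tumors, 12 normals,
    20 discriminative probes at log2 effect 2.0, arm-level losses for each
    class, Gaussian log2 noise (sd 0.5), and a 6 + 8 SNP cohort with the
    loss/gain segments above on a 2,000-probe miniature genome.
    """

    n_probes: int = 2000
    n_genes: int = 1600
    n_per_class: tuple[int, int] = (15, 15)
    class_names: tuple[str, str] = (CHRCC, ONCOCYTOMA)
    n_normals: int = 12
    n_discriminative: int = 20
    effect_size: float = 2.0
    arm_biases: list[ArmBias] = field(default_factory=_default_arm_biases)
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_cytobands_per_arm: int = 4
    # SNP copy-number cohort
    snps_per_chromosome: int = 200
    cn_cohort_sizes: tuple[int, int] = (6, 8)
    cn_background_sd: float = 0.15
    cn_segments: list[CnSegmentSpec] = field(default_factory=_default_cn_segments)

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_genes", "n_normals", "snps_per_chromosome"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_discriminative < 0 or self.n_discriminative > self.n_probes:
            raise ValueError("n_discriminative must be in [0, n_probes]")
        if self.n_genes > self.n_probes:
            raise ValueError("n_genes cannot exceed n_probes")
        if any(n <= 0 for n in self.n_per_class) or any(n <= 0 for n in self.cn_cohort_sizes):
            raise ValueError("cohort sizes must be positive")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "arm_biases" in d:
            d["arm_biases"] = [ArmBias(**b) for b in d["arm_biases"]]
        if "cn_segments" in d:
            d["cn_segments"] = [CnSegmentSpec(**s) for s in d["cn_segments"]]
        for key in ("n_per_class", "class_names", "cn_cohort_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthLedger:
    """What was injected: the ground truth for parameter-recovery tests."""

    discriminative_effects: dict[str, float] = field(default_factory=dict)
    arm_biases: list[dict] = field(default_factory=list)
    cn_segments: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Miniature genome
# ---------------------------------------------------------------------------


def build_genome(n_cytobands_per_arm: int = 4) -> pd.DataFrame:
    """A desk-scale genome: 22 autosomes + X with p/q arms and cytobands.

    Chromosome lengths shrink linearly from 250 Mb to ~60 Mb; the centromere
    sits at 40% of each chromosome. Returns one row per chromosome with
    ``chromosome, length, centromere``.
    """
    chroms = [str(i) for i in range(1, 23)] + ["X"]
    rows = []
    for i, c in enumerate(chroms):
        length = int(250e6 - i * 8.3e6)
        rows.append({"chromosome": c, "length": length, "centromere": int(0.4 * length)})
    return pd.DataFrame(rows)


def _cytoband(chrom: str, arm: str, frac_on_arm: float, n_bands: int) -> str:
    band = min(int(frac_on_arm * n_bands) + 1, n_bands)
    return f"{chrom}{arm}{band}"


def _gene_annotation(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place genes on the miniature genome proportionally to arm length."""
    genome = build_genome(config.n_cytobands_per_arm)
    arms = []
    for _, row in genome.iterrows():
        arms.append((row["chromosome"], "p", 1, row["centromere"]))
        arms.append((row["chromosome"], "q", row["centromere"] + 1, row["length"]))
    lengths = np.array([a[3] - a[2] + 1 for a in arms], dtype=float)
    weights = lengths / lengths.sum()
    counts = np.floor(weights * config.n_genes).astype(int)
    # distribute the remainder to the largest arms; never leave an arm empty
    counts = np.maximum(counts, 1)
    while counts.sum() > config.n_genes:
        counts[np.argmax(counts)] -= 1
    order = np.argsort(-weights)
    i = 0
    while counts.sum() < config.n_genes:
        counts[order[i % len(order)]] += 1
        i += 1
    records = []
    g = 0
    for (chrom, arm, start, end), k in zip(arms, counts):
        positions = np.sort(rng.integers(start, end + 1, size=k))
        for pos in positions:
            frac = (pos - start) / max(end - start, 1)
            records.append(
                {
                    "gene_symbol": f"G{g:05d}",
                    "chromosome": chrom,
                    "arm": arm,
                    "cytoband": _cytoband(chrom, arm, frac, config.n_cytobands_per_arm),
                    "position": int(pos),
                }
            )
            g += 1
    return pd.DataFrame(records)


def _probe_annotation(config: SimulationConfig, rng: np.random.Generator) -> ProbeAnnotation:
    genes = _gene_annotation(config, rng)
    rows = []
    for p in range(config.n_probes):
        gene = genes.iloc[p % len(genes)]
        rows.append(
            {
                "probe_id": f"probe{p:05d}",
                "gene_symbol": gene["gene_symbol"],
                "chromosome": gene["chromosome"],
                "arm": gene["arm"],
                "cytoband": gene["cytoband"],
                # extra probes for a gene sit a little downstream
                "position": int(gene["position"]) + 100 * (p // len(genes)),
            }
        )
    return ProbeAnnotation(pd.DataFrame(rows))


def _arm_bias_mask(annotation: ProbeAnnotation, bias: ArmBias) -> np.ndarray:
    placed = annotation.table["placed"].to_numpy()
    arm_name = (
        annotation.table["chromosome"].astype(str) + annotation.table["arm"].astype(str)
    ).to_numpy()
    mask = placed & (arm_name == bias.arm)
    if not mask.any():
        raise ValueError(f"arm {bias.arm!r} named in bias spec is absent from the annotation")
    if bias.terminal_fraction < 1.0:
        pos = annotation.table["position"].to_numpy()
        arm_pos = pos[mask]
        k = max(int(round(bias.terminal_fraction * arm_pos.size)), 1)
        if bias.arm.endswith("p"):  # p telomere = lowest positions
            cutoff = np.sort(arm_pos)[k - 1]
            mask = mask & (pos <= cutoff)
        else:  # q telomere = highest positions
            cutoff = np.sort(arm_pos)[-k]
            mask = mask & (pos >= cutoff)
    return mask


def simulate_expression(
    config: SimulationConfig, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix, ProbeAnnotation, TruthLedger]:
    """Generate tumor + normal log2 expression with injected class structure.

    Per-probe baselines are drawn once and shared by every sample; the
    discriminative probes get a signed class effect (added to the first
    class, alternating sign), arm biases shift all probes on the named arm
    for the named class, and i.i.d. Gaussian noise is added on top.
    """
    rng = np.random.default_rng([seed, _STREAM_EXPRESSION])
    annotation = _probe_annotation(config, rng)
    n1, n2 = config.n_per_class
    c1, c2 = config.class_names
    sample_ids = [f"T{i:02d}" for i in range(n1 + n2)]
    labels = pd.Series([c1] * n1 + [c2] * n2, index=sample_ids)
    normal_ids = [f"N{i:02d}" for i in range(config.n_normals)]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_probes)
    signal = np.tile(baseline[:, None], (1, n1 + n2))

    ledger = TruthLedger()
    disc_idx = rng.choice(config.n_probes, size=config.n_discriminative, replace=False)
    signs = np.where(np.arange(config.n_discriminative) % 2 == 0, 1.0, -1.0)
    for idx, sign in zip(disc_idx, signs):
        effect = sign * config.effect_size
        signal[idx, :n1] += effect  # effect carried by the first class (chRCC)
        ledger.discriminative_effects[annotation.table.loc[idx, "probe_id"]] = float(effect)

    class_cols = {c1: np.arange(n1), c2: np.arange(n1, n1 + n2)}
    for bias in config.arm_biases:
        if bias.class_name not in class_cols:
            raise ValueError(f"unknown class in arm bias: {bias.class_name!r}")
        mask = _arm_bias_mask(annotation, bias)
        cols = class_cols[bias.class_name]
        signal[np.ix_(mask.nonzero()[0], cols)] += bias.shift
        ledger.arm_biases.append(
            {
                "class_name": bias.class_name,
                "arm": bias.arm,
                "shift": bias.shift,
                "terminal_fraction": bias.terminal_fraction,
                "n_probes": int(mask.sum()),
            }
        )

    tumor_values = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    normal_values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_probes, config.n_normals)
    )

    probe_ids = annotation.table["probe_id"]
    tumors = ExpressionMatrix(
        pd.DataFrame(tumor_values, index=probe_ids, columns=sample_ids), labels
    )
    normals = ExpressionMatrix(pd.DataFrame(normal_values, index=probe_ids, columns=normal_ids))
    return tumors, normals, annotation, ledger


def simulate_cn(
    config: SimulationConfig, seed: int
) -> tuple[CnMatrix, SnpAnnotation, TruthLedger]:
    """Generate a SNP copy-number matrix: Normal(2, sd) background with
    injected segments overwriting the background in a sampled subset of the
    target cohort."""
    rng = np.random.default_rng([seed, _STREAM_CN])
    genome = build_genome(config.n_cytobands_per_arm)
    chroms = [c for c in genome["chromosome"] if c != "X"]  # autosomal SNP panel
    rows = []
    for chrom in chroms:
        length = int(genome.loc[genome["chromosome"] == chrom, "length"].iloc[0])
        step = length // (config.snps_per_chromosome + 1)
        for j in range(config.snps_per_chromosome):
            rows.append(
                {
                    "snp_id": f"snp_{chrom}_{j:04d}",
                    "chromosome": chrom,
                    "position": (j + 1) * step,
                }
            )
    annotation = SnpAnnotation(pd.DataFrame(rows))

    n1, n2 = config.cn_cohort_sizes
    c1, c2 = config.class_names
    sample_ids = [f"D{i:02d}" for i in range(n1 + n2)]
    cohorts = pd.Series([c1] * n1 + [c2] * n2, index=sample_ids)
    n_snps = len(annotation.table)
    values = np.clip(rng.normal(2.0, config.cn_background_sd, size=(n_snps, n1 + n2)), 0, None)

    chrom_arr = annotation.table["chromosome"].to_numpy()
    pos_arr = annotation.table["position"].to_numpy()
    ledger = TruthLedger()
    cohort_cols = {c1: np.arange(n1), c2: np.arange(n1, n1 + n2)}
    for seg in config.cn_segments:
        if seg.cohort not in cohort_cols:
            raise ValueError(f"unknown cohort in segment spec: {seg.cohort!r}")
        if seg.chromosome not in set(chroms):
            raise ValueError(f"segment chromosome {seg.chromosome!r} outside the SNP panel")
        length = int(genome.loc[genome["chromosome"] == seg.chromosome, "length"].iloc[0])
        lo, hi = seg.start_fraction * length, seg.end_fraction * length
        snp_mask = (chrom_arr == seg.chromosome) & (pos_arr >= lo) & (pos_arr <= hi)
        snp_idx = snp_mask.nonzero()[0]
        if snp_idx.size == 0:
            raise ValueError(f"segment on chromosome {seg.chromosome} spans no SNPs")
        cols = cohort_cols[seg.cohort]
        n_aff = int(round(seg.sample_fraction * cols.size))
        affected = rng.choice(cols, size=n_aff, replace=False) if n_aff else np.array([], int)
        for col in affected:
            values[snp_idx, col] = np.clip(
                rng.normal(seg.cn_mean, seg.cn_sd, size=snp_idx.size), 0, None
            )
        ledger.cn_segments.append(
            {
                "cohort": seg.cohort,
                "chromosome": seg.chromosome,
                "cn_mean": seg.cn_mean,
                "first_snp": annotation.table.loc[snp_idx[0], "snp_id"],
                "last_snp": annotation.table.loc[snp_idx[-1], "snp_id"],
                "snp_indices": [int(i) for i in snp_idx],
                "samples": sorted(sample_ids[c] for c in affected),
            }
        )

    cn = CnMatrix(
        pd.DataFrame(values, index=annotation.table["snp_id"].to_numpy(), columns=sample_ids),
        cohorts,
    )
    return cn, annotation, ledger


def simulate_contingency(
    p_pos_group1: float, p_pos_group2: float, n1: int, n2: int, seed: int
) -> ContingencyTable2x2:
    """Draw a 2x2 marker table: independent binomial positives per group."""
    for p in (p_pos_group1, p_pos_group2):
        if not (0.0 <= p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng([seed, _STREAM_CONTINGENCY])
    a = int(rng.binomial(n1, p_pos_group1))
    c = int(rng.binomial(n2, p_pos_group2))
    return ContingencyTable2x2(a, n1 - a, c, n2 - c)
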