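"""SNP-array copy-number segment calling and recurrent-alteration regions.

Per sample, a loss is a maximal run of at least ``min_run`` consecutive
SNPs (position order, within one chromosome) with CN strictly below 1.6; a
gain, strictly above 3.5. A single SNP on the wrong side of the threshold
(or a missing value) breaks the run; no smoothing is applied. Recurrent
copy-number-alteration (CNA) regions are maximal runs of SNPs covered by
calls of one type in strictly more than 30% of a cohort's samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CnMatrix, SnpAnnotation

__all__ = ["CnCall", "CnaRegion", "call_cn_segments", "cna_regions", "cnv_cohort_profile"]


@dataclass(frozen=True)
class CnCall:
    """One per-sample loss/gain segment."""

    sample: str
    chromosome: str
    first_index: int  # index into the chromosome's position-sorted SNPs
    last_index: int  # inclusive
    start_position: int
    end_position: int
    kind: str  # "loss" | "gain"
    n_snps: int
    mean_cn: float


@dataclass(frozen=True)
class CnaRegion:
    """A recurrent alteration region within one cohort."""

    cohort: str
    chromosome: str
    first_index: int
    last_index: int
    start_position: int
    end_position: int
    kind: str
    n_snps: int
    prevalence: float  # minimum covered fraction over the span (> cutoff)


def _runs(mask: np.ndarray):
    """Yield (start, end_inclusive) of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    yield from zip(starts, ends)


def call_cn_segments(
    cn: CnMatrix,
    annotation: SnpAnnotation,
    loss_cut: float = 1.6,
    gain_cut: float = 3.5,
    min_run: int = 4,
) -> list[CnCall]:
    """Run-length loss/gain calls per sample.

    The annotation must already be in canonical (chromosome, position)
    order; an unsorted one is a hard error (call ``annotation.sorted()``).
    """
    if loss_cut >= gain_cut:
        raise ValueError("loss_cut must be below gain_cut")
    if not annotation.is_sorted():
        raise ValueError(
            "SNP annotation is not in canonical (chromosome, position) order; "
            "apply SnpAnnotation.sorted() first"
        )
    snp_order = annotation.table["snp_id"].to_numpy()
    missing = [s for s in snp_order if s not in set(cn.snp_ids)]
    if missing:
        raise ValueError(f"CN matrix lacks annotated SNPs, e.g. {missing[:5]}")
    values = cn.values.loc[snp_order]
    chroms = annotation.table["chromosome"].to_numpy()
    positions = annotation.table["position"].to_numpy()

    calls: list[CnCall] = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos = positions[sel]
        sub = values.to_numpy()[sel]
        for j, sample in enumerate(values.columns):
            v = sub[:, j]
            finite = np.isfinite(v)
            for kind, mask in (("loss", finite & (v < loss_cut)), ("gain", finite & (v > gain_cut))):
                for start, end in _runs(mask):
                    n = end - start + 1
                    if n < min_run:
                        continue
                    calls.append(
                        CnCall(
                            sample=str(sample),
                            chromosome=str(chrom),
                            first_index=int(start),
                            last_index=int(end),
                            start_position=int(pos[start]),
                            end_position=int(pos[end]),
                            kind=kind,
                            n_snps=int(n),
                            mean_cn=float(v[start : end + 1].mean()),
                        )
                    )
    return calls


def cna_regions(
    calls: list[CnCall],
    cohort_samples: list[str],
    annotation: SnpAnnotation,
    min_fraction: float = 0.30,
    min_run: int = 4,
    cohort: str = "",
) -> list[CnaRegion]:
    """Recurrent regions: SNPs covered by one call type in > min_fraction of
    the cohort (strict), in maximal runs of at least ``min_run`` SNPs."""
    if not cohort_samples:
        raise ValueError("cohort sample list is empty")
    cohort_set = set(map(str, cohort_samples))
    n_cohort = len(cohort_set)
    chroms = annotation.table["chromosome"].to_numpy()
    positions = annotation.table["position"].to_numpy()

    regions: list[CnaRegion] = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos = positions[sel]
        n_snps = int(sel.sum())
        for kind in ("loss", "gain"):
            coverage = np.zeros(n_snps)
            for c in calls:
                if c.kind != kind or c.chromosome != str(chrom) or c.sample not in cohort_set:
                    continue
                coverage[c.first_index : c.last_index + 1] += 1
            fraction = coverage / n_cohort
            for start, end in _runs(fraction > min_fraction):
                n = end - start + 1
                if n < min_run:
                    continue
                regions.append(
                    CnaRegion(
                        cohort=cohort,
                        chromosome=str(chrom),
                        first_index=int(start),
                        last_index=int(end),
                        start_position=int(pos[start]),
                        end_position=int(pos[end]),
                        kind=kind,
                        n_snps=int(n),
                        prevalence=float(fraction[start : end + 1].min()),
                    )
                )
    return regions


def cnv_cohort_profile(regions: list[CnaRegion], annotation: SnpAnnotation) -> pd.DataFrame:
    """Per (cohort, chromosome): fraction of the chromosome's SNPs inside CNA
    regions, split by type. Chromosomes without regions report zeros."""
    chroms = annotation.table["chromosome"].astype(str)
    snp_counts = chroms.value_counts()
    cohorts = sorted({r.cohort for r in regions}) or [""]
    rows = []
    for cohort in cohorts:
        for chrom in pd.unique(chroms):
            total = int(snp_counts[chrom])
            cover = {"loss": np.zeros(total, bool), "gain": np.zeros(total, bool)}
            for r in regions:
                if r.cohort == cohort and r.chromosome == chrom:
                    cover[r.kind][r.first_index : r.last_index + 1] = True
            rows.append(
                {
                    "cohort": cohort,
                    "chromosome": chrom,
                    "n_snps": total,
                    "loss_fraction": float(cover["loss"].mean()),
                    "gain_fraction": float(cover["gain"].mean()),
                }
            )
    return pd.DataFrame(rows)
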