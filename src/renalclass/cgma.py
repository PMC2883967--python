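"""Expression-inferred regional cytogenetics (comparative genomic microarray
analysis).

Relative expression profiles R = log2(T) - log2(mean N) are computed against
a normal-tissue reference; a chromosome-arm-level sign test on gene-level R
then flags arms whose expression is coherently shifted, a proxy for copy
gain (z >= +1.96) or loss (z <= -1.96).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ProbeAnnotation

__all__ = [
    "RelativeExpressionMatrix",
    "relative_expression",
    "regional_bias",
    "cohort_bias_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class RelativeExpressionMatrix:
    """R values (probes x tumor samples): log2 tumor minus mean log2 normal."""

    values: pd.DataFrame
    labels: pd.Series | None = None

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def relative_expression(tumors: ExpressionMatrix, normals: ExpressionMatrix) -> RelativeExpressionMatrix:
    """R[i, s] = T[i, s] - mean_n N[i, n], all in log2 space.

    The probe sets must match exactly (order may differ).
    """
    t_probes, n_probes = set(tumors.probe_ids), set(normals.probe_ids)
    if t_probes != n_probes:
        diff = sorted(t_probes.symmetric_difference(n_probes))
        raise ValueError(f"probe sets differ between tumors and normals: {diff[:20]}"
                         + (" ..." if len(diff) > 20 else ""))
    normal_mean = normals.values.mean(axis=1)
    r = tumors.values.sub(normal_mean.loc[tumors.values.index], axis=0)
    return RelativeExpressionMatrix(r, tumors.labels)


def regional_bias(
    R: RelativeExpressionMatrix,
    annotation: ProbeAnnotation,
    z_threshold: float = 1.96,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Sign-test bias per (sample, chromosome arm).

    Probes are collapsed to genes by mean R; per sample and arm, with n the
    number of mapped genes whose R is not exactly 0 and k the count with
    R > 0, z = (k - n/2) / sqrt(n/4). Calls: gain if z >= z_threshold, loss
    if z <= -z_threshold, else neutral. Arms with fewer than ``min_genes``
    genes are skipped (logged).

    Returns a tidy frame: sample, chromosome, arm, region, n_genes,
    n_positive, z, call.
    """
    placed = annotation.placed()
    placed = placed[placed["probe_id"].isin(R.probe_ids)]
    if placed.empty:
        raise ValueError("no annotated probe overlaps the relative-expression matrix")
    r = R.values.loc[placed["probe_id"]]
    gene_arm = placed.set_index("probe_id")[["gene_symbol", "arm_name"]]
    # gene-level collapse: mean R over a gene's probes (within its arm)
    grouped = r.groupby(
        [gene_arm["gene_symbol"].to_numpy(), gene_arm["arm_name"].to_numpy()]
    ).mean()
    grouped.index.names = ["gene_symbol", "arm_name"]

    rows = []
    for arm, sub in grouped.groupby(level="arm_name"):
        vals = sub.to_numpy()
        for j, sample in enumerate(grouped.columns):
            v = vals[:, j]
            v = v[v != 0.0]
            n = v.size
            if n < min_genes:
                logger.info("arm %s skipped for sample %s: %d genes < %d", arm, sample, n, min_genes)
                continue
            k = int((v > 0).sum())
            z = (k - n / 2.0) / np.sqrt(n / 4.0)
            call = "gain" if z >= z_threshold else ("loss" if z <= -z_threshold else "neutral")
            rows.append(
                {
                    "sample": sample,
                    "chromosome": arm[:-1],
                    "arm": arm[-1],
                    "region": arm,
                    "n_genes": n,
                    "n_positive": k,
                    "z": float(z),
                    "call": call,
                }
            )
    return pd.DataFrame(rows)


def cohort_bias_summary(calls: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per (region, cohort): fraction of samples called gain / loss.

    ``calls`` is the output of :func:`regional_bias`; ``labels`` maps sample
    id to cohort.
    """
    if calls.empty:
        return pd.DataFrame(columns=["region", "cohort", "n_samples", "gain_fraction", "loss_fraction"])
    df = calls.copy()
    df["cohort"] = df["sample"].map(labels)
    rows = []
    for (region, cohort), sub in df.groupby(["region", "cohort"]):
        n = len(sub)
        rows.append(
            {
                "region": region,
                "cohort": cohort,
                "n_samples": n,
                "gain_fraction": float((sub["call"] == "gain").mean()),
                "loss_fraction": float((sub["call"] == "loss").mean()),
            }
        )
    return pd.DataFrame(rows)
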