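"""TPM + TMM normalisation of stage-specific abundance tables and
threshold-based expression calls.

The normalisation order follows the analysis this package supports: per-stage
TPM first, then cross-stage scaling with trimmed-mean-of-M-values (TMM)
factors computed on the TPM table. Note this differs from the common usage of
TMM on raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EXPRESSION_THRESHOLD = 0.15

TEMPORAL_CLASSES = ("not_detected", "windowed", "throughout")


@dataclass(frozen=True)
class CountMatrix:
    """Raw counts and effective lengths, genes x stages, with stage order."""

    counts: pd.DataFrame
    eff_lengths: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape != self.eff_lengths.shape:
            raise ValueError("counts and effective lengths differ in shape")
        if not (self.counts.columns == self.eff_lengths.columns).all():
            raise ValueError("stage columns differ between counts and lengths")
        if not (self.counts.index == self.eff_lengths.index).all():
            raise ValueError("gene rows differ between counts and lengths")
        if self.counts.shape[1] < 2:
            raise ValueError("need at least 2 stages for cross-stage normalisation")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if (self.eff_lengths.values <= 0).any():
            raise ValueError("effective lengths must be positive")

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


def tpm_from_counts(m: CountMatrix) -> pd.DataFrame:
    """Per-stage transcripts-per-million; every column sums to 1e6."""
    rates = m.counts / m.eff_lengths
    col_sums = rates.sum(axis=0)
    zero = [str(s) for s in col_sums.index[col_sums == 0]]
    if zero:
        raise ValueError(f"all-zero stage column(s): {zero}")
    return rates / col_sums * 1e6


def _upper_quartile(col: pd.Series) -> float:
    nonzero = col[col > 0]
    if nonzero.empty:
        return 0.0
    return float(np.percentile(nonzero, 75))


def tmm_factors(
    tpm: pd.DataFrame,
    ref_stage: str | None = None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference stage is the one whose upper-quartile expression is closest
    to the mean upper quartile (unless given). For each stage, genes nonzero
    in both stage and reference enter; the most extreme ``logratio_trim`` of
    log2 ratios and ``abundance_trim`` of mean log2 abundances are excluded,
    and the factor is 2 to the precision-weighted mean of the surviving
    log-ratios.
    """
    if tpm.shape[1] < 2:
        raise ValueError("need at least 2 stages for TMM")
    if ref_stage is None:
        uq = tpm.apply(_upper_quartile, axis=0)
        ref_stage = (uq - uq.mean()).abs().idxmin()
    if ref_stage not in tpm.columns:
        raise ValueError(f"unknown reference stage {ref_stage!r}")
    ref = tpm[ref_stage].to_numpy(dtype=float)
    n_lib = 1e6  # TPM columns behave as libraries of fixed size
    log_factors = {}
    for stage in tpm.columns:
        obs = tpm[stage].to_numpy(dtype=float)
        use = (obs > 0) & (ref > 0)
        if stage == ref_stage or not use.any():
            log_factors[stage] = 0.0
            continue
        o, r = obs[use], ref[use]
        m_vals = np.log2(o / r)
        a_vals = 0.5 * (np.log2(o / n_lib) + np.log2(r / n_lib))
        weights = (n_lib - o) / (n_lib * o) + (n_lib - r) / (n_lib * r)
        n = len(m_vals)
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
        lo_a, hi_a = np.floor(n * abundance_trim) + 1, n + 1 - (np.floor(n * abundance_trim) + 1)
        rank_m = pd.Series(m_vals).rank().to_numpy()
        rank_a = pd.Series(a_vals).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            log_factors[stage] = 0.0
            continue
        inv_w = 1.0 / weights[keep]
        log_factors[stage] = float(np.sum(m_vals[keep] * inv_w) / np.sum(inv_w))
    factors = pd.Series({s: 2.0 ** f for s, f in log_factors.items()})[tpm.columns]
    geo_mean = np.exp(np.log(factors).mean())
    return factors / geo_mean


def normalize(m: CountMatrix, ref_stage: str | None = None) -> pd.DataFrame:
    """TMM-normalised TPM table (divide each stage column by its factor)."""
    tpm = tpm_from_counts(m)
    factors = tmm_factors(tpm, ref_stage=ref_stage)
    return tpm / factors


def average_replicates(
    expr: pd.DataFrame,
    replicate_map: Mapping[str, str],
) -> pd.DataFrame:
    """Average normalised columns belonging to the same stage.

    ``replicate_map`` maps column name -> stage name; stage order follows
    first appearance among the columns.
    """
    order: list[str] = []
    for col in expr.columns:
        stage = replicate_map.get(col, col)
        if stage not in order:
            order.append(stage)
    grouped = expr.T.groupby([replicate_map.get(c, c) for c in expr.columns]).mean().T
    return grouped[order]


@dataclass(frozen=True)
class ExpressionCall:
    gene: str
    expressed: tuple[bool, ...]  # per stage, in stage order
    temporal_class: str

    @property
    def expressed_anywhere(self) -> bool:
        return any(self.expressed)


def call_expressed(
    expr: pd.DataFrame,
    threshold: float = EXPRESSION_THRESHOLD,
) -> list[ExpressionCall]:
    """Expressed at a stage iff value >= threshold (inclusive)."""
    calls = []
    for gene, row in expr.iterrows():
        flags = tuple(bool(v >= threshold) for v in row)
        if all(flags):
            cls = "throughout"
        elif any(flags):
            cls = "windowed"
        else:
            cls = "not_detected"
        calls.append(ExpressionCall(gene=str(gene), expressed=flags, temporal_class=cls))
    return calls


def summarize_survey(calls: Sequence[ExpressionCall]) -> dict[str, int]:
    n_throughout = sum(1 for c in calls if c.temporal_class == "throughout")
    n_windowed = sum(1 for c in calls if c.temporal_class == "windowed")
    n_not = sum(1 for c in calls if c.temporal_class == "not_detected")
    return {
        "n_expressed_anywhere": n_throughout + n_windowed,
        "n_throughout": n_throughout,
        "n_windowed": n_windowed,
        "n_not_detected": n_not,
    }


def long_format(expr: pd.DataFrame, calls: Sequence[ExpressionCall]) -> pd.DataFrame:
    """Heatmap-ready long table: gene, stage, value, expressed, temporal_class."""
    by_gene = {c.gene: c for c in calls}
    rows = []
    for gene, row in expr.iterrows():
        call = by_gene[str(gene)]
        for i, (stage, value) in enumerate(row.items()):
            rows.append({
                "gene": gene,
                "stage": stage,
                "value": value,
                "expressed": call.expressed[i],
                "temporal_class": call.temporal_class,
            })
    return pd.DataFrame(rows)


def read_counts_tsv(path) -> CountMatrix:
    """Long-format TSV (gene, stage, count, eff_length) -> CountMatrix.

    Stage column order follows first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "stage", "count", "eff_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    stage_order = list(dict.fromkeys(df["stage"]))
    counts = df.pivot(index="gene", columns="stage", values="count")[stage_order]
    lengths = df.pivot(index="gene", columns="stage", values="eff_length")[stage_order]
    return CountMatrix(counts=counts, eff_lengths=lengths)
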