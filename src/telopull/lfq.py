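"""Label-free (LFQ) enrichment analysis of DNA pulldowns and IPs.

The statistical recipe applied to every label-free comparison in the
pipeline: log2-transform the intensities, impute left-censored missing
values from the low tail of the observed distribution, test bait
against control per protein with Welch's unequal-variance t-test, and
call a protein enriched when it jointly clears a fold-change gate and
a raw p-value gate (more than ``min_fold``-fold with p below
``max_p``; no multiple-testing correction enters the call, though a
Benjamini-Hochberg column is emitted for reference).

Missing values in affinity-enrichment proteomics are predominantly
missing-not-at-random: a protein absent from the control pulldown has
no measurable intensity there. Imputation therefore draws replacement
values from a narrow band at the lower end of the observed
log-intensity distribution — scaled Beta(2, 2) draws between the 0.2nd
and 2.5th percentiles by default — rather than from the bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProteinGroupTable

__all__ = [
    "ImputationParams",
    "EnrichmentThresholds",
    "EnrichmentResult",
    "log2_transform",
    "impute_low_tail",
    "welch_test",
    "welch_test_matrix",
    "call_enrichment",
    "results_to_frame",
    "write_volcano",
]

#: sentinel p-value for the zero-variance, unequal-means degenerate case
TINY_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class ImputationParams:
    """Low-tail imputation band and Beta shape.

    Replacement values are L + (U - L) * X with X ~ Beta(beta_a, beta_b),
    where L and U are the ``q_low`` and ``q_high`` quantiles of the
    observed log2 intensities (pooled over the whole matrix by default).
    """

    q_low: float = 0.002
    q_high: float = 0.025
    beta_a: float = 2.0
    beta_b: float = 2.0
    seed: int = 0
    per_column: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.q_low < self.q_high <= 1):
            raise ValueError("require 0 <= q_low < q_high <= 1")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("beta shapes must be positive")


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Joint fold-change / p-value gate for calling enrichment.

    ``strict`` means the thresholds must be exceeded ("more than
    4-fold", p strictly below ``max_p``), which is the default.
    """

    min_fold: float = 4.0
    max_p: float = 0.01
    strict: bool = True

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")
        if not (0 < self.max_p < 1):
            raise ValueError("max_p must be in (0, 1)")

    @property
    def min_log2_fc(self) -> float:
        return float(np.log2(self.min_fold))


@dataclass(frozen=True)
class EnrichmentResult:
    protein_id: str
    mean_log2_bait: float
    mean_log2_control: float
    log2_fc: float  # bait - control
    t_stat: float
    df: float
    p_value: float
    p_adj: float  # Benjamini-Hochberg, reported only, never used for calling
    enriched_in: str  # "bait" | "control" | "none"
    n_imputed_bait: int
    n_imputed_control: int


def log2_transform(table: ProteinGroupTable) -> ProteinGroupTable:
    """log2 each present intensity; 0 becomes missing; NaN stays NaN."""
    vals = table.intensities
    if (vals.values < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    with np.errstate(divide="ignore"):
        out = np.log2(vals.mask(vals == 0.0))
    return table.with_intensities(out)


def impute_low_tail(
    table: ProteinGroupTable, params: ImputationParams = ImputationParams()
) -> ProteinGroupTable:
    """Fill missing cells with seeded low-tail Beta draws.

    The table must already be log2-transformed. Observed values are
    untouched; the returned table's ``imputed`` mask marks filled
    cells. Deterministic given ``params.seed``.
    """
    vals = table.intensities
    missing = vals.isna()
    n_obs = int((~missing).values.sum())
    if n_obs < 20:
        raise ValueError(
            f"only {n_obs} observed values; at least 20 needed to estimate "
            "the imputation quantiles"
        )
    rng = np.random.default_rng(params.seed)
    out = vals.to_numpy(copy=True)

    def _fill(col_mask: np.ndarray, observed: np.ndarray, cols: slice | np.ndarray):
        lo = np.quantile(observed, params.q_low)
        hi = np.quantile(observed, params.q_high)
        n_missing = int(col_mask.sum())
        draws = lo + (hi - lo) * rng.beta(params.beta_a, params.beta_b, size=n_missing)
        block = out[:, cols]
        block[col_mask] = draws
        out[:, cols] = block

    if params.per_column:
        for j in range(out.shape[1]):
            col = out[:, j]
            obs = col[~np.isnan(col)]
            if obs.size < 2:
                raise ValueError(
                    f"column {table.sample_sheet[j].name!r} has {obs.size} observed "
                    "values; cannot estimate per-column quantiles"
                )
            _fill(np.isnan(col)[:, None], obs, slice(j, j + 1))
    else:
        obs = out[~np.isnan(out)]
        _fill(np.isnan(out), obs, slice(None))

    imputed = pd.DataFrame(missing.values, index=vals.index, columns=vals.columns)
    new_vals = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return table.with_intensities(new_vals, imputed=imputed)


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns (t, df, p) with t = (mean a - mean b) / sqrt(sa^2/na + sb^2/nb)
    and the Welch-Satterthwaite df. If both groups are constant and
    equal, returns (0, na+nb-2, 1). If both are constant but unequal
    the statistic is infinite and p is returned as the smallest
    positive float (sentinel for "p below machine precision").
    """
    t, df, p = welch_test_matrix(
        np.asarray(a, dtype=float)[None, :], np.asarray(b, dtype=float)[None, :]
    )
    return float(t[0]), float(df[0]), float(p[0])


def welch_test_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test for matrices (rows = proteins, cols = replicates)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    zero_se = se2 == 0
    equal_means = ma == mb
    t = np.where(
        zero_se,
        np.where(equal_means, 0.0, np.where(ma > mb, np.inf, -np.inf)),
        t,
    )
    df = np.where(zero_se, float(na + nb - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), TINY_P, p)
    p = np.where(zero_se & equal_means, 1.0, p)
    return t, df, p


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_enrichment(
    table: ProteinGroupTable,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
    imputation: ImputationParams = ImputationParams(),
    already_log2: bool = False,
) -> list[EnrichmentResult]:
    """Full label-free enrichment analysis of a (filtered) table.

    Transforms, imputes, Welch-tests bait vs control per protein, and
    applies the joint fold/p gate on each side. Results are sorted by
    (p, -|log2 fold change|, protein id) for reproducible output.
    """
    bait_cols = table.columns_for(condition="bait", quant_mode="lfq")
    ctrl_cols = table.columns_for(condition="control", quant_mode="lfq")
    if len(bait_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"need >=2 bait and >=2 control LFQ columns, got "
            f"{len(bait_cols)} bait / {len(ctrl_cols)} control"
        )
    work = table if already_log2 else log2_transform(table)
    work = impute_low_tail(work, imputation)

    A = work.intensities[bait_cols].to_numpy()
    B = work.intensities[ctrl_cols].to_numpy()
    t, df, p = welch_test_matrix(A, B)
    fc = A.mean(axis=1) - B.mean(axis=1)
    p_adj = _bh_adjust(p)
    assert work.imputed is not None
    n_imp_a = work.imputed[bait_cols].sum(axis=1).to_numpy()
    n_imp_b = work.imputed[ctrl_cols].sum(axis=1).to_numpy()

    lfc_min = thresholds.min_log2_fc
    if thresholds.strict:
        pass_bait = (fc > lfc_min) & (p < thresholds.max_p)
        pass_ctrl = (-fc > lfc_min) & (p < thresholds.max_p)
    else:
        pass_bait = (fc >= lfc_min) & (p <= thresholds.max_p)
        pass_ctrl = (-fc >= lfc_min) & (p <= thresholds.max_p)

    results = []
    for i, pid in enumerate(work.protein_ids):
        results.append(
            EnrichmentResult(
                protein_id=str(pid),
                mean_log2_bait=float(A[i].mean()),
                mean_log2_control=float(B[i].mean()),
                log2_fc=float(fc[i]),
                t_stat=float(t[i]),
                df=float(df[i]),
                p_value=float(p[i]),
                p_adj=float(p_adj[i]),
                enriched_in="bait" if pass_bait[i] else ("control" if pass_ctrl[i] else "none"),
                n_imputed_bait=int(n_imp_a[i]),
                n_imputed_control=int(n_imp_b[i]),
            )
        )
    results.sort(key=lambda r: (r.p_value, -abs(r.log2_fc), r.protein_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = [
        "protein_id", "mean_log2_bait", "mean_log2_control", "log2_fc",
        "t_stat", "df", "p_value", "p_adj", "enriched_in",
        "n_imputed_bait", "n_imputed_control",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


def write_volcano(
    results: Sequence[EnrichmentResult],
    out_dir: str | Path,
    plot: bool = True,
    basename: str = "enrichment",
) -> dict[str, Path]:
    """Write the results TSV and (optionally) a volcano plot.

    The TSV is always written; enriched points are drawn in black,
    background in gray, matching the usual volcano presentation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{basename}.tsv"
    frame = results_to_frame(results)
    frame.to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    written = {"tsv": tsv}
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        if len(frame):
            neglogp = -np.log10(frame["p_value"].clip(lower=TINY_P))
            bg = frame["enriched_in"] == "none"
            ax.scatter(frame.loc[bg, "log2_fc"], neglogp[bg], s=8, c="lightgray")
            ax.scatter(frame.loc[~bg, "log2_fc"], neglogp[~bg], s=12, c="black")
        ax.set_xlabel("log2 fold enrichment (bait - control)")
        ax.set_ylabel("-log10 p-value (Welch t-test)")
        png = out_dir / f"{basename}_volcano.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        written["plot"] = png
    return written
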