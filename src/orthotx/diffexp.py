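"""Differential expression with TMM normalization and a triple-threshold call.

Counts are normalized by trimmed mean of M-values (TMM): per-sample
scaling factors from a doubly trimmed (30% on M, 5% on A, two-sided),
precision-weighted mean of per-gene log2 count ratios against a reference
sample, rescaled to geometric mean 1. A focal-vs-rest contrast on log-CPM
gives per-gene log2 fold-change and a (optionally variance-moderated)
t-statistic; raw p-values are Benjamini–Hochberg adjusted. A gene is
called differentially expressed only when it clears all three thresholds:

    |log2FC| >= 2,  BH-adjusted P <= 0.05,  B >= 2.945,

where B is the log posterior odds of differential expression (2.945 =
ln 19, i.e. 95% posterior probability). The exact empirical-Bayes B of
hierarchical linear-model pipelines is out of scope; when no B column is
supplied an approximate-B is computed from a two-component scaled-t
mixture on the moderated t-statistic.

Term enrichment of a flagged gene list is scored by fold enrichment and a
one-sided Fisher's exact test against a background universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ThresholdConfig:
    """The triple threshold for calling a gene differentially expressed."""

    lfc_min: float = 2.0
    padj_max: float = 0.05
    b_min: float | None = 2.945

    def __post_init__(self) -> None:
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if not (0 < self.padj_max <= 1):
            raise ValueError("padj_max must be in (0, 1]")


@dataclass
class CountMatrix:
    """Gene × sample integer counts with per-sample group labels."""

    counts: pd.DataFrame  # genes as rows, samples as columns
    groups: pd.Series  # sample -> 'focal' | 'other'
    species: pd.Series | None = None  # sample -> species id

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"unlabelled samples: {sorted(missing)}")
        sizes = self.groups.loc[list(self.counts.columns)].value_counts()
        for g in ("focal", "other"):
            if sizes.get(g, 0) < 2:
                raise ValueError(f"need >= 2 samples in group {g!r} for testing")


def _sample_uq(col: np.ndarray, libsize: float) -> float:
    return float(np.quantile(col / libsize, 0.75))


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """TMM scaling factors, one per sample, geometric mean 1.

    The reference sample defaults to the one whose upper-quartile of
    library-size-scaled counts is closest to the mean upper-quartile.
    For each sample, genes with a zero in either the sample or the
    reference are excluded; M (log2 ratio of proportions) and A (average
    log2 abundance) are computed; genes within the central two-sided trim
    windows on both M and A are retained; the factor is 2 to the
    precision-weighted mean of retained M, with inverse binomial-variance
    approximation weights.
    """
    x = counts.to_numpy(dtype=float)
    libs = x.sum(axis=0)
    if (libs <= 0).any():
        bad = counts.columns[libs <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    samples = list(counts.columns)
    if ref_sample is None:
        uq = np.array([_sample_uq(x[:, j], libs[j]) for j in range(len(samples))])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = samples.index(ref_sample)
    xr, nr = x[:, ref_j], libs[ref_j]
    log_factors = np.zeros(len(samples))
    for j in range(len(samples)):
        if j == ref_j:
            continue
        xs, ns = x[:, j], libs[j]
        keep0 = (xs > 0) & (xr > 0)
        if not keep0.any():
            raise ValueError(
                f"sample {samples[j]!r} shares no expressed genes with the reference"
            )
        obs, ref = xs[keep0] / ns, xr[keep0] / nr
        m = np.log2(obs / ref)
        a = 0.5 * np.log2(obs * ref)
        n = m.size
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        lo_m, hi_m = math.floor(n * m_trim) + 1, n - math.floor(n * m_trim)
        lo_a, hi_a = math.floor(n * a_trim) + 1, n - math.floor(n * a_trim)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        w = 1.0 / ((ns - xs[keep0]) / (ns * xs[keep0]) + (nr - xr[keep0]) / (nr * xr[keep0]))
        f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        log_factors[j] = f if abs(f) > 1e-10 else 0.0
    log_factors -= log_factors.mean()  # geometric mean 1 in factor space
    return pd.Series(2.0 ** log_factors, index=samples, name="tmm_factor")


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2 counts per million on effective library sizes:
    log2((count + 0.5) / (libsize * factor + 1) * 1e6)."""
    x = counts.to_numpy(dtype=float)
    libs = x.sum(axis=0)
    f = np.ones(x.shape[1]) if factors is None else factors.loc[list(counts.columns)].to_numpy()
    if (f <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = libs * f + 1.0
    return pd.DataFrame(
        np.log2((x + 0.5) / eff * 1e6), index=counts.index, columns=counts.columns
    )


def group_contrast(
    logcpm: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    moderation: str = "shrink",
    prior_df: float = 4.0,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Per-gene focal-vs-other contrast on log2 expression.

    logFC = mean(focal) − mean(other). With ``moderation='shrink'`` the
    pooled within-group variance s² is shrunk toward a prior:
    s̃² = (d0·s0² + d·s²)/(d0 + d) with d0 = ``prior_df`` and s0² =
    ``prior_var`` (default: mean of the per-gene s²), and the t-statistic
    uses d0 + d degrees of freedom. ``moderation='none'`` is the ordinary
    pooled two-sample t-test.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    focal_cols = [c for c in logcpm.columns if groups[c] == "focal"]
    other_cols = [c for c in logcpm.columns if groups[c] == "other"]
    n1, n2 = len(focal_cols), len(other_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    xf = logcpm[focal_cols].to_numpy()
    xo = logcpm[other_cols].to_numpy()
    logfc = xf.mean(axis=1) - xo.mean(axis=1)
    d = n1 + n2 - 2
    ss = (xf.var(axis=1, ddof=1) * (n1 - 1) + xo.var(axis=1, ddof=1) * (n2 - 1)) / d
    if moderation == "none":
        if (ss == 0).any():
            raise ValueError(
                "zero within-group variance: t undefined; use moderation='shrink'"
            )
        var, df = ss, float(d)
    elif moderation == "shrink":
        s0sq = float(np.mean(ss)) if prior_var is None else prior_var
        if s0sq <= 0:
            raise ValueError("prior variance must be positive")
        var = (prior_df * s0sq + d * ss) / (prior_df + d)
        df = float(prior_df + d)
    else:
        raise ValueError("moderation must be 'none' or 'shrink'")
    se = np.sqrt(var * (1.0 / n1 + 1.0 / n2))
    t = logfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"logfc": logfc, "t": t, "df": df, "p_raw": p}, index=logcpm.index
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def b_threshold_from_probability(prob: float) -> float:
    """Smallest three-decimal log-odds b with sigmoid(b) >= prob.

    E.g. 0.95 → 2.945, since ln 19 = 2.9444…; B is a log posterior odds,
    so a posterior-probability cutoff translates to a log-odds cutoff.
    """
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must be in (0, 1)")
    logit = math.log(prob / (1.0 - prob))
    b = math.ceil(logit * 1000.0 - 1e-9) / 1000.0
    if 1.0 / (1.0 + math.exp(-b)) < prob:  # float-edge safety
        b = round(b + 0.001, 3)
    return b


def approximate_b(
    t: np.ndarray, df: float, prior_prob: float = 0.01, alt_scale: float = 5.0
) -> np.ndarray:
    """Approximate-B: ln posterior odds of differential expression from a
    two-component mixture on the t-statistic.

    Null: t ~ t(df); alternative: t/alt_scale ~ t(df) (a heavier-tailed,
    scaled copy). Prior probability of the alternative is ``prior_prob``.
    This preserves the decision-rule role of B without claiming the exact
    hierarchical-model statistic.
    """
    if not (0 < prior_prob < 1):
        raise ValueError("prior_prob must be in (0, 1)")
    t = np.asarray(t, dtype=float)
    log_f0 = stats.t.logpdf(t, df)
    log_f1 = stats.t.logpdf(t / alt_scale, df) - math.log(alt_scale)
    return math.log(prior_prob / (1 - prior_prob)) + log_f1 - log_f0


def call_differential(
    records: pd.DataFrame, cfg: ThresholdConfig = ThresholdConfig()
) -> pd.DataFrame:
    """Apply the triple threshold to a table with columns logfc, p_adj and
    (unless B-checking is disabled) b.

    Adds ``flagged`` and ``reason`` columns; the reason is the first
    failing condition in the order (lfc, padj, B), empty when flagged.
    """
    out = records.copy()
    if cfg.b_min is not None and "b" not in out.columns:
        raise ValueError(
            "records lack a 'b' column; supply B values or disable with b_min=None"
        )
    pass_lfc = out["logfc"].abs() >= cfg.lfc_min
    pass_padj = out["p_adj"] <= cfg.padj_max
    pass_b = (
        pd.Series(True, index=out.index)
        if cfg.b_min is None
        else out["b"] >= cfg.b_min
    )
    out["flagged"] = pass_lfc & pass_padj & pass_b
    reason = np.where(~pass_lfc, "lfc", np.where(~pass_padj, "padj", np.where(~pass_b, "B", "")))
    out["reason"] = reason
    return out


def run_de(
    cm: CountMatrix,
    cfg: ThresholdConfig = ThresholdConfig(),
    moderation: str = "shrink",
    prior_df: float = 4.0,
    prior_var: float | None = None,
    b_prior_prob: float = 0.01,
    external_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """End-to-end: TMM → log-CPM → contrast → BH → approximate-B → call.

    ``external_stats`` (columns among logfc, p_raw, b, indexed by gene)
    overrides the corresponding computed columns, for pipelines that bring
    their own fitted statistics to the threshold decision.
    """
    factors = tmm_factors(cm.counts)
    lc = log_cpm(cm.counts, factors)
    rec = group_contrast(lc, cm.groups, moderation, prior_df, prior_var)
    rec["b"] = approximate_b(rec["t"].to_numpy(), float(rec["df"].iloc[0]), b_prior_prob)
    if external_stats is not None:
        for col in ("logfc", "p_raw", "b"):
            if col in external_stats.columns:
                rec.loc[external_stats.index, col] = external_stats[col]
    rec["p_adj"] = bh_adjust(rec["p_raw"].to_numpy())
    return call_differential(rec, cfg)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    list_count: int
    list_size: int
    background_count: int
    background_size: int
    fold_enrichment: float
    fisher_p: float


def term_enrichment(
    gene_list: Sequence[str],
    term_map: Mapping[str, set[str] | frozenset[str] | Sequence[str]],
    background: Sequence[str],
) -> list[EnrichmentResult]:
    """Fold enrichment and one-sided Fisher's exact p per term.

    fold = (list_count/list_size) / (background_count/background_size);
    terms with no overlap with the list are reported with fold 0.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background must be non-empty")
    gl = set(gene_list)
    if not gl <= bg:
        raise ValueError("gene_list must be a subset of background")
    results = []
    for term in sorted(term_map):
        in_term = set(term_map[term]) & bg
        a = len(gl & in_term)
        b = len(gl) - a
        c = len(in_term) - a
        d = len(bg) - len(gl) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        fold = (
            (a / len(gl)) / (len(in_term) / len(bg)) if a and in_term else 0.0
        )
        results.append(
            EnrichmentResult(term, a, len(gl), len(in_term), len(bg), fold, float(p))
        )
    return results
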