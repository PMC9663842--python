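"""Differential expression between sexes from RNA-seq counts.

The model is the classic negative-binomial Wald contrast on median-of-ratios
normalised counts: per gene, the log2 ratio of female to male mean normalised
expression is tested against zero, with the standard error obtained by the
delta method from NB group-mean variances.  Dispersion is estimated by
method of moments with a small floor — no empirical-Bayes shrinkage, which
keeps the estimator transparent at the cost of some efficiency at n = 6 + 6.

Positive log2 fold-change means higher expression in females.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionCountMatrix

ALPHA_FLOOR = 1e-4
PSEUDOCOUNT = 0.5


def fpkm(counts: ExpressionCountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``fpkm[g, s] = count[g, s] / (length_g / 1e3) / (libsize_s / 1e6)``.
    """
    lib = counts.counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    kb = counts.gene_length_bp.to_numpy(float)[:, None] / 1e3
    per_million = lib.to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        counts.counts.to_numpy(float) / kb / per_million,
        index=counts.counts.index,
        columns=counts.counts.columns,
    )


def filter_low_expression(
    fpkm_mat: pd.DataFrame, sexes: pd.Series, threshold: float = 0.2
) -> list[str]:
    """Keep genes whose mean FPKM is >= threshold in males or in females.

    Mirrors the rule that transcripts below the threshold *in both sexes*
    are removed; a gene expressed in one sex only survives.
    """
    sexes = sexes.loc[fpkm_mat.columns]
    for sex in ("M", "F"):
        if (sexes == sex).sum() == 0:
            raise ValueError(f"no samples of sex {sex}")
    mean_m = fpkm_mat.loc[:, sexes == "M"].mean(axis=1)
    mean_f = fpkm_mat.loc[:, sexes == "F"].mean(axis=1)
    keep = (mean_m >= threshold) | (mean_f >= threshold)
    return list(fpkm_mat.index[keep])


def size_factors_median_of_ratios(counts: ExpressionCountMatrix) -> pd.Series:
    """Median-of-ratios sample scale factors, rescaled to geometric mean 1."""
    mat = counts.counts.to_numpy(float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene with positive counts in every sample")
    sub = mat[all_pos]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geomean)
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.counts.columns, name="size_factor")


def estimate_nb_dispersion(
    counts: ExpressionCountMatrix,
    size_factors: pd.Series,
    groups: pd.Series | None = None,
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalised counts.

    Group means are removed before pooling the within-group variance, so a
    real sex effect does not inflate the dispersion.  ``alpha = max(floor,
    (s2 - mbar) / mbar^2)`` with ``mbar`` the grand mean.
    """
    norm = counts.counts.to_numpy(float) / size_factors.loc[counts.samples].to_numpy()
    if groups is None:
        groups = pd.Series("all", index=counts.samples)
    groups = groups.loc[counts.samples]
    resid_ss = np.zeros(norm.shape[0])
    dof = 0
    for g in groups.unique():
        cols = (groups == g).to_numpy()
        sub = norm[:, cols]
        if cols.sum() < 2:
            continue
        resid_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += cols.sum() - 1
    if dof == 0:
        raise ValueError("need >=2 samples in some group")
    s2 = resid_ss / dof
    mbar = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mbar) / mbar**2
    alpha = np.where(np.isfinite(alpha), alpha, alpha_floor)
    alpha = np.maximum(alpha, alpha_floor)
    return pd.Series(alpha, index=counts.counts.index, name="dispersion")


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class DeResult:
    gene_id: str
    log2fc: float
    lfcse: float
    wald_stat: float
    p_value: float
    fdr: float = np.nan


class SexDifferentialExpression:
    """NB Wald differential-expression model contrasting females vs males.

    Parameters
    ----------
    counts : ExpressionCountMatrix
        Raw counts for the genes surviving the FPKM filter.
    sexes : pd.Series
        'M'/'F' per sample id.

    Examples
    --------
    >>> model = SexDifferentialExpression(counts, meta.sexes)  # doctest: +SKIP
    >>> res = model.fit()                                      # doctest: +SKIP
    >>> res.summary().head()                                   # doctest: +SKIP
    """

    def __init__(self, counts: ExpressionCountMatrix, sexes: pd.Series):
        self.counts = counts
        self.sexes = sexes.loc[counts.samples]
        for sex in ("M", "F"):
            if (self.sexes == sex).sum() < 2:
                raise ValueError(f"need >=2 samples of sex {sex}")

    def fit(self, pseudocount: float = PSEUDOCOUNT) -> "DeResults":
        sf = size_factors_median_of_ratios(self.counts)
        disp = estimate_nb_dispersion(self.counts, sf, groups=self.sexes)
        norm = self.counts.counts.to_numpy(float) / sf.to_numpy()
        is_f = (self.sexes == "F").to_numpy()
        is_m = (self.sexes == "M").to_numpy()
        mean_f = norm[:, is_f].mean(axis=1)
        mean_m = norm[:, is_m].mean(axis=1)
        lfc = np.log2((mean_f + pseudocount) / (mean_m + pseudocount))
        alpha = disp.to_numpy()

        def group_var(mean_g, cols):
            # var of the normalised-count group mean under NB(mu, alpha):
            # per sample var(c/sf) = mu/sf + alpha mu^2
            inv_sf = 1.0 / sf.to_numpy()[cols]
            n = cols.sum()
            return (mean_g[:, None] * inv_sf[None, :] + alpha[:, None] * mean_g[:, None] ** 2).sum(
                axis=1
            ) / n**2

        var_f = group_var(mean_f, is_f)
        var_m = group_var(mean_m, is_m)
        ln2sq = np.log(2.0) ** 2
        var_lfc = var_f / ((mean_f + pseudocount) ** 2 * ln2sq) + var_m / (
            (mean_m + pseudocount) ** 2 * ln2sq
        )
        lfcse = np.sqrt(np.maximum(var_lfc, 1e-12))
        wald = lfc / lfcse
        # t reference with df = n - 2: the group-mean variances are estimated
        # from the same 12 samples, and a normal reference is visibly
        # anti-conservative at this depth
        df = int(is_f.sum() + is_m.sum() - 2)
        p = 2 * stats.t.sf(np.abs(wald), df=df)
        p = np.where((mean_f == mean_m), 1.0, p)
        table = pd.DataFrame(
            dict(
                gene_id=self.counts.genes,
                log2fc=lfc,
                lfcse=lfcse,
                wald_stat=wald,
                p_value=p,
                fdr=bh_fdr(p),
            )
        ).set_index("gene_id", drop=False)
        return DeResults(self, table, sf, disp)


class DeResults:
    """Fitted DE contrast: per-gene log2FC, SE, Wald p and BH FDR."""

    def __init__(
        self,
        model: SexDifferentialExpression,
        table: pd.DataFrame,
        size_factors: pd.Series,
        dispersions: pd.Series,
    ):
        self.model = model
        self.table = table
        self.size_factors = size_factors
        self.dispersions = dispersions

    def summary(self, top: int | None = 10) -> pd.DataFrame:
        out = self.table.sort_values("p_value")
        return out if top is None else out.head(top)

    def call_degs(self, fdr_max: float = 0.05, lfc_min: float = 2.0) -> list[str]:
        """Differentially expressed genes: FDR < 0.05 and |log2FC| > 2."""
        t = self.table
        keep = (t["fdr"] < fdr_max) & (t["log2fc"].abs() > lfc_min)
        return list(t.index[keep.fillna(False)])

    def call_candidates(self, lfc_min: float = 1.0) -> list[str]:
        """Integration candidates: |log2FC| > 1, ignoring FDR."""
        keep = self.table["log2fc"].abs() > lfc_min
        return list(self.table.index[keep])

    def to_tsv(self, path) -> None:
        self.table.drop(columns="gene_id").to_csv(path, sep="\t")


def call_degs(results: DeResults, fdr_max: float = 0.05, lfc_min: float = 2.0) -> list[str]:
    return results.call_degs(fdr_max=fdr_max, lfc_min=lfc_min)


def call_candidates(results: DeResults, lfc_min: float = 1.0) -> list[str]:
    return results.call_candidates(lfc_min=lfc_min)
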