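"""Differential methylation between sexes from per-cytosine call tables.

Sites are analysed separately per sequence context (CG, CHG, CHH).  Group
methylation means are smoothed by pooling reads over a window of neighbouring
same-context sites; site-level dispersion is estimated under a beta-binomial
model by method of moments; a Wald statistic contrasts the smoothed female
and male means, with the variance of each smoothed mean computed from
phi-inflated binomial variances pooled over the same window.  Differentially
methylated regions (DMRs) are then called by a rule set: cluster sub-0.01
sites, require minimum length 50 bp, >=3 sites, >=50% significant, and merge
regions closer than 50 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GeneModel, GenomicInterval
from .io import CONTEXTS, MethylationCallTable, SampleTable

PHI_FLOOR = 1e-3
PHI_CEIL = 0.5


def collapse_cpg_strands(calls: MethylationCallTable) -> MethylationCallTable:
    """Merge opposite-strand CpG calls at adjacent positions (p on '+',
    p+1 on '-') into one '+' record with summed reads.

    By default CG sites on opposite strands are analysed separately; this
    optional preprocessing pools them when symmetric CpG methylation can be
    assumed.  Non-CG contexts pass through unchanged.
    """
    t = calls.table
    cg = t[t["context"] == "CG"]
    plus = cg[cg["strand"] == "+"].set_index(["chrom", "pos"])
    minus = cg[cg["strand"] == "-"]
    consumed = []
    merged = plus.copy()
    for idx, row in minus.iterrows():
        key = (row["chrom"], row["pos"] - 1)
        if key in merged.index:
            for s in calls.samples:
                merged.loc[key, f"{s}_meth"] += row[f"{s}_meth"]
                merged.loc[key, f"{s}_total"] += row[f"{s}_total"]
            consumed.append(idx)
    rest = t.drop(index=consumed)
    rest = rest[~((rest["context"] == "CG") & (rest["strand"] == "+"))]
    out = pd.concat([rest, merged.reset_index()], ignore_index=True)
    return MethylationCallTable(out[t.columns], calls.samples)


# ---------------------------------------------------------------------------
# smoothing and dispersion
# ---------------------------------------------------------------------------


def _group_read_sums(calls: MethylationCallTable, samples: list[str]):
    m = calls.table[[f"{s}_meth" for s in samples]].to_numpy(float).sum(axis=1)
    n = calls.table[[f"{s}_total" for s in samples]].to_numpy(float).sum(axis=1)
    return m, n


def _window_slices(pos: np.ndarray, half: int):
    """For sorted positions, [lo, hi) index bounds of each site's window."""
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    return lo, hi


def smooth_methylation(
    calls: MethylationCallTable, sexes: pd.Series, window_bp: int = 500
) -> pd.DataFrame:
    """Window-pooled group methylation means per site.

    For each site and sex the methylated and total reads of all same-context
    sites within +/- window_bp/2 on the same chromosome are summed; the
    smoothed mean is their ratio (NaN where the window has zero coverage).
    Returns a frame aligned with ``calls.table`` with columns ``mu_F``,
    ``mu_M``, ``n_F``, ``n_M`` (pooled totals).
    """
    t = calls.table
    males = [s for s in calls.samples if sexes.get(s) == "M"]
    females = [s for s in calls.samples if sexes.get(s) == "F"]
    out = {k: np.full(len(t), np.nan) for k in ("mu_F", "mu_M")}
    out["n_F"] = np.zeros(len(t))
    out["n_M"] = np.zeros(len(t))
    half = window_bp // 2
    for (chrom, context), idx in t.groupby(["chrom", "context"], sort=False).groups.items():
        idx = np.asarray(idx)
        pos = t.loc[idx, "pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        idx, pos = idx[order], pos[order]
        lo, hi = _window_slices(pos, half)
        for sex, samples in (("F", females), ("M", males)):
            sub = calls.table.loc[idx]
            m = sub[[f"{s}_meth" for s in samples]].to_numpy(float).sum(axis=1)
            n = sub[[f"{s}_total" for s in samples]].to_numpy(float).sum(axis=1)
            cm = np.concatenate([[0.0], np.cumsum(m)])
            cn = np.concatenate([[0.0], np.cumsum(n)])
            wm = cm[hi] - cm[lo]
            wn = cn[hi] - cn[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                mu = np.where(wn > 0, wm / np.where(wn > 0, wn, 1), np.nan)
            out[f"mu_{sex}"][idx] = mu
            out[f"n_{sex}"][idx] = wn
    return pd.DataFrame(out, index=t.index)


def estimate_site_dispersion(
    calls: MethylationCallTable,
    sexes: pd.Series,
    smoothed: pd.DataFrame | None = None,
    phi_floor: float = PHI_FLOOR,
    phi_ceil: float = PHI_CEIL,
) -> np.ndarray:
    """Per-site beta-binomial dispersion phi by method of moments.

    Residual sums of squares around each sex's smoothed mean are pooled:
    ``phi = sum[(m_i - n_i p)^2 - n_i p (1-p)] / sum[n_i (n_i - 1) p (1-p)]``
    over covered samples of both sexes, clamped to [phi_floor, phi_ceil].
    Sites with <2 covered samples overall fall back to the floor.
    """
    if smoothed is None:
        smoothed = smooth_methylation(calls, sexes)
    t = calls.table
    num = np.zeros(len(t))
    den = np.zeros(len(t))
    covered = np.zeros(len(t))
    for sex in ("F", "M"):
        p = smoothed[f"mu_{sex}"].to_numpy()
        pq = np.clip(p * (1 - p), 1e-8, None)
        samples = [s for s in calls.samples if sexes.get(s) == sex]
        for s in samples:
            m = t[f"{s}_meth"].to_numpy(float)
            n = t[f"{s}_total"].to_numpy(float)
            has = (n > 0) & np.isfinite(p)
            resid = np.where(has, (m - n * p) ** 2 - n * pq, 0.0)
            num += resid
            den += np.where(has, n * (n - 1) * pq, 0.0)
            covered += has
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, phi_floor)
    phi = np.where(covered >= 2, phi, phi_floor)
    return np.clip(phi, phi_floor, phi_ceil)


# ---------------------------------------------------------------------------
# DML Wald test
# ---------------------------------------------------------------------------


@dataclass
class DmlResult:
    site: GenomicInterval
    context: str
    mu_f: float
    mu_m: float
    phi: float
    wald_stat: float
    p_value: float


class DifferentialMethylation:
    """Smoothed beta-binomial Wald model for per-site sex differences.

    Parameters
    ----------
    calls : MethylationCallTable
    sexes : pd.Series mapping sample id to 'M'/'F'
    window_bp : size of the smoothing window (total span, centred).
    """

    def __init__(
        self,
        calls: MethylationCallTable,
        sexes: pd.Series,
        window_bp: int = 500,
    ):
        self.calls = calls
        self.sexes = sexes
        self.window_bp = window_bp

    def fit(self) -> "DmlResults":
        calls, sexes = self.calls, self.sexes
        smoothed = smooth_methylation(calls, sexes, self.window_bp)
        phi = estimate_site_dispersion(calls, sexes, smoothed)
        t = calls.table
        half = self.window_bp // 2
        var = {}
        for sex in ("F", "M"):
            samples = [s for s in calls.samples if sexes.get(s) == sex]
            p = smoothed[f"mu_{sex}"].to_numpy()
            pq = p * (1 - p)
            v = np.zeros(len(t))
            for (chrom, context), idx in t.groupby(
                ["chrom", "context"], sort=False
            ).groups.items():
                idx = np.asarray(idx)
                pos = t.loc[idx, "pos"].to_numpy()
                order = np.argsort(pos, kind="mergesort")
                idx, pos = idx[order], pos[order]
                lo, hi = _window_slices(pos, half)
                # per-site sum over samples of n_s (1 + (n_s - 1) phi_i)
                contrib = np.zeros(len(idx))
                sub = t.loc[idx]
                for s in samples:
                    n = sub[f"{s}_total"].to_numpy(float)
                    contrib += n * (1.0 + (n - 1.0) * phi[idx])
                c = np.concatenate([[0.0], np.cumsum(contrib)])
                pooled = c[hi] - c[lo]
                v[idx] = pooled * pq[idx]
            total = smoothed[f"n_{sex}"].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                var[sex] = np.where(total > 0, v / total**2, np.nan)
        mu_f, mu_m = smoothed["mu_F"].to_numpy(), smoothed["mu_M"].to_numpy()
        se = np.sqrt(var["F"] + var["M"])
        diff = mu_f - mu_m
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(se > 0, diff / np.where(se > 0, se, 1), 0.0)
        stat = np.where(diff == 0, 0.0, stat)
        p = 2 * stats.norm.sf(np.abs(stat))
        ok = np.isfinite(mu_f) & np.isfinite(mu_m)
        table = t[["chrom", "pos", "strand", "context"]].copy()
        # raw (unsmoothed) per-site read-pooled fractions, used for DMR means
        for sex in ("F", "M"):
            samples = [s for s in calls.samples if sexes.get(s) == sex]
            m = t[[f"{s}_meth" for s in samples]].to_numpy(float).sum(axis=1)
            n = t[[f"{s}_total" for s in samples]].to_numpy(float).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                table[f"raw_{sex.lower()}"] = np.where(
                    n > 0, m / np.where(n > 0, n, 1), np.nan
                )
        table["mu_f"] = mu_f
        table["mu_m"] = mu_m
        table["phi"] = phi
        table["wald_stat"] = np.where(ok, stat, np.nan)
        table["p_value"] = np.where(ok, p, np.nan)
        n_skipped = int((~ok).sum())
        return DmlResults(self, table[ok].reset_index(drop=True), n_skipped)


class DmlResults:
    """Per-site Wald results; DMLs are sites with p below a threshold."""

    def __init__(self, model: DifferentialMethylation, table: pd.DataFrame, n_skipped: int = 0):
        self.model = model
        self.table = table
        self.n_skipped = n_skipped

    def dmls(self, p_max: float = 0.001) -> pd.DataFrame:
        return self.table[self.table["p_value"] < p_max]

    def summary(self, p_max: float = 0.001) -> pd.DataFrame:
        rows = []
        for ctx in CONTEXTS:
            sub = self.table[self.table["context"] == ctx]
            rows.append(
                dict(
                    context=ctx,
                    n_sites=len(sub),
                    n_dml=int((sub["p_value"] < p_max).sum()),
                )
            )
        return pd.DataFrame(rows)

    def call_dmrs(self, **kwargs) -> list["Dmr"]:
        return call_dmrs(self.table, **kwargs)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------


@dataclass
class Dmr:
    interval: GenomicInterval
    context: str
    n_sites: int
    n_significant: int
    mean_meth_f: float
    mean_meth_m: float
    genomic_context: str = ""
    assigned_gene: str | None = None
    distance_to_gene: int | None = None

    @property
    def length(self) -> int:
        return len(self.interval)


def _pooled_fraction(table: pd.DataFrame, mask: np.ndarray, sex_cols: dict) -> dict:
    out = {}
    for sex, (mcols, ncols) in sex_cols.items():
        m = table.loc[mask, mcols].to_numpy(float)
        n = table.loc[mask, ncols].to_numpy(float)
        msum, nsum = m.sum(axis=1), n.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(nsum > 0, msum / np.where(nsum > 0, nsum, 1), np.nan)
        out[sex] = float(np.nanmean(frac)) if np.isfinite(frac).any() else np.nan
    return out


def call_dmrs(
    dml_table: pd.DataFrame,
    p_site: float = 0.01,
    min_len: int = 50,
    min_sites: int = 3,
    min_pct_sig: float = 0.5,
    cluster_gap: int = 100,
    merge_gap: int = 50,
) -> list[Dmr]:
    """Rule-based DMR calling from per-site Wald results.

    1. candidate sites: ``p < p_site``;
    2. cluster candidates with inter-candidate gap <= ``cluster_gap`` into
       proto-regions bounded by the first and last candidate;
    3. keep proto-regions with length >= ``min_len``, >= ``min_sites``
       analysed sites in span, and significant fraction >= ``min_pct_sig``;
    4. merge survivors separated by fewer than ``merge_gap`` intervening
       bases (gap = start2 - end1 - 1), recomputing counts and means.

    Group means are simple means over the span's per-site smoothed group
    means.  Each context and chromosome is processed independently.
    """
    out: list[Dmr] = []
    for (chrom, ctx), sub in dml_table.groupby(["chrom", "context"], sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        pvals = sub["p_value"].to_numpy()
        cand = pos[pvals < p_site]
        if len(cand) == 0:
            continue
        # 2: cluster candidates
        breaks = np.where(np.diff(cand) > cluster_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(cand) - 1]])
        regions = [(int(cand[a]), int(cand[b])) for a, b in zip(starts, ends)]

        fcol = "raw_f" if "raw_f" in sub.columns else "mu_f"
        mcol = "raw_m" if "raw_m" in sub.columns else "mu_m"

        def region_stats(lo: int, hi: int) -> Dmr:
            in_span = (pos >= lo) & (pos <= hi)
            n_sites = int(in_span.sum())
            n_sig = int((pvals[in_span] < p_site).sum())
            mu_f = float(sub.loc[in_span, fcol].mean())
            mu_m = float(sub.loc[in_span, mcol].mean())
            return Dmr(
                GenomicInterval(chrom, lo, hi),
                ctx,
                n_sites,
                n_sig,
                mu_f,
                mu_m,
            )

        # 3: filter
        kept = []
        for lo, hi in regions:
            d = region_stats(lo, hi)
            if (
                d.length >= min_len
                and d.n_sites >= min_sites
                and d.n_significant / d.n_sites >= min_pct_sig
            ):
                kept.append(d)
        # 4: merge close survivors
        merged: list[Dmr] = []
        for d in kept:
            if merged:
                gap = d.interval.start - merged[-1].interval.end - 1
                if gap < merge_gap:
                    merged[-1] = region_stats(
                        merged[-1].interval.start, d.interval.end
                    )
                    continue
            merged.append(d)
        out.extend(merged)
    return out


# ---------------------------------------------------------------------------
# annotation and per-DMR features
# ---------------------------------------------------------------------------


def annotate_genomic_context(
    dmr: Dmr,
    gene_models: list[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 1000,
) -> Dmr:
    """Assign a gene and a genomic-context label to a DMR.

    Overlapping genes win (largest overlap, ties by gene id); the label is
    the '/'-joined set of overlapped feature classes in precedence order
    Promoter > Exon > Intron.  A DMR with no overlapping gene is
    'Intergenic', assigned to the nearest gene by edge distance.
    """
    iv = dmr.interval

    def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
        if not a.overlaps(b):
            return 0
        return min(a.end, b.end) - max(a.start, b.start) + 1

    overlapping = [
        g for g in gene_models
        if g.body.overlaps(iv) or g.promoter(promoter_up, promoter_down).overlaps(iv)
    ]
    if overlapping:
        gene = max(
            overlapping,
            key=lambda g: (
                overlap_bp(g.body, iv) + overlap_bp(g.promoter(promoter_up, promoter_down), iv),
                # tie-break: lexicographically smaller id wins
            ),
        )
        ties = [
            g for g in overlapping
            if overlap_bp(g.body, iv) + overlap_bp(g.promoter(promoter_up, promoter_down), iv)
            == overlap_bp(gene.body, iv)
            + overlap_bp(gene.promoter(promoter_up, promoter_down), iv)
        ]
        gene = min(ties, key=lambda g: g.gene_id)
        classes = []
        if gene.promoter(promoter_up, promoter_down).overlaps(iv):
            classes.append("Promoter")
        if any(ex.overlaps(iv) for ex in gene.exons):
            classes.append("Exon")
        if any(intr.overlaps(iv) for intr in gene.introns):
            classes.append("Intron")
        label = "/".join(classes) if classes else "Intergenic"
        return replace(
            dmr, genomic_context=label, assigned_gene=gene.gene_id, distance_to_gene=0
        )
    if not gene_models:
        return replace(
            dmr, genomic_context="Intergenic", assigned_gene=None, distance_to_gene=None
        )
    best, best_d = None, None
    for g in gene_models:
        d = g.body.distance_to(iv)
        if d is None:
            continue
        if best_d is None or d < best_d or (d == best_d and g.gene_id < best.gene_id):
            best, best_d = g, d
    if best is None:
        return replace(
            dmr, genomic_context="Intergenic", assigned_gene=None, distance_to_gene=None
        )
    return replace(
        dmr,
        genomic_context="Intergenic",
        assigned_gene=best.gene_id,
        distance_to_gene=best_d,
    )


def dmr_mean_methylation(calls: MethylationCallTable, dmr: Dmr) -> pd.Series:
    """Per-sample mean methylation fraction over same-context sites in span.

    Samples with zero coverage at every site in the span are NaN (to be
    imputed by the integration block builder).
    """
    t = calls.table
    mask = (
        (t["chrom"] == dmr.interval.chrom)
        & (t["pos"] >= dmr.interval.start)
        & (t["pos"] <= dmr.interval.end)
        & (t["context"] == dmr.context)
    )
    frac = calls.fractions()[mask.to_numpy()]
    return frac.mean(axis=0, skipna=True)


@dataclass
class ContextSummary:
    context: str
    mean_f: float
    sd_f: float
    mean_m: float
    sd_m: float
    cohens_d: float


def context_summary(calls: MethylationCallTable, sexes: pd.Series) -> list[ContextSummary]:
    """Global per-context methylation means, SDs and Cohen's D by sex.

    Site-level methylation is the read-pooled fraction per sex;
    ``cohens_d = |mean_f - mean_m| / sqrt((sd_f^2 + sd_m^2) / 2)``.
    """
    out = []
    t = calls.table
    males = [s for s in calls.samples if sexes.get(s) == "M"]
    females = [s for s in calls.samples if sexes.get(s) == "F"]
    for ctx in CONTEXTS:
        mask = (t["context"] == ctx).to_numpy()
        if mask.sum() < 2:
            continue
        vals = {}
        for sex, samples in (("F", females), ("M", males)):
            m = t.loc[mask, [f"{s}_meth" for s in samples]].to_numpy(float).sum(axis=1)
            n = t.loc[mask, [f"{s}_total" for s in samples]].to_numpy(float).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(n > 0, m / np.where(n > 0, n, 1), np.nan)
            vals[sex] = frac[np.isfinite(frac)]
        mean_f, sd_f = float(np.mean(vals["F"])), float(np.std(vals["F"], ddof=1))
        mean_m, sd_m = float(np.mean(vals["M"])), float(np.std(vals["M"], ddof=1))
        pooled = np.sqrt((sd_f**2 + sd_m**2) / 2.0)
        d = abs(mean_f - mean_m) / pooled if pooled > 0 else 0.0
        out.append(ContextSummary(ctx, mean_f, sd_f, mean_m, sd_m, float(d)))
    return out


def dmrs_to_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=d.interval.chrom,
                start=d.interval.start,
                end=d.interval.end,
                length=d.length,
                context=d.context,
                n_sites=d.n_sites,
                n_significant=d.n_significant,
                mean_meth_f=d.mean_meth_f,
                mean_meth_m=d.mean_meth_m,
                genomic_context=d.genomic_context,
                assigned_gene=d.assigned_gene if d.assigned_gene else "",
                distance_to_gene=d.distance_to_gene,
            )
            for d in dmrs
        ]
    )
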