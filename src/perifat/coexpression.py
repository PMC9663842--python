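"""Per-sex signed weighted co-expression networks and DcoExp calling.

The network construction follows the signed WGCNA recipe: adjacency
``a_ij = ((1 + cor_ij) / 2)^beta``, topological overlap similarity, and
average-linkage clustering of ``1 - TOM``, with a k-means-style reassignment
of genes to the module eigengene they correlate with best (up to 20
iterations).  Cross-sex module comparison uses a one-sided Fisher exact test
of gene-set overlap; a module with no significantly overlapping counterpart
in the other sex after BH adjustment is a differentially co-expressed
(DcoExp) module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import bh_fdr
from .io import SampleTable

GREY = "grey"


def good_samples_genes(
    expr: pd.DataFrame, max_missing_frac: float = 0.5
) -> pd.DataFrame:
    """Drop zero-variance genes and genes/samples with >50% missing values.

    ``expr`` is genes x samples (FPKM or similar).
    """
    out = expr.copy()
    sample_missing = out.isna().mean(axis=0)
    out = out.loc[:, sample_missing <= max_missing_frac]
    gene_missing = out.isna().mean(axis=1)
    out = out.loc[gene_missing <= max_missing_frac]
    var = out.var(axis=1, ddof=1)
    out = out.loc[var.fillna(0) > 0]
    if out.empty:
        raise ValueError("no genes left after quality filtering")
    return out


def gene_correlation(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation (genes are rows)."""
    x = expr.to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((x**2).sum(axis=1))
    sd[sd == 0] = 1.0
    c = (x / sd[:, None]) @ (x / sd[:, None]).T
    return np.clip(c, -1.0, 1.0)


def signed_adjacency(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Signed adjacency ``((1 + cor)/2)^beta`` with unit diagonal."""
    a = ((1.0 + gene_correlation(expr)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: range = range(1, 21),
    r2_target: float = 0.8,
    fallback: int = 12,
    n_bins: int = 10,
    min_mean_connectivity: float = 1.0,
) -> int:
    """Smallest power whose scale-free topology fit reaches R^2 >= 0.8.

    The fit regresses log10 frequency on log10 binned connectivity and
    requires a negative slope and a mean connectivity of at least one —
    without the connectivity guard the fit spuriously improves on iid
    noise as the power drives the network towards emptiness.  If no power
    qualifies, returns the fallback.
    """
    for beta in powers:
        a = signed_adjacency(expr, beta)
        k = a.sum(axis=1) - 1.0
        if k.mean() < min_mean_connectivity:
            continue
        k = k[k > 0]
        if len(k) < n_bins:
            continue
        edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
        which = np.digitize(k, edges[1:-1])
        freq, centers = [], []
        for b in range(n_bins):
            mask = which == b
            if mask.sum() == 0:
                continue
            freq.append(mask.mean())
            centers.append(k[mask].mean())
        if len(freq) < 3:
            continue
        lx, ly = np.log10(centers), np.log10(freq)
        slope, _, r, _, _ = stats.linregress(lx, ly)
        if slope < 0 and r**2 >= r2_target:
            return beta
    return fallback


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal.

    ``TOM_ij = (sum_u a_iu a_uj - 2 a_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)``
    where the summation excludes u in {i, j} and ``k_i = sum_{u != i} a_iu``.
    """
    a = adjacency
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    prod = a @ a
    # remove u = i and u = j terms: a_ii a_ij + a_ij a_jj = 2 a_ij
    shared = prod - 2.0 * a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# WGCNA-style module colour labels, in assignment order
_LABELS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
]


def _label(i: int) -> str:
    return _LABELS[i] if i < len(_LABELS) else f"module{i + 1}"


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    corr: np.ndarray | None = None,
    min_module_cor: float = 0.5,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a largest-gap branch cut.

    Candidate cut heights are a small set of merge-height quantiles plus
    the midpoint of the largest jump between consecutive merge heights in
    the upper half of the dendrogram (which marks the transition from
    within-block to between-block merges when the blocks dominate).  Each
    candidate is scored by the number of clusters that qualify as modules:
    at least ``min_module_size`` genes and — when the gene-gene correlation
    matrix is supplied — a mean within-cluster correlation of at least
    ``min_module_cor``, a coherence chance clusters of unrelated genes fall
    well short of.  The best cut wins (ties: more genes inside modules,
    then the lower cut).  Everything outside a module is grey (unassigned);
    labels are ordered by decreasing module size.
    """
    n = len(gene_ids)
    if n < 2 or min_module_size > n:
        return pd.Series(GREY, index=gene_ids)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    heights = link[:, 2]
    candidates = [float(np.quantile(heights, q)) for q in (0.3, 0.4, 0.5, 0.6, 0.7)]
    gaps = np.diff(heights)
    start = len(heights) // 2
    if len(gaps) > start:
        i = start + int(np.argmax(gaps[start:]))
        candidates.append(float((heights[i] + heights[i + 1]) / 2.0))

    def valid_clusters(flat: np.ndarray) -> list[int]:
        sizes = pd.Series(flat).value_counts()
        keep = []
        for c in sizes[sizes >= min_module_size].index:
            if corr is not None:
                members = np.where(flat == c)[0]
                sub = corr[np.ix_(members, members)]
                iu = np.triu_indices(len(members), 1)
                if sub[iu].mean() < min_module_cor:
                    continue
            keep.append(int(c))
        return keep

    best = None  # (n_modules, n_assigned, -cut), (flat, keep)
    for cut_h in candidates:
        flat = hierarchy.fcluster(link, t=cut_h, criterion="distance")
        keep = valid_clusters(flat)
        n_assigned = int(np.isin(flat, keep).sum())
        key = (len(keep), n_assigned, -cut_h)
        if best is None or key > best[0]:
            best = (key, (flat, keep))
    flat, keep = best[1]
    sizes = pd.Series(flat).value_counts()
    ordered = sorted(keep, key=lambda c: (-sizes[c], c))
    mapping = {c: _label(i) for i, c in enumerate(ordered)}
    labels = [mapping.get(c, GREY) for c in flat]
    return pd.Series(labels, index=gene_ids)


def module_eigengene(expr: pd.DataFrame, member_genes: list[str]) -> pd.Series:
    """First principal component of the standardised member submatrix.

    Returns one score per sample, scaled to unit variance, with the sign
    fixed so that it correlates non-negatively with mean member expression.
    """
    if len(member_genes) < 2:
        raise ValueError("need >=2 member genes for an eigengene")
    sub = expr.loc[member_genes].to_numpy(float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance member gene")
    z = (sub - mu) / sd
    # samples x genes; first right singular vector gives per-sample scores
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0:
        raise ValueError("singular member submatrix")
    scores = vt[0]
    scores = scores / scores.std(ddof=1)
    rowmean = z.mean(axis=0)
    if np.corrcoef(scores, rowmean)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=expr.columns, name="eigengene")


@dataclass
class ModuleSet:
    """Gene-to-module assignment with eigengenes, for one sex."""

    sex: str
    assignment: pd.Series  # gene -> label; 'grey' = unassigned
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    soft_power: int = 12

    @property
    def modules(self) -> list[str]:
        return [m for m in self.assignment.unique() if m != GREY]

    def members(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.assignment.index, "module": self.assignment.to_numpy(),
             "sex": self.sex}
        )


def _compute_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    cols = {}
    for m in sorted(assignment.unique()):
        if m == GREY:
            continue
        cols[m] = module_eigengene(expr, list(assignment.index[assignment == m]))
    return pd.DataFrame(cols, index=expr.columns)


def kmeans_refine(
    expr: pd.DataFrame,
    assignment: pd.Series,
    sex: str = ".",
    iterations: int = 20,
    min_module_size: int = 30,
    soft_power: int = 12,
    grey_join_min_cor: float = 0.7,
) -> ModuleSet:
    """Reassign genes to the module eigengene they correlate with best.

    Up to ``iterations`` rounds; ties keep the current label; modules that
    shrink below ``min_module_size`` dissolve to grey.  Grey genes join a
    module only when their best eigengene correlation reaches
    ``grey_join_min_cor`` — detection stragglers are recovered without
    sweeping noise genes into modules.  Deterministic.
    """
    assign = assignment.copy()
    if not any(m != GREY for m in assign.unique()):
        raise ValueError("no non-grey module to refine")
    for _ in range(iterations):
        eig = _compute_eigengenes(expr, assign)
        if eig.empty:
            break
        x = expr.to_numpy(float)
        xz = x - x.mean(axis=1, keepdims=True)
        xsd = np.sqrt((xz**2).sum(axis=1))
        xsd[xsd == 0] = 1.0
        e = eig.to_numpy(float).T  # modules x samples
        ez = e - e.mean(axis=1, keepdims=True)
        esd = np.sqrt((ez**2).sum(axis=1))
        cors = (xz / xsd[:, None]) @ (ez / esd[:, None]).T  # genes x modules
        best_idx = np.argmax(cors, axis=1)
        best_cor = cors[np.arange(len(cors)), best_idx]
        labels = list(eig.columns)
        new = assign.copy()
        for gi, gene in enumerate(assign.index):
            cur = assign.iloc[gi]
            cand = labels[best_idx[gi]]
            if cur == GREY:
                if best_cor[gi] >= grey_join_min_cor:
                    new.iloc[gi] = cand
                continue
            if cand == cur:
                continue
            cur_cor = cors[gi, labels.index(cur)] if cur in labels else -np.inf
            if best_cor[gi] > cur_cor:
                new.iloc[gi] = cand
        # dissolve undersized modules
        sizes = new.value_counts()
        for m in list(sizes.index):
            if m != GREY and sizes[m] < min_module_size:
                new[new == m] = GREY
        if new.equals(assign):
            assign = new
            break
        assign = new
    eig = _compute_eigengenes(expr, assign)
    return ModuleSet(sex=sex, assignment=assign, eigengenes=eig, soft_power=soft_power)


def build_network(
    expr: pd.DataFrame,
    sex: str,
    min_module_size: int = 30,
    min_module_cor: float = 0.5,
    kmeans_iterations: int = 20,
    soft_power: int | None = None,
) -> ModuleSet:
    """Full per-sex pipeline: QC -> soft power -> TOM -> modules -> refine."""
    clean = good_samples_genes(expr)
    beta = soft_power if soft_power is not None else pick_soft_threshold(clean)
    adj = signed_adjacency(clean, beta)
    tom = tom_similarity(adj)
    prelim = detect_modules(
        tom, list(clean.index), min_module_size,
        corr=gene_correlation(clean), min_module_cor=min_module_cor,
    )
    if not any(m != GREY for m in prelim.unique()):
        return ModuleSet(sex=sex, assignment=prelim, soft_power=beta)
    return kmeans_refine(
        clean, prelim, sex=sex, iterations=kmeans_iterations,
        min_module_size=min_module_size, soft_power=beta,
    )


@dataclass
class DcoExpResult:
    module: str
    sex: str
    best_match_module: str | None
    fisher_p: float
    fisher_fdr: float
    specific: bool


def dcoexp_fisher(
    modules_m: ModuleSet,
    modules_f: ModuleSet,
    background: list[str],
    fdr_max: float = 0.05,
) -> list[DcoExpResult]:
    """Cross-sex module overlap by one-sided Fisher exact tests.

    For every ordered pair (module in one sex, module in the other), the
    2x2 table (overlap, A-only, B-only, rest of background) is tested for
    over-enrichment; BH adjustment is applied within each direction.  A
    module is *specific* (DcoExp) when no other-sex module overlaps it at
    FDR < 0.05.
    """
    bg = set(background)
    for ms in (modules_m, modules_f):
        extra = set(ms.assignment.index) - bg
        if extra:
            raise ValueError(f"module genes outside background: {sorted(extra)[:3]}")
    out: list[DcoExpResult] = []
    for ms, other in ((modules_m, modules_f), (modules_f, modules_m)):
        rows = []
        for a in ms.modules:
            genes_a = set(ms.members(a))
            for b in other.modules:
                genes_b = set(other.members(b))
                k = len(genes_a & genes_b)
                table = [
                    [k, len(genes_a - genes_b)],
                    [len(genes_b - genes_a), len(bg - genes_a - genes_b)],
                ]
                _, p = stats.fisher_exact(table, alternative="greater")
                rows.append((a, b, p))
        if not rows:
            continue
        pvals = np.array([r[2] for r in rows])
        fdrs = bh_fdr(pvals)
        per_module: dict[str, list[tuple[str, float, float]]] = {}
        for (a, b, p), q in zip(rows, fdrs):
            per_module.setdefault(a, []).append((b, p, q))
        for a, hits in per_module.items():
            hits.sort(key=lambda h: (h[2], h[1], h[0]))
            b, p, q = hits[0]
            specific = q >= fdr_max
            out.append(
                DcoExpResult(
                    module=a,
                    sex=ms.sex,
                    best_match_module=None if specific else b,
                    fisher_p=p,
                    fisher_fdr=q,
                    specific=bool(specific),
                )
            )
    return out


@dataclass
class ModuleTraitCorrelation:
    module: str
    sex: str
    trait: str
    pearson_r: float
    p_value: float
    significant: bool


def module_trait_correlation(
    module_set: ModuleSet,
    metadata: SampleTable,
    traits: list[str] | None = None,
    p_max: float = 0.05,
) -> list[ModuleTraitCorrelation]:
    """Pearson correlation between module eigengenes and fat traits.

    Correlations are computed strictly within the module set's own sex, as
    eigengenes of male modules only exist for male samples.
    """
    traits = traits if traits is not None else metadata.trait_names
    out = []
    sex_samples = [
        s for s in module_set.eigengenes.index
        if metadata.frame.loc[s, "sex"] == module_set.sex
    ]
    for m in module_set.eigengenes.columns:
        eig = module_set.eigengenes.loc[sex_samples, m]
        for t in traits:
            vals = metadata.frame.loc[sex_samples, t].astype(float)
            ok = vals.notna()
            if ok.sum() < 3 or vals[ok].std(ddof=1) == 0:
                out.append(
                    ModuleTraitCorrelation(m, module_set.sex, t, np.nan, np.nan, False)
                )
                continue
            r, p = stats.pearsonr(eig[ok], vals[ok])
            out.append(
                ModuleTraitCorrelation(m, module_set.sex, t, float(r), float(p), bool(p < p_max))
            )
    return out
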