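"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the post-quantification products of a 6-male /
6-female lamb perirenal-fat experiment: negative-binomial RNA-seq counts
with planted sex log2 fold-changes, beta-binomial WGBS calls with
context-specific baselines (CG ~0.6, CHG ~0.2, CHH ~0.15) and planted DMRs
— a configurable fraction placed inside planted genes — sex-specific
co-expressed gene blocks driven by latent factors, fat-percentage traits
correlated with those factors, and a QTL table enriched near planted genes.
Every output parses through :mod:`perifat.io` readers, and a
:class:`GroundTruth` object records what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import GeneModel, GenomicInterval
from .io import (
    CONTEXTS,
    ExpressionCountMatrix,
    MethylationCallTable,
    QtlRecord,
    SampleTable,
)


def _default_module_spec():
    # (size, within-sex correlation, sex-specificity: 'M', 'F' or None=shared)
    return [
        (60, 0.85, "M"),
        (60, 0.85, "F"),
        (60, 0.80, None),
        (60, 0.80, None),
        (60, 0.80, None),
    ]


def _default_trait_spec():
    # trait -> (linked module index, target correlation with its factor)
    return {
        "renal": (0, 0.8),
        "pelvic": (1, 0.8),
        "renal_and_pelvic": (2, 0.7),
        "leg_intramuscular": (3, 0.7),
        "leg_subcutaneous": (4, 0.7),
    }


@dataclass
class SimulationConfig:
    """Generating parameters; defaults mirror the 6 vs 6 lamb design at a
    desk-scale gene and site count."""

    n_per_sex: int = 6
    n_genes: int = 2000
    n_sites: dict = field(
        default_factory=lambda: {"CG": 4000, "CHG": 1200, "CHH": 1200}
    )
    genome: dict = field(
        default_factory=lambda: {"1": 10_000_000, "2": 10_000_000, "3": 10_000_000}
    )
    de_fraction: float = 0.05
    de_log2fc_range: tuple = (1.5, 4.0)
    dmr_count: int = 30
    dmr_length_range: tuple = (100, 300)
    dmr_delta_range: tuple = (0.2, 0.5)
    dmr_in_gene_fraction: float = 0.5
    dmr_site_spacing: tuple = (10, 40)
    context_baseline_mean: dict = field(
        default_factory=lambda: {"CG": 0.6, "CHG": 0.2, "CHH": 0.15}
    )
    context_baseline_sd: dict = field(
        default_factory=lambda: {"CG": 0.25, "CHG": 0.17, "CHH": 0.12}
    )
    nb_dispersion_range: tuple = (0.05, 0.3)
    bb_dispersion_range: tuple = (0.01, 0.05)
    coverage_mean: float = 20.0
    missing_rate: float = 0.05
    module_spec: list = field(default_factory=_default_module_spec)
    module_log2_sd: float = 1.0
    trait_spec: dict = field(default_factory=_default_trait_spec)
    n_qtls: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_sex < 2:
            raise ValueError("n_per_sex must be >= 2")
        for frac in (self.de_fraction, self.dmr_in_gene_fraction, self.missing_rate):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        lo, hi = self.dmr_delta_range
        if not (0 < lo <= hi < 1):
            raise ValueError("dmr deltas must lie in (0, 1)")
        dmr_bp = self.dmr_count * self.dmr_length_range[1]
        if dmr_bp > sum(self.genome.values()):
            raise ValueError("more DMR bp requested than genome available")

    @property
    def samples(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_per_sex)] + [
            f"F{i + 1}" for i in range(self.n_per_sex)
        ]

    @property
    def sexes(self) -> pd.Series:
        return pd.Series(
            ["M"] * self.n_per_sex + ["F"] * self.n_per_sex, index=self.samples
        )


@dataclass
class GroundTruth:
    """What was planted: signed DE effects, DMRs, modules and trait links.

    Internal generating tables (per-gene means, per-site mus, latent
    factors) ride along so the count and methylation samplers are
    reproducible functions of (config, truth).
    """

    true_de_genes: pd.DataFrame  # gene_id, log2fc (positive = female-high)
    true_dmrs: pd.DataFrame  # chrom, start, end, context, mu_f, mu_m, delta, gene_id
    true_module_membership: pd.DataFrame  # gene_id, module, sex_specificity
    true_trait_links: dict
    gene_models: list[GeneModel] = field(repr=False, default_factory=list)
    gene_params: pd.DataFrame = field(repr=False, default=None)
    size_factors: pd.Series = field(repr=False, default=None)
    module_factors: pd.DataFrame = field(repr=False, default=None)
    site_params: pd.DataFrame = field(repr=False, default=None)

    def to_json(self, path) -> None:
        obj = dict(
            true_de_genes=self.true_de_genes.to_dict(orient="records"),
            true_dmrs=self.true_dmrs.to_dict(orient="records"),
            true_module_membership=self.true_module_membership.to_dict(
                orient="records"
            ),
            true_trait_links={
                k: list(v) for k, v in self.true_trait_links.items()
            },
        )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = list(config.genome)
    models: list[GeneModel] = []
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    gid = 0
    for chrom in chroms:
        cursor = int(rng.integers(1_000, 5_000))
        length = config.genome[chrom]
        for _ in range(per_chrom):
            if gid >= config.n_genes:
                break
            body_len = int(rng.integers(2_000, 10_000))
            if cursor + body_len > length - 1_000:
                break
            start = cursor
            end = cursor + body_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 5))
            cuts = np.sort(rng.choice(np.arange(1, body_len - 1), size=2 * (n_exons - 1), replace=False)) if n_exons > 1 else np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [body_len - 1]])
            exons = []
            for i in range(0, len(bounds) - 1, 2):
                exons.append(
                    GenomicInterval(chrom, start + int(bounds[i]), start + int(bounds[i + 1]), strand)
                )
            gid += 1
            models.append(GeneModel(f"G{gid:05d}", GenomicInterval(chrom, start, end, strand), exons))
            cursor = end + int(rng.integers(2_000, 8_000))
    return models


def _plan_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    genes = _place_genes(config, rng)
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(genes)
    samples = config.samples
    sexes = config.sexes

    # --- DE effects
    n_de = int(round(config.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lo, hi = config.de_log2fc_range
    lfc = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    lfc_full = np.zeros(n_genes)
    lfc_full[de_idx] = lfc
    true_de = pd.DataFrame(
        {"gene_id": [gene_ids[i] for i in de_idx], "log2fc": lfc}
    ).sort_values("gene_id").reset_index(drop=True)

    # --- modules (drawn from non-DE genes)
    non_de = np.setdiff1d(np.arange(n_genes), de_idx)
    rng.shuffle(non_de)
    rows = []
    cursor = 0
    module_of_gene = np.full(n_genes, -1)
    for mi, (size, rho, sex) in enumerate(config.module_spec):
        members = non_de[cursor : cursor + size]
        cursor += size
        for g in members:
            rows.append(
                dict(gene_id=gene_ids[g], module=mi, sex_specificity=sex or "both")
            )
            module_of_gene[g] = mi
        if len(members) < size:
            raise ValueError("not enough non-DE genes for the module spec")
    membership = pd.DataFrame(rows, columns=["gene_id", "module", "sex_specificity"])

    factors = pd.DataFrame(
        rng.normal(size=(len(samples), len(config.module_spec))),
        index=samples,
        columns=[f"module{m}" for m in range(len(config.module_spec))],
    )

    # --- gene-level NB parameters
    base = 10 ** rng.uniform(1.2, 3.2, size=n_genes)
    base[module_of_gene >= 0] = 10 ** rng.uniform(2.3, 3.2, size=(module_of_gene >= 0).sum())
    alpha = rng.uniform(*config.nb_dispersion_range, size=n_genes)
    # small dispersion for module genes so correlation survives NB noise
    alpha[module_of_gene >= 0] = rng.uniform(0.01, 0.05, size=(module_of_gene >= 0).sum())
    gene_params = pd.DataFrame(
        dict(
            gene_id=gene_ids,
            base_mean=base,
            dispersion=alpha,
            log2fc=lfc_full,
            module=module_of_gene,
        )
    ).set_index("gene_id")
    size_factors = pd.Series(
        np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=len(samples))),
        index=samples,
    )

    # --- methylation sites and DMRs
    site_rows = []
    dmr_rows = []
    genome_chroms = list(config.genome)
    de_hosts = [genes[i] for i in de_idx]
    ctx_names = list(config.n_sites)
    ctx_weights = np.array([config.n_sites[c] for c in ctx_names], float)
    ctx_weights = ctx_weights / ctx_weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_chroms}
    spacing_lo, spacing_hi = config.dmr_site_spacing
    def overlaps_occupied(chrom: str, start: int, end: int) -> bool:
        return any(start <= hi and lo <= end for lo, hi in occupied[chrom])

    for di in range(config.dmr_count):
        ctx = str(rng.choice(ctx_names, p=ctx_weights))
        dmr_len = int(rng.integers(config.dmr_length_range[0], config.dmr_length_range[1] + 1))
        host_gene = ""
        # rejection-sample a non-overlapping placement; prefer DE-gene hosts
        for attempt in range(60):
            want_host = de_hosts and rng.random() < config.dmr_in_gene_fraction
            if want_host and attempt < 40:
                g = de_hosts[int(rng.integers(len(de_hosts)))]
                chrom = g.body.chrom
                lo_pos = g.body.start
                hi_pos = max(lo_pos + 1, g.body.end - dmr_len)
                start = int(rng.integers(lo_pos, hi_pos))
                host_gene = g.gene_id
            else:
                chrom = str(rng.choice(genome_chroms))
                start = int(rng.integers(10_000, config.genome[chrom] - dmr_len - 10_000))
                host_gene = ""
            if not overlaps_occupied(chrom, start, start + dmr_len - 1):
                break
        end = start + dmr_len - 1
        occupied[chrom].append((start - 500, end + 500))
        delta = rng.uniform(*config.dmr_delta_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        b = _draw_baseline(config, ctx, rng)
        center = float(np.clip(b, delta / 2 + 0.01, 1 - delta / 2 - 0.01))
        mu_f = center + sign * delta / 2
        mu_m = center - sign * delta / 2
        pos = start
        n_placed = 0
        while pos <= end:
            site_rows.append(
                dict(chrom=chrom, pos=pos, strand="+", context=ctx, mu_f=mu_f,
                     mu_m=mu_m, dmr=di)
            )
            n_placed += 1
            pos += int(rng.integers(spacing_lo, spacing_hi + 1))
        dmr_rows.append(
            dict(chrom=chrom, start=start, end=end, context=ctx, mu_f=mu_f,
                 mu_m=mu_m, delta=mu_f - mu_m, gene_id=host_gene, n_sites=n_placed)
        )

    def in_occupied(chrom: str, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in occupied[chrom])

    for ctx in ctx_names:
        n_bg = config.n_sites[ctx] - sum(
            1 for r in site_rows if r["context"] == ctx
        )
        placed = 0
        while placed < n_bg:
            chrom = str(rng.choice(genome_chroms))
            pos = int(rng.integers(1_000, config.genome[chrom] - 1_000))
            if in_occupied(chrom, pos):
                continue
            mu = _draw_baseline(config, ctx, rng)
            site_rows.append(
                dict(chrom=chrom, pos=pos, strand="+", context=ctx, mu_f=mu,
                     mu_m=mu, dmr=-1)
            )
            placed += 1
    site_params = pd.DataFrame(site_rows).sort_values(["chrom", "pos"]).reset_index(
        drop=True
    )
    site_params = site_params.drop_duplicates(subset=["chrom", "pos"], keep="first")
    site_params["phi"] = rng.uniform(
        *config.bb_dispersion_range, size=len(site_params)
    )
    true_dmrs = pd.DataFrame(
        dmr_rows,
        columns=["chrom", "start", "end", "context", "mu_f", "mu_m", "delta",
                 "gene_id", "n_sites"],
    )
    return GroundTruth(
        true_de_genes=true_de,
        true_dmrs=true_dmrs,
        true_module_membership=membership,
        true_trait_links=dict(config.trait_spec),
        gene_models=genes,
        gene_params=gene_params,
        size_factors=size_factors,
        module_factors=factors,
        site_params=site_params,
    )


def _draw_baseline(config: SimulationConfig, ctx: str, rng: np.random.Generator) -> float:
    mean = config.context_baseline_mean[ctx]
    sd = config.context_baseline_sd[ctx]
    # Beta moment match, guarded against infeasible (mean, sd) pairs
    v = min(sd**2, mean * (1 - mean) * 0.95)
    conc = mean * (1 - mean) / v - 1
    a, b = mean * conc, (1 - mean) * conc
    return float(np.clip(rng.beta(a, b), 0.01, 0.99))


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def simulate_counts(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator | None = None
) -> ExpressionCountMatrix:
    """NB counts: ``mean = base * sf_s * 2^(+-lfc/2) * 2^(module effect)``.

    The sex effect splits symmetrically so library depth stays sex-balanced;
    module genes follow a latent-factor model on the log2 scale with the
    configured within-sex correlation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    gp = truth.gene_params
    samples = config.samples
    sexes = config.sexes
    n_g, n_s = len(gp), len(samples)
    lfc = gp["log2fc"].to_numpy()
    sex_sign = np.where(sexes.to_numpy() == "F", 0.5, -0.5)
    with np.errstate(divide="ignore"):  # zero-mean genes stay all-zero
        log2_mean = np.log2(gp["base_mean"].to_numpy())[:, None] + np.outer(
            lfc, sex_sign
        )
    # module latent-factor structure
    mod = gp["module"].to_numpy()
    sd = config.module_log2_sd
    for mi, (size, rho, sex) in enumerate(config.module_spec):
        members = mod == mi
        if not members.any():
            continue
        f = truth.module_factors.iloc[:, mi].to_numpy()
        eps = rng.normal(size=(members.sum(), n_s))
        active = np.ones(n_s, bool) if sex is None else (sexes.to_numpy() == sex)
        shared = np.sqrt(rho) * f[None, :] + np.sqrt(1 - rho) * eps
        x = np.where(active[None, :], shared, eps)
        log2_mean[members] += sd * x
    mean = (2.0**log2_mean) * truth.size_factors.to_numpy()[None, :]
    alpha = gp["dispersion"].to_numpy()[:, None]
    counts = np.zeros((n_g, n_s), dtype=int)
    pos_mean = mean > 0
    lam = np.where(
        alpha > 1e-8,
        rng.gamma(np.clip(1.0 / np.maximum(alpha, 1e-8), None, 1e8), np.maximum(alpha, 1e-8) * mean),
        mean,
    )
    counts = rng.poisson(np.where(pos_mean, lam, 0.0))
    counts_df = pd.DataFrame(counts, index=gp.index, columns=samples)
    lengths = pd.Series(
        [float(len(g.body)) for g in truth.gene_models],
        index=[g.gene_id for g in truth.gene_models],
    ).loc[gp.index]
    return ExpressionCountMatrix(counts_df, lengths)


def simulate_methylation(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator | None = None
) -> MethylationCallTable:
    """Beta-binomial calls: coverage ~ Poisson(mean), methylated reads from
    Beta(mu (1-phi)/phi, (1-mu)(1-phi)/phi) then Binomial; phi = 0 is pure
    binomial.  A ``missing_rate`` fraction of site-sample pairs may have
    zero coverage; the rest are truncated to >= 1 read."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    sp = truth.site_params
    samples = config.samples
    sexes = config.sexes
    n_sites = len(sp)
    table = sp[["chrom", "pos", "strand", "context"]].copy()
    phi = sp["phi"].to_numpy()
    for s in samples:
        mu = (sp["mu_f"] if sexes[s] == "F" else sp["mu_m"]).to_numpy()
        n = rng.poisson(config.coverage_mean, size=n_sites)
        keep = rng.random(n_sites) >= config.missing_rate
        n = np.where(keep, np.maximum(n, 1), n)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = mu * (1 - phi) / np.maximum(phi, 1e-12)
            b = (1 - mu) * (1 - phi) / np.maximum(phi, 1e-12)
        interior = (mu > 0) & (mu < 1) & (phi > 0)
        p = np.where(interior, rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)), mu)
        m = rng.binomial(n, np.clip(p, 0, 1))
        table[f"{s}_meth"] = m
        table[f"{s}_total"] = n
    return MethylationCallTable(table.reset_index(drop=True), samples)


def _simulate_metadata(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> SampleTable:
    samples = config.samples
    frame = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    frame["sex"] = config.sexes
    frame["age_days"] = np.round(rng.normal(26, 4, size=len(samples)), 1)
    for trait, (mi, r) in config.trait_spec.items():
        if mi >= len(config.module_spec):
            raise ValueError(f"trait {trait} links to unknown module {mi}")
        f = truth.module_factors.iloc[:, mi].to_numpy()
        noise = rng.normal(size=len(samples))
        vals = 15 + 5 * (r * f + np.sqrt(1 - r**2) * noise)
        frame[trait] = np.round(np.clip(vals, 0.0, 100.0), 2)
    return SampleTable(frame)


def _simulate_qtls(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> list[QtlRecord]:
    qtl_types = ["Meat_and_Carcass", "Production", "Milk", "Reproduction", "Health"]
    traits = [
        "body_weight_slaughter", "carcass_fat_percentage", "fat_weight_in_carcass",
        "internal_fat_amount", "lean_meat_yield", "subcutaneous_fat_area",
        "milk_yield", "somatic_cell_score", "litter_size", "fleece_weight",
    ]
    out = []
    de_genes = [
        g for g in truth.gene_models
        if g.gene_id in set(truth.true_de_genes["gene_id"])
    ]
    for i in range(config.n_qtls):
        # a third of QTLs anchored on planted genes -> fat traits cluster there
        if de_genes and i % 3 == 0:
            g = de_genes[int(rng.integers(len(de_genes)))]
            chrom = g.body.chrom
            center = (g.body.start + g.body.end) // 2
            trait = traits[int(rng.integers(0, 6))]
            qtl_type = "Meat_and_Carcass"
        else:
            chrom = str(rng.choice(list(config.genome)))
            center = int(rng.integers(100_000, config.genome[chrom] - 100_000))
            trait = traits[int(rng.integers(len(traits)))]
            qtl_type = qtl_types[int(rng.integers(len(qtl_types)))]
        half = int(rng.integers(25_000, 500_000))
        start = max(1, center - half)
        end = min(config.genome[chrom], center + half)
        out.append(
            QtlRecord(f"QTL{i + 1:04d}", trait, qtl_type, GenomicInterval(chrom, start, end))
        )
    return out


def simulate_experiment(config: SimulationConfig):
    """Generate a complete synthetic experiment.

    Returns ``(counts, calls, gene_models, qtls, metadata, truth)``;
    deterministic for a given config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    truth = _plan_truth(config, rng)
    counts = simulate_counts(config, truth, np.random.default_rng(config.seed + 1))
    calls = simulate_methylation(config, truth, np.random.default_rng(config.seed + 2))
    meta = _simulate_metadata(config, truth, np.random.default_rng(config.seed + 3))
    qtls = _simulate_qtls(config, truth, np.random.default_rng(config.seed + 4))
    return counts, calls, truth.gene_models, qtls, meta, truth
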