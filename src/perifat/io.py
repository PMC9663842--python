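"""Typed containers and readers/writers for the pipeline's on-disk formats.

Every format is UTF-8, tab-separated, with a header row.  Readers validate
invariants and raise :class:`FormatError` naming the offending line; writers
round-trip exactly through their readers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import GeneModel, GenomicInterval

CONTEXTS = ("CG", "CHG", "CHH")


class FormatError(ValueError):
    """A file violated its format contract; message names the line."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionCountMatrix:
    """Gene x sample integer read counts plus per-gene transcript lengths."""

    counts: pd.DataFrame  # genes x samples, non-negative int
    gene_length_bp: pd.Series  # indexed like counts

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_length_bp.index):
            raise ValueError("counts and gene_length_bp indexes differ")
        if len(self.counts) and (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if len(self.counts) and (self.gene_length_bp <= 0).any():
            raise ValueError("non-positive gene length")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionCountMatrix":
        return ExpressionCountMatrix(self.counts[sample_ids], self.gene_length_bp)


@dataclass
class MethylationCallTable:
    """Per-cytosine methylated/total read counts for every sample.

    ``table`` has columns ``chrom``, ``pos``, ``strand``, ``context`` and,
    for each sample id ``s``, ``{s}_meth`` and ``{s}_total``; rows are sorted
    by (chrom, pos).  Zero total coverage is retained, not dropped.
    """

    table: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        t = self.table
        bad = ~t["context"].isin(CONTEXTS)
        if bad.any():
            raise ValueError(f"invalid context {t.loc[bad, 'context'].iloc[0]!r}")
        for s in self.samples:
            m, n = t[f"{s}_meth"].to_numpy(), t[f"{s}_total"].to_numpy()
            if (m < 0).any() or (n < 0).any() or (m > n).any():
                raise ValueError(f"methylated > total (or negative) for sample {s}")
        self.table = t.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    def meth(self) -> pd.DataFrame:
        return self.table[[f"{s}_meth" for s in self.samples]].set_axis(
            self.samples, axis=1
        )

    def total(self) -> pd.DataFrame:
        return self.table[[f"{s}_total" for s in self.samples]].set_axis(
            self.samples, axis=1
        )

    def fractions(self) -> pd.DataFrame:
        """Per-site per-sample methylation fraction; NaN at zero coverage."""
        m = self.meth().to_numpy(float)
        n = self.total().to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, m / np.where(n > 0, n, 1), np.nan)
        return pd.DataFrame(f, columns=self.samples)


@dataclass(frozen=True)
class QtlRecord:
    qtl_id: str
    trait: str
    qtl_type: str
    interval: GenomicInterval


TRAIT_NAMES = (
    "renal",
    "pelvic",
    "renal_and_pelvic",
    "leg_intramuscular",
    "leg_subcutaneous",
)


@dataclass
class SampleTable:
    """Sample metadata: sex and fat-percentage traits per sample."""

    frame: pd.DataFrame  # indexed by sample_id; columns sex, age_days, traits

    def __post_init__(self) -> None:
        if "sex" not in self.frame.columns:
            raise ValueError("metadata missing 'sex' column")
        bad = ~self.frame["sex"].isin(["M", "F"])
        if bad.any():
            raise ValueError(
                f"sex must be M or F (sample {self.frame.index[bad][0]!r})"
            )
        for t in self.trait_names:
            vals = self.frame[t].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ValueError(f"trait {t} outside [0, 100]")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sexes(self) -> pd.Series:
        return self.frame["sex"]

    @property
    def trait_names(self) -> list[str]:
        skip = {"sex", "age_days"}
        return [c for c in self.frame.columns if c not in skip]

    def samples_of_sex(self, sex: str) -> list[str]:
        return list(self.frame.index[self.frame["sex"] == sex])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc


def read_counts(path) -> ExpressionCountMatrix:
    """Read a counts TSV (gene_id, length_bp, one column per sample)."""
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["gene_id", "length_bp"]:
        raise FormatError(
            f"{path}: first columns must be gene_id, length_bp; got {list(df.columns[:2])}"
        )
    samples = list(df.columns[2:])
    if df.empty:
        counts = pd.DataFrame(
            np.zeros((0, len(samples)), dtype=int), columns=samples, index=pd.Index([], name=None)
        )
        return ExpressionCountMatrix(counts, pd.Series([], dtype=float))
    for line_offset, row in enumerate(df.itertuples(index=False), start=2):
        vals = row[2:]
        for v in vals:
            if int(v) < 0:
                raise FormatError(f"{path}: negative count at line {line_offset}")
        if row[1] == "" or float(row[1]) <= 0:
            raise FormatError(f"{path}: missing/invalid length at line {line_offset}")
    counts = df[samples].astype(int)
    counts.index = df["gene_id"]
    counts.index.name = None
    lengths = df["length_bp"].astype(float)
    lengths.index = counts.index
    return ExpressionCountMatrix(counts, lengths)


def write_counts(ecm: ExpressionCountMatrix, path) -> None:
    out = ecm.counts.copy()
    out.insert(0, "length_bp", ecm.gene_length_bp.astype(int))
    out.insert(0, "gene_id", ecm.counts.index)
    out.to_csv(path, sep="\t", index=False)


def read_methylation_calls(path) -> MethylationCallTable:
    """Read a methylation-call TSV.

    Columns: chrom, pos, strand, context, then ``{sample}_meth`` /
    ``{sample}_total`` pairs.  Contexts are case-normalised; output is
    sorted by (chrom, pos).
    """
    df = _read_tsv(path)
    fixed = ["chrom", "pos", "strand", "context"]
    if list(df.columns[:4]) != fixed:
        raise FormatError(f"{path}: expected columns {fixed}, got {list(df.columns[:4])}")
    rest = list(df.columns[4:])
    samples = []
    for i in range(0, len(rest), 2):
        a, b = rest[i], rest[i + 1]
        if not (a.endswith("_meth") and b.endswith("_total") and a[:-5] == b[:-6]):
            raise FormatError(f"{path}: unpaired sample columns {a!r}/{b!r}")
        samples.append(a[:-5])
    df["pos"] = df["pos"].astype(int)
    df["context"] = df["context"].str.upper()
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        line = df.index[bad][0] + 2
        raise FormatError(f"{path}: unknown context at line {line}")
    for s in samples:
        df[f"{s}_meth"] = df[f"{s}_meth"].astype(int)
        df[f"{s}_total"] = df[f"{s}_total"].astype(int)
        over = df[f"{s}_meth"] > df[f"{s}_total"]
        if over.any():
            line = df.index[over][0] + 2
            raise FormatError(
                f"{path}: methylated > total for sample {s} at line {line}"
            )
    return MethylationCallTable(df, samples)


def write_methylation_calls(mct: MethylationCallTable, path) -> None:
    mct.table.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> list[GeneModel]:
    """Read gene and exon features from a GFF3 file into :class:`GeneModel` s.

    Exons are merged per gene; an exon extending beyond its gene body is
    clamped with a warning; a missing strand is treated as '+' with a warning.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[str, int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: malformed GFF3 at line {lineno}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if strand not in ("+", "-"):
                warnings.warn(
                    f"{path}:{lineno}: missing strand, assuming '+'", stacklevel=2
                )
                strand = "+"
            if ftype == "gene":
                gid = attr.get("ID", attr.get("gene_id", f"line{lineno}"))
                genes[gid] = dict(
                    chrom=chrom, start=int(start), end=int(end), strand=strand
                )
            elif ftype == "exon":
                parent = attr.get("Parent", attr.get("gene_id", ""))
                # mRNA level is not modelled; Parent may point at the gene
                parent = parent.split(",")[0]
                exons.setdefault(parent, []).append((chrom, int(start), int(end)))
    models = []
    for gid, g in genes.items():
        body = GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"])
        exlist = []
        for chrom, s, e in exons.get(gid, []):
            if s < body.start or e > body.end:
                warnings.warn(
                    f"exon {s}-{e} outside gene body of {gid}; clamped",
                    stacklevel=2,
                )
                s, e = max(s, body.start), min(e, body.end)
            exlist.append(GenomicInterval(chrom, s, e, body.strand))
        models.append(GeneModel(gid, body, exlist))
    return models


def write_gene_models(models: list[GeneModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            b = gm.body
            fh.write(
                f"{b.chrom}\tperifat\tgene\t{b.start}\t{b.end}\t.\t{b.strand}\t.\t"
                f"ID={gm.gene_id}\n"
            )
            for i, ex in enumerate(gm.exons, 1):
                fh.write(
                    f"{ex.chrom}\tperifat\texon\t{ex.start}\t{ex.end}\t.\t{b.strand}\t.\t"
                    f"ID={gm.gene_id}.exon{i};Parent={gm.gene_id}\n"
                )


def strip_chr_prefix(name: str) -> str:
    """Drop a leading 'chr' from a chromosome name ('chrX' -> 'X')."""
    return name[3:] if name.lower().startswith("chr") else name


def read_qtl_table(
    path, zero_based_half_open: bool = False, normalize_chr: bool = False
) -> list[QtlRecord]:
    """Read a QTL TSV (qtl_id, trait, qtl_type, chrom, start, end).

    Chromosome names are matched exactly downstream; ``normalize_chr``
    strips a 'chr' prefix at read time for inputs using the other dialect.
    """
    df = _read_tsv(path)
    need = ["qtl_id", "trait", "qtl_type", "chrom", "start", "end"]
    if list(df.columns[:6]) != need:
        raise FormatError(f"{path}: expected columns {need}")
    out = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if zero_based_half_open:
            start += 1
        chrom = strip_chr_prefix(row.chrom) if normalize_chr else row.chrom
        out.append(
            QtlRecord(
                row.qtl_id,
                row.trait,
                row.qtl_type,
                GenomicInterval(chrom, start, end),
            )
        )
    return out


def write_qtl_table(qtls: list[QtlRecord], path) -> None:
    rows = [
        dict(
            qtl_id=q.qtl_id,
            trait=q.trait,
            qtl_type=q.qtl_type,
            chrom=q.interval.chrom,
            start=q.interval.start,
            end=q.interval.end,
        )
        for q in qtls
    ]
    pd.DataFrame(rows, columns=["qtl_id", "trait", "qtl_type", "chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleTable(df)


def write_metadata(meta: SampleTable, path) -> None:
    out = meta.frame.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)
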