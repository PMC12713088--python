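"""Genomic file formats and coordinate operations.

All coordinates are 0-based half-open throughout (BED-native); the gene
table on disk uses the same convention and says so in a header comment.
Readers tolerate '#' comment lines and report malformed lines with their
line number.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GeneModel:
    """A gene interval. TSS/TES are strand-aware single bases."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Peak:
    peak_id: str
    chrom: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.peak_id}: start {self.start} >= end {self.end}")
        if self.score < 0:
            raise ValueError(f"{self.peak_id}: negative score")


@dataclass
class SignalMatrix:
    """Gene x sample matrix of nonnegative real signal (RPKM units)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids")
        if v.isna().any().any():
            raise ValueError("missing cells are not allowed")
        if (v.to_numpy() < 0).any():
            raise ValueError("signal values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CountMatrix:
    """Gene x sample integer read counts plus per-sample library sizes.

    library_size counts all mapped reads genome-wide, so it may exceed (or
    fall below) the column sum over the genes in the matrix.
    """

    values: pd.DataFrame
    library_size: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids")
        if v.isna().any().any():
            raise ValueError("missing cells are not allowed")
        arr = v.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        if list(self.library_size.index) != list(v.columns):
            raise ValueError("library_size must cover exactly the sample columns")
        if (self.library_size <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# readers / writers

_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts == _GENE_COLS:
                continue
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            gid, chrom, start, end, strand = parts
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            try:
                genes.append(GeneModel(gid, chrom, int(start), int(end), strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_bed(path: str | Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], parts[1], parts[2]
            name = parts[3] if len(parts) > 3 else f"peak_{lineno}"
            score = float(parts[4]) if len(parts) > 4 else 0.0
            try:
                peaks.append(Peak(name, chrom, int(start), int(end), score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.score:g}\n")


def read_counts(path: str | Path) -> CountMatrix:
    """Read a counts TSV (genes x samples).

    Per-sample library sizes are carried in header comment lines of the form
    ``#library_size<TAB>sample<TAB>reads``; if absent, column sums are used.
    """
    libs: dict[str, int] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#library_size\t"):
                _, sample, size = line.rstrip("\n").split("\t")
                libs[sample] = int(size)
            elif not line.startswith("#"):
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, sep="\t", index_col=0)
    arr = df.to_numpy()
    bad = np.argwhere(~np.isfinite(arr) | (arr < 0) | (arr != np.floor(arr)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: invalid count at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    if not libs:
        libs = {s: int(df[s].sum()) for s in df.columns}
    missing = [s for s in df.columns if s not in libs]
    if missing:
        raise ValueError(f"{path}: no library size for sample(s) {missing}")
    return CountMatrix(df, pd.Series([libs[s] for s in df.columns], index=df.columns))


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in counts.sample_ids:
            fh.write(f"#library_size\t{s}\t{int(counts.library_size[s])}\n")
        counts.values.to_csv(fh, sep="\t", index_label="gene_id")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        bad = set(s) - set("ACGTN")
        if bad:
            raise ValueError(f"{path}: non-ACGTN characters {sorted(bad)} in {rec.id}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# quantification

def rpkm(counts: CountMatrix, genes: Iterable[GeneModel]) -> SignalMatrix:
    """Reads per kilobase of gene per million mapped reads.

    value = count / ((gene length / 1e3) * (library size / 1e6)). Doubling
    every count together with the library size leaves RPKM unchanged.
    """
    lengths = {g.gene_id: g.length for g in genes}
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise ValueError(f"no gene model (length) for: {missing[:5]}")
    len_kb = np.array([lengths[g] / 1e3 for g in counts.gene_ids])
    lib_m = counts.library_size.to_numpy() / 1e6
    vals = counts.values.to_numpy(dtype=float) / len_kb[:, None] / lib_m[None, :]
    return SignalMatrix(
        pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns)
    )


def assign_peaks_to_genes(
    peaks: Iterable[Peak],
    genes: Iterable[GeneModel],
    upstream_window: int = 1000,
) -> tuple[dict[str, set[str]], dict[str, list[str]]]:
    """Assign peaks to genes they overlap, promoter-extended.

    A peak is assigned to a gene iff it overlaps the gene body extended by
    ``upstream_window`` bp upstream of the TSS (strand-aware). A peak may hit
    several genes and every overlapped gene is kept. Returns
    (gene_id -> set of peak_ids, peak_id -> list of gene_ids).
    """
    if upstream_window < 0:
        raise ValueError("upstream_window must be >= 0")
    rows: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        lo = g.start - upstream_window if g.strand == "+" else g.start
        hi = g.end if g.strand == "+" else g.end + upstream_window
        rows.setdefault(g.chrom, []).append((max(0, lo), hi, g.gene_id))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, ivals in rows.items():
        ivals.sort()
        by_chrom[chrom] = (
            np.array([iv[0] for iv in ivals]),
            np.array([iv[1] for iv in ivals]),
            [iv[2] for iv in ivals],
        )

    gene_peaks: dict[str, set[str]] = {}
    peak_genes: dict[str, list[str]] = {}
    for p in peaks:
        hits: list[str] = []
        if p.chrom in by_chrom:
            los, his, ids = by_chrom[p.chrom]
            for i in np.flatnonzero((los < p.end) & (his > p.start)):
                hits.append(ids[i])  # half-open overlap
        peak_genes[p.peak_id] = hits
        for gid in hits:
            gene_peaks.setdefault(gid, set()).add(p.peak_id)
    return gene_peaks, peak_genes


def bound_genes(gene_peaks: Mapping[str, set[str]]) -> set[str]:
    """Genes with at least one assigned peak."""
    return {g for g, ps in gene_peaks.items() if ps}


def metagene_profile(
    signal: Mapping[str, np.ndarray],
    genes: Iterable[GeneModel],
    n_body_bins: int = 50,
    flank_bp: int = 1000,
    flank_bins: int = 10,
) -> np.ndarray:
    """Mean signal over scaled gene bodies with fixed-bp flanks.

    Each gene body is rescaled to ``n_body_bins`` bins (fractional-overlap
    averaging, so genes shorter than the bin count still contribute);
    flanks are binned in fixed base pairs. Minus-strand genes are reversed
    so bin 0 is always the 5' flank. Output length is
    ``2*flank_bins + n_body_bins``.
    """
    genes = list(genes)
    if n_body_bins < 1:
        raise ValueError("n_body_bins must be >= 1")
    if not genes:
        raise ValueError("no genes")
    if flank_bins > 0 and flank_bp % flank_bins != 0:
        raise ValueError("flank_bp must be divisible by flank_bins")

    # prefix sums let us average signal over fractional-coordinate windows
    cums = {c: np.concatenate([[0.0], np.cumsum(np.asarray(v, dtype=float))])
            for c, v in signal.items()}

    def window_mean(cum: np.ndarray, a: float, b: float) -> float:
        # mean of per-base signal over real interval [a, b), linear
        # interpolation of the prefix sum handles fractional endpoints
        n = len(cum) - 1
        a, b = max(0.0, a), min(float(n), b)
        if b <= a:
            return 0.0
        ia, ib = int(np.floor(a)), int(np.floor(b))
        ca = cum[ia] + (a - ia) * (cum[min(ia + 1, n)] - cum[ia])
        cb = cum[ib] + (b - ib) * (cum[min(ib + 1, n)] - cum[ib])
        return (cb - ca) / (b - a)

    total = np.zeros(2 * flank_bins + n_body_bins)
    bp_per_flank_bin = flank_bp / flank_bins if flank_bins else 0
    for g in genes:
        cum = cums[g.chrom]
        bins = []
        for i in range(flank_bins):  # upstream, 5'->3' genomic
            a = g.start - flank_bp + i * bp_per_flank_bin
            bins.append((a, a + bp_per_flank_bin))
        step = g.length / n_body_bins
        for i in range(n_body_bins):
            bins.append((g.start + i * step, g.start + (i + 1) * step))
        for i in range(flank_bins):
            a = g.end + i * bp_per_flank_bin
            bins.append((a, a + bp_per_flank_bin))
        vals = np.array([window_mean(cum, a, b) for a, b in bins])
        if g.strand == "-":
            vals = vals[::-1]
        total += vals
    return total / len(genes)
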