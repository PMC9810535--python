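"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular formats are tab-separated. BED/BEDPE files carry no header;
matrix TSVs carry a header row of column labels and an index column of row
labels. Sparse count matrices use MatrixMarket (cells as columns, genes as
rows, the 10x convention) with companion ``genes.tsv``/``cells.tsv``.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .genome import Genome, GenomicInterval

# ---------------------------------------------------------------------------
# BED / chrom sizes / BEDPE


def read_chrom_sizes(path: str) -> Genome:
    """Two-column ``chrom<TAB>length`` file -> Genome."""
    names, lengths = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            names.append(chrom)
            lengths.append(int(length))
    return Genome(tuple(names), tuple(lengths))


def write_chrom_sizes(genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    """BED3/BED6 reader; strand taken from column 6 when present."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    """BED3 by default; BED6 when names/scores given (score may be a
    footprint posterior)."""
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            if names is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else f"iv{i}"
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def read_footprints(path: str) -> tuple[list[GenomicInterval], list[str], np.ndarray]:
    """BED6+1 footprint reader: name column 4, posterior in column 7.

    Falls back to the BED score column (5) for the posterior when only six
    columns are present.
    """
    ivs, names, post = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
            names.append(f[3] if len(f) >= 4 else "")
            post.append(float(f[6] if len(f) >= 7 else f[4] if len(f) >= 5 else 0.0))
    return ivs, names, np.asarray(post)


def read_bedpe(path: str) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """BEDPE reader returning (anchor1, anchor2) with anchor1 upstream."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            a = GenomicInterval(f[0], int(f[1]), int(f[2]))
            b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            if a.chrom == b.chrom and b.start < a.start:
                a, b = b, a
            out.append((a, b))
    return out


def write_bedpe(pairs: Iterable[tuple[GenomicInterval, GenomicInterval]],
                path: str, extra: Sequence[Sequence] | None = None) -> None:
    pairs = list(pairs)
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(pairs):
            row = [a.chrom, a.start, a.end, b.chrom, b.start, b.end]
            if extra is not None:
                row += list(extra[i])
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sets[f[0]] = [g for g in f[2:] if g]
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str,
              description: str = "hscnet") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Sparse count matrices (MTX + gene/cell TSVs) <-> AnnData


def write_counts_mtx(adata: AnnData, outdir: str) -> None:
    """Write counts as ``matrix.mtx`` (genes x cells), ``genes.tsv``,
    ``cells.tsv`` (cell id + one column per obs field)."""
    os.makedirs(outdir, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), X.T.astype(int))
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", header=False, index=False
    )
    cells = adata.obs.copy()
    cells.insert(0, "cell", adata.obs_names)
    cells.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index=False)


def read_counts_mtx(indir: str) -> AnnData:
    X = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).tocsr().T.tocsr()
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t", header=None)[0]
    cells = pd.read_csv(os.path.join(indir, "cells.tsv"), sep="\t")
    obs = cells.set_index("cell")
    obs.index = obs.index.astype(str)
    ad = AnnData(X=sp.csr_matrix(X), obs=obs)
    ad.var_names = genes.astype(str)
    return ad


# ---------------------------------------------------------------------------
# Dense labelled matrices, TSS tables, PFMs, contact triplets


def read_matrix_tsv(path: str) -> pd.DataFrame:
    """Labelled matrix: header row of column names, first column row names."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def read_tss_table(path: str) -> pd.DataFrame:
    """4-column TSV ``gene chrom pos strand`` -> DataFrame indexed by gene."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene", "chrom", "pos", "strand"])
    return df.set_index("gene")


def write_tss_table(tss: pd.DataFrame, path: str) -> None:
    tss.reset_index().to_csv(path, sep="\t", header=False, index=False)


def read_pfm(path: str) -> dict[str, np.ndarray]:
    """JASPAR-style PFM text: ``>name`` header then four rows ``A [ ... ]``.

    Returns motif name -> 4 x w count/frequency matrix (rows A, C, G, T).
    """
    motifs: dict[str, np.ndarray] = {}
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None and rows:
                    motifs[name] = np.asarray(rows, dtype=float)
                name, rows = line[1:].split()[0], []
            else:
                vals = line.replace("[", " ").replace("]", " ").split()
                if vals and vals[0] in "ACGT":
                    vals = vals[1:]
                rows.append([float(v) for v in vals])
    if name is not None and rows:
        motifs[name] = np.asarray(rows, dtype=float)
    return motifs


def write_pfm(motifs: dict[str, np.ndarray], path: str) -> None:
    bases = "ACGT"
    with open(path, "w") as fh:
        for name, mat in motifs.items():
            fh.write(f">{name}\n")
            for b, row in zip(bases, np.asarray(mat)):
                fh.write(f"{b} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


def read_contact_triplets(path: str, resolution: int) -> tuple[np.ndarray, int]:
    """3-column ``bin1_start<TAB>bin2_start<TAB>count`` text for one
    chromosome -> dense symmetric matrix plus resolution."""
    df = pd.read_csv(path, sep="\t", header=None, names=["b1", "b2", "count"])
    i = (df["b1"] // resolution).to_numpy()
    j = (df["b2"] // resolution).to_numpy()
    n = int(max(i.max(), j.max())) + 1 if len(df) else 0
    m = np.zeros((n, n))
    m[i, j] = df["count"].to_numpy()
    m[j, i] = df["count"].to_numpy()
    return m, resolution


def write_contact_triplets(matrix: np.ndarray, resolution: int, path: str) -> None:
    iu, ju = np.triu_indices_from(matrix)
    keep = matrix[iu, ju] != 0
    with open(path, "w") as fh:
        for i, j in zip(iu[keep], ju[keep]):
            fh.write(f"{i * resolution}\t{j * resolution}\t{matrix[i, j]:g}\n")
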