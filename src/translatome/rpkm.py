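"""Expression quantification with unique-k-mer effective lengths.

Reads of length k can only be attributed unambiguously to a gene where
the transcriptome sequence is gene-specific, so the effective length of a
gene is the number of distinct k-mers (default k = 58, the read length)
that occur in at least one of its transcript isoforms and in no
transcript of any other gene. rpkm is then reads per kilobase of unique
k-mers per million mapped reads:

    rpkm = count / (unique_kmers / 1000) / (library_size / 1e6)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["unique_kmers", "rpkm", "rpkm_table", "fold_change_vs_control"]

_COMP = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMP)[::-1]
    return min(kmer, rc)


def unique_kmers(
    transcriptome: dict,
    k: int = 58,
    canonical: bool = False,
    count_positions: bool = False,
) -> pd.Series:
    """Per-gene count of k-mers unique to that gene's transcript isoforms.

    Parameters
    ----------
    transcriptome
        Mapping gene_id -> iterable of transcript sequences.
    k
        k-mer length; k larger than every transcript yields all-zero
        counts (not an error).
    canonical
        Collapse a k-mer with its reverse complement (for unstranded
        protocols; off by default, the reference protocol is stranded).
    count_positions
        Count occurrences (positions) of unique k-mers instead of
        distinct strings; by default duplicates within a gene (shared
        across isoforms or internal repeats) collapse to one.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    per_gene: dict[str, set] = {}
    owner: dict[str, str | None] = {}  # kmer -> sole gene, or None if shared
    for gene, seqs in transcriptome.items():
        kmers = set()
        for seq in seqs:
            s = seq.upper().replace("U", "T")
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if canonical:
                    km = _canonical(km)
                kmers.add(km)
        per_gene[gene] = kmers
        for km in kmers:
            if km not in owner:
                owner[km] = gene
            elif owner[km] != gene:
                owner[km] = None
    counts = {}
    for gene, kmers in per_gene.items():
        mine = {km for km in kmers if owner[km] == gene}
        if count_positions:
            n = 0
            for seq in transcriptome[gene]:
                s = seq.upper().replace("U", "T")
                for i in range(len(s) - k + 1):
                    km = s[i : i + k]
                    if canonical:
                        km = _canonical(km)
                    if km in mine:
                        n += 1
            counts[gene] = n
        else:
            counts[gene] = len(mine)
    return pd.Series(counts, name="unique_kmers").sort_index()


def rpkm(count: float, n_unique: int, library_size: float) -> float:
    """reads per kilobase (of unique k-mers) per million reads; NaN if no unique k-mers."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if n_unique == 0:
        return float("nan")
    return count / (n_unique / 1000.0) / (library_size / 1e6)


def rpkm_table(counts: pd.DataFrame, index: pd.Series) -> pd.DataFrame:
    """rpkm for a gene x sample count matrix; library size = per-sample count sum."""
    idx = index.reindex(counts.index)
    lib = counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = counts.div(idx / 1000.0, axis=0).div(lib / 1e6, axis=1)
    out[idx.fillna(0) == 0] = np.nan
    return out


def fold_change_vs_control(
    counts: pd.DataFrame, sizes: pd.Series, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-gene ratio of size-factor-normalized counts to the normalized control.

    The control is the first column. Zero normalized counts receive the
    pseudocount (in numerator or denominator) so ratios stay defined.
    """
    norm = counts.div(sizes.reindex(counts.columns), axis=1)
    norm = norm.where(norm > 0, pseudocount)
    control = norm.iloc[:, 0]
    return norm.div(control, axis=0)
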