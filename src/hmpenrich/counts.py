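"""Count preprocessing: transcript aggregation, detection filter, TMM, CPM.

Transcript-level ``est_counts`` from a pseudo-aligner are summed over each
gene's *mature* transcripts (rows flagged as unspliced, i.e. intron-retaining,
are omitted), undetectable genes are removed by a counts-per-million rule, and
between-sample scaling factors are computed with the trimmed mean of M-values
(TMM) method.  Estimated counts are fractional and stay fractional throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import UNSPLICED_SUFFIX, TranscriptTables

logger = logging.getLogger(__name__)


class AggregationError(ValueError):
    """Raised when transcripts cannot be mapped to genes."""


@dataclass
class TranscriptAbundanceTable:
    """Per-transcript estimated counts with a transcript-to-gene map."""

    est_counts: pd.DataFrame          # transcripts x samples
    tx2gene: pd.Series                # transcript -> gene
    unspliced: pd.Series              # transcript -> bool

    def __post_init__(self) -> None:
        if (self.est_counts.to_numpy() < 0).any():
            raise ValueError("est_counts must be non-negative")


@dataclass
class CountMatrix:
    """Gene-level counts with library sizes and normalization factors.

    ``lib_sizes`` are the column sums of ``counts`` at construction;
    ``norm_factors`` default to 1 and after TMM have geometric mean 1.
    ``samples`` optionally carries sample metadata aligned to the columns.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series = None
    norm_factors: pd.Series = None
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0)
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        if (self.norm_factors <= 0).any():
            raise ValueError("norm_factors must be positive")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.norm_factors

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class FilterRule:
    """Detection rule: drop a gene undetectable (CPM below ``cpm_threshold``)
    in at least ``min_undetected`` libraries; ``None`` means ceil(n/2)."""

    cpm_threshold: float = 0.66
    min_undetected: int | None = None

    def resolve_min(self, n_samples: int) -> int:
        m = (math.ceil(n_samples / 2) if self.min_undetected is None
             else self.min_undetected)
        if self.cpm_threshold <= 0:
            raise ValueError("cpm_threshold must be > 0")
        if not (0 < m <= n_samples):
            raise ValueError("min_undetected must lie in (0, n_samples]")
        return m


# ---------------------------------------------------------------------------
# readers


def read_kallisto_dir(root, tx2gene_path=None) -> TranscriptAbundanceTable:
    """Read ``abundance/<sample>/abundance.tsv`` trees plus a tx2gene TSV.

    ``root`` is either the fixture root (containing ``abundance/`` and
    ``tx2gene.tsv``) or the abundance directory itself, in which case
    ``tx2gene_path`` must be given.  Unspliced transcripts are recognised by
    the ID suffix ``.unspliced``.
    """
    root = Path(root)
    abundance = root / "abundance" if (root / "abundance").is_dir() else root
    if tx2gene_path is None:
        tx2gene_path = root / "tx2gene.tsv"
    sample_dirs = sorted(p for p in abundance.iterdir() if p.is_dir())
    if not sample_dirs:
        raise FileNotFoundError(f"no sample directories under {abundance}")
    cols = {}
    index = None
    for sdir in sample_dirs:
        tab = pd.read_csv(sdir / "abundance.tsv", sep="\t")
        tab = tab.set_index("target_id")
        if index is None:
            index = tab.index
        elif not index.equals(tab.index):
            tab = tab.reindex(index)
        cols[sdir.name] = tab["est_counts"]
    est = pd.DataFrame(cols)
    t2g = pd.read_csv(tx2gene_path, sep="\t").set_index("transcript_id")["gene_id"]
    unspliced = pd.Series(
        est.index.str.endswith(UNSPLICED_SUFFIX), index=est.index
    )
    return TranscriptAbundanceTable(est_counts=est, tx2gene=t2g, unspliced=unspliced)


def from_simulation(tables: TranscriptTables) -> TranscriptAbundanceTable:
    """Wrap in-memory simulator output as a :class:`TranscriptAbundanceTable`."""
    return TranscriptAbundanceTable(
        est_counts=tables.est_counts,
        tx2gene=tables.tx2gene,
        unspliced=tables.unspliced,
    )


def read_counts_tsv(path, metadata_path=None) -> CountMatrix:
    """Read a plain genes x samples count TSV (first column = gene IDs)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    samples = None
    if metadata_path is not None:
        samples = pd.read_csv(metadata_path, sep="\t").set_index("sample")
        samples = samples.loc[counts.columns]
    return CountMatrix(counts=counts, samples=samples)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("sample")


def write_counts_tsv(m: CountMatrix, path) -> None:
    m.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def write_norm_factors(m: CountMatrix, path) -> None:
    pd.DataFrame(
        {"lib_size": m.lib_sizes, "norm_factor": m.norm_factors}
    ).rename_axis("sample").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# aggregation and filtering


def aggregate_to_genes(table: TranscriptAbundanceTable,
                       metadata: pd.DataFrame | None = None) -> CountMatrix:
    """Sum mature-transcript counts per gene; unspliced rows are omitted.

    Every gene with at least one transcript (of any kind) appears in the
    output, so a gene whose only reads are unspliced keeps a zero row.  Gene
    order is lexicographic.
    """
    unmapped = table.est_counts.index.difference(table.tx2gene.index)
    if len(unmapped):
        raise AggregationError(
            f"transcripts with no gene mapping: {sorted(unmapped)[:10]}"
            + ("..." if len(unmapped) > 10 else "")
        )
    genes = table.tx2gene.loc[table.est_counts.index]
    mature = ~table.unspliced.loc[table.est_counts.index].to_numpy()
    summed = table.est_counts.loc[mature].groupby(
        genes[mature].to_numpy()
    ).sum()
    all_genes = pd.Index(sorted(genes.unique()))
    summed = summed.reindex(all_genes, fill_value=0.0)
    return CountMatrix(counts=summed, samples=metadata)


def cpm(m: CountMatrix, log: bool = False, prior_count: float = 0.5,
        use_norm_factors: bool = True) -> pd.DataFrame:
    """Counts per million on effective library sizes.

    The log variant returns ``log2((count + prior) / (eff_lib + 2 * prior)
    * 1e6)``, an offset-stabilised logCPM that is finite at zero counts.
    """
    eff = m.lib_sizes * (m.norm_factors if use_norm_factors else 1.0)
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be positive")
    if not log:
        return m.counts / eff * 1e6
    return np.log2(
        (m.counts + prior_count) / (eff + 2.0 * prior_count) * 1e6
    )


def filter_undetected(m: CountMatrix, rule: FilterRule | None = None) -> CountMatrix:
    """Drop genes undetectable in at least ``min_undetected`` libraries.

    CPM is computed on the *pre-filter* raw library sizes (filtering precedes
    normalization); library sizes are recomputed on the retained genes and
    normalization factors reset to 1.
    """
    rule = rule or FilterRule()
    n = m.counts.shape[1]
    min_undetected = rule.resolve_min(n)
    vals = cpm(m, use_norm_factors=False)
    undetected = (vals < rule.cpm_threshold).sum(axis=1)
    keep = undetected < min_undetected
    if not keep.any():
        logger.warning("detection filter removed every gene")
    logger.info("detection filter: %d of %d genes retained",
                int(keep.sum()), len(keep))
    return CountMatrix(counts=m.counts.loc[keep], samples=m.samples)


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              logratio_trim: float, sum_trim: float) -> float:
    """Two-sample TMM factor (log2 scale) for ``obs`` against ``ref``."""
    ok = (obs > 0) & (ref > 0)
    o, r = obs[ok], ref[ok]
    if o.size == 0:
        return 0.0
    m_vals = np.log2((o / lib_obs) / (r / lib_ref))
    a_vals = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # inverse asymptotic binomial variances as precision weights
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.allclose(m_vals, 0.0, atol=1e-10):
        return 0.0
    n = m_vals.size
    # rank-based double trimming of M and A
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m_vals).rank().to_numpy()
    rank_a = pd.Series(a_vals).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m_vals[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_normalize(m: CountMatrix, logratio_trim: float = 0.3,
                  sum_trim: float = 0.05) -> CountMatrix:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile CPM is closest to the
    mean upper-quartile across samples.  For each other sample, genes with a
    zero count in either sample are excluded, the top/bottom
    ``logratio_trim`` of M-values and ``sum_trim`` of A-values are trimmed,
    and the factor is ``2**`` the precision-weighted mean of the surviving
    M-values.
    """
    counts = m.counts.to_numpy(dtype=float)
    libs = m.lib_sizes.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    if (counts.sum(axis=0) <= 0).any():
        raise ValueError("sample with all-zero counts")
    q75 = np.array([
        np.quantile(counts[:, j] / libs[j], 0.75) for j in range(counts.shape[1])
    ])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    log_factors = np.array([
        _tmm_pair(counts[:, j], counts[:, ref_idx], libs[j], libs[ref_idx],
                  logratio_trim, sum_trim)
        for j in range(counts.shape[1])
    ])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return replace(
        m, norm_factors=pd.Series(factors, index=m.counts.columns)
    )
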