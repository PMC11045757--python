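"""Expression quantities: exon-union gene lengths, TPM, spike-in loess.

TPM uses the read-length form of the formula (rate = count * read_length /
exon_length, scaled to 1e6 per sample); the read length cancels within a
sample but is kept for fidelity with how the quantity is usually written
down for paired-end data.

The cross-sample normalization is MA-style loess anchored exclusively on
spike-in rows: for each sample, M = log2(sample) - log2(reference) is
regressed on A = (log2(sample) + log2(reference))/2 over spike-ins only
(reference = per-row geometric mean across samples), and the fitted trend
is subtracted from every row. Because spike-ins are added per cell at fixed
abundance, this removes technical between-sample trends while *preserving*
genuine global shifts in the endogenous transcriptome — the property that
motivates spike-in anchoring in the first place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import SPIKEIN_PREFIX

DEFAULT_READ_LENGTH = 100
DEFAULT_SPAN = 0.5
LOESS_ITERATIONS = 4  # robustifying reweights
LOG_PSEUDO_TPM = 0.5
MIN_SPIKEINS = 8


# ---------------------------------------------------------------------------
# gene lengths
# ---------------------------------------------------------------------------

def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open [start, end) intervals, merged and sorted."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"malformed interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def exon_union_length(exons: list[tuple[int, int]]) -> int:
    """Length (bp) of the union of all exon intervals across isoforms.

    Exons are half-open [start, end) on a single chromosome; duplicated and
    overlapping exons from different isoforms count once. Strand is
    irrelevant to length.
    """
    if not exons:
        raise ValueError("gene has no exons")
    return sum(e - s for s, e in merge_intervals(exons))


def gene_lengths_from_exons(exons: pd.DataFrame) -> pd.Series:
    """Exon-union length per gene from a table with gene_id/start/end.

    Coordinates are half-open 0-based (the internal convention; GTF input is
    converted on read). Raises if a gene's exons span several chromosomes.
    """
    required = {"gene_id", "start", "end"}
    if missing := required - set(exons.columns):
        raise ValueError(f"exon table missing columns: {sorted(missing)}")
    if "chromosome" in exons.columns:
        per_gene = exons.groupby("gene_id")["chromosome"].nunique()
        bad = per_gene[per_gene > 1]
        if len(bad):
            raise ValueError(f"genes with exons on multiple chromosomes: {list(bad.index)[:5]}")
    lengths = {
        gene: exon_union_length(list(zip(grp["start"], grp["end"])))
        for gene, grp in exons.groupby("gene_id")
    }
    return pd.Series(lengths, name="length_bp")


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def compute_tpm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    read_length: int = DEFAULT_READ_LENGTH,
) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and exon-union lengths.

    Per sample: rate_g = count_g * read_length / length_g, normterm = sum of
    rates over all rows (spike-ins included), TPM_g = rate_g * 1e6 / normterm.
    Column sums are exactly 1e6 for any sample with nonzero counts.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"rows without a length: {list(missing[:5])}")
    length = lengths.reindex(counts.index).astype(float)
    if (length <= 0).any():
        bad = length.index[length <= 0]
        raise ValueError(f"non-positive lengths for rows: {list(bad[:5])}")
    rate = counts.div(length, axis=0) * read_length
    normterm = rate.sum(axis=0)
    if (normterm == 0).any():
        empty = normterm.index[normterm == 0]
        raise ValueError(f"samples with zero total counts: {list(empty[:5])}")
    return rate.div(normterm, axis=1) * 1e6


# ---------------------------------------------------------------------------
# spike-in anchored loess
# ---------------------------------------------------------------------------

def detect_spikeins(row_ids, prefix: str = SPIKEIN_PREFIX) -> list[str]:
    return [r for r in row_ids if str(r).startswith(prefix)]


def loess_normalize(
    tpm: pd.DataFrame,
    spikein_ids: list[str] | None = None,
    span: float = DEFAULT_SPAN,
    pseudocount: float = LOG_PSEUDO_TPM,
) -> pd.DataFrame:
    """Remove per-sample M-vs-A trends fitted on spike-in rows only.

    The fitted loess curve (locally weighted linear regression, robustified)
    is evaluated at every row's A value — constant extension beyond the
    spike-in A range — and subtracted from the sample's log2 values; output
    is back-transformed to the TPM scale. After normalization the spike-in
    M-vs-A trend is flat, while coordinated endogenous-only shifts survive.
    """
    if spikein_ids is None:
        spikein_ids = detect_spikeins(tpm.index)
    spikein_ids = [s for s in spikein_ids if s in tpm.index]
    if len(spikein_ids) < MIN_SPIKEINS:
        raise ValueError(f"need >= {MIN_SPIKEINS} spike-in rows, found {len(spikein_ids)}")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")

    log2 = np.log2(tpm.to_numpy(dtype=float) + pseudocount)
    ref = log2.mean(axis=1)  # log2 geometric-mean pseudo-reference
    spike_mask = tpm.index.isin(spikein_ids)

    corrected = np.empty_like(log2)
    for j in range(log2.shape[1]):
        m = log2[:, j] - ref
        a = 0.5 * (log2[:, j] + ref)
        fit = sm.nonparametric.lowess(
            m[spike_mask],
            a[spike_mask],
            frac=span,
            it=LOESS_ITERATIONS,
            return_sorted=True,
        )
        # evaluate at every row's A; np.interp extends constantly at the ends
        trend = np.interp(a, fit[:, 0], fit[:, 1])
        corrected[:, j] = log2[:, j] - trend

    out = np.maximum(2.0**corrected - pseudocount, 0.0)
    return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)


def spikein_ma(
    tpm: pd.DataFrame,
    spikein_ids: list[str] | None = None,
    pseudocount: float = LOG_PSEUDO_TPM,
) -> pd.DataFrame:
    """Per-sample spike-in M values against the geometric-mean reference.

    Diagnostic companion to :func:`loess_normalize`: rows = spike-ins,
    columns = samples, values = log2(sample) - log2(reference).
    """
    if spikein_ids is None:
        spikein_ids = detect_spikeins(tpm.index)
    log2 = np.log2(tpm.to_numpy(dtype=float) + pseudocount)
    ref = log2.mean(axis=1)
    m = pd.DataFrame(log2 - ref[:, None], index=tpm.index, columns=tpm.columns)
    return m.loc[[s for s in spikein_ids if s in tpm.index]]
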