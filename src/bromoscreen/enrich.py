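"""k-means with elbow-based k selection, hypergeometric gene-set enrichment
and E-box promoter-motif statistics.

The elbow is formalized kneedle-style: over the within-cluster sum of
squares (WSS) curve, both axes are min-max normalized and the chosen k
maximizes the distance from the curve to the chord joining its endpoints.
Gene-set enrichment is the exact hypergeometric upper tail (equivalently a
one-sided Fisher test), a self-contained stand-in for remote over-
representation services. Motif statistics count sliding-window matches to an
IUPAC consensus (CACGTG, the MYC/MAX E-box, by default), with palindromic
sites counted once when both strands are scanned.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .de import bh_adjust
from .integrate import fisher_two_sided

logger = logging.getLogger(__name__)

EBOX = "CACGTG"
FLAT_WSS_RANGE = 1e-9


# ---------------------------------------------------------------------------
# k-means + elbow
# ---------------------------------------------------------------------------

@dataclass
class ElbowResult:
    k: int
    assignments: np.ndarray
    k_values: np.ndarray
    wss: np.ndarray


def elbow_k(k_values: np.ndarray, wss: np.ndarray) -> int:
    """Kneedle-style elbow of a WSS curve: max distance to the endpoint chord.

    Axes are min-max normalized first so the choice is invariant to the
    scales of k and WSS. Flat curves (WSS range below 1e-9) return the
    smallest k — there is no elbow to find.
    """
    k_values = np.asarray(k_values, dtype=float)
    wss = np.asarray(wss, dtype=float)
    if len(k_values) != len(wss) or len(k_values) < 2:
        raise ValueError("need matched k and WSS vectors of length >= 2")
    span = wss.max() - wss.min()
    if span < FLAT_WSS_RANGE or wss[0] < FLAT_WSS_RANGE:
        # degenerate curve (e.g. one tight cluster): no elbow, keep smallest k
        return int(k_values[0])
    x = (k_values - k_values[0]) / (k_values[-1] - k_values[0])
    y = (wss - wss.min()) / span
    # distance from each point to the chord joining the endpoints
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    return int(k_values[int(np.argmax(dist))])


def kmeans_elbow(
    matrix: pd.DataFrame | np.ndarray,
    k_range: range | tuple[int, int] = (1, 10),
    restarts: int = 20,
    seed: int = 0,
    standardize_rows: bool = True,
) -> ElbowResult:
    """Best-of-restarts k-means over a k grid with elbow-based k selection.

    Rows (genes) are observations; by default each row is standardized to
    mean 0 / sd 1, the usual convention before clustering fold-change
    profiles for a heatmap. Fully seed-deterministic.
    """
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    keep = np.isfinite(values).all(axis=1)
    if not keep.all():
        logger.warning("dropping %d row(s) with non-finite values", int((~keep).sum()))
        values = values[keep]
    if isinstance(k_range, tuple):
        k_range = range(k_range[0], k_range[1] + 1)
    ks = np.array(sorted(k_range))
    if ks[0] < 1 or ks[-1] > len(values):
        raise ValueError("k_range must lie within [1, n_rows]")

    if standardize_rows:
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=1, keepdims=True)) / sd

    wss = []
    models = {}
    for k in ks:
        km = KMeans(n_clusters=int(k), n_init=restarts, random_state=seed)
        km.fit(values)
        wss.append(km.inertia_)
        models[int(k)] = km
    wss = np.array(wss)
    chosen = elbow_k(ks, wss)
    return ElbowResult(k=chosen, assignments=models[chosen].labels_, k_values=ks, wss=wss)


# ---------------------------------------------------------------------------
# hypergeometric gene-set enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    query, gene_sets: dict[str, set], universe
) -> pd.DataFrame:
    """Exact hypergeometric over-representation p per gene set, BH across sets.

    p = P(X >= overlap) with X ~ Hypergeom(|universe|, |set|, |query|); sets
    are intersected with the universe and the query must be contained in it.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes) & universe
        overlap = len(query & genes)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(genes), len(query)))
        rows.append((name, len(genes), overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"]).set_index("gene_set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")


# ---------------------------------------------------------------------------
# motif scanning and enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSpec:
    consensus: str = EBOX
    both_strands: bool = True

    def __post_init__(self):
        consensus = self.consensus.upper()
        bad = set(consensus) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"non-IUPAC characters in consensus: {sorted(bad)}")
        object.__setattr__(self, "consensus", consensus)

    @property
    def pattern(self) -> re.Pattern:
        return re.compile(_iupac_regex(self.consensus))

    @property
    def revcomp_pattern(self) -> re.Pattern:
        return re.compile(_iupac_regex(str(Seq(self.consensus).reverse_complement())))


def _iupac_regex(consensus: str) -> str:
    parts = []
    for ch in consensus:
        options = ambiguous_dna_values[ch]
        parts.append(options if len(options) == 1 else f"[{options}]")
    return "".join(parts)


_VALID_SEQ = re.compile(r"^[ACGTN]*$")


def motif_scan(sequences: dict[str, str], motif: MotifSpec | str = EBOX) -> pd.Series:
    """Sliding-window match counts per sequence (overlaps allowed).

    With both_strands, positions matching the reverse-complement consensus
    are added, but a position matching on both strands — as every occurrence
    of a palindrome like CACGTG does — counts once.
    """
    if isinstance(motif, str):
        motif = MotifSpec(consensus=motif)
    fwd = re.compile(f"(?=({motif.pattern.pattern}))")
    rev = re.compile(f"(?=({motif.revcomp_pattern.pattern}))")
    counts = {}
    for sid, seq in sequences.items():
        seq = seq.upper()
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"invalid characters {bad} in sequence {sid!r}")
        positions = {m.start() for m in fwd.finditer(seq)}
        if motif.both_strands:
            positions |= {m.start() for m in rev.finditer(seq)}
        counts[sid] = len(positions)
    return pd.Series(counts, name="motif_count", dtype=int)


@dataclass(frozen=True)
class MotifEnrichment:
    query_positive: int
    query_total: int
    background_positive: int
    background_total: int
    fisher_p: float
    table: tuple[tuple[int, int], tuple[int, int]] = field(repr=False, default=None)


def motif_enrichment(
    query_promoters: dict[str, str],
    background_promoters: dict[str, str],
    motif: MotifSpec | str = EBOX,
) -> MotifEnrichment:
    """Two-sided Fisher test on motif-positive promoter counts, query vs background.

    A promoter is motif-positive if it carries >= 1 match. Query sequences
    also present in the background are excluded from the background (logged).
    """
    if not query_promoters or not background_promoters:
        raise ValueError("query and background must be non-empty")
    shared = set(query_promoters) & set(background_promoters)
    if shared:
        logger.info("excluding %d query promoter(s) from the background", len(shared))
        background_promoters = {
            k: v for k, v in background_promoters.items() if k not in shared
        }
        if not background_promoters:
            raise ValueError("background empty after removing query promoters")
    q = motif_scan(query_promoters, motif)
    b = motif_scan(background_promoters, motif)
    qp, bp = int((q > 0).sum()), int((b > 0).sum())
    table = ((qp, len(q) - qp), (bp, len(b) - bp))
    return MotifEnrichment(
        query_positive=qp,
        query_total=len(q),
        background_positive=bp,
        background_total=len(b),
        fisher_p=fisher_two_sided(table),
        table=table,
    )
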