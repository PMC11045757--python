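"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of input the analysis consumes:

* pooled-screen viability tables (Hill curves with multiplicative noise and
  planted compound-preferential cell lines),
* raw RNA-seq count matrices with fixed-abundance spike-in rows, planted
  fold-changes and condition-level global transcriptional shifts,
* Chronos-style gene-effect matrices with planted dependencies,
* confidence-weighted interaction graphs with a planted dense module,
* promoter sequences with planted E-box (CACGTG) occurrences.

All generators are seed-deterministic: the same config and seed reproduce
the output bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

BRD_COMPOUND = "CCS1477"
HAT_COMPOUND = "A485"

CLASS_BRD = "brd_preferential"
CLASS_HAT = "hat_preferential"
CLASS_NEUTRAL = "neutral"

SPIKEIN_PREFIX = "ERCC-"


def default_dose_grid(n: int = 10, low: float = 1e-9, high: float = 1e-5) -> np.ndarray:
    """Log-spaced molar dose grid, 1 nM to 10 uM by default."""
    return np.logspace(np.log10(low), np.log10(high), n)


# ---------------------------------------------------------------------------
# pooled viability screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Configuration for the pooled dose-response viability screen simulator.

    A fraction of lines is planted as BRD-preferential (the CCS1477-like
    compound has a ``preferential_ic50_factor``-fold lower IC50 in those
    lines), a fraction as HAT-preferential (symmetric), and the rest are
    neutral (identical Hill parameters for both compounds).
    """

    n_lines: int = 100
    n_lineages: int = 8
    n_brd_preferential: int = 20
    n_hat_preferential: int = 0
    preferential_ic50_factor: float = 100.0
    dose_grid: np.ndarray = field(default_factory=default_dose_grid)
    ic50_log10_mean: float = -6.0  # 1 uM
    ic50_log10_sd: float = 0.3
    slope_mean: float = 1.0
    slope_sd: float = 0.15
    floor_max: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        doses = np.asarray(self.dose_grid, dtype=float)
        if doses.ndim != 1 or len(doses) < 2:
            raise ValueError("dose_grid must be a 1-D grid of >= 2 doses")
        if np.any(doses <= 0):
            raise ValueError("doses must be positive molar concentrations")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.n_brd_preferential + self.n_hat_preferential > self.n_lines:
            raise ValueError("planted classes exceed n_lines")
        if not 0 <= self.floor_max <= 1:
            raise ValueError("floor must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def hill_viability(doses: np.ndarray, ic50: float, slope: float, floor: float) -> np.ndarray:
    """Fraction-of-control viability under a descending Hill curve."""
    d = np.asarray(doses, dtype=float)
    return floor + (1.0 - floor) / (1.0 + (d / ic50) ** slope)


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the two-compound pooled screen.

    Returns
    -------
    viability : DataFrame
        Long format, one row per line x compound x dose with columns
        ``cell_line, lineage, compound, dose_molar, viability``.
    truth : DataFrame
        One row per cell line with the planted class and per-compound IC50s.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.dose_grid, dtype=float)

    labels = np.array(
        [CLASS_BRD] * config.n_brd_preferential
        + [CLASS_HAT] * config.n_hat_preferential
        + [CLASS_NEUTRAL] * (config.n_lines - config.n_brd_preferential - config.n_hat_preferential)
    )
    rng.shuffle(labels)

    lines = [f"LINE{i:04d}" for i in range(config.n_lines)]
    lineages = [f"lineage{rng.integers(config.n_lineages)}" for _ in lines]

    base_ic50 = 10 ** rng.normal(config.ic50_log10_mean, config.ic50_log10_sd, config.n_lines)
    slopes = np.clip(rng.normal(config.slope_mean, config.slope_sd, config.n_lines), 0.2, None)
    floors = rng.uniform(0.0, config.floor_max, config.n_lines)

    rows = []
    truth_rows = []
    for i, line in enumerate(lines):
        ic50 = {BRD_COMPOUND: base_ic50[i], HAT_COMPOUND: base_ic50[i]}
        if labels[i] == CLASS_BRD:
            ic50[BRD_COMPOUND] /= config.preferential_ic50_factor
        elif labels[i] == CLASS_HAT:
            ic50[HAT_COMPOUND] /= config.preferential_ic50_factor
        for compound in (BRD_COMPOUND, HAT_COMPOUND):
            clean = hill_viability(doses, ic50[compound], slopes[i], floors[i])
            noise = np.exp(rng.normal(0.0, config.noise_sd, len(doses))) if config.noise_sd > 0 else 1.0
            viab = clean * noise
            for d, v in zip(doses, viab):
                rows.append((line, lineages[i], compound, d, v))
        truth_rows.append((line, lineages[i], labels[i], ic50[BRD_COMPOUND], ic50[HAT_COMPOUND]))

    viability = pd.DataFrame(
        rows, columns=["cell_line", "lineage", "compound", "dose_molar", "viability"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["cell_line", "lineage", "planted_class", "ic50_brd", "ic50_hat"],
    )
    return viability, truth


# ---------------------------------------------------------------------------
# spike-in RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass
class RnaSimConfig:
    """Configuration for the spike-in count-matrix simulator.

    Endogenous counts are negative-binomial with a mean-dependent dispersion
    trend ``alpha(mu) = a0 + a1/mu``; a condition-level ``global_shift``
    multiplies endogenous means only (emulating a global transcriptional
    change per cell), while the 92 spike-in rows keep fixed per-cell
    abundances and respond only to per-sample technical depth.
    """

    n_genes: int = 2000
    n_spikeins: int = 92
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("DMSO", "treated")
    baseline_mean_logdist: tuple[float, float] = (3.0, 1.8)  # natural-log mu, sigma
    dispersion_trend: tuple[float, float] = (0.02, 2.0)  # a0, a1 in alpha = a0 + a1/mu
    spikein_dispersion: float = 0.01
    planted_de_fraction: float = 0.0
    planted_log2fc: float = 2.0
    planted_log2fc_sd: float = 0.0
    global_shift: dict[str, float] | None = None  # condition -> endogenous multiplier
    depth_sd: float = 0.1  # lognormal sigma of per-sample technical depth
    read_length: int = 100
    gene_length_log10_range: tuple[float, float] = (2.7, 4.3)
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate per condition")
        if not 0 <= self.planted_de_fraction <= 1:
            raise ValueError("planted_de_fraction must lie in [0, 1]")
        if self.n_spikeins < 1:
            raise ValueError("need >= 1 spike-in row")
        if self.depth_sd < 0 or self.read_length <= 0:
            raise ValueError("depth_sd >= 0 and read_length > 0 required")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2, via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson_mask = alpha <= 0
    if np.any(poisson_mask):
        out[poisson_mask] = rng.poisson(mean[poisson_mask])
    if np.any(~poisson_mask):
        shape = 1.0 / alpha[~poisson_mask]
        lam = rng.gamma(shape, mean[~poisson_mask] * alpha[~poisson_mask])
        out[~poisson_mask] = rng.poisson(lam)
    return out


def spikein_ids(n: int = 92) -> list[str]:
    return [f"{SPIKEIN_PREFIX}{i:05d}" for i in range(1, n + 1)]


def spikein_abundances(n: int = 92, seed: int = 92) -> np.ndarray:
    """Fixed synthetic spike-in panel: log-uniform abundances over 2^0..2^15.

    The panel mimics the dynamic range of a commercial spike-in mix without
    redistributing vendor data; it depends only on its own seed, not on the
    experiment seed, so the 'known fixed abundance' contract holds across
    simulations.
    """
    rng = np.random.default_rng(seed)
    return 2.0 ** rng.uniform(0.0, 15.0, n)


def simulate_counts(config: RnaSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a raw count matrix (genes + spike-ins) x samples.

    Returns
    -------
    counts : DataFrame
        Integer counts, rows = gene/spike-in ids, columns = sample ids.
    gene_truth : DataFrame
        Per-row truth: baseline mean, true log2 fold change (treated vs the
        first condition), planted-DE flag, spike-in flag, length_bp.
    sample_sheet : DataFrame
        sample_id, condition, replicate, true technical depth factor.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a0, a1 = config.dispersion_trend
    mu_log, sd_log = config.baseline_mean_logdist

    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    spikes = spikein_ids(config.n_spikeins)
    base_mean = np.exp(rng.normal(mu_log, sd_log, config.n_genes))
    spike_mean = spikein_abundances(config.n_spikeins)

    n_de = int(round(config.planted_de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    lfc = np.zeros(config.n_genes)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        mags = config.planted_log2fc + (
            rng.normal(0.0, config.planted_log2fc_sd, n_de) if config.planted_log2fc_sd > 0 else 0.0
        )
        lfc[de_idx] = signs * mags

    shift = {c: 1.0 for c in config.conditions}
    if config.global_shift:
        unknown = set(config.global_shift) - set(config.conditions)
        if unknown:
            raise ValueError(f"global_shift names unknown conditions: {sorted(unknown)}")
        shift.update(config.global_shift)

    samples, sample_rows = [], []
    cols = {}
    ref_condition = config.conditions[0]
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            sid = f"{cond}_r{rep}"
            depth = float(np.exp(rng.normal(0.0, config.depth_sd))) if config.depth_sd > 0 else 1.0
            cond_lfc = lfc if cond != ref_condition else np.zeros_like(lfc)
            gene_mu = base_mean * (2.0 ** cond_lfc) * shift[cond] * depth
            gene_alpha = a0 + a1 / np.maximum(base_mean, 1e-8)
            gene_counts = _nb_draw(rng, gene_mu, gene_alpha)
            spike_counts = _nb_draw(rng, spike_mean * depth, config.spikein_dispersion)
            cols[sid] = np.concatenate([gene_counts, spike_counts])
            samples.append(sid)
            sample_rows.append((sid, cond, rep, depth))

    counts = pd.DataFrame(cols, index=genes + spikes)
    lengths = 10 ** rng.uniform(*config.gene_length_log10_range, config.n_genes)
    spike_lengths = rng.integers(250, 2001, config.n_spikeins).astype(float)
    gene_truth = pd.DataFrame(
        {
            "baseline_mean": np.concatenate([base_mean, spike_mean]),
            "true_log2fc": np.concatenate([lfc, np.zeros(config.n_spikeins)]),
            "is_planted_de": np.concatenate(
                [lfc != 0, np.zeros(config.n_spikeins, dtype=bool)]
            ),
            "is_spikein": [False] * config.n_genes + [True] * config.n_spikeins,
            "length_bp": np.concatenate([np.round(lengths), spike_lengths]),
        },
        index=genes + spikes,
    )
    sample_sheet = pd.DataFrame(
        sample_rows, columns=["sample_id", "condition", "replicate", "true_depth"]
    )
    return counts, gene_truth, sample_sheet


# ---------------------------------------------------------------------------
# CRISPR dependency scores
# ---------------------------------------------------------------------------

@dataclass
class DepSimConfig:
    """Chronos-style gene-effect score simulator with planted dependencies."""

    n_genes: int = 500
    n_lines: int = 7
    planted_dependency_genes: tuple[str, ...] | None = None
    n_planted: int = 50
    dependency_mean: float = -1.0
    background_mean: float = 0.0
    sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 1:
            raise ValueError("need >= 1 cell line")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.planted_dependency_genes is None and self.n_planted > self.n_genes:
            raise ValueError("n_planted exceeds gene universe")


DEFAULT_MB_LINES = ("UW228", "DAOY", "ONS76", "D458", "D425", "D283MED", "D341MED")


def simulate_dependency(config: DepSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x cell-line effect-score matrix.

    Planted dependency genes score around ``dependency_mean`` in every line;
    the rest score around ``background_mean``. Line names follow the seven
    medulloblastoma models when ``n_lines == 7``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    if config.planted_dependency_genes is not None:
        planted = list(config.planted_dependency_genes)
        missing = set(planted) - set(genes)
        if missing:
            raise ValueError(f"planted genes outside universe: {sorted(missing)[:5]}")
    else:
        planted = list(rng.choice(genes, size=config.n_planted, replace=False))
    planted_set = set(planted)

    lines = (
        list(DEFAULT_MB_LINES)
        if config.n_lines == len(DEFAULT_MB_LINES)
        else [f"LINE{i}" for i in range(config.n_lines)]
    )
    means = np.where(
        np.isin(genes, planted), config.dependency_mean, config.background_mean
    )[:, None]
    scores = rng.normal(means, config.sd, size=(config.n_genes, config.n_lines))
    dep = pd.DataFrame(scores, index=genes, columns=lines)
    truth = pd.DataFrame({"is_dependency": [g in planted_set for g in genes]}, index=genes)
    return dep, truth


# ---------------------------------------------------------------------------
# interaction graph with a planted module
# ---------------------------------------------------------------------------

@dataclass
class GraphSimConfig:
    """Planted dense-module graph: clique-ish module over a sparse background."""

    n_genes: int = 200
    module_size: int = 20
    p_within: float = 0.8
    p_background: float = 0.02
    confidence_range: tuple[float, float] = (0.4, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.p_background <= 1 and 0 <= self.p_within <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.module_size > self.n_genes:
            raise ValueError("module larger than gene universe")


def simulate_graph(config: GraphSimConfig) -> tuple[nx.Graph, list[str]]:
    """Return (graph, planted module genes). Edges carry 'confidence'."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    module = list(rng.choice(genes, size=config.module_size, replace=False))
    module_set = set(module)

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    lo, hi = config.confidence_range
    for i in range(config.n_genes):
        for j in range(i + 1, config.n_genes):
            p = (
                config.p_within
                if genes[i] in module_set and genes[j] in module_set
                else config.p_background
            )
            if rng.random() < p:
                graph.add_edge(genes[i], genes[j], confidence=float(rng.uniform(lo, hi)))
    return graph, module


# ---------------------------------------------------------------------------
# promoter sequences with planted E-boxes
# ---------------------------------------------------------------------------

@dataclass
class PromoterSimConfig:
    """Random promoters; a fraction carries one planted motif occurrence."""

    n_sequences: int = 100
    length: int = 500
    motif: str = "CACGTG"
    positive_fraction: float = 0.1
    id_prefix: str = "PROM"
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.length < len(self.motif):
            raise ValueError("sequences shorter than the motif")


def simulate_promoters(config: PromoterSimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Return ({id: sequence}, truth with planted flag per sequence)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    truth_rows = []
    for i in range(config.n_sequences):
        seq = rng.choice(bases, size=config.length)
        planted = bool(rng.random() < config.positive_fraction)
        if planted:
            pos = int(rng.integers(0, config.length - len(config.motif) + 1))
            seq[pos : pos + len(config.motif)] = list(config.motif)
        sid = f"{config.id_prefix}{i:05d}"
        seqs[sid] = "".join(seq)
        truth_rows.append((sid, planted))
    truth = pd.DataFrame(truth_rows, columns=["sequence_id", "planted_motif"]).set_index(
        "sequence_id"
    )
    return seqs, truth
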