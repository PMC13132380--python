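"""Synthetic data with planted truth.

Generates the inputs every downstream stage consumes — gene annotation, peak
sets for separate and sequential ChIP, promoter signal matrices for two
conditions, coupled expression changes, and multi-sample program-structured
expression — so the whole pipeline is testable without any external dataset.

Model sketch
------------
Each gene is planted into one of five states per condition: three bivalent
(H3K4me3-high, H3K27me3-high, equal) and two non-bivalent (active, silent).
Promoter intensities for the two marks are the state means scaled by a shared
per-gene, per-condition log-normal factor ``exp(eps)``, eps ~ N(0, sigma^2) —
promoter-level efficiency noise that preserves the K4/K27 ratio.  A mark's
peak is emitted at the promoter iff its intensity exceeds an emission
threshold (default twice the silent-state mean); sequential-ChIP peaks are
emitted exactly at bivalent promoters.  Between conditions, a fraction of
cluster-II/III genes switch to cluster I (bivalency resolution), and their
expression change is positive with a configurable coupling probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, PeakSet, SignalMatrix

__all__ = [
    "STATES",
    "BIVALENT_STATES",
    "SimulationConfig",
    "PlantedTruth",
    "ChipSimulation",
    "simulate_genome",
    "simulate_chip",
    "simulate_expression",
    "simulate_program_matrices",
]

K4_HIGH = "K4_HIGH"
K27_HIGH = "K27_HIGH"
EQUAL = "EQUAL"
NONBIVALENT_ACTIVE = "NONBIVALENT_ACTIVE"
NONBIVALENT_SILENT = "NONBIVALENT_SILENT"

STATES = (K4_HIGH, K27_HIGH, EQUAL, NONBIVALENT_ACTIVE, NONBIVALENT_SILENT)
BIVALENT_STATES = frozenset({K4_HIGH, K27_HIGH, EQUAL})

#: default (mu_K4, mu_K27) per state; separated enough that the 1.5-fold
#: ratio rule is unambiguous under the shared-noise model.
DEFAULT_MEANS: dict[str, tuple[float, float]] = {
    K4_HIGH: (8.0, 2.0),
    K27_HIGH: (2.0, 8.0),
    EQUAL: (5.0, 5.0),
    NONBIVALENT_ACTIVE: (8.0, 0.5),
    NONBIVALENT_SILENT: (0.5, 0.5),
}

DEFAULT_FRACTIONS: dict[str, float] = {
    K4_HIGH: 0.10,
    K27_HIGH: 0.10,
    EQUAL: 0.10,
    NONBIVALENT_ACTIVE: 0.35,
    NONBIVALENT_SILENT: 0.35,
}


@dataclass
class SimulationConfig:
    """Study conditions for the ChIP/expression simulator.

    Parameters
    ----------
    n_genes : int
        Genome size.
    state_fractions : dict
        Fraction of genes planted in each of the five states; must sum to 1.
        Default plants 30% bivalent genes (10% each cluster).
    mean_intensity : dict
        Per-state (mu_K4, mu_K27) promoter intensity means.
    noise_sigma : float
        Standard deviation (natural-log scale) of the shared log-normal
        multiplicative noise per gene per condition.
    switch_fraction : float
        Fraction of eligible (cluster II/III) genes whose state resolves to
        cluster I in condition B.
    coupling_prob : float
        Probability that a switching gene's expression log-fold-change is
        positive.
    emission_factor : float
        Peak emission threshold as a multiple of the silent-state mean.
    """

    n_genes: int = 1000
    state_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    mean_intensity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MEANS)
    )
    noise_sigma: float = 0.3
    switch_fraction: float = 0.5
    coupling_prob: float = 0.85
    emission_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if set(self.state_fractions) != set(STATES):
            raise ValueError(f"state_fractions must cover exactly {STATES}")
        total = sum(self.state_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state_fractions sum to {total}, expected 1")
        for state, (mu4, mu27) in self.mean_intensity.items():
            if mu4 <= 0 or mu27 <= 0:
                raise ValueError(f"non-positive mean intensity for {state}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("switch_fraction", "coupling_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``table`` holds per-gene: ``state_a``, ``state_b``, ``is_bivalent``
    (bivalent in condition A), ``is_switch`` (II/III -> I) and, once
    :func:`simulate_expression` has run, ``expr_lfc_sign``.  ``programs``
    is filled by :func:`simulate_program_matrices`.
    """

    table: pd.DataFrame
    programs: pd.DataFrame | None = None

    def state_counts(self, condition: str = "a") -> pd.Series:
        return self.table[f"state_{condition}"].value_counts()

    @property
    def bivalent_genes(self) -> set[str]:
        t = self.table
        return set(t.index[t["is_bivalent"]])

    @property
    def switch_genes(self) -> set[str]:
        t = self.table
        return set(t.index[t["is_switch"]])


@dataclass
class ChipSimulation:
    """Output bundle of :func:`simulate_chip`."""

    peak_sets: dict[tuple[str, str], PeakSet]  # (mark-or-"sequential", condition)
    signal: dict[str, SignalMatrix]  # condition -> genes x {H3K4me3, H3K27me3}
    truth: PlantedTruth


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Apportion n into integer counts proportional to fractions.

    Largest-remainder rounding; remainder ties are broken by state
    enumeration order.
    """
    order = [s for s in STATES if s in fractions]
    raw = np.array([fractions[s] * n for s in order])
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    # stable sort => earlier states win remainder ties
    by_rem = sorted(range(len(order)), key=lambda i: -(raw[i] - base[i]))
    for i in by_rem[:short]:
        base[i] += 1
    return dict(zip(order, base.tolist()))


def simulate_genome(n_genes: int, seed: int) -> GenomeAnnotation:
    """Deterministic synthetic annotation of ``n_genes`` protein-coding genes.

    TSSs are spaced 10 kb apart across five chromosomes so that default
    +/-1 kb promoter windows never overlap; strands are drawn from the seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed, 1)
    n_chroms = 5
    chrom_of = np.arange(n_genes) % n_chroms
    pos_in_chrom = np.arange(n_genes) // n_chroms
    records = pd.DataFrame(
        {
            "gene_id": [f"G{i:06d}" for i in range(n_genes)],
            "chrom": [f"chr{c + 1}" for c in chrom_of],
            "strand": rng.choice(["+", "-"], size=n_genes),
            "tss": 5000 + pos_in_chrom * 10000,
            "biotype": "protein_coding",
        }
    )
    return GenomeAnnotation(records)


def _plant_states(
    gene_ids: pd.Index, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(gene_ids)
    counts = largest_remainder_counts(cfg.state_fractions, n)
    labels = np.concatenate([[s] * counts[s] for s in STATES])
    state_a = pd.Series(labels[rng.permutation(n)], index=gene_ids)

    eligible = state_a.index[state_a.isin([K27_HIGH, EQUAL])]
    n_switch = int(round(cfg.switch_fraction * len(eligible)))
    switch_genes = pd.Index(
        rng.choice(np.asarray(eligible, dtype=object), size=n_switch, replace=False)
    )
    state_b = state_a.copy()
    state_b.loc[switch_genes] = K4_HIGH
    table = pd.DataFrame(
        {
            "state_a": state_a,
            "state_b": state_b,
            "is_bivalent": state_a.isin(BIVALENT_STATES),
            "is_switch": state_a.index.isin(switch_genes),
        }
    )
    return table


def simulate_chip(ann: GenomeAnnotation, cfg: SimulationConfig) -> ChipSimulation:
    """Simulate separate + sequential ChIP peaks and promoter signal.

    See the module docstring for the generative model.  Peak intervals are
    the TSS +/- 1 kb promoter windows themselves; peak scores carry the drawn
    intensity.  Deterministic given ``cfg.seed``.
    """
    from .io import make_promoters

    rng = _rng(cfg.seed, 2)
    genes = pd.Index(ann.records["gene_id"])
    table = _plant_states(genes, cfg, rng)
    promoters = make_promoters(ann)

    silent_mu4, silent_mu27 = cfg.mean_intensity[NONBIVALENT_SILENT]
    thr_k4 = cfg.emission_factor * silent_mu4
    thr_k27 = cfg.emission_factor * silent_mu27

    prom = promoters.to_frame().set_index("gene_id").loc[genes]
    peak_sets: dict[tuple[str, str], PeakSet] = {}
    signal: dict[str, SignalMatrix] = {}
    for cond in ("A", "B"):
        states = table[f"state_{'a' if cond == 'A' else 'b'}"]
        mu = np.array([cfg.mean_intensity[s] for s in states])
        eps = rng.normal(0.0, cfg.noise_sigma, size=len(genes))
        factor = np.exp(eps)
        k4 = mu[:, 0] * factor
        k27 = mu[:, 1] * factor

        values = pd.DataFrame({"H3K4me3": k4, "H3K27me3": k27}, index=genes)
        info = pd.DataFrame(
            {"mark": ["H3K4me3", "H3K27me3"], "condition": cond},
            index=pd.Index(["H3K4me3", "H3K27me3"], name="sample_id"),
        )
        signal[cond] = SignalMatrix(values, info)

        for mark, intensity, thr in (
            ("H3K4me3", k4, thr_k4),
            ("H3K27me3", k27, thr_k27),
        ):
            emit = intensity > thr
            frame = prom.loc[genes[emit]]
            peaks = pd.DataFrame(
                {
                    "chrom": frame["chrom"].to_numpy(),
                    "start": frame["start"].to_numpy(),
                    "end": frame["end"].to_numpy(),
                    "score": intensity[emit],
                }
            )
            peak_sets[(mark, cond)] = PeakSet(f"{mark}_{cond}", peaks)

        bivalent = states.isin(BIVALENT_STATES).to_numpy()
        frame = prom.loc[genes[bivalent]]
        seq = pd.DataFrame(
            {
                "chrom": frame["chrom"].to_numpy(),
                "start": frame["start"].to_numpy(),
                "end": frame["end"].to_numpy(),
                "score": np.minimum(k4, k27)[bivalent],
            }
        )
        peak_sets[("sequential", cond)] = PeakSet(f"sequential_K27-K4_{cond}", seq)

    return ChipSimulation(peak_sets, signal, PlantedTruth(table))


def simulate_expression(truth: PlantedTruth, cfg: SimulationConfig) -> pd.Series:
    """Per-gene expression log2 fold change coupled to bivalency resolution.

    Switching (II/III -> I) genes receive a positive change with probability
    ``cfg.coupling_prob`` and a negative one otherwise; magnitudes are
    Exponential(1) draws (strictly positive almost surely).  Non-switch genes
    draw from N(0, 1).  The realised signs are recorded in the truth table.
    """
    rng = _rng(cfg.seed, 3)
    table = truth.table
    n = len(table)
    lfc = pd.Series(rng.normal(0.0, 1.0, size=n), index=table.index)
    switch = table.index[table["is_switch"]]
    signs = np.where(rng.random(len(switch)) < cfg.coupling_prob, 1.0, -1.0)
    lfc.loc[switch] = signs * rng.exponential(1.0, size=len(switch))
    truth.table = table.assign(expr_lfc_sign=np.sign(lfc))
    return lfc


def simulate_program_matrices(
    n_samples: int,
    n_cells_per_sample: int,
    n_genes: int,
    planted_programs: list[list[str]],
    program_share: dict[int, list[int]] | None = None,
    seed: int = 0,
    baseline_scale: float = 0.5,
    signal_amplitude: float = 5.0,
    cell_fraction: float = 0.25,
) -> tuple[dict[str, pd.DataFrame], PlantedTruth]:
    """Multi-sample non-negative expression with planted additive programs.

    Each sample matrix (genes x cells) is baseline gamma noise (mean
    ``baseline_scale``; exactly zero when ``baseline_scale`` is 0) plus, for
    every program assigned to the sample, an additive block of
    ``signal_amplitude`` on (program genes x a random ``cell_fraction`` subset
    of cells).  ``program_share`` maps program index to the sample indices
    expressing it (default: every program in every sample).

    Returns the per-sample matrices keyed ``S1..Sn`` and a PlantedTruth whose
    ``programs`` frame lists (program, gene) memberships plus per-program
    sample support.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_cells_per_sample < 1:
        raise ValueError("n_cells_per_sample must be >= 1")
    seen: set[str] = set()
    for prog in planted_programs:
        overlap = seen.intersection(prog)
        if overlap:
            raise ValueError(f"planted programs overlap, e.g. {sorted(overlap)[:3]}")
        seen.update(prog)
    if len(seen) > n_genes:
        raise ValueError("program genes exceed n_genes")
    if program_share is None:
        program_share = {p: list(range(n_samples)) for p in range(len(planted_programs))}

    rng = _rng(seed, 4)
    gene_ids = [f"G{i:06d}" for i in range(n_genes)]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    matrices: dict[str, pd.DataFrame] = {}
    for s in range(n_samples):
        if baseline_scale > 0:
            base = rng.gamma(2.0, baseline_scale / 2.0, size=(n_genes, n_cells_per_sample))
        else:
            base = np.zeros((n_genes, n_cells_per_sample))
        for p, prog in enumerate(planted_programs):
            if s not in program_share.get(p, []):
                continue
            n_on = max(1, int(round(cell_fraction * n_cells_per_sample)))
            cells = rng.choice(n_cells_per_sample, size=n_on, replace=False)
            rows = [gene_pos[g] for g in prog]
            base[np.ix_(rows, cells)] += signal_amplitude
        matrices[f"S{s + 1}"] = pd.DataFrame(
            base,
            index=gene_ids,
            columns=[f"S{s + 1}_c{j}" for j in range(n_cells_per_sample)],
        )
    rows = []
    for p, prog in enumerate(planted_programs):
        support = program_share.get(p, [])
        for g in prog:
            rows.append(
                {
                    "program": f"P{p + 1}",
                    "gene_id": g,
                    "n_samples": len(support),
                    "recurrent": len(support) >= 2,
                }
            )
    programs = pd.DataFrame(rows)
    truth = PlantedTruth(table=pd.DataFrame(index=pd.Index(gene_ids)), programs=programs)
    return matrices, truth


def default_program_simulation(
    seed: int = 0,
    n_samples: int = 8,
    n_cells: int = 150,
    n_genes: int = 2000,
    n_programs: int = 5,
    program_size: int = 90,
) -> tuple[dict[str, pd.DataFrame], list[list[str]], PlantedTruth]:
    """The default planted meta-program study: 5 disjoint 90-gene programs
    shared by 8 samples over a 2,000-gene universe (the typical
    highly-variable-gene count of an scRNA-seq input) with moderate
    baseline noise.  Returns (matrices, planted program gene lists, truth).
    """
    programs = [
        [f"G{i:06d}" for i in range(p * program_size, (p + 1) * program_size)]
        for p in range(n_programs)
    ]
    matrices, truth = simulate_program_matrices(
        n_samples, n_cells, n_genes, programs, seed=seed
    )
    return matrices, programs, truth
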