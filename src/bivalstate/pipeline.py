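"""Pipeline orchestration: simulate -> call-bivalent -> diff -> classify ->
transitions (-> metaprograms), driven by a single YAML config.

Every stage writes its output in the same plain-text format its standalone
CLI subcommand would (BED for peaks, TSV for tables), and the run ends with
a machine-readable JSON summary.  Given the same config and seed, two runs
produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bivalency, differential, io, simulate, states

logger = logging.getLogger("bivalstate")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pipeline parameters; every field has the module default.

    Round-trips unchanged through YAML (``from_yaml``/``to_yaml``).
    """

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    outdir: str = "bivalstate_run"
    # simulate stage; when disabled, the input paths below must exist
    simulate: bool = True
    n_genes: int = 1000
    noise_sigma: float = 0.3
    switch_fraction: float = 0.5
    coupling_prob: float = 0.85
    # external inputs (used when simulate is false)
    annotation_path: str | None = None
    k4_bed: dict[str, str] = field(default_factory=dict)  # condition -> path
    k27_bed: dict[str, str] = field(default_factory=dict)
    seq_bed: dict[str, str] = field(default_factory=dict)
    signal_tsv: dict[str, str] = field(default_factory=dict)
    expression_lfc_tsv: str | None = None
    # promoter windows
    upstream_bp: int = 1000
    downstream_bp: int = 1000
    biotype_filter: str | None = "protein_coding"
    # differential
    alpha: float = 0.05
    lfc_threshold: float = 0.58
    diff_pseudocount: float = 1.0
    # states
    fc_threshold: float = 1.5
    state_pseudocount: float = 0.5
    # metaprograms (off by default; needs multi-sample expression input)
    metaprograms: bool = False
    mp_sample_dir: str | None = None
    mp_ks: list[int] = field(default_factory=lambda: [4, 5, 6, 7, 8, 9])
    mp_n_top: int = 90
    mp_j_min: float = 0.2
    mp_min_samples: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if not self.simulate:
            needed = [("annotation_path", self.annotation_path)]
            for cond in ("A", "B"):
                needed += [
                    (f"k4_bed[{cond}]", self.k4_bed.get(cond)),
                    (f"k27_bed[{cond}]", self.k27_bed.get(cond)),
                    (f"signal_tsv[{cond}]", self.signal_tsv.get(cond)),
                ]
            needed.append(("seq_bed[A]", self.seq_bed.get("A")))
            for name, path in needed:
                if path is None:
                    raise PipelineError("validate", f"missing input path {name}")
                if not Path(path).exists():
                    raise PipelineError("validate", f"input file not found: {path}")
        if self.metaprograms and not self.simulate and self.mp_sample_dir is None:
            raise PipelineError("validate", "metaprograms enabled without mp_sample_dir")


def _simulation_inputs(cfg: RunConfig, outdir: Path):
    sim_cfg = simulate.SimulationConfig(
        n_genes=cfg.n_genes,
        noise_sigma=cfg.noise_sigma,
        switch_fraction=cfg.switch_fraction,
        coupling_prob=cfg.coupling_prob,
        seed=cfg.seed,
    )
    ann = simulate.simulate_genome(cfg.n_genes, cfg.seed)
    chip = simulate.simulate_chip(ann, sim_cfg)
    expr_lfc = simulate.simulate_expression(chip.truth, sim_cfg)
    ann.to_tsv(outdir / "annotation.tsv")
    for (label, cond), ps in chip.peak_sets.items():
        io.write_bed(ps, outdir / f"{label}_{cond}.bed")
    for cond, sm in chip.signal.items():
        sm.to_tsv(outdir / f"signal_{cond}.tsv", outdir / f"samples_{cond}.tsv")
    expr_lfc.rename("log2FC").to_csv(outdir / "expression_lfc.tsv", sep="\t")
    chip.truth.table.to_csv(outdir / "planted_truth.tsv", sep="\t")
    return ann, chip.peak_sets, chip.signal, expr_lfc, chip.truth


def _file_inputs(cfg: RunConfig):
    ann = io.read_annotation(cfg.annotation_path)
    peak_sets = {}
    for cond, path in cfg.k4_bed.items():
        peak_sets[("H3K4me3", cond)] = io.read_bed(path, label=f"H3K4me3_{cond}")
    for cond, path in cfg.k27_bed.items():
        peak_sets[("H3K27me3", cond)] = io.read_bed(path, label=f"H3K27me3_{cond}")
    for cond, path in cfg.seq_bed.items():
        peak_sets[("sequential", cond)] = io.read_bed(path, label=f"sequential_{cond}")
    signal = {
        cond: io.SignalMatrix.from_tsv(path) for cond, path in cfg.signal_tsv.items()
    }
    expr_lfc = None
    if cfg.expression_lfc_tsv:
        expr_lfc = pd.read_csv(
            cfg.expression_lfc_tsv, sep="\t", index_col=0
        ).iloc[:, 0]
    return ann, peak_sets, signal, expr_lfc, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns (and writes) the JSON-ready run summary."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": cfg.schema_version, "seed": cfg.seed}

    stage = "inputs"
    try:
        if cfg.simulate:
            ann, peak_sets, signal, expr_lfc, truth = _simulation_inputs(cfg, outdir)
        else:
            ann, peak_sets, signal, expr_lfc, truth = _file_inputs(cfg)
        summary["n_genes"] = len(ann)

        stage = "promoters"
        promoters = io.make_promoters(
            ann, cfg.upstream_bp, cfg.downstream_bp, cfg.biotype_filter
        )
        summary["n_promoters"] = len(promoters)

        stage = "call-bivalent"
        sep = bivalency.call_bivalent_separate(
            peak_sets[("H3K4me3", "A")], peak_sets[("H3K27me3", "A")], promoters
        )
        seq = bivalency.call_bivalent_sequential(
            peak_sets[("sequential", "A")], promoters
        )
        calls, venn = bivalency.bona_fide_bivalent(sep, seq)
        calls.to_csv(outdir / "bivalency_calls.tsv", sep="\t")
        bona_fide = set(calls.index[calls["bona_fide"]])
        summary["venn"] = {
            "n_sequential": venn.n_sequential,
            "n_separate": venn.n_separate,
            "n_overlap": venn.n_overlap,
        }
        summary["n_bona_fide"] = len(bona_fide)

        stage = "diff"
        summary["n_significant"] = {}
        diff_results = {}
        for mark in ("H3K4me3", "H3K27me3"):
            res = differential.call_differential(
                signal["B"].column(mark),
                signal["A"].column(mark),
                genes=bona_fide,
                alpha=cfg.alpha,
                lfc_threshold=cfg.lfc_threshold,
                pseudocount=cfg.diff_pseudocount,
                mark=mark,
            )
            res.to_csv(outdir / f"differential_{mark}.tsv", sep="\t")
            diff_results[mark] = res
            summary["n_significant"][mark] = int(res["significant"].sum())

        stage = "classify"
        assignments = {}
        for cond in ("A", "B"):
            sa = states.assign_states(
                signal[cond].column("H3K4me3"),
                signal[cond].column("H3K27me3"),
                bona_fide,
                condition=cond,
                fc_threshold=cfg.fc_threshold,
                pseudocount=cfg.state_pseudocount,
            )
            assignments[cond] = sa
            sa.labels.rename("cbs").to_csv(outdir / f"cbs_{cond}.tsv", sep="\t")
        summary["cbs_counts"] = {
            cond: {k: int(v) for k, v in assignments[cond].counts().items()}
            for cond in ("A", "B")
        }

        stage = "transitions"
        table = states.transition_table(assignments["A"], assignments["B"])
        table.to_long().to_csv(outdir / "transitions.tsv", sep="\t", index=False)
        summary["transitions"] = {
            f"{a}->{b}": int(table.counts.loc[a, b])
            for a in states.CBS_LABELS
            for b in states.CBS_LABELS
            if table.counts.loc[a, b] > 0
        }
        if expr_lfc is not None:
            frac, n_switch = states.switch_expression_fraction(table, expr_lfc)
            summary["switch_fraction_up"] = round(frac, 10)
            summary["n_switch"] = n_switch
            biv_genes = sorted(bona_fide)
            corr = states.bivalency_expression_correlation(
                diff_results["H3K4me3"]["log2FC"].loc[biv_genes], expr_lfc
            )
            summary["correlation"] = {
                "r": round(corr.r, 10),
                "p_value": float(f"{corr.p_value:.6g}"),
                "n": corr.n,
            }

        if cfg.metaprograms:
            stage = "metaprograms"
            from .metaprograms import MetaProgramNMF

            if cfg.simulate:
                matrices, _, _ = simulate.default_program_simulation(seed=cfg.seed)
            else:
                matrices = {
                    p.stem: pd.read_csv(p, sep="\t", index_col=0)
                    for p in sorted(Path(cfg.mp_sample_dir).glob("*.tsv"))
                }
            finder = MetaProgramNMF(
                ks=tuple(cfg.mp_ks),
                n_top=cfg.mp_n_top,
                j_min=cfg.mp_j_min,
                min_samples=cfg.mp_min_samples,
                random_state=cfg.seed,
            ).fit(matrices)
            finder.instances_frame().to_csv(
                outdir / "program_instances.tsv", sep="\t", index=False
            )
            finder.meta_programs_frame().to_csv(
                outdir / "meta_programs.tsv", sep="\t", index=False
            )
            summary["n_program_instances"] = len(finder.program_instances_)
            summary["n_meta_programs"] = len(finder.meta_programs_)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", outdir / "summary.json")
    return summary
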