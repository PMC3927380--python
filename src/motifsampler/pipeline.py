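"""End-to-end orchestration: read -> sample -> score -> summarize.

``run_pipeline`` runs the whole analysis and writes the full report set:
background composition (with the global score F), site-specific counts,
site-specific frequencies, the PWM, the per-sequence motif/start/PWMS table,
the S1D/S2D scatter table and summary, and a JSON run manifest.
``score_only`` produces the same reports for a fixed alignment without any
sampling, which makes it the deterministic verification path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import MotifSamplerError
from .gibbs import SamplerConfig, SamplerResult, run_sampler
from .io import (
    BackgroundComposition,
    SequenceSet,
    background_composition,
    composition_table,
    read_fasta,
)
from .positional import positional_distances, scatter_table, summary_dict
from .pwm import (
    MotifAlignment,
    alignment_score,
    count_matrix,
    count_table,
    excluded_background,
    frequency_table,
    motif_report,
    pwm_table,
    site_frequencies,
    weight_matrix,
)
from .synthetic import SyntheticSpec, generate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_fasta`` / ``synthetic`` must be set.  Report
    precisions follow the reference tables: 4 decimals for frequencies,
    5 for PWM entries, 4 for PWMS and F.
    """

    input_fasta: str | Path | None = None
    synthetic: SyntheticSpec | None = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    out_dir: str | Path | None = None
    freq_precision: int = 4
    pwm_precision: int = 5
    score_precision: int = 4
    log_base: float = math.e
    exclude_motif_background: bool = True

    def __post_init__(self) -> None:
        if (self.input_fasta is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_fasta / synthetic must be given"
            )
        if min(self.freq_precision, self.pwm_precision, self.score_precision) < 1:
            raise ValueError("report precision must be >= 1")


@dataclass(frozen=True)
class ReportBundle:
    """In-memory report set; ``paths`` filled when written to disk."""

    seqs: SequenceSet
    alignment: MotifAlignment
    background: BackgroundComposition
    frequency: pd.DataFrame
    site_counts: pd.DataFrame
    site_freqs: pd.DataFrame
    pwm: pd.DataFrame
    motifs: pd.DataFrame
    positional: pd.DataFrame
    positional_summary: dict
    F: float
    manifest: dict
    paths: dict = field(default_factory=dict)


def _stage(name: str):
    """Decorator re-raising inner errors with the pipeline stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MotifSamplerError as exc:
                raise MotifSamplerError(f"[{name}] {exc}") from exc

        return inner

    return wrap


def score_only(
    seqs: SequenceSet,
    aln: MotifAlignment,
    *,
    out_dir: str | Path | None = None,
    freq_precision: int = 4,
    pwm_precision: int = 5,
    score_precision: int = 4,
    log_base: float = math.e,
    exclude_motif_background: bool = True,
    extra_manifest: dict | None = None,
) -> ReportBundle:
    """Build every report table for a fixed alignment (no sampling)."""
    aln.validate(seqs)
    bg = background_composition(seqs)
    cm = count_matrix(seqs, aln)
    sf = site_frequencies(cm, bg)
    denom = excluded_background(bg, cm) if exclude_motif_background else bg
    pwm = weight_matrix(sf, denom, log_base=log_base)
    score = alignment_score(pwm, seqs, aln)
    ps = positional_distances(seqs, aln)

    manifest = {
        "motifsampler_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "n_sequences": seqs.n,
        "total_length": seqs.total_length,
        "width": aln.width,
        "log_base": log_base,
        "exclude_motif_background": exclude_motif_background,
        "F": score.F,
    }
    if extra_manifest:
        manifest.update(extra_manifest)

    bundle = ReportBundle(
        seqs=seqs,
        alignment=aln,
        background=bg,
        frequency=composition_table(bg),
        site_counts=count_table(cm),
        site_freqs=frequency_table(sf),
        pwm=pwm_table(pwm),
        motifs=motif_report(seqs, aln, pwm),
        positional=scatter_table(ps),
        positional_summary=summary_dict(ps),
        F=score.F,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_bundle(
            bundle,
            Path(out_dir),
            freq_precision=freq_precision,
            pwm_precision=pwm_precision,
            score_precision=score_precision,
        )
    return bundle


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Load or generate sequences, run the sampler and emit all reports."""
    load = _stage("load")(_load_sequences)
    seqs, truth = load(cfg)
    logger.info("loaded %d sequences, %d nt total", seqs.n, seqs.total_length)

    sample = _stage("sample")(run_sampler)
    result: SamplerResult = sample(seqs, cfg.sampler)
    logger.info(
        "sampler best F = %.4f (chain %d of %d)",
        result.best_F,
        result.chain_id,
        cfg.sampler.restarts,
    )

    extra = {
        "sampler_config": dataclasses.asdict(cfg.sampler),
        "sampler_best_F": result.best_F,
        "sampler_chain_id": result.chain_id,
        "sampler_restart_best": list(result.restart_best),
        "trajectory": list(result.trajectory),
    }
    if truth is not None:
        extra["synthetic_spec"] = dataclasses.asdict(cfg.synthetic)
        extra["ground_truth_starts"] = list(truth.alignment.starts)

    report = _stage("report")(score_only)
    return report(
        seqs,
        result.best_alignment,
        out_dir=cfg.out_dir,
        freq_precision=cfg.freq_precision,
        pwm_precision=cfg.pwm_precision,
        score_precision=cfg.score_precision,
        log_base=cfg.log_base,
        exclude_motif_background=cfg.exclude_motif_background,
        extra_manifest=extra,
    )


def _load_sequences(cfg: PipelineConfig):
    if cfg.input_fasta is not None:
        return read_fasta(cfg.input_fasta), None
    seqs, truth = generate(cfg.synthetic)
    return seqs, truth


def _write_bundle(
    bundle: ReportBundle,
    out_dir: Path,
    *,
    freq_precision: int,
    pwm_precision: int,
    score_precision: int,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str, precision: int | None) -> None:
        path = out_dir / name
        fmt = None if precision is None else f"%.{precision}f"
        df.to_csv(path, sep="\t", index=False, float_format=fmt)
        bundle.paths[name] = path

    motifs = bundle.motifs.copy()
    motifs["PWMS_log"] = motifs["PWMS_log"].round(score_precision)
    motifs["PWMS"] = motifs["PWMS"].round(score_precision)

    tsv(bundle.frequency, "frequency_table.tsv", freq_precision)
    tsv(bundle.site_counts, "site_counts.tsv", None)
    tsv(bundle.site_freqs, "site_frequencies.tsv", freq_precision + 1)
    tsv(bundle.pwm, "pwm.tsv", pwm_precision)
    tsv(motifs, "motifs.tsv", score_precision)
    tsv(bundle.positional, "positional.tsv", None)

    summary = dict(bundle.positional_summary)
    summary["F"] = round(bundle.F, score_precision)
    for name, payload in (
        ("positional_summary.json", summary),
        ("manifest.json", bundle.manifest),
    ):
        path = out_dir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        bundle.paths[name] = path


def score_reference_assignments():
    """Score the bundled reference motif assignments with the bundled PWM.

    Deterministic fixture-mode path: recomputes every published PWMS (odds
    form) and the global score F from the printed weight matrix and motif
    strings alone.  Returns ``(table, F)`` where the table carries recomputed
    ``PWMS_log`` / ``PWMS`` columns next to the published values.
    """
    from .fixtures import assignment_fixture, pwm_fixture
    from .pwm import motif_score

    pwm = pwm_fixture()
    table = assignment_fixture().rename(columns={"PWMS": "PWMS_published"})
    scores = [motif_score(pwm, m) for m in table["Motif"]]
    table["PWMS_log"] = [s.log_pwms for s in scores]
    table["PWMS"] = [s.odds_pwms for s in scores]
    F = float(table["PWMS_log"].sum())
    return table, F
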