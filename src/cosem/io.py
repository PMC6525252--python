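"""Readers/writers, run configuration and the end-to-end pipeline.

Artifacts are deliberately plain text: FASTA for sequences, TSV for tables
and profiles, JSON for models, results and the run manifest — diff-able and
language neutral.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .boosting import fit_expression_model, save_model, load_model
from .features import features_frame
from .optimizer import OptimizerConfig, optimize
from .rate_model import load_rate_table

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_abundance",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs, uppercased, U mapped to T.

    An empty file yields an empty list; a file whose first non-blank line is
    not a header is rejected with the offending line number.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(
                    f"{path.name}: malformed FASTA at line {lineno}: "
                    "expected a '>' header"
                )
            break
    else:
        return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_abundance(path: str | Path) -> dict[str, float]:
    """TSV with columns id / abundance -> mapping."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    cols = list(frame.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: need two columns (id, abundance)")
    return dict(zip(frame[cols[0]].astype(str), frame[cols[1]].astype(float)))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips losslessly via JSON.

    Every stochastic stage carries an explicit seed derived from ``seed``.
    """

    fasta: str
    rates: str
    out_dir: str
    init_rate: float = 0.1
    dropoff_rate: float = 0.0
    footprint: int = 10
    term_rate: float | None = None
    transcript_abundance: str | None = None
    protein_abundance: str | None = None
    model: str | None = None
    optimize_target: str | None = None  # record id to optimize
    objective: str = "maximize"
    freeze: int = 0  # freeze the first N codons
    max_proposals: int = 300
    stop_window: int = 100
    cv_threshold: float = 0.05
    seed: int = 0
    target_completions: int = 200
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """features -> (optional fit) -> (optional optimize), with a manifest.

    Returns the manifest dict; all artifacts land in ``config.out_dir``.
    Stage failures abort with a diagnostic naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("load")
        records = read_fasta(config.fasta)
        table = load_rate_table(config.rates)
        transcript = (
            read_abundance(config.transcript_abundance)
            if config.transcript_abundance
            else None
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    try:
        stage("features")
        feats = features_frame(
            records,
            table,
            init_rate=config.init_rate,
            dropoff_rate=config.dropoff_rate,
            term_rate=config.term_rate,
            footprint=config.footprint,
            transcript_abundances=transcript,
            seed=config.seed,
            simulate_kwargs={"target_completions": config.target_completions},
        )
        feats.to_csv(out / "features.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    model = None
    if config.protein_abundance:
        try:
            stage("fit")
            protein = read_abundance(config.protein_abundance)
            ids = [rid for rid, _ in records if rid in protein]
            import numpy as np

            y = np.log10([protein[r] for r in ids])
            model, r2, _, _ = fit_expression_model(
                feats.loc[ids], y, seed=config.seed
            )
            save_model(model, out / "model.json")
            manifest["test_r2"] = r2
        except Exception as exc:
            raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    elif config.model:
        model = load_model(config.model)

    if config.optimize_target:
        if model is None:
            raise RuntimeError(
                "stage 'optimize' failed: no fitted model available "
                "(provide --model or protein abundances to fit one)"
            )
        try:
            stage("optimize")
            seqs = dict(records)
            wt = seqs[config.optimize_target]
            res = optimize(
                wt,
                table,
                model,
                OptimizerConfig(
                    objective=config.objective,
                    frozen=frozenset(range(config.freeze)),
                    stop_window=config.stop_window,
                    cv_threshold=config.cv_threshold,
                    max_proposals=config.max_proposals,
                    seed=config.seed,
                ),
                init_rate=config.init_rate,
                dropoff_rate=config.dropoff_rate,
                footprint=config.footprint,
                simulate_kwargs={"target_completions": config.target_completions},
            )
            write_fasta(
                [(f"{config.optimize_target}|{config.objective}d", res.best_sequence)],
                out / "optimized.fasta",
            )
            (out / "result.json").write_text(
                json.dumps(
                    {
                        "best_score": res.best_score,
                        "wildtype_score": res.wildtype_score,
                        "relative_score": res.relative_score,
                        "proposals_evaluated": res.proposals_evaluated,
                        "converged": res.converged,
                    },
                    indent=1,
                )
            )
            manifest["relative_score"] = res.relative_score
        except Exception as exc:
            if isinstance(exc, RuntimeError) and "stage" in str(exc):
                raise
            raise RuntimeError(f"stage 'optimize' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
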