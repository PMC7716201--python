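"""End-to-end pipeline orchestration with a run manifest.

A single config (YAML or dict) drives the stages in dependency order:

    ingest/load -> dbs (median-benchmark DBS, HAC calls, group ANOVA)
               -> classify (iterative feature selection, predictions)
               -> permtest -> conserve

Every stage writes plain-text outputs (TSV/JSON) into the run directory and
nothing mutates another stage's files.  The manifest records the config
snapshot, input digests, per-stage outputs, package versions and the seed, so
an identical config on identical inputs reproduces identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classifier import (
    RFConfig,
    heatmap_matrix,
    iterative_feature_selection,
    predict_source,
    predictions_frame,
)
from .conservation import conservation_calls, permanova_by_category
from .dbs import hac_count_anova, hac_counts_per_strain, median_benchmark_dbs
from .errors import ParameterError
from .matrix import (
    ENVIRONMENT,
    GASTROINTESTINAL,
    UNKNOWN,
    BitscoreMatrix,
    read_categories,
    read_labels,
    read_matrix,
    write_matrix,
)
from .permutation import permutation_test
from .synthetic import SyntheticSpec, generate_dataset

log = logging.getLogger("nichesig")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    matrix: str | None = None
    hmmer_dir: str | None = None
    hmmer_dialect: str = "tblout"
    labels: str | None = None
    categories: str | None = None
    simulate: dict | None = None  # SyntheticSpec fields
    stages: list[str] = field(
        default_factory=lambda: ["dbs", "classify", "permtest", "conserve"]
    )
    tail_fraction: float = 0.025
    two_sided_hacs: bool = False
    ntree: int = 10_000
    mtry: str = "n/10"
    vote_threshold: float = 0.5
    max_iterations: int = 20
    importance: str = "permutation"
    prune_rule: str = "le_zero"
    impute: str = "min_minus_sd"
    n_perm: int = 1000
    fdr_q: float = 0.25
    permanova_n_perm: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        """Pre-flight validation; reports every problem at once."""
        problems: list[str] = []
        if not 0.0 < self.tail_fraction < 0.5:
            problems.append(f"tail_fraction {self.tail_fraction} not in (0, 0.5)")
        if self.ntree < 1:
            problems.append("ntree must be >= 1")
        if not 0.0 < self.vote_threshold < 1.0:
            problems.append("vote_threshold must lie in (0, 1)")
        if self.n_perm < 1:
            problems.append("n_perm must be >= 1")
        if not 0.0 < self.fdr_q < 1.0:
            problems.append("fdr_q must lie in (0, 1)")
        sources = [s for s in (self.matrix, self.hmmer_dir) if s] + (
            ["simulate"] if self.simulate is not None else []
        )
        if len(sources) != 1:
            problems.append(
                "exactly one input source required: matrix, hmmer_dir or simulate"
            )
        if self.matrix and not Path(self.matrix).exists():
            problems.append(f"matrix file not found: {self.matrix}")
        if self.hmmer_dir and not Path(self.hmmer_dir).is_dir():
            problems.append(f"hmmer_dir not found: {self.hmmer_dir}")
        if self.labels and not Path(self.labels).exists():
            problems.append(f"labels file not found: {self.labels}")
        if self.categories and not Path(self.categories).exists():
            problems.append(f"categories file not found: {self.categories}")
        needs_labels = {"classify", "permtest", "conserve"} & set(self.stages)
        if needs_labels and not self.labels and self.simulate is None:
            problems.append(f"stages {sorted(needs_labels)} need a labels file")
        if problems:
            raise ParameterError("invalid run config:\n  - " + "\n  - ".join(problems))

    def rf_config(self) -> RFConfig:
        return RFConfig(
            ntree=self.ntree,
            mtry=self.mtry,
            vote_threshold=self.vote_threshold,
            seed=self.seed,
            max_iterations=self.max_iterations,
            importance=self.importance,
            prune_rule=self.prune_rule,
            impute=self.impute,
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest (also written).

    A stage failure stops all downstream stages; the manifest records the
    failing stage and error.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "versions": {"nichesig": __version__},
        "inputs": {},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    log.info(
        "run start: seed=%d tail=%.3f ntree=%d mtry=%s prune=%s impute=%s "
        "two_sided_hacs=%s perm_p=frequency",
        config.seed, config.tail_fraction, config.ntree, config.mtry,
        config.prune_rule, config.impute, config.two_sided_hacs,
    )

    # ---------------------------------------------------------------- input
    labels = None
    if config.simulate is not None:
        spec = SyntheticSpec(**{**config.simulate, "seed": config.seed})
        dataset = generate_dataset(spec)
        paths = dataset.write(out_dir / "input")
        matrix, labels = dataset.matrix, dataset.labels
        manifest["stages"]["simulate"] = {"outputs": [str(p) for p in paths.values()]}
    elif config.hmmer_dir:
        from .hmmer_io import ingest_hmmer_dir

        matrix = ingest_hmmer_dir(config.hmmer_dir, dialect=config.hmmer_dialect)
        mpath = out_dir / "matrix.tsv"
        write_matrix(matrix, mpath)
        manifest["stages"]["ingest"] = {"outputs": [str(mpath)]}
    else:
        matrix = read_matrix(config.matrix)
        manifest["inputs"]["matrix"] = _digest(Path(config.matrix))
    if labels is None and config.labels:
        labels = read_labels(config.labels)
        manifest["inputs"]["labels"] = _digest(Path(config.labels))
    if config.categories:
        manifest["inputs"]["categories"] = _digest(Path(config.categories))

    log.info("matrix: %d genes x %d strains", matrix.n_genes, matrix.n_strains)

    train_labels = None
    if labels is not None:
        known = labels[labels.isin([ENVIRONMENT, GASTROINTESTINAL])]
        train_labels = known[known.index.isin(matrix.strains)]

    trace = None
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            if stage == "dbs":
                outputs = _stage_dbs(config, matrix, train_labels, out_dir)
            elif stage == "classify":
                outputs, trace = _stage_classify(config, matrix, train_labels, labels, out_dir)
            elif stage == "permtest":
                outputs = _stage_permtest(config, matrix, train_labels, out_dir, trace)
            elif stage == "conserve":
                outputs = _stage_conserve(config, matrix, train_labels, out_dir)
            else:
                raise ParameterError(f"unknown stage {stage!r}")
            manifest["stages"][stage] = {
                "outputs": [str(p) for p in outputs],
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out_dir)
        raise

    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))


def _stage_dbs(config, matrix, train_labels, out_dir: Path) -> list[Path]:
    stage_dir = out_dir / "dbs"
    stage_dir.mkdir(exist_ok=True)
    outputs = []
    tables = median_benchmark_dbs(matrix)
    counts, calls = hac_counts_per_strain(
        matrix, tail_fraction=config.tail_fraction, two_sided=config.two_sided_hacs
    )
    for strain, table in tables.items():
        path = stage_dir / f"dbs_median_{strain}.tsv"
        calls[strain].write(table, path)
        outputs.append(path)
    summary = {
        "n_genes_compared": len(next(iter(tables.values()))),
        "hac_counts": counts.to_dict(),
        "cutoffs": {s: calls[s].cutoff for s in calls},
        "tail_fraction": config.tail_fraction,
    }
    if train_labels is not None and train_labels.nunique() == 2:
        groups = {
            lab: counts[train_labels[train_labels == lab].index].tolist()
            for lab in (ENVIRONMENT, GASTROINTESTINAL)
        }
        if all(len(v) >= 2 for v in groups.values()):
            f, p = hac_count_anova(groups)
            summary["hac_anova"] = {"F": f, "p": p}
            log.info("HAC count ANOVA: F=%.3f p=%.4g", f, p)
    spath = stage_dir / "summary.json"
    spath.write_text(json.dumps(summary, indent=1))
    outputs.append(spath)
    return outputs


def _stage_classify(config, matrix, train_labels, labels, out_dir: Path):
    if train_labels is None or train_labels.nunique() < 2:
        raise ParameterError("classify stage needs two-class labels")
    stage_dir = out_dir / "classify"
    stage_dir.mkdir(exist_ok=True)
    train_matrix = matrix.subset_strains(list(train_labels.index))
    trace = iterative_feature_selection(train_matrix, train_labels, config.rf_config())
    outputs = []

    tpath = stage_dir / "selection_trace.json"
    trace.to_json(tpath)
    outputs.append(tpath)

    terminal = trace.terminal
    gpath = stage_dir / "terminal_predictors.tsv"
    terminal.importance.sort_values(ascending=False).rename("vi").to_csv(
        gpath, sep="\t", index_label="gene"
    )
    outputs.append(gpath)

    hpath = stage_dir / "heatmap_matrix.tsv"
    heatmap_matrix(train_matrix, terminal.genes).to_csv(
        hpath, sep="\t", index_label="gene", float_format="%.6g"
    )
    outputs.append(hpath)

    log.info(
        "selection: %s after %d iterations; terminal predictors=%d acc=%.3f",
        trace.status, len(trace.iterations), terminal.n_predictors,
        terminal.oob_accuracy,
    )

    # Predict strains labeled unknown (or unlabeled) on the terminal model.
    unseen = [
        s
        for s in matrix.strains
        if labels is None or labels.get(s, UNKNOWN) == UNKNOWN
    ]
    if unseen and trace.terminal.model is not None:
        preds = predict_source(trace, matrix.subset_strains(unseen))
        ppath = stage_dir / "predictions.tsv"
        predictions_frame(preds).to_csv(ppath, sep="\t", index=False)
        outputs.append(ppath)
    return outputs, trace


def _stage_permtest(config, matrix, train_labels, out_dir: Path, trace) -> list[Path]:
    if train_labels is None or train_labels.nunique() < 2:
        raise ParameterError("permtest stage needs two-class labels")
    stage_dir = out_dir / "permtest"
    stage_dir.mkdir(exist_ok=True)
    train_matrix = matrix.subset_strains(list(train_labels.index))
    result = permutation_test(
        train_matrix,
        train_labels,
        config.rf_config(),
        n_perm=config.n_perm,
        seed=config.seed,
        original_trace=trace,
    )
    spath = stage_dir / "summary.json"
    spath.write_text(json.dumps(result.summary(), indent=1))
    rpath = stage_dir / "permutations.tsv"
    result.records_frame().to_csv(rpath, sep="\t", index=False)
    log.info("permutation test: p=%.4g (%d/%d)", result.p_value,
             result.n_matching, result.n_perm)
    return [spath, rpath]


def _stage_conserve(config, matrix, train_labels, out_dir: Path) -> list[Path]:
    if train_labels is None or train_labels.nunique() < 2:
        raise ParameterError("conserve stage needs two-class labels")
    stage_dir = out_dir / "conserve"
    stage_dir.mkdir(exist_ok=True)
    train_matrix = matrix.subset_strains(list(train_labels.index))
    calls = conservation_calls(train_matrix, train_labels, q=config.fdr_q)
    cpath = stage_dir / "conservation_calls.tsv"
    calls.to_csv(cpath, sep="\t", float_format="%.6g")
    outputs = [cpath]
    if config.categories:
        categories = read_categories(config.categories)
        table = permanova_by_category(
            train_matrix,
            train_labels,
            categories,
            n_perm=config.permanova_n_perm,
            seed=config.seed,
        )
        ppath = stage_dir / "permanova.tsv"
        table.to_csv(ppath, sep="\t", index=False, float_format="%.6g")
        outputs.append(ppath)
    return outputs
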