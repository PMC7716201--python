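"""Random-forest habitat classifier with iterative sparsity pruning.

Strains are classified as gastrointestinal vs. external-environment from
their per-ortholog bitscores.  Training follows the iterative feature
selection recipe used for niche-signature discovery in bacterial
comparative genomics:

1. Fit a forest on all predictors (ntree trees, mtry = n/10 candidate
   features per split) and compute out-of-bag (OOB) permutation variable
   importance (VI).
2. After the first fit, discard predictors with VI <= 0 (genes the forest
   never used or that actively misled OOB prediction).
3. Refit; at each later round keep only the top 50% of predictors by VI
   (ties at the boundary retained).
4. Stop at the first round whose OOB majority votes classify every training
   strain correctly ("perfect OOB accuracy"), or at ``max_iterations``.

The terminal model's full-forest vote proportions classify unseen strains;
a strain is called gastrointestinal when its gut vote share exceeds
``vote_threshold`` (default 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .forest import BaggedTreeEnsemble
from .matrix import ENVIRONMENT, GASTROINTESTINAL, BitscoreMatrix

CLASS_ORDER = (ENVIRONMENT, GASTROINTESTINAL)  # integer codes 0, 1

STATUS_CONVERGED = "converged"
STATUS_MAX_ITERATIONS = "max_iterations"
STATUS_EMPTY = "no_model_converged_empty_predictor_set"
STATUS_STALLED = "no_model_converged_pruning_stalled"


@dataclass(frozen=True)
class RFConfig:
    """Forest and selection-loop settings.

    ``ntree`` defaults to 10,000 (the scale at which OOB error stabilises);
    desk-scale runs typically reduce it to ~1,000.  ``mtry`` is the number
    of candidate predictors per split, given as the rule ``"n/10"`` (of the
    current predictor count, recomputed every iteration, minimum 1), an
    integer, or a callable n -> int.
    """

    ntree: int = 10_000
    mtry: int | str | Callable[[int], int] = "n/10"
    vote_threshold: float = 0.5
    seed: int = 0
    max_iterations: int = 20
    importance: str = "permutation"  # or "impurity"
    prune_rule: str = "le_zero"  # "le_zero" (VI <= 0) or "eq_zero" (VI == 0)
    impute: str = "min_minus_sd"  # or "median"

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ParameterError("ntree must be >= 1")
        if not 0.0 < self.vote_threshold < 1.0:
            raise ParameterError("vote_threshold must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.importance not in ("permutation", "impurity"):
            raise ParameterError("importance must be 'permutation' or 'impurity'")
        if self.prune_rule not in ("le_zero", "eq_zero"):
            raise ParameterError("prune_rule must be 'le_zero' or 'eq_zero'")
        if self.impute not in ("min_minus_sd", "median"):
            raise ParameterError("impute must be 'min_minus_sd' or 'median'")

    def resolve_mtry(self, n_predictors: int) -> int:
        if callable(self.mtry):
            value = int(self.mtry(n_predictors))
        elif isinstance(self.mtry, str):
            rule = self.mtry.replace(" ", "")
            if rule in ("n/10", "n_over_10"):
                value = n_predictors // 10
            elif rule == "sqrt":
                value = int(np.sqrt(n_predictors))
            elif rule == "n":
                value = n_predictors
            elif rule.startswith("n/"):
                value = n_predictors // int(rule[2:])
            else:
                raise ParameterError(f"unrecognised mtry rule {self.mtry!r}")
        else:
            value = int(self.mtry)
        return max(1, min(value, n_predictors))

    def to_dict(self) -> dict:
        d = asdict(self)
        if callable(d["mtry"]):
            d["mtry"] = getattr(self.mtry, "__name__", "callable")
        return d


def _encode_labels(labels: pd.Series, strains: Sequence[str]) -> np.ndarray:
    missing = [s for s in strains if s not in labels.index]
    if missing:
        raise ParameterError(f"strains without labels: {missing[:5]}")
    bad = sorted(set(labels.loc[list(strains)]) - set(CLASS_ORDER))
    if bad:
        raise ParameterError(
            f"training labels must be in {CLASS_ORDER}, found {bad}"
        )
    y = np.array([CLASS_ORDER.index(labels[s]) for s in strains], dtype=np.int64)
    for code, name in enumerate(CLASS_ORDER):
        if (y == code).sum() < 2:
            raise ParameterError(f"class {name!r} has < 2 training strains")
    return y


def imputation_values(matrix: BitscoreMatrix, policy: str) -> pd.Series:
    """Per-gene fill value for absent bitscores.

    ``min_minus_sd`` treats absence as maximal degradation (one SD below the
    lowest observed score of the gene); ``median`` is neutral imputation.
    A gene observed nowhere falls back to 0 bits.
    """
    scores = matrix.scores
    if policy == "min_minus_sd":
        sd = scores.std(axis=1, ddof=1).fillna(0.0)
        fills = scores.min(axis=1) - sd
    elif policy == "median":
        fills = scores.median(axis=1)
    else:
        raise ParameterError(f"unknown imputation policy {policy!r}")
    return fills.fillna(0.0)


def _design_matrix(
    matrix: BitscoreMatrix, genes: Sequence[str], fills: pd.Series
) -> np.ndarray:
    """Strains x genes float design matrix with absences imputed."""
    sub = matrix.scores.loc[list(genes)]
    # transpose so fillna aligns the per-gene fill Series on columns
    return sub.T.fillna(fills).to_numpy().copy()


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to audit and reuse it."""

    ensemble: BaggedTreeEnsemble
    genes: list[str]
    strains: list[str]
    labels: pd.Series
    fill_values: pd.Series  # indexed by gene
    importance: pd.Series  # indexed by gene
    oob_votes: pd.DataFrame  # strains x [environment, gastrointestinal]
    oob_accuracy: float
    config: RFConfig

    def vote_for_true_class(self) -> pd.Series:
        """Each training strain's OOB vote share for its own label."""
        return pd.Series(
            {
                s: self.oob_votes.at[s, self.labels[s]]
                for s in self.strains
            },
            name="vote_true_class",
        )

    def majority_vote_proportions(self) -> pd.Series:
        """Winning-class OOB vote share per training strain."""
        return self.oob_votes.max(axis=1)


def train_rf(
    matrix: BitscoreMatrix,
    labels: pd.Series,
    config: RFConfig | None = None,
    seed: int | None = None,
    genes: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit one forest on (a subset of) the bitscore matrix.

    Absent bitscores are imputed per ``config.impute`` before fitting.
    Returns the fitted model with per-gene variable importance, per-strain
    OOB vote proportions, and the OOB accuracy under majority voting.
    """
    config = config or RFConfig()
    genes = list(genes) if genes is not None else matrix.genes
    if not genes:
        raise ParameterError("empty predictor set")
    strains = matrix.strains
    y = _encode_labels(labels, strains)

    fills = imputation_values(matrix, config.impute)
    X = _design_matrix(matrix, genes, fills)
    mtry = config.resolve_mtry(len(genes))
    ensemble = BaggedTreeEnsemble(
        n_trees=config.ntree,
        mtry=mtry,
        seed=config.seed if seed is None else seed,
    ).fit(X, y)

    if config.importance == "permutation":
        vi = ensemble.permutation_importance()
    else:
        vi = ensemble.impurity_importance()
    votes = ensemble.oob_vote_proportions()
    return TrainedModel(
        ensemble=ensemble,
        genes=genes,
        strains=strains,
        labels=labels.loc[strains],
        fill_values=fills.loc[genes],
        importance=pd.Series(vi, index=genes, name="vi"),
        oob_votes=pd.DataFrame(votes, index=strains, columns=list(CLASS_ORDER)),
        oob_accuracy=ensemble.oob_accuracy(config.vote_threshold),
        config=config,
    )


@dataclass
class IterationRecord:
    index: int  # 1-based
    genes: list[str]
    importance: pd.Series
    oob_votes: pd.DataFrame
    oob_accuracy: float
    mtry: int
    model: TrainedModel | None = field(default=None, repr=False)

    @property
    def n_predictors(self) -> int:
        return len(self.genes)


@dataclass
class SelectionTrace:
    """Full record of the iterative feature-selection loop."""

    iterations: list[IterationRecord]
    terminal_index: int  # 0-based position in `iterations`
    converged: bool
    status: str
    config: RFConfig

    @property
    def terminal(self) -> IterationRecord:
        return self.iterations[self.terminal_index]

    @property
    def terminal_model(self) -> TrainedModel:
        model = self.terminal.model
        if model is None:
            raise ParameterError("terminal model not retained in this trace")
        return model

    def predictor_counts(self) -> list[int]:
        return [it.n_predictors for it in self.iterations]

    def min_majority_vote(self) -> float:
        """Smallest winning-class OOB vote share among training strains, terminal model."""
        return float(self.terminal.oob_votes.max(axis=1).min())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "status": self.status,
            "converged": self.converged,
            "terminal_index": self.terminal_index,
            "config": self.config.to_dict(),
            "iterations": [
                {
                    "index": it.index,
                    "n_predictors": it.n_predictors,
                    "mtry": it.mtry,
                    "oob_accuracy": it.oob_accuracy,
                    "genes": it.genes,
                    "importance": {g: float(v) for g, v in it.importance.items()},
                    "oob_votes": {
                        s: {c: float(it.oob_votes.at[s, c]) for c in it.oob_votes.columns}
                        for s in it.oob_votes.index
                    },
                }
                for it in self.iterations
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _prune_after_first(vi: pd.Series, rule: str) -> list[str]:
    if rule == "eq_zero":
        keep = vi[vi != 0.0]
    else:
        keep = vi[vi > 0.0]
    return list(keep.index)


def _prune_top_half(vi: pd.Series) -> list[str]:
    """Keep the top 50% of predictors by VI; ties at the boundary retained."""
    n = len(vi)
    k = (n + 1) // 2  # ceil(n/2) survivors before tie expansion
    order = vi.sort_values(ascending=False, kind="mergesort")
    boundary = order.iloc[k - 1]
    keep = vi[vi >= boundary]
    return list(keep.index)


def iterative_feature_selection(
    matrix: BitscoreMatrix,
    labels: pd.Series,
    config: RFConfig | None = None,
) -> SelectionTrace:
    """Run the prune-and-retrain loop to a perfect-OOB-accuracy terminal model.

    Iteration 1 uses every gene; after it, predictors with VI <= 0 (or == 0
    under ``prune_rule='eq_zero'``) are dropped; every later iteration keeps
    the top half of predictors by VI.  The loop stops at the first iteration
    whose OOB accuracy is 1.0, when pruning empties or fails to shrink the
    predictor set, or at ``max_iterations``.  If no iteration converges, the
    terminal model is the one with the highest OOB accuracy (latest on ties,
    favouring the sparser model).
    """
    config = config or RFConfig()
    seed_seq = np.random.SeedSequence(config.seed)
    iter_seeds = seed_seq.generate_state(config.max_iterations) % (2**31 - 1)

    genes = matrix.genes
    iterations: list[IterationRecord] = []
    status = STATUS_MAX_ITERATIONS
    converged = False

    for i in range(1, config.max_iterations + 1):
        model = train_rf(
            matrix, labels, config, seed=int(iter_seeds[i - 1]), genes=genes
        )
        iterations.append(
            IterationRecord(
                index=i,
                genes=list(genes),
                importance=model.importance,
                oob_votes=model.oob_votes,
                oob_accuracy=model.oob_accuracy,
                mtry=config.resolve_mtry(len(genes)),
                model=model,
            )
        )
        if model.oob_accuracy == 1.0:
            status, converged = STATUS_CONVERGED, True
            break
        if i == config.max_iterations:
            break

        if i == 1:
            next_genes = _prune_after_first(model.importance, config.prune_rule)
            if len(next_genes) == len(genes):
                # Nothing had VI <= 0; fall through to the halving rule so
                # the predictor set still shrinks.
                next_genes = _prune_top_half(model.importance)
        else:
            next_genes = _prune_top_half(model.importance)

        if not next_genes:
            status = STATUS_EMPTY
            break
        if len(next_genes) >= len(genes):
            status = STATUS_STALLED
            break
        genes = next_genes

    if converged:
        terminal_index = len(iterations) - 1
    else:
        accs = [it.oob_accuracy for it in iterations]
        best = max(accs)
        terminal_index = max(i for i, a in enumerate(accs) if a == best)
    return SelectionTrace(
        iterations=iterations,
        terminal_index=terminal_index,
        converged=converged,
        status=status,
        config=config,
    )


@dataclass
class PredictionResult:
    strain: str
    vote_env: float
    vote_gut: float
    call: str
    n_imputed: int = 0
    fully_missing_genes: list[str] = field(default_factory=list)


def predict_source(
    model_or_trace: TrainedModel | SelectionTrace,
    new_matrix: BitscoreMatrix,
    config: RFConfig | None = None,
) -> list[PredictionResult]:
    """Predict habitat of unseen strains from full-forest vote proportions.

    New strains are scored on the terminal model's predictor genes; absences
    are imputed with the training-time fill values.  A predictor gene absent
    from the new matrix altogether is imputed for every strain and flagged
    on each result rather than treated as fatal.
    """
    if isinstance(model_or_trace, SelectionTrace):
        model = model_or_trace.terminal_model
    else:
        model = model_or_trace
    config = config or model.config

    scores = new_matrix.scores
    fully_missing = [g for g in model.genes if g not in scores.index]
    block = scores.reindex(model.genes)
    X_new = block.T.fillna(model.fill_values).to_numpy().copy()
    votes = model.ensemble.predict_vote_proportions(X_new)

    results = []
    n_absent = block.isna().sum(axis=0)
    for j, strain in enumerate(new_matrix.strains):
        vote_env, vote_gut = float(votes[j, 0]), float(votes[j, 1])
        call = (
            GASTROINTESTINAL if vote_gut > config.vote_threshold else ENVIRONMENT
        )
        results.append(
            PredictionResult(
                strain=strain,
                vote_env=vote_env,
                vote_gut=vote_gut,
                call=call,
                n_imputed=int(n_absent[strain]),
                fully_missing_genes=list(fully_missing),
            )
        )
    return results


def predictions_frame(results: list[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": [r.strain for r in results],
            "vote_env": [r.vote_env for r in results],
            "vote_gut": [r.vote_gut for r in results],
            "call": [r.call for r in results],
            "n_imputed": [r.n_imputed for r in results],
        }
    )


def heatmap_matrix(
    matrix: BitscoreMatrix,
    genes: Sequence[str],
    impute: str = "median",
) -> pd.DataFrame:
    """Row-scaled (centered, unit variance) bitscore block for heatmap export.

    Rows are genes; values are imputed first, then each row is centered and
    divided by its standard deviation (sample SD, ddof=1).  Constant rows
    scale to all-zero.
    """
    fills = imputation_values(matrix, impute)
    sub = matrix.scores.loc[list(genes)]
    filled = sub.T.fillna(fills).T
    centered = filled.sub(filled.mean(axis=1), axis=0)
    sd = filled.std(axis=1, ddof=1).replace(0.0, np.nan)
    scaled = centered.div(sd, axis=0).fillna(0.0)
    return scaled
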