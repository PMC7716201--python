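"""Label-permutation significance for the habitat classifier.

The null hypothesis is that predictor genes and habitat labels are randomly
associated.  The entire model-building pipeline (iterative feature selection
included) is rerun on datasets whose habitat labels have been shuffled across
strains — preserving the group sizes — and the p-value is the frequency of
permuted pipelines whose terminal OOB accuracy reaches the original's.

Even permuted pipelines can stumble into perfect OOB accuracy on a handful of
strains; what separates them from a real signal is the *confidence* of the
votes, so the winning-class vote proportions of accuracy-matching permuted
models are summarised alongside the p-value for comparison with the original
model's margins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import RFConfig, SelectionTrace, iterative_feature_selection
from .errors import ParameterError
from .matrix import BitscoreMatrix

_MAX_SEED = 2**31 - 1


@dataclass
class PermutationRecord:
    index: int
    terminal_accuracy: float
    min_majority_vote: float
    converged: bool
    n_terminal_predictors: int


@dataclass
class PermutationResult:
    n_perm: int
    n_matching: int
    p_value: float
    original_accuracy: float
    original_converged: bool
    original_margins: pd.Series  # per-strain winning-class OOB vote share
    permuted_margin_summary: dict
    records: list[PermutationRecord]
    seed: int
    conservative_p: float = float("nan")
    original_trace: SelectionTrace | None = field(default=None, repr=False)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self.records],
                "terminal_accuracy": [r.terminal_accuracy for r in self.records],
                "min_majority_vote": [r.min_majority_vote for r in self.records],
                "converged": [r.converged for r in self.records],
                "n_terminal_predictors": [
                    r.n_terminal_predictors for r in self.records
                ],
            }
        )

    def summary(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "n_matching": self.n_matching,
            "p_value": self.p_value,
            "conservative_p": self.conservative_p,
            "original_accuracy": self.original_accuracy,
            "original_converged": self.original_converged,
            "original_min_majority_vote": float(self.original_margins.min()),
            "permuted_margin_summary": self.permuted_margin_summary,
            "seed": self.seed,
        }


def permutation_test(
    matrix: BitscoreMatrix,
    labels: pd.Series,
    config: RFConfig | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    original_trace: SelectionTrace | None = None,
) -> PermutationResult:
    """Rebuild the selection pipeline on ``n_perm`` label shuffles.

    ``p_value = n_matching / n_perm`` where a permutation *matches* when its
    terminal OOB accuracy is >= the original terminal accuracy (equality when
    the original is perfect).  The ``(count+1)/(n_perm+1)`` estimator is also
    reported as ``conservative_p``.  Each permutation draws its RNG stream
    from ``(seed, index)``, so results do not depend on execution order.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    config = config or RFConfig()
    seed = config.seed if seed is None else seed

    if original_trace is None:
        original_trace = iterative_feature_selection(matrix, labels, config)
    original_acc = original_trace.terminal.oob_accuracy
    original_margins = original_trace.terminal.oob_votes.max(axis=1)

    strains = matrix.strains
    label_values = labels.loc[strains].to_numpy()

    records: list[PermutationRecord] = []
    matching_margins: list[float] = []
    n_matching = 0
    for i in range(n_perm):
        stream = np.random.SeedSequence([seed, i])
        rng = np.random.default_rng(stream)
        shuffled = pd.Series(
            rng.permutation(label_values), index=strains, name="habitat"
        )
        perm_seed = int(stream.generate_state(1)[0] % _MAX_SEED)
        perm_config = dataclasses.replace(config, seed=perm_seed)
        trace = iterative_feature_selection(matrix, shuffled, perm_config)
        acc = trace.terminal.oob_accuracy
        min_margin = trace.min_majority_vote()
        records.append(
            PermutationRecord(
                index=i,
                terminal_accuracy=acc,
                min_majority_vote=min_margin,
                converged=trace.converged,
                n_terminal_predictors=trace.terminal.n_predictors,
            )
        )
        if acc >= original_acc:
            n_matching += 1
            matching_margins.append(min_margin)

    if matching_margins:
        arr = np.asarray(matching_margins)
        margin_summary = {
            "n_models": len(arr),
            "mean_min_majority_vote": float(arr.mean()),
            "median_min_majority_vote": float(np.median(arr)),
            "min_min_majority_vote": float(arr.min()),
            "max_min_majority_vote": float(arr.max()),
        }
    else:
        margin_summary = {"n_models": 0}

    return PermutationResult(
        n_perm=n_perm,
        n_matching=n_matching,
        p_value=n_matching / n_perm,
        original_accuracy=original_acc,
        original_converged=original_trace.converged,
        original_margins=original_margins,
        permuted_margin_summary=margin_summary,
        records=records,
        seed=seed,
        conservative_p=(n_matching + 1) / (n_perm + 1),
        original_trace=original_trace,
    )
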