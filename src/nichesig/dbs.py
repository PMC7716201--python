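"""Delta-bitscore computation, HAC calling, and group-degradation tests.

Delta-bitscore (DBS) quantifies functional divergence of two orthologous
proteins scored against the same profile HMM::

    DBS = X_ref - X_var        (bits)

Positive DBS means the variant conforms less well to the family model than
the reference, i.e. the variant is putatively degraded.  For a cohort of
proteomes compared at once, each strain is instead compared against the
per-gene median across strains (positive DBS = strain degraded relative to
the cohort).

HACs (hypothetically attenuated coding sequences) are called from the
empirical DBS distribution of a comparison: the tail whose extreme quantile
lies closer to zero (the *least dispersed* tail) calibrates technical noise,
and its quantile magnitude becomes the cutoff applied to the opposite,
signal-carrying side.  By default genes are flagged one-sided on the
more-dispersed side; two-sided calling is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    EmptyComparisonError,
    InsufficientDataError,
    ParameterError,
)
from .matrix import BitscoreMatrix


class DBSRecord(NamedTuple):
    gene: str
    x_ref: float
    x_var: float
    dbs: float


@dataclass
class DBSTable:
    """Per-gene delta-bitscore records for one comparison."""

    comparison: str
    data: pd.DataFrame  # index gene, columns x_ref, x_var, dbs

    @property
    def dbs(self) -> pd.Series:
        return self.data["dbs"]

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def records(self) -> list[DBSRecord]:
        return [
            DBSRecord(g, row.x_ref, row.x_var, row.dbs)
            for g, row in self.data.iterrows()
        ]

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class HACCallSet:
    """Empirical cutoff and the genes called hypothetically attenuated."""

    tail_fraction: float
    cutoff: float
    least_dispersed_tail: str  # "negative" | "positive"
    hacs: set[str]
    n_total: int
    comparison: str = ""

    @property
    def fraction(self) -> float:
        return len(self.hacs) / self.n_total if self.n_total else 0.0

    def write(self, table: DBSTable, path: str | Path) -> None:
        out = table.data.copy()
        out["cutoff"] = self.cutoff
        out["hac"] = [g in self.hacs for g in out.index]
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g")


def pairwise_dbs(
    ref: pd.Series,
    var: pd.Series,
    comparison: str | None = None,
    absent_as_zero: bool = False,
) -> DBSTable:
    """DBS = ref - var per gene shared between two score vectors.

    Genes absent (NaN) in either vector are excluded by default; with
    ``absent_as_zero`` an absent score is treated as 0 bits (deletion read as
    total loss of conformance).
    """
    ref = ref.astype(float)
    var = var.astype(float)
    shared = ref.index.intersection(var.index)
    x_ref = ref.loc[shared]
    x_var = var.loc[shared]
    if absent_as_zero:
        x_ref = x_ref.fillna(0.0)
        x_var = x_var.fillna(0.0)
    keep = x_ref.notna() & x_var.notna()
    x_ref, x_var = x_ref[keep], x_var[keep]
    if len(x_ref) == 0:
        raise EmptyComparisonError(
            "no genes scored in both members of the comparison"
        )
    data = pd.DataFrame(
        {"x_ref": x_ref, "x_var": x_var, "dbs": x_ref - x_var}
    )
    name = comparison or f"{ref.name or 'ref'} vs {var.name or 'var'}"
    return DBSTable(comparison=name, data=data)


def median_benchmark_dbs(matrix: BitscoreMatrix) -> dict[str, DBSTable]:
    """Per-strain DBS against the per-gene median across all strains.

    Restricted to genes present in every strain.  For each gene,
    ``dbs = median(scores across strains) - strain score``; positive values
    mean the strain is degraded relative to the cohort.
    """
    if matrix.n_strains < 3:
        raise ParameterError(
            f"median benchmark needs >= 3 strains, got {matrix.n_strains}"
        )
    complete = matrix.complete_genes()
    if not complete:
        raise EmptyComparisonError("no genes present in all strains")
    sub = matrix.scores.loc[complete]
    medians = sub.median(axis=1)
    tables = {}
    for strain in matrix.strains:
        data = pd.DataFrame(
            {
                "x_ref": medians,
                "x_var": sub[strain],
                "dbs": medians - sub[strain],
            }
        )
        tables[strain] = DBSTable(comparison=f"median vs {strain}", data=data)
    return tables


def _as_dbs_series(table) -> pd.Series:
    if isinstance(table, DBSTable):
        return table.dbs
    if isinstance(table, pd.Series):
        return table.astype(float)
    values = np.asarray(table, dtype=float)
    return pd.Series(values, index=[f"g{i}" for i in range(len(values))])


def call_hacs(
    table: DBSTable | pd.Series | np.ndarray,
    tail_fraction: float = 0.025,
    two_sided: bool = False,
) -> HACCallSet:
    """Call HACs from the empirical DBS distribution of one comparison.

    The ``tail_fraction`` quantile is taken on both sides; the side whose
    quantile has the smaller magnitude is the least dispersed (noise-
    calibrating) tail, and its magnitude is the cutoff.  Genes whose DBS lies
    strictly beyond the cutoff on the opposite side are flagged (both sides
    with ``two_sided``).  An exact tie in tail magnitudes treats the negative
    side as least dispersed.
    """
    if not 0.0 < tail_fraction < 0.5:
        raise ParameterError("tail_fraction must lie in (0, 0.5)")
    dbs = _as_dbs_series(table).dropna()
    n = len(dbs)
    if n * tail_fraction < 1.0:
        raise InsufficientDataError(
            f"{n} DBS records cannot support a {tail_fraction:.3%} tail quantile"
        )
    values = dbs.to_numpy()
    q_lo = float(np.quantile(values, tail_fraction))
    q_hi = float(np.quantile(values, 1.0 - tail_fraction))
    if abs(q_lo) <= abs(q_hi):
        least, cutoff = "negative", abs(q_lo)
        signal = values > cutoff
    else:
        least, cutoff = "positive", abs(q_hi)
        signal = values < -cutoff
    if two_sided:
        signal = np.abs(values) > cutoff
    hacs = set(dbs.index[signal])
    return HACCallSet(
        tail_fraction=tail_fraction,
        cutoff=cutoff,
        least_dispersed_tail=least,
        hacs=hacs,
        n_total=n,
        comparison=getattr(table, "comparison", ""),
    )


def wilcoxon_skewness_test(table: DBSTable | pd.Series | np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank test of DBS symmetry about zero.

    Tests whether one proteome of the pair is degraded relative to the other
    (an asymmetric DBS distribution).  Zeros are discarded (Wilcoxon zero
    handling); the exact null distribution is used when the non-zero count is
    <= 25 and tie-free, otherwise the normal approximation with continuity
    correction.
    """
    dbs = _as_dbs_series(table).dropna().to_numpy()
    nonzero = dbs[dbs != 0.0]
    if len(nonzero) == 0:
        raise DegenerateDataError("all DBS values are zero; test undefined")
    if len(nonzero) < 6:
        raise InsufficientDataError(
            f"need >= 6 non-zero DBS values, got {len(nonzero)}"
        )
    ranks_tied = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(
        nonzero,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return float(res.pvalue)


def hac_count_anova(
    counts_by_group: Mapping[str, Iterable[float]],
) -> tuple[float, float]:
    """One-way ANOVA on per-strain HAC counts between two habitat groups.

    With exactly two groups the F statistic equals the squared equal-variance
    t statistic.  Returns ``(F, p)``.
    """
    groups = {k: np.asarray(list(v), dtype=float) for k, v in counts_by_group.items()}
    if len(groups) != 2:
        raise ParameterError(f"expected exactly two groups, got {len(groups)}")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ParameterError(f"group {name!r} has < 2 strains")
    a, b = groups.values()
    if np.var(a, ddof=0) == 0 and np.var(b, ddof=0) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)


def hac_counts_per_strain(
    matrix: BitscoreMatrix, tail_fraction: float = 0.025, two_sided: bool = False
) -> tuple[pd.Series, dict[str, HACCallSet]]:
    """Median-benchmark HAC counts per strain (the multi-proteome workflow)."""
    tables = median_benchmark_dbs(matrix)
    calls = {
        s: call_hacs(t, tail_fraction=tail_fraction, two_sided=two_sided)
        for s, t in tables.items()
    }
    counts = pd.Series({s: len(c.hacs) for s, c in calls.items()}, name="n_hacs")
    return counts, calls


def save_hac_boxplot(
    counts_by_group: Mapping[str, Iterable[float]], path: str | Path
) -> None:
    """Plain boxplot of per-strain HAC counts by habitat group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = {k: list(v) for k, v in counts_by_group.items()}
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()))
    ax.set_ylabel("HACs per strain")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
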