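"""Conservation direction of predictor genes and category-level separation.

Two questions about the genes a habitat classifier singles out:

* **Per gene** — in which habitat group is the gene more conserved (higher
  bitscores)?  Mood's median test on the two groups' bitscores with
  Benjamini–Hochberg control of the false discovery rate across genes.
* **Per functional category** — do the two groups separate when strains are
  viewed through all the genes of a category at once?  PERMANOVA on the
  strain-by-strain distance matrix of the category's bitscore profiles,
  with significance from label permutation (exhaustive over all distinct
  label arrangements whenever that is feasible).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InsufficientDataError, ParameterError
from .matrix import ENVIRONMENT, GASTROINTESTINAL, BitscoreMatrix

DIRECTION_ENV = ENVIRONMENT
DIRECTION_GUT = GASTROINTESTINAL
DIRECTION_NONE = "none"


def moods_median_test(
    env_values: Iterable[float],
    gut_values: Iterable[float],
    correction: bool = True,
    strict_above: bool = True,
) -> tuple[float, float]:
    """Mood's median test between two groups of bitscores.

    Counts per group above vs. not-above the pooled grand median form a 2x2
    table tested by chi-squared with 1 df (Yates continuity correction by
    default, appropriate at the small strain counts typical here).  Returns
    ``(chi2, p)``.
    """
    env = np.asarray(list(env_values), dtype=float)
    gut = np.asarray(list(gut_values), dtype=float)
    env = env[~np.isnan(env)]
    gut = gut[~np.isnan(gut)]
    if len(env) == 0 or len(gut) == 0:
        raise ParameterError("both groups must be non-empty")
    if len(env) + len(gut) < 4:
        raise InsufficientDataError("need >= 4 values in total")
    pooled = np.concatenate([env, gut])
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all values identical; median test undefined")
    grand = np.median(pooled)
    if strict_above:
        a, c = int((env > grand).sum()), int((gut > grand).sum())
    else:
        a, c = int((env >= grand).sum()), int((gut >= grand).sum())
    table = np.array([[a, len(env) - a], [c, len(gut) - c]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # One margin empty (heavy ties at the median): no association testable.
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def bh_fdr(p_values: Sequence[float], q: float = 0.25) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ParameterError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class ConservationCall:
    gene: str
    median_env: float
    median_gut: float
    chi2: float
    p: float
    bh_significant: bool
    direction: str


def conservation_calls(
    matrix: BitscoreMatrix,
    labels: pd.Series,
    genes: Sequence[str] | None = None,
    q: float = 0.25,
    correction: bool = True,
) -> pd.DataFrame:
    """Per-gene conservation direction between habitat groups.

    For each gene, Mood's median test compares the two groups' bitscores;
    BH flags are computed across all testable genes at FDR ``q``.  The
    direction is the group with the higher median (more conserved); equal
    medians give direction ``none``.  Genes that are untestable (too few
    observed values, or all values identical) are reported with NaN p and
    excluded from the FDR correction.
    """
    genes = list(genes) if genes is not None else matrix.genes
    env_strains = [s for s in matrix.strains if labels.get(s) == ENVIRONMENT]
    gut_strains = [s for s in matrix.strains if labels.get(s) == GASTROINTESTINAL]
    if not env_strains or not gut_strains:
        raise ParameterError("need strains from both habitat groups")

    rows = []
    for gene in genes:
        env = matrix.scores.loc[gene, env_strains].dropna()
        gut = matrix.scores.loc[gene, gut_strains].dropna()
        med_env = float(env.median()) if len(env) else np.nan
        med_gut = float(gut.median()) if len(gut) else np.nan
        try:
            chi2, p = moods_median_test(env, gut, correction=correction)
        except (InsufficientDataError, DegenerateDataError, ParameterError):
            chi2, p = np.nan, np.nan
        if np.isnan(med_env) or np.isnan(med_gut) or med_env == med_gut:
            direction = DIRECTION_NONE
        elif med_env > med_gut:
            direction = DIRECTION_ENV
        else:
            direction = DIRECTION_GUT
        rows.append((gene, med_env, med_gut, chi2, p, direction))

    out = pd.DataFrame(
        rows, columns=["gene", "median_env", "median_gut", "chi2", "p", "direction"]
    ).set_index("gene")
    out["bh_significant"] = False
    testable = out["p"].notna()
    if testable.any():
        out.loc[testable, "bh_significant"] = bh_fdr(out.loc[testable, "p"], q=q)
    return out


@dataclass
class PermanovaResult:
    category: str
    n_genes: int
    df_between: int
    df_residual: int
    ss_between: float
    ss_residual: float
    r2: float
    f: float
    p: float
    n_perm: int
    exhaustive: bool
    distance: str

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_residual


def _group_ss(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in group_indices:
        if len(idx) > 1:
            block = d2[np.ix_(idx, idx)]
            ss += block[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss


def _pseudo_f(d2: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(ss_between, ss_within, F) for a two-group labeling ``y`` (0/1)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    groups = [np.flatnonzero(y == 0), np.flatnonzero(y == 1)]
    ss_within = _group_ss(d2, groups)
    ss_between = ss_total - ss_within
    df_b, df_w = 1, n - 2
    if ss_within <= 0:
        return ss_between, ss_within, np.inf
    return ss_between, ss_within, (ss_between / df_b) / (ss_within / df_w)


def permanova(
    category_matrix: pd.DataFrame | BitscoreMatrix,
    labels: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    category: str = "",
    distance: str = "euclidean",
) -> PermanovaResult:
    """PERMANOVA of habitat groups on a category's gene x strain bitscores.

    Strain-by-strain distances (Euclidean by default, ``"correlation"``
    optional) are computed on complete-case genes.  The pseudo-F partitions
    the squared-distance sum into between- and within-group components.  The
    p-value enumerates every distinct label arrangement when their number is
    <= ``n_perm`` (p = fraction with F >= observed, identity included);
    otherwise it samples ``n_perm`` shuffles and reports
    ``(count + 1) / (n_perm + 1)``.
    """
    if isinstance(category_matrix, BitscoreMatrix):
        frame = category_matrix.scores
    else:
        frame = category_matrix.astype(float)
    if distance not in ("euclidean", "correlation"):
        raise ParameterError("distance must be 'euclidean' or 'correlation'")
    frame = frame.dropna(axis=0)
    if frame.shape[0] < 1:
        raise InsufficientDataError("no complete-case genes in category")

    strains = list(frame.columns)
    y = np.array(
        [0 if labels[s] == ENVIRONMENT else 1 for s in strains], dtype=np.int64
    )
    bad = [s for s in strains if labels.get(s) not in (ENVIRONMENT, GASTROINTESTINAL)]
    if bad:
        raise ParameterError(f"strains without two-group labels: {bad[:5]}")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ParameterError("each group needs >= 2 strains")

    X = frame.to_numpy().T  # strains x genes
    d = pdist(X, metric=distance)
    if np.allclose(d, 0.0):
        raise DegenerateDataError("all strains identical; pseudo-F undefined")
    d2 = squareform(d**2)

    ss_b, ss_w, f_obs = _pseudo_f(d2, y)
    n = len(strains)

    from math import comb

    n_arrangements = comb(n, n0)
    if n_arrangements <= n_perm:
        count = 0
        for combo in combinations(range(n), n0):
            y_perm = np.ones(n, dtype=np.int64)
            y_perm[list(combo)] = 0
            _, _, f_perm = _pseudo_f(d2, y_perm)
            if f_perm >= f_obs - 1e-12:
                count += 1
        p = count / n_arrangements
        used, exhaustive = n_arrangements, True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            y_perm = rng.permutation(y)
            _, _, f_perm = _pseudo_f(d2, y_perm)
            if f_perm >= f_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        used, exhaustive = n_perm, False

    ss_total = ss_b + ss_w
    return PermanovaResult(
        category=category,
        n_genes=frame.shape[0],
        df_between=1,
        df_residual=n - 2,
        ss_between=float(ss_b),
        ss_residual=float(ss_w),
        r2=float(ss_b / ss_total) if ss_total > 0 else np.nan,
        f=float(f_obs),
        p=float(p),
        n_perm=used,
        exhaustive=exhaustive,
        distance=distance,
    )


def permanova_by_category(
    matrix: BitscoreMatrix,
    labels: pd.Series,
    categories: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    distance: str = "euclidean",
) -> pd.DataFrame:
    """Run PERMANOVA per functional category; returns a Table-3-style frame."""
    rows = []
    for cat, sub in categories.groupby("category", sort=True):
        genes = [g for g in sub["gene"].unique() if g in matrix.scores.index]
        if not genes:
            continue
        try:
            res = permanova(
                matrix.scores.loc[genes],
                labels,
                n_perm=n_perm,
                seed=seed,
                category=cat,
                distance=distance,
            )
        except (InsufficientDataError, DegenerateDataError):
            continue
        rows.append(
            {
                "category": cat,
                "n_genes": res.n_genes,
                "df": res.df_between,
                "ss_between": res.ss_between,
                "ss_residual": res.ss_residual,
                "r2": res.r2,
                "f": res.f,
                "p": res.p,
                "n_perm": res.n_perm,
                "exhaustive": res.exhaustive,
            }
        )
    return pd.DataFrame(rows)
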