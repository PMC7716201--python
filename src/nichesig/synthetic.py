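"""Synthetic bitscore datasets with planted habitat signal.

The generator emulates the statistical structure the downstream analysis
assumes: each ortholog group has a gene-specific baseline bitscore (drawn once
per gene), strains scatter around that baseline with Gaussian noise, and a
chosen subset of *informative* genes is degraded (shifted down) in one habitat
group.  *Confounder* genes shift along a random strain bipartition drawn once
per dataset — a stand-in for phylogenetic signal that tracks lineage rather
than habitat.  Genes can be absent at random, and absence is recorded as an
explicit marker (NaN in the matrix), never as a low score.

Only bitscore *differences* matter to the delta-bitscore method, so the noise
model is deliberately simple: Gaussian per gene, common within-gene standard
deviation.  Effect sizes are expressed in units of that standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matrix import (
    ENVIRONMENT,
    GASTROINTESTINAL,
    BitscoreMatrix,
    write_labels,
    write_matrix,
    write_truth,
)

ROLE_INFORMATIVE = "informative"
ROLE_CONFOUNDER = "confounder"
ROLE_NOISE = "noise"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic labeled bitscore dataset.

    Defaults describe the benchmark condition used throughout the package's
    own evaluation: 4 environment vs 5 gastrointestinal strains scored on
    6709 ortholog groups, 200 of them habitat-informative at an effect of
    3 within-gene standard deviations, with gastrointestinal strains the
    degraded group (host-restricted lineages accumulate loss-of-function
    variation).

    Attributes
    ----------
    n_env, n_gut :
        Strain counts per habitat group.
    n_genes :
        Number of ortholog groups.
    n_informative :
        Genes degraded in the ``degrade_direction`` group.
    effect_size :
        Mean bitscore drop for informative genes, in units of
        ``baseline_sd``.
    n_confounder :
        Genes whose shift follows a random strain bipartition (lineage,
        not habitat).
    baseline_mean_range :
        Interval (bits) from which each gene's baseline mean is drawn
        uniformly; typical full-sequence bitscores of bacterial proteins
        against family HMMs span tens to hundreds of bits.
    baseline_sd :
        Within-gene bitscore standard deviation (bits).
    missing_rate :
        Per-cell probability that a gene is absent from a strain.
    degrade_direction :
        Which habitat group receives lower scores on informative genes.
    seed :
        RNG seed; identical (spec, seed) reproduces a bit-identical dataset.
    """

    n_env: int = 4
    n_gut: int = 5
    n_genes: int = 6709
    n_informative: int = 200
    effect_size: float = 3.0
    n_confounder: int = 0
    baseline_mean_range: tuple[float, float] = (50.0, 500.0)
    baseline_sd: float = 5.0
    missing_rate: float = 0.02
    degrade_direction: str = GASTROINTESTINAL
    seed: int = 0

    def validate(self) -> None:
        if self.n_env < 1 or self.n_gut < 1:
            raise ParameterError("need at least one strain per group")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        if self.n_informative < 0 or self.n_confounder < 0:
            raise ParameterError("gene role counts must be non-negative")
        if self.n_informative + self.n_confounder > self.n_genes:
            raise ParameterError(
                "n_informative + n_confounder exceeds n_genes "
                f"({self.n_informative} + {self.n_confounder} > {self.n_genes})"
            )
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ParameterError("missing_rate must lie in [0, 1]")
        lo, hi = self.baseline_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ParameterError("baseline_mean_range must be a finite interval")
        if self.baseline_sd <= 0:
            raise ParameterError("baseline_sd must be positive")
        if self.degrade_direction not in (ENVIRONMENT, GASTROINTESTINAL):
            raise ParameterError(
                f"degrade_direction must be {ENVIRONMENT!r} or {GASTROINTESTINAL!r}"
            )


@dataclass
class LabeledDataset:
    """A synthetic matrix plus habitat labels and per-gene ground truth."""

    matrix: BitscoreMatrix
    labels: pd.Series  # strain -> habitat
    truth: pd.Series  # gene -> role (informative | confounder | noise)
    spec: SyntheticSpec | None = None

    def informative_genes(self) -> list[str]:
        return list(self.truth.index[self.truth == ROLE_INFORMATIVE])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write matrix/labels/truth TSVs; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": outdir / "matrix.tsv",
            "labels": outdir / "labels.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_matrix(self.matrix, paths["matrix"])
        write_labels(self.labels, paths["labels"])
        write_truth(self.truth, paths["truth"])
        return paths


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled synthetic bitscore dataset from ``spec``.

    Informative genes have an expected group-mean difference of
    ``effect_size * baseline_sd`` bits (degraded group lower); noise genes
    have no group effect; confounder genes shift along a random bipartition
    of strains drawn once.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    strains = [f"ENV{i + 1:02d}" for i in range(spec.n_env)] + [
        f"GUT{i + 1:02d}" for i in range(spec.n_gut)
    ]
    labels = pd.Series(
        [ENVIRONMENT] * spec.n_env + [GASTROINTESTINAL] * spec.n_gut,
        index=strains,
        name="habitat",
    )
    n_strains = len(strains)

    width = max(4, len(str(spec.n_genes)))
    genes = [f"OG{i + 1:0{width}d}" for i in range(spec.n_genes)]

    # Role assignment: random gene subset for informative, disjoint subset
    # for confounders, rest noise.
    perm = rng.permutation(spec.n_genes)
    informative_idx = perm[: spec.n_informative]
    confounder_idx = perm[spec.n_informative : spec.n_informative + spec.n_confounder]
    roles = np.full(spec.n_genes, ROLE_NOISE, dtype=object)
    roles[informative_idx] = ROLE_INFORMATIVE
    roles[confounder_idx] = ROLE_CONFOUNDER
    truth = pd.Series(roles, index=genes, name="role")

    lo, hi = spec.baseline_mean_range
    gene_means = rng.uniform(lo, hi, size=spec.n_genes)
    scores = rng.normal(
        loc=gene_means[:, None], scale=spec.baseline_sd, size=(spec.n_genes, n_strains)
    )

    shift = spec.effect_size * spec.baseline_sd
    degraded_mask = (labels == spec.degrade_direction).to_numpy()
    scores[np.ix_(informative_idx, np.flatnonzero(degraded_mask))] -= shift

    # Confounder bipartition: drawn once per dataset, independent of habitat.
    if spec.n_confounder > 0 and n_strains >= 2:
        side_size = int(rng.integers(1, n_strains))
        side = rng.choice(n_strains, size=side_size, replace=False)
        scores[np.ix_(confounder_idx, side)] -= shift

    if spec.missing_rate > 0:
        absent = rng.random((spec.n_genes, n_strains)) < spec.missing_rate
        scores[absent] = np.nan

    frame = pd.DataFrame(scores, index=pd.Index(genes, name="gene"), columns=strains)
    matrix = BitscoreMatrix(frame, provenance=f"synthetic(seed={spec.seed})")
    return LabeledDataset(matrix=matrix, labels=labels, truth=truth, spec=spec)


def generate_proteome_pair(
    n_genes: int,
    n_degraded: int,
    shift: float,
    seed: int = 0,
    baseline_mean_range: tuple[float, float] = (50.0, 500.0),
    baseline_sd: float = 5.0,
) -> tuple[pd.Series, pd.Series, set[str]]:
    """Two aligned per-gene bitscore vectors with a planted degraded subset.

    Returns ``(ref, var, degraded_genes)``: both vectors share gene-specific
    baselines; the ``n_degraded`` randomly chosen genes are lower by ``shift``
    bits in expectation in the variant vector, all other genes are identically
    distributed in both.  Used as the fixture for pairwise delta-bitscore
    evaluation.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be positive")
    if not 0 <= n_degraded <= n_genes:
        raise ParameterError(
            f"n_degraded must be in [0, n_genes]; got {n_degraded} > {n_genes}"
        )
    if shift < 0:
        raise ParameterError("shift must be >= 0 bits")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"OG{i + 1:0{width}d}" for i in range(n_genes)]
    lo, hi = baseline_mean_range
    means = rng.uniform(lo, hi, size=n_genes)
    ref = means + rng.normal(0.0, baseline_sd, size=n_genes)
    var = means + rng.normal(0.0, baseline_sd, size=n_genes)
    degraded_idx = rng.choice(n_genes, size=n_degraded, replace=False)
    var[degraded_idx] -= shift
    degraded = {genes[i] for i in degraded_idx}
    return (
        pd.Series(ref, index=genes, name="ref"),
        pd.Series(var, index=genes, name="var"),
        degraded,
    )
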