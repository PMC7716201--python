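"""The strain x ortholog bitscore matrix and the pipeline's plain-text table formats.

The central in-memory container is :class:`BitscoreMatrix`, a thin wrapper
around a pandas DataFrame with ortholog groups (profile-HMM accessions) as
rows and strains as columns.  A cell holds the best full-sequence bitscore of
that strain's proteins against that profile; ``NaN`` marks a gene that is
absent from a strain.  Absence is deliberately kept distinct from any numeric
sentinel so that downstream policy (exclude vs. impute-as-degraded) remains an
explicit, auditable decision.

On disk every table is a TSV with a header row; absent cells are written as
``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError

# Canonical habitat labels.
ENVIRONMENT = "environment"
GASTROINTESTINAL = "gastrointestinal"
UNKNOWN = "unknown"

_HABITAT_ALIASES = {
    "environment": ENVIRONMENT,
    "environmental": ENVIRONMENT,
    "external": ENVIRONMENT,
    "external environment": ENVIRONMENT,
    "env": ENVIRONMENT,
    "e": ENVIRONMENT,
    "gastrointestinal": GASTROINTESTINAL,
    "gut": GASTROINTESTINAL,
    "gi": GASTROINTESTINAL,
    "g": GASTROINTESTINAL,
    "unknown": UNKNOWN,
    "na": UNKNOWN,
    "?": UNKNOWN,
    "": UNKNOWN,
}


def normalize_habitat(value: str) -> str:
    """Map free-form habitat strings onto the canonical label set."""
    key = str(value).strip().lower()
    if key not in _HABITAT_ALIASES:
        raise ParameterError(
            f"unrecognised habitat label {value!r}; expected one of "
            f"environment / gastrointestinal / unknown (or common aliases)"
        )
    return _HABITAT_ALIASES[key]


@dataclass
class BitscoreMatrix:
    """Genes x strains table of profile-HMM bitscores with explicit absence.

    Parameters
    ----------
    scores :
        DataFrame indexed by ortholog-group id with one column per strain.
        Values are bitscores in bits; ``NaN`` means the gene is absent.
    provenance :
        Free-text description of where the scores came from.
    """

    scores: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            dupes = self.scores.index[self.scores.index.duplicated()].unique()
            raise ParameterError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        if self.scores.columns.has_duplicates:
            dupes = self.scores.columns[self.scores.columns.duplicated()].unique()
            raise ParameterError(f"duplicate strain identifiers: {list(dupes)[:5]}")
        self.scores = self.scores.astype(float)
        values = self.scores.to_numpy()
        if np.isinf(values).any():
            raise ParameterError("bitscores must be finite (NaN marks absence)")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def strains(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_genes(self) -> int:
        return self.scores.shape[0]

    @property
    def n_strains(self) -> int:
        return self.scores.shape[1]

    def present(self) -> pd.DataFrame:
        """Boolean mask, True where the gene is scored in the strain."""
        return self.scores.notna()

    def complete_genes(self) -> list[str]:
        """Genes present in every strain."""
        mask = self.scores.notna().all(axis=1)
        return list(self.scores.index[mask])

    def subset_genes(self, genes: Iterable[str]) -> "BitscoreMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.scores.index)
        if missing:
            raise ParameterError(f"genes not in matrix: {sorted(missing)[:5]}")
        return BitscoreMatrix(self.scores.loc[genes].copy(), self.provenance)

    def subset_strains(self, strains: Iterable[str]) -> "BitscoreMatrix":
        strains = list(strains)
        missing = set(strains) - set(self.scores.columns)
        if missing:
            raise ParameterError(f"strains not in matrix: {sorted(missing)[:5]}")
        return BitscoreMatrix(self.scores[strains].copy(), self.provenance)

    def strain_scores(self, strain: str) -> pd.Series:
        """Per-gene bitscores of one strain (NaN where absent)."""
        if strain not in self.scores.columns:
            raise ParameterError(f"unknown strain {strain!r}")
        return self.scores[strain]


def write_matrix(matrix: BitscoreMatrix, path: str | Path) -> None:
    """Write a bitscore matrix as TSV (rows = genes, columns = strains, NA = absent)."""
    df = matrix.scores.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_matrix(path: str | Path, provenance: str | None = None) -> BitscoreMatrix:
    """Read a bitscore TSV written by :func:`write_matrix`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse bitscore TSV: {exc}") from exc
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric bitscore columns {non_numeric}")
    return BitscoreMatrix(df, provenance or str(path))


def write_labels(labels: Mapping[str, str] | pd.Series, path: str | Path) -> None:
    series = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    df = pd.DataFrame({"strain": series.index, "habitat": series.values})
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.Series:
    """Read a strain -> habitat TSV; labels are normalised to the canonical set."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"strain", "habitat"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: labels TSV needs columns {sorted(required)}")
    if df["strain"].duplicated().any():
        raise ParseError(f"{path}: duplicate strain rows")
    labels = pd.Series(
        [normalize_habitat(h) for h in df["habitat"]],
        index=df["strain"].tolist(),
        name="habitat",
    )
    return labels


def write_truth(truth: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"gene": truth.index, "role": truth.values})
    df.to_csv(path, sep="\t", index=False)


def read_categories(path: str | Path) -> pd.DataFrame:
    """Read a gene -> functional category TSV (columns: gene, category)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene", "category"}.issubset(df.columns):
        raise ParseError(f"{path}: categories TSV needs columns ['gene', 'category']")
    return df[["gene", "category"]]


def genes_by_category(categories: pd.DataFrame) -> dict[str, list[str]]:
    return {
        cat: sorted(sub["gene"].unique())
        for cat, sub in categories.groupby("category", sort=True)
    }
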