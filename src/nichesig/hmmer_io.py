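"""Parsing HMMER3 tabular output and assembling the bitscore matrix.

``hmmsearch --tblout`` and ``--domtblout`` files are whitespace-delimited with
``#`` comment lines.  Only the per-sequence (full-sequence) score columns are
consumed here: the full-sequence bitscore is the quantity the delta-bitscore
method differences between strains.

Column offsets (0-based, after whitespace split):

=============  ==========  =============
field          tblout      domtblout
=============  ==========  =============
target (protein)   0           0
query (profile)    2           3
query accession    3           4
full E-value       4           6
full bitscore      5           7
=============  ==========  =============

The profile identifier used as the ortholog-group id is the query accession
when HMMER reports one, else the query name.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError
from .matrix import BitscoreMatrix

_DIALECTS = {
    # dialect -> (min fields, target col, query col, query acc col, evalue col, score col)
    "tblout": (18, 0, 2, 3, 4, 5),
    "domtblout": (22, 0, 3, 4, 6, 7),
}


@dataclass(frozen=True)
class HmmHit:
    """One protein-vs-profile hit from a HMMER3 tabular file."""

    query_protein: str
    profile: str
    full_seq_bitscore: float
    e_value: float
    strain: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.full_seq_bitscore):
            raise ParameterError(f"non-finite bitscore for {self.query_protein}")
        if self.e_value < 0:
            raise ParameterError(f"negative E-value for {self.query_protein}")


def parse_hmmer_tabular(
    path: str | Path, dialect: str = "tblout", strain: str | None = None
) -> list[HmmHit]:
    """Parse a HMMER3 ``--tblout`` or ``--domtblout`` file into hits.

    Parameters
    ----------
    path :
        Tabular file produced by ``hmmsearch``.
    dialect :
        ``"tblout"`` (per-sequence table) or ``"domtblout"`` (per-domain
        table; the full-sequence score columns are used either way, so a
        protein with several domains yields repeated identical full-sequence
        scores that collapse under best-hit selection).
    strain :
        Strain identifier to stamp on every hit; defaults to the file stem.
    """
    if dialect not in _DIALECTS:
        raise ParameterError(
            f"unknown HMMER dialect {dialect!r}; expected 'tblout' or 'domtblout'"
        )
    min_fields, t_col, q_col, qacc_col, e_col, s_col = _DIALECTS[dialect]
    path = Path(path)
    strain = strain if strain is not None else path.stem

    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < min_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_fields} fields for "
                    f"{dialect}, got {len(fields)}"
                )
            try:
                score = float(fields[s_col])
                evalue = float(fields[e_col])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric score/E-value field: {exc}"
                ) from exc
            profile = fields[qacc_col] if fields[qacc_col] != "-" else fields[q_col]
            hits.append(
                HmmHit(
                    query_protein=fields[t_col],
                    profile=profile,
                    full_seq_bitscore=score,
                    e_value=evalue,
                    strain=strain,
                )
            )
    return hits


def best_hits(hits: Iterable[HmmHit]) -> dict[str, HmmHit]:
    """Best hit per profile: highest bitscore, ties by lower E-value then protein id."""
    best: dict[str, HmmHit] = {}
    for hit in hits:
        cur = best.get(hit.profile)
        if cur is None or _hit_key(hit) < _hit_key(cur):
            best[hit.profile] = hit
    return best


def _hit_key(hit: HmmHit) -> tuple:
    return (-hit.full_seq_bitscore, hit.e_value, hit.query_protein)


def build_matrix(
    hits_by_strain: Mapping[str, Iterable[HmmHit]],
    min_strains_present: int | None = None,
) -> BitscoreMatrix:
    """Assemble a strain x profile bitscore matrix from per-strain hit lists.

    Per (strain, profile) cell the best hit is retained.  Profiles scored in
    fewer than ``min_strains_present`` strains are dropped (default: present
    in all strains, the filter used for the median-benchmark comparison; for
    classifier input half the strains rounded up is the customary choice).
    """
    strains = list(hits_by_strain)
    if len(strains) < 2:
        raise ParameterError("need at least two strains to build a matrix")
    if min_strains_present is None:
        min_strains_present = len(strains)
    if not 1 <= min_strains_present <= len(strains):
        raise ParameterError(
            f"min_strains_present must be in [1, {len(strains)}], got {min_strains_present}"
        )

    per_strain = {s: best_hits(hits_by_strain[s]) for s in strains}
    profiles = sorted({p for bh in per_strain.values() for p in bh})
    data = pd.DataFrame(
        np.nan, index=pd.Index(profiles, name="gene"), columns=strains, dtype=float
    )
    for strain in strains:
        for profile, hit in per_strain[strain].items():
            data.at[profile, strain] = hit.full_seq_bitscore

    presence = data.notna().sum(axis=1)
    data = data.loc[presence >= min_strains_present]
    return BitscoreMatrix(
        data, provenance=f"built from HMMER hits of {len(strains)} strains"
    )


def ingest_hmmer_dir(
    directory: str | Path,
    dialect: str = "tblout",
    min_strains_present: int | None = None,
    pattern: str = "*.tbl*",
) -> BitscoreMatrix:
    """Parse every HMMER tabular file in a directory (one file per strain)."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if len(files) < 2:
        raise ParameterError(
            f"{directory}: found {len(files)} files matching {pattern!r}; need >= 2"
        )
    hits_by_strain = {f.stem: parse_hmmer_tabular(f, dialect=dialect) for f in files}
    return build_matrix(hits_by_strain, min_strains_present=min_strains_present)
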