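"""Input/output for DMS score sets, sequences, PSSM profiles and prediction tables.

DMS supplements come in many delimited-text layouts; :func:`read_scoreset`
maps arbitrary column names onto the fields the pipeline needs.  Profiles
from iterative sequence search arrive in the PSI-BLAST ASCII PSSM dialect,
parsed by :func:`read_pssm`.  All tables are written back as TSV with a
fixed column order so runs are diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Literal, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from dmsbench.errors import (
    ConfigurationError,
    FormatError,
    SequenceMismatchError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from dmsbench.predictors import MethodSpec, PredictionSet

logger = logging.getLogger(__name__)

#: The 20 proteinogenic amino acids, in PSI-BLAST PSSM column order.
PSSM_AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")
AA_ALPHABET = frozenset(PSSM_AA_ORDER)

Orientation = Literal["higher_is_fitter", "lower_is_fitter"]

#: Variant key: (protein_id, 1-based position, wt residue, mutant residue).
VariantKey = tuple[str, int, str, str]

SCORESET_COLUMNS = [
    "protein_id", "position", "wt_aa", "mut_aa", "raw_score", "is_synonymous",
]


@dataclass(frozen=True)
class VariantRecord:
    """One scored variant: a SAV, or a synonymous record (``wt_aa == mut_aa``)."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    raw_score: float
    is_synonymous: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        for aa, name in ((self.wt_aa, "wt_aa"), (self.mut_aa, "mut_aa")):
            if aa not in AA_ALPHABET:
                raise ValidationError(
                    f"{name}={aa!r} at position {self.position} is not one of "
                    f"the 20 amino acids"
                )
        if self.is_synonymous != (self.wt_aa == self.mut_aa):
            raise ValidationError(
                f"variant {self.wt_aa}{self.position}{self.mut_aa}: synonymous "
                f"flag must be set exactly when wt_aa == mut_aa"
            )

    @property
    def key(self) -> VariantKey:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)


@dataclass
class DmsDataset:
    """One DMS measurement: a protein, its variants and the assay conventions.

    ``wt_score`` is the raw score of the unmutated protein (0 for assays that
    already report log ratios versus wild type).  ``orientation`` states which
    direction of the raw scale means higher fitness.  ``provenance`` tags the
    publication of origin so that replicate comparisons can exclude pairs from
    the same study.
    """

    dataset_id: str
    protein_id: str
    sequence: str
    variants: list[VariantRecord]
    wt_score: float = 0.0
    orientation: Orientation = "higher_is_fitter"
    provenance: str = ""
    flagged_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[VariantKey, float] = {}
        for v in self.variants:
            if v.key in seen and not v.is_synonymous:
                raise ValidationError(
                    f"duplicate variant {v.wt_aa}{v.position}{v.mut_aa} "
                    f"in dataset {self.dataset_id}"
                )
            seen[v.key] = v.raw_score
        n_sav = sum(not v.is_synonymous for v in self.variants)
        if self.sequence and n_sav > 19 * len(self.sequence):
            raise ValidationError(
                f"dataset {self.dataset_id}: {n_sav} SAVs exceeds the "
                f"19*N={19 * len(self.sequence)} possible non-native SAVs"
            )

    @property
    def savs(self) -> list[VariantRecord]:
        return [v for v in self.variants if not v.is_synonymous]

    @property
    def synonymous(self) -> list[VariantRecord]:
        return [v for v in self.variants if v.is_synonymous]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.protein_id, v.position, v.wt_aa, v.mut_aa, v.raw_score,
              v.is_synonymous) for v in self.variants],
            columns=SCORESET_COLUMNS,
        )


@dataclass
class PssmProfile:
    """Per-position 20-value log-odds profile with its query sequence."""

    protein_id: str
    sequence: str
    log_odds: np.ndarray  # shape (N, 20), PSSM_AA_ORDER columns, integer

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds)
        if self.log_odds.shape != (len(self.sequence), 20):
            raise ValidationError(
                f"log_odds shape {self.log_odds.shape} does not match "
                f"sequence length {len(self.sequence)} x 20"
            )

    def score(self, position: int, aa: str) -> int:
        """Log-odds of residue ``aa`` at 1-based ``position``."""
        return int(self.log_odds[position - 1, PSSM_AA_ORDER.index(aa)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PssmProfile):
            return NotImplemented
        return (self.protein_id == other.protein_id
                and self.sequence == other.sequence
                and np.array_equal(self.log_odds, other.log_odds))


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "t", "yes", "y", "1"}:
        return True
    if s in {"false", "f", "no", "n", "0", ""}:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a synonymous flag")


def read_scoreset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    orientation: Orientation = "higher_is_fitter",
    wt_score: float = 0.0,
    dataset_id: str | None = None,
    sequence: str = "",
    provenance: str = "",
    sep: str = "\t",
) -> DmsDataset:
    """Read a delimited DMS score table into a :class:`DmsDataset`.

    Parameters
    ----------
    column_map
        Maps required field names (``protein_id``, ``position``, ``wt_aa``,
        ``mut_aa``, ``raw_score``, optionally ``is_synonymous``) to the
        table's actual column names.  Identity mapping by default.
    orientation, wt_score
        Assay conventions; supplied per dataset, not inferred.

    Rows whose score does not parse as a number are dropped with a logged
    count.  Duplicate rows with identical scores are deduplicated silently;
    duplicates with conflicting scores raise :class:`ValidationError`.
    Categorical (non-numeric) score columns are rejected outright.
    """
    path = Path(path)
    cmap = dict(column_map or {})
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    def col(fieldname: str, required: bool = True) -> str | None:
        name = cmap.get(fieldname, fieldname)
        if name not in table.columns:
            if required:
                raise ConfigurationError(
                    f"{path.name}: required column {name!r} (for field "
                    f"{fieldname!r}) not found; have {list(table.columns)}"
                )
            return None
        return name

    c_prot = col("protein_id")
    c_pos = col("position")
    c_wt = col("wt_aa")
    c_mut = col("mut_aa")
    c_score = col("raw_score")
    c_syn = col("is_synonymous", required=False)

    scores = pd.to_numeric(table[c_score], errors="coerce")
    n_bad = int(scores.isna().sum())
    if n_bad == len(table) and len(table) > 0:
        raise ValidationError(
            f"{path.name}: no numeric scores in column {c_score!r}; "
            f"categorical score sets are not supported"
        )
    if n_bad:
        logger.warning("%s: dropped %d rows with unparseable scores",
                       path.name, n_bad)
    keep = ~scores.isna()

    seen: dict[VariantKey, float] = {}
    variants: list[VariantRecord] = []
    for row, score in zip(table.loc[keep].itertuples(index=False),
                          scores[keep]):
        rec = dict(zip(table.columns, row))
        is_syn = _parse_bool(rec[c_syn]) if c_syn else False
        v = VariantRecord(
            protein_id=str(rec[c_prot]),
            position=int(rec[c_pos]),
            wt_aa=str(rec[c_wt]).upper(),
            mut_aa=str(rec[c_mut]).upper(),
            raw_score=float(score),
            is_synonymous=is_syn,
        )
        if v.key in seen and not v.is_synonymous:
            if seen[v.key] != v.raw_score:
                raise ValidationError(
                    f"{path.name}: variant {v.wt_aa}{v.position}{v.mut_aa} "
                    f"repeated with conflicting scores "
                    f"{seen[v.key]} vs {v.raw_score}"
                )
            continue  # identical duplicate: deduplicate silently
        seen[v.key] = v.raw_score
        variants.append(v)

    return DmsDataset(
        dataset_id=dataset_id or path.stem,
        protein_id=variants[0].protein_id if variants else "",
        sequence=sequence,
        variants=variants,
        wt_score=wt_score,
        orientation=orientation,
        provenance=provenance,
    )


def write_scoreset(dataset: DmsDataset, path: str | Path) -> None:
    """Write a score set as TSV in the fixed column order."""
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def check_sequence_consistency(
    dataset: DmsDataset,
    sequence: str,
    max_mismatch: int = 5,
    min_identity: float = 0.98,
) -> DmsDataset:
    """Verify variant wild-type residues against a reference sequence.

    Published variant tables and the mapped reference protein may differ by a
    handful of substitutions; such datasets are retained as long as at most
    ``max_mismatch`` positions disagree and the implied pairwise identity is
    at least ``min_identity``.  Returns a copy of the dataset carrying the
    reference sequence with mismatching positions recorded in
    ``flagged_positions``; raises :class:`SequenceMismatchError` otherwise.

    Idempotent: re-checking an accepted dataset yields the same flags.
    """
    if not sequence:
        raise ValidationError("reference sequence is empty")
    mismatched: list[int] = []
    for v in dataset.variants:
        if v.position > len(sequence):
            mismatched.append(v.position)
        elif sequence[v.position - 1] != v.wt_aa:
            mismatched.append(v.position)
    positions = sorted(set(mismatched))
    identity = 1.0 - len(positions) / len(sequence)
    if len(positions) > max_mismatch or identity < min_identity:
        raise SequenceMismatchError(
            f"dataset {dataset.dataset_id}: wild-type residues disagree with "
            f"the reference at {len(positions)} positions "
            f"(identity {identity:.3f}): {positions}",
            positions,
        )
    return replace(dataset, sequence=sequence, flagged_positions=positions)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA, keyed by record id."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# --- PSI-BLAST ASCII PSSM -------------------------------------------------
#
# Dialect (confirmed against psiblast output): a description line, a header
# line listing the amino acid columns, then one row per query position:
#   <idx> <residue> <20 integer log-odds> [<20 integer percentages>
#   [<information> <relative weight>]]
# followed by blank lines and K/Lambda footer lines.  The percentage and
# trailing-real blocks are optional; only the first 20-integer block is used.

def read_pssm(path: str | Path, protein_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII position-specific scoring matrix.

    Tolerates variable whitespace and missing percentage/statistics blocks.
    Raises :class:`FormatError` (with the line number) for rows that do not
    carry 20 parsable integer log-odds, and for an empty body.
    """
    path = Path(path)
    residues: list[str] = []
    rows: list[list[int]] = []
    expected_index = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            # Position rows start with the running 1-based index.
            if len(parts) < 2 or not parts[0].isdigit():
                continue
            if int(parts[0]) != expected_index:
                continue  # e.g. footer lines that happen to start with digits
            residue = parts[1]
            if len(residue) != 1 or residue.upper() not in AA_ALPHABET:
                raise FormatError(
                    f"{path.name}:{lineno}: expected a one-letter residue, "
                    f"got {residue!r}"
                )
            values = parts[2:22]
            if len(values) < 20:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 20 log-odds values, "
                    f"found {len(values)}"
                )
            try:
                row = [int(v) for v in values]
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer log-odds value "
                    f"({exc})"
                ) from None
            residues.append(residue.upper())
            rows.append(row)
            expected_index += 1
    if not rows:
        raise FormatError(f"{path.name}: no PSSM rows found")
    return PssmProfile(
        protein_id=protein_id or path.stem,
        sequence="".join(residues),
        log_odds=np.array(rows, dtype=int),
    )


def write_pssm(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (log-odds block only,
    plus a zero percentage block so standard consumers can read it)."""
    with open(path, "w") as fh:
        fh.write("Last position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down, information per "
                 "position, and relative weight of gapless real matches to "
                 "pseudocounts\n")
        header = "  ".join(PSSM_AA_ORDER)
        fh.write(f"            {header}   {header}\n")
        for i, aa in enumerate(profile.sequence):
            lo = "".join(f"{int(v):4d}" for v in profile.log_odds[i])
            pct = "".join(f"{0:4d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {aa}  {lo} {pct}  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1374     0.3224\n")


def read_prediction_table(
    path: str | Path,
    method: "MethodSpec",
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> "PredictionSet":
    """Read one method's per-SAV score table into a :class:`PredictionSet`.

    SAVs without a score row are simply absent — downstream evaluation
    always runs on the largest common subset, never imputes.  Scores outside
    the method's declared ``[raw_min, raw_max]`` raise
    :class:`ValidationError`.
    """
    from dmsbench.predictors import PredictionSet

    path = Path(path)
    cmap = dict(column_map or {})
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    scores: dict[VariantKey, float] = {}
    if len(table):
        names = {f: cmap.get(f, f) for f in
                 ("protein_id", "position", "wt_aa", "mut_aa", "raw_score")}
        missing = [n for n in names.values() if n not in table.columns]
        if missing:
            raise ConfigurationError(
                f"{path.name}: missing columns {missing}; have "
                f"{list(table.columns)}"
            )
        for rec in table.to_dict("records"):
            raw = rec[names["raw_score"]]
            try:
                value = float(raw)
            except ValueError:
                raise ValidationError(
                    f"{path.name}: non-numeric prediction score {raw!r}"
                ) from None
            if not (method.raw_min <= value <= method.raw_max):
                raise ValidationError(
                    f"{path.name}: score {value} outside {method.name}'s "
                    f"declared range [{method.raw_min}, {method.raw_max}]"
                )
            key = (str(rec[names["protein_id"]]), int(rec[names["position"]]),
                   str(rec[names["wt_aa"]]).upper(),
                   str(rec[names["mut_aa"]]).upper())
            scores[key] = value
    return PredictionSet(method=method, scores=scores)
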