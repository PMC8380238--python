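"""Domain types, score-table IO, and reference-set curation.

A screened compound carries two docking scores (kcal/mol, more negative =
more favorable): one against the enzyme's orthosteric (catalytic) site and
one against a surface allosteric site near the CYP–POR interface. Compounds
for which the docking engine finds no sterically valid pose are "bumped" and
carry a score of +inf. Reference compounds come from a high-throughput
bioactivity screen and are labeled inhibitor / non-inhibitor by a multi-step
curation of the screen's per-compound fit records.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Sentinel for a "bumped" docking score: no valid pose, treated as +infinity.
#: Distinct from missing data (which is rejected at ingestion).
BUMPED = math.inf


class Label(str, Enum):
    INHIBITOR = "inhibitor"
    NON_INHIBITOR = "non_inhibitor"
    UNLABELED = "unlabeled"


class PotencyBand(str, Enum):
    STRONG = "strong"
    WEAK = "weak"
    NONE = "none"
    UNKNOWN = "unknown"


class ScoreTableFormatError(ValueError):
    """A score table is missing a required column."""


class ScoreParseError(ValueError):
    """A score cell is neither numeric nor the bumped token."""


@dataclass
class CompoundRecord:
    """One screened molecule with its two docking scores.

    ``ortho_score`` / ``allo_score`` are kcal/mol, with :data:`BUMPED`
    (+inf) marking a bumped pose. They may be ``None`` only for records
    that have not yet been docked (e.g. fresh out of curation); the score
    readers guarantee non-``None`` values.
    """

    compound_id: str
    ortho_score: float | None = None
    allo_score: float | None = None
    cas: str | None = None
    smiles: str | None = None
    label: Label = Label.UNLABELED
    potency_band: PotencyBand = PotencyBand.UNKNOWN
    ac50: float | None = None  # µM
    # pre-capping originals, populated by cap_scores for reporting
    raw_ortho_score: float | None = None
    raw_allo_score: float | None = None

    def __post_init__(self) -> None:
        self.label = Label(self.label)
        self.potency_band = PotencyBand(self.potency_band)
        if self.potency_band is PotencyBand.STRONG:
            if self.label is not Label.INHIBITOR or self.ac50 is None or not self.ac50 < 1.0:
                raise ValueError(
                    f"{self.compound_id}: strong band requires inhibitor label and AC50 < 1 µM"
                )
        if self.potency_band is PotencyBand.WEAK:
            if self.label is not Label.INHIBITOR or self.ac50 is None or not 1.0 <= self.ac50 < 100.0:
                raise ValueError(
                    f"{self.compound_id}: weak band requires inhibitor label and 1 ≤ AC50 < 100 µM"
                )


@dataclass
class ActivityRecord:
    """One compound's record from the upstream bioactivity screen.

    ``single_conc_active`` is the single-concentration triage flag;
    compounds failing it were never dose–response tested. ``fitted_model``
    names the winning concentration–response model of the screen's own
    pipeline ("constant" = flat, i.e. inactive).
    """

    compound_id: str
    smiles: str | None = None
    single_conc_active: bool = False
    fitted_model: str = "none"  # {constant, non_constant, none}
    ac50: float | None = None  # µM
    max_response: float | None = None  # %

    def __post_init__(self) -> None:
        if self.fitted_model not in ("constant", "non_constant", "none"):
            raise ValueError(f"unknown fitted_model {self.fitted_model!r}")
        if self.fitted_model == "none" and self.single_conc_active:
            raise ValueError(
                f"{self.compound_id}: single-concentration actives must carry a fitted model"
            )


@dataclass
class CurationReport:
    """Per-step accounting of the reference-set curation."""

    n_input: int = 0
    n_removed_overlap: int = 0
    n_removed_ambiguous: int = 0
    n_removed_undockable: int = 0
    n_final: int = 0
    n_inhibitors: int = 0
    n_non_inhibitors: int = 0
    smiles_checker: str = "rdkit"

    def __post_init__(self) -> None:
        assert self.n_final == self.n_inhibitors + self.n_non_inhibitors
        assert (
            self.n_input
            == self.n_removed_overlap
            + self.n_removed_ambiguous
            + self.n_removed_undockable
            + self.n_final
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


# ---------------------------------------------------------------------------
# score-table IO

#: accepted header aliases, lowercased
_ID_COLS = ("compound_id", "id", "compound", "name", "chemical_name")
_ORTHO_COLS = ("ortho_score", "orthosteric_score", "orthosteric", "ortho")
_ALLO_COLS = ("allo_score", "allosteric_score", "allosteric", "allo")
_LABEL_COLS = ("label", "class", "activity")
_AC50_COLS = ("ac50", "ac50_um")
_SMILES_COLS = ("smiles",)
_CAS_COLS = ("cas", "casn", "cas_number")


def _find_col(columns: Sequence[str], aliases: Sequence[str], required_name: str | None) -> str | None:
    lower = {c.lower().strip(): c for c in columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    if required_name is not None:
        raise ScoreTableFormatError(
            f"no column for {required_name!r}; expected one of {list(aliases)}, got {list(columns)}"
        )
    return None


def _parse_score(cell, bumped_token: str, row: int, col: str) -> float:
    if isinstance(cell, str) and cell.strip().lower() in (bumped_token.lower(), "+inf", "+∞", "∞"):
        return BUMPED
    try:
        v = float(cell)
    except (TypeError, ValueError):
        raise ScoreParseError(f"row {row}: cannot parse {col}={cell!r} as score") from None
    if math.isnan(v):
        raise ScoreParseError(f"row {row}: missing {col}")
    return v


def read_score_table(
    path: str | Path,
    dialect: str = "csv",
    bumped_token: str = "inf",
    column_map: dict[str, str] | None = None,
) -> list[CompoundRecord]:
    """Read a docking-score table (one compound per row) from CSV/TSV.

    Required columns: compound identifier, orthosteric score, allosteric
    score (header aliases are recognized case-insensitively; override via
    ``column_map`` with keys ``id``, ``ortho``, ``allo``, ``label``,
    ``ac50``, ``smiles``, ``cas``). Score cells must be numeric or the
    ``bumped_token`` (mapped to :data:`BUMPED`). Row order is preserved.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cmap = column_map or {}

    def col(key, aliases, required=None):
        if key in cmap:
            if cmap[key] not in df.columns:
                raise ScoreTableFormatError(f"mapped column {cmap[key]!r} not in table")
            return cmap[key]
        return _find_col(df.columns, aliases, required)

    id_c = col("id", _ID_COLS, "compound id")
    ortho_c = col("ortho", _ORTHO_COLS, "orthosteric score")
    allo_c = col("allo", _ALLO_COLS, "allosteric score")
    label_c = col("label", _LABEL_COLS)
    ac50_c = col("ac50", _AC50_COLS)
    smiles_c = col("smiles", _SMILES_COLS)
    cas_c = col("cas", _CAS_COLS)

    records: list[CompoundRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        d = dict(zip(df.columns, row))
        label = Label.UNLABELED
        if label_c and d[label_c].strip():
            raw = d[label_c].strip().lower()
            label = Label.INHIBITOR if raw in ("inhibitor", "1", "true", "active") else Label.NON_INHIBITOR
        ac50 = None
        if ac50_c and d[ac50_c].strip():
            ac50 = float(d[ac50_c])
        band = PotencyBand.UNKNOWN
        if label is Label.INHIBITOR and ac50 is not None:
            band = PotencyBand(assign_potency_band(ac50))
        elif label is Label.NON_INHIBITOR:
            band = PotencyBand.NONE
        records.append(
            CompoundRecord(
                compound_id=str(d[id_c]),
                ortho_score=_parse_score(d[ortho_c], bumped_token, i, ortho_c),
                allo_score=_parse_score(d[allo_c], bumped_token, i, allo_c),
                smiles=(d[smiles_c] or None) if smiles_c else None,
                cas=(d[cas_c] or None) if cas_c else None,
                label=label,
                potency_band=band,
                ac50=ac50,
            )
        )
    return records


def write_score_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write the canonical CSV (bumped scores serialized as ``inf``)."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "smiles": r.smiles or "",
                "ortho_score": "inf" if r.ortho_score == BUMPED else r.ortho_score,
                "allo_score": "inf" if r.allo_score == BUMPED else r.allo_score,
                "label": r.label.value,
                "potency_band": r.potency_band.value,
                "ac50": "" if r.ac50 is None else r.ac50,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# curation

_ATOM_RE = re.compile(
    # two-letter organic/common elements first so "Cl" is not read as C+l
    r"Cl|Br|Si|Se|As|[BCNOPSFI]|\[[^\]]+\]|\b(?:c|n|o|s|p|b)\b|c|n|o|s|p"
)


def _atom_count_tokenizer(smiles: str) -> int | None:
    """Count heavy atoms in a SMILES string by regex tokenization.

    Fallback used when rdkit is unavailable: counts element tokens
    (aromatic lowercase, bracket atoms, Cl/Br/Si/Se/As and the one-letter
    organic subset). Hydrogens inside brackets are not counted. Returns
    ``None`` for strings with no recognizable atoms.
    """
    if not smiles or not smiles.strip():
        return None
    n = len(_ATOM_RE.findall(smiles))
    return n or None


def _atom_count(smiles: str | None) -> tuple[int | None, str]:
    """Heavy-atom count and the name of the checker used; None = invalid."""
    if smiles is None or not smiles.strip():
        return None, "rdkit"
    try:
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
        mol = Chem.MolFromSmiles(smiles)
        return (mol.GetNumHeavyAtoms() if mol is not None else None), "rdkit"
    except ImportError:
        return _atom_count_tokenizer(smiles), "tokenizer"


def assign_potency_band(ac50: float) -> str:
    """Potency band from AC50 (µM): <1 strong, [1,100) weak, else none."""
    if not ac50 > 0:
        raise ValueError(f"AC50 must be positive, got {ac50}")
    if ac50 < 1.0:
        return "strong"
    if ac50 < 100.0:
        return "weak"
    return "none"


def curate_reference_set(
    records: Iterable[ActivityRecord],
    exclude_ids: set[str] | frozenset[str] = frozenset(),
    min_atoms: int = 5,
    discard_ac50: float = 10.0,
    discard_max_response: float = 10.0,
) -> tuple[list[CompoundRecord], CurationReport]:
    """Label screen records as inhibitor / non-inhibitor and drop the rest.

    Steps, in order:

    1. drop compounds in ``exclude_ids`` (overlap with validation compounds);
    2. single-concentration inactives → non-inhibitor;
    3. "constant" fitted model → non-inhibitor;
    4. non-constant fits with AC50 > ``discard_ac50`` µM or maximum response
       < ``discard_max_response`` % → discarded as ambiguous;
    5. remaining compounds → inhibitor;
    6. drop records whose SMILES is missing/invalid or has fewer than
       ``min_atoms`` heavy atoms (undockable).

    Returns the labeled records plus a :class:`CurationReport` accounting
    for every input compound exactly once. Idempotent: re-curating the
    output (converted back to activity records) changes nothing.
    """
    if min_atoms < 1:
        raise ValueError("min_atoms must be ≥ 1")

    n_input = n_overlap = n_ambig = n_undock = 0
    checker = "rdkit"
    out: list[CompoundRecord] = []
    for rec in records:
        n_input += 1
        if rec.compound_id in exclude_ids:
            n_overlap += 1
            continue
        if not rec.single_conc_active or rec.fitted_model == "constant":
            label = Label.NON_INHIBITOR
        elif (rec.ac50 is not None and rec.ac50 > discard_ac50) or (
            rec.max_response is not None and rec.max_response < discard_max_response
        ):
            n_ambig += 1
            continue
        else:
            label = Label.INHIBITOR
        n, checker = _atom_count(rec.smiles)
        if n is None or n < min_atoms:
            n_undock += 1
            continue
        band = PotencyBand.NONE
        if label is Label.INHIBITOR:
            band = (
                PotencyBand(assign_potency_band(rec.ac50))
                if rec.ac50 is not None
                else PotencyBand.UNKNOWN
            )
        out.append(
            CompoundRecord(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                label=label,
                potency_band=band,
                ac50=rec.ac50,
            )
        )

    n_inh = sum(1 for r in out if r.label is Label.INHIBITOR)
    report = CurationReport(
        n_input=n_input,
        n_removed_overlap=n_overlap,
        n_removed_ambiguous=n_ambig,
        n_removed_undockable=n_undock,
        n_final=len(out),
        n_inhibitors=n_inh,
        n_non_inhibitors=len(out) - n_inh,
        smiles_checker=checker,
    )
    return out, report


def cap_scores(
    records: Iterable[CompoundRecord],
    allo_cap: float = 0.0,
    ortho_cap: float = 20.0,
) -> list[CompoundRecord]:
    """Cap scores from above: values (incl. BUMPED) above the cap become the cap.

    Originals are kept in ``raw_allo_score`` / ``raw_ortho_score`` for
    reporting. Allosteric default cap 0 kcal/mol, orthosteric 20 kcal/mol.
    """
    if not (math.isfinite(allo_cap) and math.isfinite(ortho_cap)):
        raise ValueError("caps must be finite")
    out = []
    for r in records:
        if r.ortho_score is None or r.allo_score is None:
            raise ValueError(f"{r.compound_id}: cannot cap missing scores")
        out.append(
            CompoundRecord(
                compound_id=r.compound_id,
                ortho_score=min(r.ortho_score, ortho_cap),
                allo_score=min(r.allo_score, allo_cap),
                cas=r.cas,
                smiles=r.smiles,
                label=r.label,
                potency_band=r.potency_band,
                ac50=r.ac50,
                raw_ortho_score=r.raw_ortho_score if r.raw_ortho_score is not None else r.ortho_score,
                raw_allo_score=r.raw_allo_score if r.raw_allo_score is not None else r.allo_score,
            )
        )
    return out


def records_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Tabular view of records (scores as floats, BUMPED as +inf)."""
    records = list(records)
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "ortho_score": [r.ortho_score for r in records],
            "allo_score": [r.allo_score for r in records],
            "label": [r.label.value for r in records],
            "potency_band": [r.potency_band.value for r in records],
            "ac50": [r.ac50 for r in records],
        }
    )
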