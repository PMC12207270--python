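"""Lookup-table regioselectivity predictor over SMARTS directing-group patterns.

Each table row pairs a SMARTS pattern -- whose first atom is the reactive
aromatic CH -- with a directing-group strength in kcal/mol (more negative
means stronger directing).  All patterns are matched onto the substrate
and, per reaction site, ranked by three keys applied sequentially: most
heavy atoms matched, then largest sum of atomic numbers over the matched
heavy atoms, then lowest (most negative) DG strength.  Each site is
assigned the strength of its top-ranked match, and the site(s) achieving
the overall minimum strength are predicted to react.

The table format is TSV with columns ``smarts`` and ``dg_strength_kcal``;
a small bundled table carries the worked-example patterns, and users can
supply a complete table in the same format.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "PatternEntry",
    "MatchRecord",
    "PatternPrediction",
    "PatternTableError",
    "load_pattern_table",
    "bundled_pattern_table",
    "match_patterns",
    "predict_site_from_patterns",
]


class PatternTableError(ValueError):
    """A pattern table row is malformed or duplicated."""


@dataclass(frozen=True)
class PatternEntry:
    """One SMARTS pattern with its directing-group strength."""

    smarts: str
    dg_strength_kcal: float
    query: Chem.Mol = field(repr=False, compare=False, default=None)

    @staticmethod
    def create(smarts: str, dg_strength_kcal: float) -> "PatternEntry":
        query = Chem.MolFromSmarts(smarts)
        if query is None or query.GetNumAtoms() == 0:
            raise PatternTableError(f"unparsable SMARTS: {smarts!r}")
        first = query.GetAtomWithIdx(0)
        if first.GetAtomicNum() not in (0, 6):
            raise PatternTableError(
                f"first SMARTS atom must be the reactive CH site: {smarts!r}"
            )
        return PatternEntry(smarts, float(dg_strength_kcal), query)


@dataclass(frozen=True)
class MatchRecord:
    """One prioritized match of a pattern onto a substrate site.

    ``n_heavy`` and ``z_sum`` are computed from the atoms actually matched,
    so generic SMARTS atoms (``A``, ``[C,c]``) contribute the matched
    atom's own atomic number.
    """

    site_atom: int
    pattern: PatternEntry
    n_heavy: int
    z_sum: int
    rank_at_site: int
    matched_atoms: tuple[int, ...] = ()

    @property
    def sort_key(self) -> tuple[int, int, float]:
        return (-self.n_heavy, -self.z_sum, self.pattern.dg_strength_kcal)


def load_pattern_table(path: str | Path) -> list[PatternEntry]:
    """Load a TSV pattern table (columns ``smarts``, ``dg_strength_kcal``).

    Rows with duplicated SMARTS or malformed content raise
    :class:`PatternTableError` naming the offending row; an empty file
    yields an empty table with a warning.
    """
    entries: list[PatternEntry] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("pattern table %s is empty", path)
            return []
        required = {"smarts", "dg_strength_kcal"}
        if not required <= set(reader.fieldnames):
            raise PatternTableError(
                f"table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row_no, row in enumerate(reader, start=2):
            smarts = (row["smarts"] or "").strip()
            try:
                entry = PatternEntry.create(smarts, float(row["dg_strength_kcal"]))
            except PatternTableError as exc:
                raise PatternTableError(f"row {row_no}: {exc}") from exc
            except (TypeError, ValueError) as exc:
                raise PatternTableError(
                    f"row {row_no}: bad strength {row['dg_strength_kcal']!r}"
                ) from exc
            if entry.smarts in seen:
                raise PatternTableError(
                    f"row {row_no}: duplicate SMARTS {entry.smarts!r}"
                )
            seen.add(entry.smarts)
            entries.append(entry)
    if not entries:
        logger.warning("pattern table %s contains no rows", path)
    return entries


def bundled_pattern_table() -> list[PatternEntry]:
    """The small pattern table shipped with the package."""
    ref = resources.files("regiocmd.data") / "dg_patterns.tsv"
    with resources.as_file(ref) as path:
        return load_pattern_table(path)


def match_patterns(smiles: str, table: list[PatternEntry]) -> list[MatchRecord]:
    """Match every table pattern onto the substrate and rank per site.

    Per (site, pattern) only the best-scoring substructure match is kept.
    Within each site, records are sorted by (n_heavy desc, z_sum desc,
    dg_strength asc); ties preserve table order (stable sort).  Records
    are returned grouped by ascending site atom index with
    ``rank_at_site`` starting at 1.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    per_site: dict[int, list[MatchRecord]] = defaultdict(list)
    for entry in table:
        best: dict[int, MatchRecord] = {}
        for match in mol.GetSubstructMatches(entry.query, uniquify=True):
            heavy = [
                mol.GetAtomWithIdx(i).GetAtomicNum()
                for i in match
                if mol.GetAtomWithIdx(i).GetAtomicNum() > 1
            ]
            rec = MatchRecord(
                site_atom=match[0],
                pattern=entry,
                n_heavy=len(heavy),
                z_sum=sum(heavy),
                rank_at_site=0,
                matched_atoms=tuple(match),
            )
            prev = best.get(rec.site_atom)
            if prev is None or rec.sort_key < prev.sort_key:
                best[rec.site_atom] = rec
        for rec in best.values():
            per_site[rec.site_atom].append(rec)
    out: list[MatchRecord] = []
    for site in sorted(per_site):
        ranked = sorted(per_site[site], key=lambda r: r.sort_key)
        for rank, rec in enumerate(ranked, start=1):
            out.append(
                MatchRecord(
                    site_atom=rec.site_atom,
                    pattern=rec.pattern,
                    n_heavy=rec.n_heavy,
                    z_sum=rec.z_sum,
                    rank_at_site=rank,
                    matched_atoms=rec.matched_atoms,
                )
            )
    return out


@dataclass(frozen=True)
class PatternPrediction:
    """Outcome of the lookup-table predictor for one substrate.

    ``matched`` distinguishes "no pattern matched anywhere, no prediction
    possible" from a prediction proper.  ``site_strengths`` maps each
    matched site atom to the DG strength of its top-ranked match; display
    ids number the matched sites 1..N in ascending atom-index order, the
    convention used in annotated depictions.
    """

    matched: bool
    predicted_sites: tuple[int, ...]
    site_strengths: dict[int, float]
    records: tuple[MatchRecord, ...]

    def display_id(self, site_atom: int) -> int:
        return sorted(self.site_strengths).index(site_atom) + 1

    def records_at(self, site_atom: int) -> list[MatchRecord]:
        return [r for r in self.records if r.site_atom == site_atom]

    def records_at_display_id(self, display_id: int) -> list[MatchRecord]:
        site = sorted(self.site_strengths)[display_id - 1]
        return self.records_at(site)


def predict_site_from_patterns(
    smiles: str, table: list[PatternEntry]
) -> PatternPrediction:
    """Predict the reaction site(s) by top-ranked DG strength per site.

    Every site keeps the strength of its rank-1 match; the predicted sites
    are those achieving the minimum (strongest-directing) strength, with
    ties all reported.
    """
    records = match_patterns(smiles, table)
    if not records:
        return PatternPrediction(False, (), {}, ())
    strengths = {
        r.site_atom: r.pattern.dg_strength_kcal
        for r in records
        if r.rank_at_site == 1
    }
    best = min(strengths.values())
    predicted = tuple(
        sorted(s for s, v in strengths.items() if v == best)
    )
    return PatternPrediction(True, predicted, strengths, tuple(records))
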