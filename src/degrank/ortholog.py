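"""Mouse-to-human ortholog resolution and DEG-table re-keying.

Cross-species gene-set tests need every mouse gene expressed in the
experiment mapped to exactly one human Ensembl gene ID.  Ortholog
correspondence tables are many-to-many; the resolution rule used here keeps,
for a mouse symbol with several human candidates, the candidate whose human
symbol equals the mouse symbol converted to upper case (mouse nomenclature
capitalizes only the first letter, human symbols are fully capitalized, so
the true ortholog almost always satisfies this).  Mouse symbols with no
candidate surviving the rule are dropped, and dropped genes are excluded
from every downstream test universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io_formats import DEGTable, FormatError, IntegrityError

log = logging.getLogger("degrank")

__all__ = [
    "OrthologTable",
    "GeneIdMap",
    "HumanizeResult",
    "read_ortholog_table",
    "write_ortholog_table",
    "resolve_one_to_one",
    "humanize",
]

_ORTHO_COLUMNS = ("mouse_symbol", "human_symbol", "human_gene_id")


@dataclass
class OrthologTable:
    """Raw many-to-many symbol correspondences (one candidate pair per row)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _ORTHO_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"ortholog table missing columns: {missing}")
        d = self.data.loc[:, list(_ORTHO_COLUMNS)].astype(str)
        empty = (d == "").any(axis=1) | d.isin(["nan"]).any(axis=1)
        if empty.any():
            raise IntegrityError(
                f"ortholog table has {int(empty.sum())} rows with empty fields"
            )
        ndup = int(d.duplicated().sum())
        if ndup:
            log.warning("ortholog table: collapsed %d fully duplicated rows", ndup)
            d = d.drop_duplicates()
        self.data = d.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneIdMap:
    """Resolved one-to-one mouse symbol -> human gene ID map plus its report."""

    entries: dict[str, str]
    n_input: int
    n_mapped: int
    n_dropped_no_match: int
    n_dropped_ambiguous: int

    def report(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_mapped": self.n_mapped,
            "n_dropped_no_match": self.n_dropped_no_match,
            "n_dropped_ambiguous": self.n_dropped_ambiguous,
        }

    def __len__(self) -> int:
        return len(self.entries)


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read a 3-column TSV (mouse_symbol, human_symbol, human_gene_id)."""
    return OrthologTable(pd.read_csv(path, sep="\t", dtype=str))


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def resolve_one_to_one(table: OrthologTable) -> GeneIdMap:
    """Collapse a many-to-many correspondence to one human ID per mouse symbol.

    A mouse symbol with a single human candidate keeps it.  With several
    candidates, the one whose human symbol equals the upper-cased mouse
    symbol is kept; if none matches the symbol is dropped (counted as
    ambiguous).  Two distinct IDs both matching the capitalization rule for
    one mouse symbol indicate a corrupt table and raise.
    """
    if len(table) == 0:
        raise IntegrityError("ortholog table is empty")
    entries: dict[str, str] = {}
    n_ambiguous = 0
    for mouse, group in table.data.groupby("mouse_symbol", sort=True):
        cands = group.drop_duplicates(subset=["human_symbol", "human_gene_id"])
        ids = cands["human_gene_id"].unique()
        if len(ids) == 1:
            entries[mouse] = ids[0]
            continue
        match = cands[cands["human_symbol"] == mouse.upper()]
        matched_ids = match["human_gene_id"].unique()
        if len(matched_ids) == 1:
            entries[mouse] = matched_ids[0]
        elif len(matched_ids) == 0:
            n_ambiguous += 1
        else:
            raise IntegrityError(
                f"mouse symbol {mouse!r} has multiple exact-capitalization "
                f"candidates: {sorted(matched_ids)}"
            )
    n_input = table.data["mouse_symbol"].nunique()
    return GeneIdMap(
        entries=entries,
        n_input=n_input,
        n_mapped=len(entries),
        n_dropped_no_match=0,  # counted per-table when queried via humanize()
        n_dropped_ambiguous=n_ambiguous,
    )


@dataclass
class HumanizeResult:
    """A re-keyed DEG table plus the bookkeeping for dropped rows."""

    table: DEGTable
    unmapped_symbols: list[str]
    n_collision_dropped: int


def humanize(deg: DEGTable, gene_map: GeneIdMap) -> HumanizeResult:
    """Re-key a mouse DEG table to human gene IDs via a resolved map.

    Rows whose symbol is absent from the map are dropped and reported.  When
    two mouse genes resolve to the same human ID the row with the smaller
    P value is kept (preserving the strongest evidence keeps the table
    one-to-one, which the hypergeometric universes require).
    """
    d = deg.data
    mapped_ids = d["symbol"].map(gene_map.entries)
    unmapped = sorted(d.loc[mapped_ids.isna(), "symbol"].tolist())
    if unmapped:
        log.warning(
            "%s: %d symbols not in ortholog map", deg.comparison_label, len(unmapped)
        )
    kept = d[mapped_ids.notna()].copy()
    kept["gene_id"] = mapped_ids[mapped_ids.notna()].to_numpy()
    if kept.empty:
        log.warning("%s: no rows map to human IDs", deg.comparison_label)
        return HumanizeResult(DEGTable(deg.comparison_label, kept), unmapped, 0)

    # stable min-p winner per human ID; ties broken by original order
    kept = kept.sort_values("p_value", kind="mergesort")
    before = len(kept)
    dedup = kept.drop_duplicates(subset=["gene_id"], keep="first")
    n_coll = before - len(dedup)
    if n_coll:
        log.warning(
            "%s: %d rows dropped in many-mouse-to-one-human collisions",
            deg.comparison_label,
            n_coll,
        )
    dedup = dedup.sort_index().reset_index(drop=True)
    return HumanizeResult(DEGTable(deg.comparison_label, dedup), unmapped, n_coll)
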